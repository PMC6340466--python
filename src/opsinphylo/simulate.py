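"""Synthetic codon alignments with known ground truth.

Sequences are evolved along a tree by exact event-by-event (Gillespie)
sampling of the continuous-time Markov chain on the 61 sense codons, with a
transition/transversion ratio κ and a branch-specific dN/dS ratio ω.  Every
substitution event is recorded, so downstream stages (ancestral
reconstruction, substitution enumeration, ω estimation) can be checked
against the true history.

Loss-of-function is modelled two ways: :func:`inject_lesions` plants
frameshift indels and premature stops at stated coordinates, and
:func:`simulate_pseudogenization` switches a lineage to neutral evolution
(ω = 1, stop codons tolerated) at a stated time, the sudden-relaxation
regime used to date pseudogenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import (
    ALL_CODON_INDEX,
    ALL_CODONS,
    CODON_INDEX,
    SENSE_CODONS,
    STANDARD_CODE,
    CodonAlignment,
    SequenceRecord,
    TimeTree,
    is_transition,
    read_newick,
)

N_SENSE = len(SENSE_CODONS)
N_ALL = len(ALL_CODONS)


def name_nodes(tree: TimeTree) -> TimeTree:
    """Give every unnamed internal node a stable id ('n<postorder index>')."""
    for node in tree.nodes:
        if node.name is None:
            node.name = f"n{node.index}"
    return tree


@dataclass
class TrueHistory:
    """Ground truth of a simulation: per-branch substitution events
    ``(site, time, from_codon, to_codon)`` keyed by child-node name, and the
    full sequence at every node (ancestors included)."""

    events: dict
    node_sequences: dict


@dataclass
class SimulationSpec:
    tree: TimeTree
    kappa: float = 2.0
    omega: float = 0.2  # default for branches absent from omega_by_branch
    omega_by_branch: dict = field(default_factory=dict)  # branch name -> omega
    n_codons: int = 300
    codon_freqs: str = "uniform"  # {uniform, F1x4}
    nt_freqs: Optional[np.ndarray] = None  # TCAG order, for F1x4
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0 or any(w < 0 for w in self.omega_by_branch.values()):
            raise ValueError("omega must be >= 0")


def _codon_pi(spec: SimulationSpec, codons) -> np.ndarray:
    base_idx = {"T": 0, "C": 1, "A": 2, "G": 3}
    if spec.codon_freqs == "uniform":
        pi = np.ones(len(codons))
    elif spec.codon_freqs == "F1x4":
        if spec.nt_freqs is None:
            raise ValueError("F1x4 requires nt_freqs (TCAG order)")
        f = np.asarray(spec.nt_freqs, dtype=float)
        pi = np.array(
            [np.prod([f[base_idx[b]] for b in c]) for c in codons]
        )
    else:
        raise ValueError(f"unknown codon_freqs {spec.codon_freqs!r}")
    return pi / pi.sum()


def _mutation_matrix(kappa: float, pi: np.ndarray, codons) -> np.ndarray:
    """Single-nucleotide mutation rates a_ij = pi_j * kappa^(transition)."""
    n = len(codons)
    M = np.zeros((n, n))
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            M[i, j] = pi[j] * (kappa if is_transition(a, b) else 1.0)
    return M


def _generator(M: np.ndarray, omega_mask: Optional[np.ndarray], omega: float):
    Q = M.copy()
    if omega_mask is not None:
        Q[omega_mask] *= omega
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _nonsyn_mask(codons) -> np.ndarray:
    n = len(codons)
    mask = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i != j:
                mask[i, j] = STANDARD_CODE.table[ci] != STANDARD_CODE.table[cj]
    return mask


class _GillespieSampler:
    """Event-by-event CTMC sampling from a fixed generator."""

    def __init__(self, Q: np.ndarray):
        self.exit = -np.diag(Q).copy()
        jump = Q.copy()
        np.fill_diagonal(jump, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            jump = jump / jump.sum(axis=1, keepdims=True)
        self.cum = np.nan_to_num(np.cumsum(jump, axis=1))

    def evolve(self, state: int, duration: float, rng) -> tuple:
        """Final state and the (time, from, to) events along the way."""
        t, events = 0.0, []
        while True:
            rate = self.exit[state]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= duration:
                break
            nxt = int(np.searchsorted(self.cum[state], rng.random()))
            events.append((t, state, nxt))
            state = nxt
        return state, events


def simulate_codon_alignment(spec: SimulationSpec):
    """Evolve an alignment; returns (CodonAlignment, true_history).

    ``true_history`` maps branch name (child-node name) to the list of
    substitution events ``(site, time, from_codon, to_codon)``.  Branch
    lengths are in expected substitutions per codon site under each branch's
    own ω (the convention of the likelihood engine).
    """
    tree = name_nodes(spec.tree.copy())
    rng = np.random.default_rng(spec.seed)
    pi = _codon_pi(spec, SENSE_CODONS)
    M = _mutation_matrix(spec.kappa, pi, SENSE_CODONS)
    nonsyn = _nonsyn_mask(SENSE_CODONS)

    samplers = {}

    def sampler_for(omega: float) -> _GillespieSampler:
        if omega not in samplers:
            Q = _generator(M, nonsyn, omega)
            scale = -(pi * np.diag(Q)).sum()
            samplers[omega] = _GillespieSampler(Q / scale)
        return samplers[omega]

    root_states = rng.choice(N_SENSE, size=spec.n_codons, p=pi)
    states = {tree.root.index: root_states}
    history: dict = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        omega = spec.omega_by_branch.get(node.name, spec.omega)
        smp = sampler_for(omega)
        parent_states = states[node.parent.index]
        child = np.empty_like(parent_states)
        events = []
        for site in range(spec.n_codons):
            s, ev = smp.evolve(int(parent_states[site]), node.length, rng)
            child[site] = s
            events.extend(
                (site + 1, t, SENSE_CODONS[a], SENSE_CODONS[b]) for t, a, b in ev
            )
        states[node.index] = child
        history[node.name] = events

    records = [
        SequenceRecord(
            id=leaf.name,
            seq="".join(SENSE_CODONS[s] for s in states[leaf.index]),
            moltype="nt",
        )
        for leaf in tree.leaves()
    ]
    node_seqs = {
        node.name: "".join(SENSE_CODONS[s] for s in states[node.index])
        for node in tree.preorder()
    }
    return CodonAlignment(records), TrueHistory(history, node_seqs)


# ---------------------------------------------------------------------------
# Lesion injection


@dataclass
class LesionSpec:
    taxon: str
    kind: str  # {deletion, insertion, stop_substitution}
    position: int  # 1-based codon column
    length_nt: int = 1
    bases: Optional[str] = None  # inserted bases; default poly-A

    def __post_init__(self):
        if self.kind not in {"deletion", "insertion", "stop_substitution"}:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.length_nt < 1:
            raise ValueError("length_nt must be >= 1")
        if self.kind == "stop_substitution":
            self.length_nt = 3


def inject_lesions(alignment: CodonAlignment, lesions: list):
    """Apply lesions; returns (new alignment, ground-truth table).

    Deletions overwrite bases with gaps (length preserved); insertions add a
    gapped column block in all other rows; stop substitutions rewrite one
    codon to TAA.  Overlapping lesions on one taxon are an error.  The
    ground-truth table reports each lesion's codon column in the returned
    alignment's coordinates.
    """
    seqs = {r.id: list(r.seq) for r in alignment.records}
    n_nt = alignment.n_nt_columns
    spans = {}
    for les in lesions:
        if les.taxon not in seqs:
            raise ValueError(f"taxon {les.taxon!r} not in alignment")
        start = 3 * (les.position - 1)
        if les.position < 1 or start >= n_nt:
            raise ValueError(f"lesion position {les.position} outside alignment")
        end = start + (les.length_nt if les.kind != "insertion" else 0)
        if end > n_nt and les.kind == "deletion":
            raise ValueError("deletion runs past alignment end")
        for s, e in spans.setdefault(les.taxon, []):
            if start < e and s < max(end, start + 1):
                raise ValueError(f"overlapping lesions on {les.taxon!r}")
        spans[les.taxon].append((start, max(end, start + 1)))

    truth = []
    # insertions change coordinates; apply right-to-left, insertions last at
    # equal positions so earlier columns keep their indices
    ordered = sorted(
        lesions, key=lambda l: (-(l.position), l.kind == "insertion")
    )
    inserted_at: list = []  # (original nt offset, length) applied so far
    for les in ordered:
        start = 3 * (les.position - 1)
        if les.kind == "deletion":
            row = seqs[les.taxon]
            row[start : start + les.length_nt] = ["-"] * les.length_nt
        elif les.kind == "stop_substitution":
            row = seqs[les.taxon]
            row[start : start + 3] = list("TAA")
        else:  # insertion
            block = les.bases or "A" * les.length_nt
            if len(block) != les.length_nt:
                raise ValueError("bases length must equal length_nt")
            for taxon, row in seqs.items():
                ins = list(block) if taxon == les.taxon else ["-"] * les.length_nt
                seqs[taxon] = row[:start] + ins + row[start:]
            inserted_at.append((start, les.length_nt))
        truth.append(
            {
                "taxon": les.taxon,
                "kind": les.kind,
                "codon_column": les.position,
                "length_nt": les.length_nt,
                "causes_frameshift": les.kind != "stop_substitution"
                and les.length_nt % 3 != 0,
            }
        )
    # shift ground-truth columns for insertions applied to their left
    for row in truth:
        start = 3 * (row["codon_column"] - 1)
        shift = sum(l for s, l in inserted_at if s < start)
        row["codon_column"] = (start + shift) // 3 + 1
    new_len = len(next(iter(seqs.values())))
    pad = (3 - new_len % 3) % 3  # frameshift insertions break codon framing
    records = [
        SequenceRecord(id=r.id, seq="".join(seqs[r.id]) + "-" * pad, moltype="nt")
        for r in alignment.records
    ]
    return CodonAlignment(records, code=alignment.code), truth


# ---------------------------------------------------------------------------
# Sudden-relaxation pseudogenization


def simulate_pseudogenization(
    spec: SimulationSpec,
    loss_events: dict,
    rate: float = 0.01,
    inject_stop: bool = True,
):
    """Evolve under constraint, then neutrally after each lineage's loss time.

    ``spec.tree`` must be a calibrated time tree (branch lengths in My);
    ``loss_events`` maps a tip name to its loss age in Ma before present.
    ``rate`` is the neutral substitution rate in expected substitutions per
    codon site per My, shared by all branches, so the synonymous clock is
    constant and dN scales with ω — the sudden-relaxation model's premises.

    Before loss a lineage evolves on the 61 sense codons at the background ω;
    after loss the chain runs on all 64 codons with no selection (stops
    tolerated and sense↔sense changes neutral).  A premature stop is injected
    at a deterministic-by-seed codon if none arose by the present.

    Returns (alignment, true_T_p, history) where ``true_T_p`` maps lineage to
    its time since relaxation in My.
    """
    tree = name_nodes(spec.tree.copy())
    ages = tree.node_ages()
    for tip, loss_age in loss_events.items():
        node = tree.find(tip)
        root_age = ages[tree.root]
        if not (0.0 <= loss_age <= root_age):
            raise ValueError(
                f"loss age {loss_age} outside the root-to-tip span of {tip!r}"
            )
    rng = np.random.default_rng(spec.seed)
    pi61 = _codon_pi(spec, SENSE_CODONS)
    pi64 = _codon_pi(spec, ALL_CODONS)
    M61 = _mutation_matrix(spec.kappa, pi61, SENSE_CODONS)
    M64 = _mutation_matrix(spec.kappa, pi64, ALL_CODONS)
    nonsyn = _nonsyn_mask(SENSE_CODONS)
    # neutral clock: scale everything by the neutral 61-state rate
    Q_neutral = _generator(M61, None, 1.0)
    s_neutral = -(pi61 * np.diag(Q_neutral)).sum()

    samplers61 = {}

    def sampler61(omega: float) -> _GillespieSampler:
        if omega not in samplers61:
            Q = _generator(M61, nonsyn, omega)
            samplers61[omega] = _GillespieSampler(rate * Q / s_neutral)
        return samplers61[omega]

    Q64 = _generator(M64, None, 1.0)
    sampler64 = _GillespieSampler(rate * Q64 / s_neutral)

    # a lineage is "lost" on the path to any tip in loss_events once the age
    # drops below that tip's loss age
    lost_tips = set(loss_events)

    def tips_below(node):
        return {t.name for t in tree.tips_below(node)}

    root_states = rng.choice(N_SENSE, size=spec.n_codons, p=pi61)
    # promote to the 64-codon index space (shared by both regimes)
    to64 = np.array([ALL_CODON_INDEX[c] for c in SENSE_CODONS])
    states = {tree.root.index: to64[root_states]}
    history: dict = {}
    stop_idx = {ALL_CODON_INDEX[c] for c in STANDARD_CODE.stop_codons}
    from61 = {ALL_CODON_INDEX[c]: CODON_INDEX[c] for c in SENSE_CODONS}

    for node in tree.preorder():
        if node is tree.root:
            continue
        below = tips_below(node)
        relevant = below & lost_tips
        start_age = ages[node.parent]
        end_age = ages[node]
        # loss applies on a branch only when every tip below it is lost;
        # branches ancestral to any functional tip stay constrained
        loss_age = None
        if relevant and below <= lost_tips:
            loss_age = max(loss_events[t] for t in relevant)
        omega = spec.omega_by_branch.get(node.name, spec.omega)
        parent_states = states[node.parent.index]
        child = parent_states.copy()
        events = []

        def run(segment_states, duration, sampler, codons, offset_age):
            for site in range(spec.n_codons):
                s, ev = sampler.evolve(int(segment_states[site]), duration, rng)
                segment_states[site] = s
                events.extend(
                    (site + 1, offset_age - t, codons[a], codons[b])
                    for t, a, b in ev
                )

        if loss_age is None or loss_age <= end_age:
            # fully functional branch
            seg = np.array([from61[s] for s in child])
            run(seg, start_age - end_age, sampler61(omega), SENSE_CODONS, start_age)
            child = to64[seg]
        elif loss_age >= start_age:
            # fully neutral branch
            run(child, start_age - end_age, sampler64, ALL_CODONS, start_age)
        else:
            # branch split internally at the loss time; the pseudogenizing
            # stop arises at that moment and is inherited by all descendants
            seg = np.array([from61[s] for s in child])
            run(seg, start_age - loss_age, sampler61(omega), SENSE_CODONS, start_age)
            child = to64[seg]
            if inject_stop:
                col = int(rng.integers(0, spec.n_codons))
                child[col] = ALL_CODON_INDEX["TAA"]
            run(child, loss_age - end_age, sampler64, ALL_CODONS, loss_age)
        states[node.index] = child
        history[node.name] = events

    # inject a premature stop on lost tips that acquired none
    lesion_truth = []
    for tip in sorted(lost_tips):
        leaf = tree.find(tip)
        tip_states = states[leaf.index]
        if inject_stop and not any(int(s) in stop_idx for s in tip_states):
            col = int(rng.integers(0, max(spec.n_codons - 1, 1)))
            tip_states[col] = ALL_CODON_INDEX["TAA"]
            lesion_truth.append(
                {"taxon": tip, "kind": "stop_substitution", "codon_column": col + 1}
            )

    records = [
        SequenceRecord(
            id=leaf.name,
            seq="".join(ALL_CODONS[s] for s in states[leaf.index]),
            moltype="nt",
        )
        for leaf in tree.leaves()
    ]
    true_tp = {tip: float(loss_events[tip]) for tip in loss_events}
    node_seqs = {
        node.name: "".join(ALL_CODONS[s] for s in states[node.index])
        for node in tree.preorder()
    }
    return CodonAlignment(records), true_tp, TrueHistory(history, node_seqs)


# ---------------------------------------------------------------------------
# Fixture presets: 12-taxon trees mirroring the bat contrast groups (one
# clade of high-duty-cycle echolocators, two cave-roosting lineages)

_PRESET_NEWICK = {
    "pteropodid-like": (
        "(((hdc1:4,hdc2:4):4,((hdc3:3,hdc4:3):3,out1:6):2):12,"
        "(((cave1:6,cave2:6):6,(tree1:8,tree2:8):4):6,"
        "((tree3:9,cave3:9):5,tree4:14):4):2);"
    ),
    "mormoopid-like": (
        "((((hdc1:3,hdc2:3):3,(hdc3:4,hdc4:4):2):6,out1:12):8,"
        "(((cave1:5,cave2:5):5,tree1:10):6,((tree2:7,cave3:7):5,"
        "(tree3:8,tree4:8):4):4):4);"
    ),
}

PRESET_TAGS = {
    name: {
        **{t: {"HDC"} for t in ("hdc1", "hdc2", "hdc3", "hdc4")},
        **{t: {"cave"} for t in ("cave1", "cave2", "cave3")},
    }
    for name in _PRESET_NEWICK
}


def preset_tree(name: str = "pteropodid-like") -> TimeTree:
    """A bundled 12-taxon calibrated tree (branch lengths in My) with
    HDC-tagged and cave-tagged lineages for end-to-end exercises."""
    if name not in _PRESET_NEWICK:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(_PRESET_NEWICK)}")
    tree = read_newick(_PRESET_NEWICK[name], units="My")
    name_nodes(tree)
    tags = PRESET_TAGS[name]
    for leaf in tree.leaves():
        leaf.tags |= tags.get(leaf.name, set())
    return tree
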