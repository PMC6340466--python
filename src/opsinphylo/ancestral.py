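"""Ancestral amino-acid reconstruction and convergence detection.

Two reconstruction routes: two-pass Fitch parsimony (ambiguity carried as
state sets) and marginal maximum likelihood under a uniform-rate Poisson
model (pluggable exchangeability matrix), with per-node posterior
distributions from the standard inside–outside computation.  Substitutions
are enumerated branch-wise from parent/child state differences, and a branch
pair's shared changed sites are split into convergent (same derived state)
and divergent (different derived states) classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .io import TimeTree
from .selection import _Propagator

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
N_AA = 20
MISSING = set("-X?*BZJUO")


@dataclass
class AncestralStates:
    """Per-node reconstructed sequences over a fixed site list.

    ``states[node]`` is a string (one deterministic representative per site,
    '?' where unresolved); ``state_sets`` carries full Fitch ambiguity sets;
    ``posteriors[node]`` is an (n_sites × 20) array for the ML method.
    """

    method: str
    n_sites: int
    states: dict
    state_sets: dict = field(default_factory=dict)
    posteriors: dict = field(default_factory=dict)
    change_count: Optional[int] = None
    skipped_sites: list = field(default_factory=list)


def _tip_state_matrix(tip_states: dict, n_sites: int) -> dict:
    out = {}
    for taxon, seq in tip_states.items():
        if len(seq) != n_sites:
            raise ValueError(f"sequence length mismatch for {taxon!r}")
        out[taxon] = [
            None if c.upper() in MISSING else c.upper() for c in seq
        ]
        for c in out[taxon]:
            if c is not None and c not in AA_INDEX:
                raise ValueError(f"invalid amino acid {c!r} in {taxon!r}")
    return out


def fitch_parsimony(tree: TimeTree, tip_states: dict) -> AncestralStates:
    """Two-pass Fitch parsimony, site by site.

    Gaps/'X' are missing data (full state set, no cost).  Sites with fewer
    than two observed tips are skipped ('?' everywhere, listed in
    ``skipped_sites``).  ``change_count`` is the summed parsimony score; on
    binary trees it equals the exhaustive minimum.  The deterministic
    representative at ambiguous nodes is the alphabetically first member of
    the final state set, after the top-down pass prefers the parent's state.
    """
    n_sites = len(next(iter(tip_states.values())))
    tips = _tip_state_matrix(tip_states, n_sites)
    for leaf in tree.leaves():
        if leaf.name not in tips:
            raise ValueError(f"no states for tip {leaf.name!r}")
    full = frozenset(AA_ALPHABET)
    states = {n.name: [] for n in tree.nodes}
    state_sets = {}
    total_changes = 0
    skipped = []
    for s in range(n_sites):
        observed = [
            tips[l.name][s] for l in tree.leaves() if tips[l.name][s] is not None
        ]
        if len(observed) < 2:
            skipped.append(s + 1)
            for n in tree.nodes:
                obs = tips[n.name][s] if n.is_leaf else None
                states[n.name].append(obs or "?")
            continue
        down: dict = {}
        for node in tree.nodes:  # postorder
            if node.is_leaf:
                c = tips[node.name][s]
                down[node.index] = frozenset(c) if c is not None else full
                continue
            acc = None
            for child in node.children:
                cs = down[child.index]
                if acc is None:
                    acc = cs
                else:
                    inter = acc & cs
                    if inter:
                        acc = inter
                    else:
                        acc = acc | cs
                        total_changes += 1
            down[node.index] = acc
        # top-down refinement
        final: dict = {}
        for node in tree.preorder():
            cand = down[node.index]
            if node is tree.root:
                pick = min(cand)
            else:
                parent_state = final[node.parent.index]
                pick = parent_state if parent_state in cand else min(cand)
            final[node.index] = pick
            states[node.name].append(
                tips[node.name][s] or "?" if node.is_leaf else pick
            )
            state_sets[(node.name, s + 1)] = cand
    return AncestralStates(
        method="fitch",
        n_sites=n_sites,
        states={k: "".join(v) for k, v in states.items()},
        state_sets=state_sets,
        change_count=total_changes,
        skipped_sites=skipped,
    )


# ---------------------------------------------------------------------------
# Marginal ML reconstruction


def _poisson_propagator() -> _Propagator:
    pi = np.full(N_AA, 1.0 / N_AA)
    Q = np.full((N_AA, N_AA), 1.0 / 19.0)
    np.fill_diagonal(Q, -1.0)
    return _Propagator(Q, pi), pi


def _matrix_propagator(Q: np.ndarray, pi: np.ndarray) -> _Propagator:
    scale = -(pi * np.diag(Q)).sum()
    return _Propagator(Q / scale, pi), pi


def marginal_ml_reconstruction(
    tree: TimeTree,
    tip_states: dict,
    model: Union[str, tuple] = "poisson",
) -> AncestralStates:
    """Marginal posterior reconstruction by inside–outside pruning.

    ``model`` is ``"poisson"`` (equal rates and frequencies; the default when
    no empirical matrix is preferred) or a ``(Q, pi)`` pair of a reversible
    20-state generator and its stationary distribution.  Branch lengths are
    expected substitutions/site.  Tip states are fixed to the observations;
    the reported state per node/site is the posterior argmax with alphabetical
    tie-breaking.
    """
    n_sites = len(next(iter(tip_states.values())))
    tips = _tip_state_matrix(tip_states, n_sites)
    if model == "poisson":
        prop, pi = _poisson_propagator()
    else:
        prop, pi = _matrix_propagator(*model)

    nodes = tree.nodes  # postorder
    P = {}
    for node in nodes:
        if node is not tree.root:
            P[node.index] = prop.probability_matrix(max(node.length, 0.0))

    eye = np.eye(N_AA)
    up: dict = {}
    for node in nodes:
        if node.is_leaf:
            L = np.ones((n_sites, N_AA))
            for s in range(n_sites):
                c = tips[node.name][s]
                if c is not None:
                    L[s] = eye[AA_INDEX[c]]
            up[node.index] = L
        else:
            L = np.ones((n_sites, N_AA))
            for child in node.children:
                L = L * (up[child.index] @ P[child.index].T)
            mx = L.max(axis=1, keepdims=True)
            mx[mx == 0] = 1.0
            up[node.index] = L / mx  # rescale; posteriors are ratios

    down: dict = {tree.root.index: np.tile(pi, (n_sites, 1))}
    for node in tree.preorder():
        for child in node.children:
            msg = down[node.index].copy()
            for sib in node.children:
                if sib is child:
                    continue
                msg = msg * (up[sib.index] @ P[sib.index].T)
            down[child.index] = msg @ P[child.index]
            mx = down[child.index].max(axis=1, keepdims=True)
            mx[mx == 0] = 1.0
            down[child.index] /= mx

    states, posteriors = {}, {}
    for node in nodes:
        post = up[node.index] * down[node.index]
        norm = post.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        post = post / norm
        posteriors[node.name] = post
        if node.is_leaf:
            chars = [
                tips[node.name][s] or AA_ALPHABET[int(post[s].argmax())]
                for s in range(n_sites)
            ]
        else:
            # argmax with alphabetical tie-break (argmax returns first max)
            chars = [AA_ALPHABET[int(post[s].argmax())] for s in range(n_sites)]
        states[node.name] = "".join(chars)
    return AncestralStates(
        method="marginal_ml",
        n_sites=n_sites,
        states=states,
        posteriors=posteriors,
    )


# ---------------------------------------------------------------------------
# Substitution events and convergence


@dataclass(frozen=True)
class SubstitutionEvent:
    branch: str  # child-node name
    site: int  # 1-based
    from_state: str
    to_state: str


def enumerate_substitutions(
    states: AncestralStates, tree: TimeTree
) -> list:
    """One event per (branch, site) where the reconstructed parent and child
    representatives differ; unresolved ('?') states yield no events."""
    events = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_seq = states.states[node.parent.name]
        child_seq = states.states[node.name]
        for s, (a, b) in enumerate(zip(parent_seq, child_seq), start=1):
            if a != b and a != "?" and b != "?":
                events.append(
                    SubstitutionEvent(
                        branch=node.name, site=s, from_state=a, to_state=b
                    )
                )
    return events


@dataclass
class ConvergenceReport:
    branch_pair: tuple
    convergent_sites: list
    divergent_sites: list

    @property
    def n_convergent(self) -> int:
        return len(self.convergent_sites)

    @property
    def n_divergent(self) -> int:
        return len(self.divergent_sites)


def detect_convergence(
    events: Sequence[SubstitutionEvent],
    branch_pair: tuple,
    tree: TimeTree,
) -> ConvergenceReport:
    """Classify sites substituted on both branches of a pair.

    Sites where both branches end in the same derived amino acid are
    convergent; different derived states are divergent.  The branches must be
    distinct and neither ancestral to the other (the comparison is undefined
    on a single evolutionary path).
    """
    a, b = branch_pair
    if a == b:
        raise ValueError("branch pair must be two distinct branches")
    na, nb = tree.find(a), tree.find(b)
    if tree.is_ancestor(na, nb) or tree.is_ancestor(nb, na):
        raise ValueError(f"branches {a!r} and {b!r} are nested")
    changed = {a: {}, b: {}}
    for ev in events:
        if ev.branch in changed:
            changed[ev.branch][ev.site] = ev.to_state
    shared = sorted(set(changed[a]) & set(changed[b]))
    convergent = [s for s in shared if changed[a][s] == changed[b][s]]
    divergent = [s for s in shared if changed[a][s] != changed[b][s]]
    return ConvergenceReport(
        branch_pair=(a, b),
        convergent_sites=convergent,
        divergent_sites=divergent,
    )
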