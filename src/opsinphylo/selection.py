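"""dN/dS estimation under codon substitution models.

Two routes to ω are provided: the NG86-style counting estimator
(:func:`count_dnds`) and maximum likelihood under a GY-class codon model
(:func:`fit_model`) with Felsenstein pruning over site patterns.  Supported
models: M0 (one ratio), two-ratio and free-ratio branch models, and the
M1a/M2a/M7/M8 site-mixture models, compared by likelihood-ratio tests.

The rate matrix acts on the 61 sense codons of the standard code:

    q_ij = 0                         more than one nucleotide change
         = pi_j                      synonymous transversion
         = kappa * pi_j              synonymous transition
         = omega * pi_j              nonsynonymous transversion
         = omega * kappa * pi_j      nonsynonymous transition

scaled so one unit of branch length is one expected substitution per codon
site at the model's stationary distribution.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .io import (
    CODON_INDEX,
    SENSE_CODONS,
    STANDARD_CODE,
    CodonAlignment,
    GeneticCode,
    TimeTree,
    is_transition,
)

N_STATES = len(SENSE_CODONS)  # 61

# -- structural masks over the 61x61 state space, computed once -------------


def _build_masks():
    n = N_STATES
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = is_transition(a, b)
            nonsyn[i, j] = (
                STANDARD_CODE.table[ci] != STANDARD_CODE.table[cj]
            )
    return single, transition, nonsyn


_SINGLE, _TRANSITION, _NONSYN = _build_masks()


def codon_frequencies(
    alignment: Optional[CodonAlignment] = None, method: str = "F1x4"
) -> np.ndarray:
    """Equilibrium codon frequencies over the 61 sense codons.

    ``uniform`` ignores the data; ``F1x4`` builds codon frequencies from the
    empirical nucleotide composition; ``F3x4`` from position-specific
    composition.  Stop codons are excluded and the vector renormalized.
    """
    if method == "uniform":
        return np.full(N_STATES, 1.0 / N_STATES)
    if alignment is None:
        raise ValueError(f"{method} frequencies require an alignment")
    counts = np.zeros((3, 4))
    base_idx = {"T": 0, "C": 1, "A": 2, "G": 3}
    for rec in alignment.records:
        s = rec.seq.upper()
        for i, b in enumerate(s):
            if b in base_idx:
                counts[i % 3, base_idx[b]] += 1
    counts += 1e-9
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    overall = counts.sum(axis=0) / counts.sum()
    pi = np.empty(N_STATES)
    for k, codon in enumerate(SENSE_CODONS):
        p = 1.0
        for pos, b in enumerate(codon):
            p *= pos_freqs[pos, base_idx[b]] if method == "F3x4" else overall[base_idx[b]]
        pi[k] = p
    return pi / pi.sum()


def build_rate_matrix(
    kappa: float, omega: float, codon_freqs: np.ndarray
) -> np.ndarray:
    """GY-class 61×61 generator, scaled to 1 expected substitution/site."""
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (N_STATES,) or abs(pi.sum() - 1.0) > 1e-8 or (pi < 0).any():
        raise ValueError("codon_freqs must be a distribution over 61 sense codons")
    rate = np.where(_SINGLE, pi[None, :], 0.0)
    rate = np.where(_TRANSITION, kappa * rate, rate)
    rate = np.where(_NONSYN, omega * rate, rate)
    np.fill_diagonal(rate, 0.0)
    np.fill_diagonal(rate, -rate.sum(axis=1))
    scale = -(pi * np.diag(rate)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return rate / scale


class _Propagator:
    """Eigendecomposition of a reversible Q for cheap P(t) evaluation."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
        B = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        B = 0.5 * (B + B.T)
        self.evals, self.evecs = np.linalg.eigh(B)
        self.left = self.evecs / sqrt_pi[:, None]
        self.right = self.evecs * sqrt_pi[:, None]

    def probability_matrix(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.evals * t)) @ self.right.T
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# Alignment preprocessing


def strip_indel_codons(
    alignment: CodonAlignment,
    remove_stop_columns: bool = True,
    remove_ambiguous: bool = True,
):
    """Drop every codon column with a gap (and, optionally, a stop or an
    ambiguous base) in any retained sequence.

    Returns the stripped alignment and a removal log of
    ``(codon_column, reason)`` pairs (1-based columns).
    """
    code = alignment.code
    keep, log = [], []
    rows = [alignment.codons(t) for t in alignment.ids]
    for c in range(alignment.n_codon_columns):
        reason = None
        for row in rows:
            codon = row[c].upper()
            if alignment.gap_char in codon:
                reason = "gap"
                break
            if any(b not in "ACGT" for b in codon):
                if remove_ambiguous:
                    reason = "ambiguous"
                    break
            elif codon in code.stop_codons and remove_stop_columns:
                reason = "stop"
                break
        if reason is None:
            keep.append(c)
        else:
            log.append((c + 1, reason))
    if not keep:
        raise ValueError("all codon columns removed by indel stripping")
    from .io import SequenceRecord

    records = [
        SequenceRecord(
            id=t, seq="".join(row[c] for c in keep), moltype="nt"
        )
        for t, row in zip(alignment.ids, rows)
    ]
    return CodonAlignment(records, code=code, gap_char=alignment.gap_char), log


# ---------------------------------------------------------------------------
# NG86 counting estimator


@dataclass
class CountingResult:
    N: float
    S: float
    Nd: float
    Sd: float
    dN: Optional[float]
    dS: Optional[float]
    omega: Optional[float]
    note: str = ""


def _syn_fraction(codon: str, code: GeneticCode) -> tuple:
    """Per-position synonymous site fractions; stops excluded from the
    denominator so every position contributes exactly one site."""
    fracs = []
    aa = code.table[codon]
    for pos in range(3):
        syn = valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in code.stop_codons:
                continue
            valid += 1
            if code.table[mut] == aa:
                syn += 1
        fracs.append(syn / valid if valid else 0.0)
    return tuple(fracs)


def _pathway_counts(ca: str, cb: str, code: GeneticCode) -> tuple:
    """Average synonymous/nonsynonymous step counts over minimal mutational
    pathways between two codons, excluding pathways through stop codons."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in itertools.permutations(diff_pos):
        cur, sd, nd, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in code.stop_codons:
                ok = False
                break
            if code.table[cur] == code.table[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # all pathways hit a stop; fall back to including them
        for order in itertools.permutations(diff_pos):
            cur, sd, nd = ca, 0, 0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if code.table.get(cur, "*") == code.table.get(nxt, "*"):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> Optional[float]:
    if p <= 0:
        return 0.0
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def count_dnds(
    seq_a: str, seq_b: str, code: GeneticCode = STANDARD_CODE
) -> CountingResult:
    """NG86 pairwise dN/dS with Jukes–Cantor correction.

    Codon pairs where either codon is not a sense codon (gap, ambiguity) are
    skipped; an internal stop codon is an error — strip disrupted columns
    first.
    """
    if len(seq_a) != len(seq_b) or len(seq_a) % 3:
        raise ValueError("sequences must be equal-length codon sequences")
    S = N = Sd = Nd = 0.0
    compared = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        clean_a = all(b in "ACGT" for b in ca)
        clean_b = all(b in "ACGT" for b in cb)
        for codon, clean in ((ca, clean_a), (cb, clean_b)):
            if clean and codon in code.stop_codons and i + 3 < len(seq_a):
                raise ValueError(f"internal stop codon {codon} at nt {i+1}")
        if not (clean_a and clean_b) or ca in code.stop_codons or cb in code.stop_codons:
            continue
        compared += 1
        sa, sb = _syn_fraction(ca, code), _syn_fraction(cb, code)
        S += (sum(sa) + sum(sb)) / 2
        N += 3 - (sum(sa) + sum(sb)) / 2
        if ca != cb:
            sd, nd = _pathway_counts(ca, cb, code)
            Sd += sd
            Nd += nd
    if compared == 0:
        raise ValueError("no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = _jukes_cantor(pS), _jukes_cantor(pN)
    omega, note = None, ""
    if dS is None or dN is None:
        note = "substitution saturation (p >= 3/4)"
    elif dS == 0:
        note = "dS = 0; omega undefined"
    else:
        omega = dN / dS
    return CountingResult(N=N, S=S, Nd=Nd, Sd=Sd, dN=dN, dS=dS, omega=omega, note=note)


# ---------------------------------------------------------------------------
# Maximum likelihood engine

BRANCH_MODELS = {"M0", "two-ratio", "free-ratio", "labels"}
SITE_MODELS = {"M1a", "M2a", "M7", "M8"}


@dataclass
class CodonModelSpec:
    model_id: str
    codon_freqs: str = "F1x4"
    kappa: Optional[float] = None  # None: estimated
    foreground_tag: Optional[str] = None  # two-ratio
    branch_label_map: Optional[dict] = None  # "labels": branch name -> label str
    n_beta_categories: int = 10  # M7/M8 discretization
    fix_branch_lengths: bool = False
    n_starts: int = 3
    seed: int = 0
    init_omega: float = 0.4
    max_iter: int = 500

    def __post_init__(self):
        if self.model_id not in BRANCH_MODELS | SITE_MODELS:
            raise ValueError(f"unknown model {self.model_id!r}")
        if self.model_id == "two-ratio" and not self.foreground_tag:
            raise ValueError("two-ratio model needs a foreground_tag")
        if self.model_id == "labels" and not self.branch_label_map:
            raise ValueError("labels model needs a branch_label_map")


@dataclass
class FitResult:
    model_id: str
    lnL: float
    np: int
    estimates: dict
    tree: TimeTree
    converged: bool
    site_lnL: Optional[np.ndarray] = None
    site_class_posterior: Optional[np.ndarray] = None
    message: str = ""


@dataclass
class LRTResult:
    twice_delta: float
    df: int
    p_value: float
    warning: str = ""


def _encode_alignment(alignment: CodonAlignment, taxa: Sequence[str]):
    """Codon-state matrix (taxa × columns; −1 = missing) and site patterns."""
    mat = np.full((len(taxa), alignment.n_codon_columns), -1, dtype=np.int64)
    for ti, taxon in enumerate(taxa):
        for c, codon in enumerate(alignment.codons(taxon)):
            codon = codon.upper()
            idx = CODON_INDEX.get(codon)
            if idx is not None:
                mat[ti, c] = idx
            elif all(b in "ACGT" for b in codon):
                raise ValueError(
                    f"stop codon {codon} in {taxon} at codon column {c + 1}; "
                    "run strip_indel_codons first"
                )
    patterns, inverse, counts = np.unique(
        mat, axis=1, return_inverse=True, return_counts=True
    )
    return mat, patterns, inverse, counts


class _Pruner:
    """Felsenstein pruning over compressed site patterns on a fixed tree."""

    def __init__(self, tree: TimeTree, patterns: np.ndarray, taxa: Sequence[str]):
        self.tree = tree
        self.nodes = tree.nodes  # postorder
        self.taxon_row = {t: i for i, t in enumerate(taxa)}
        self.n_patterns = patterns.shape[1]
        # leaf partials: one-hot, or ones for missing states
        self.leaf_partials = {}
        eye = np.eye(N_STATES)
        for node in self.nodes:
            if node.is_leaf:
                states = patterns[self.taxon_row[node.name]]
                L = np.where(
                    (states >= 0)[:, None], eye[np.maximum(states, 0)], 1.0
                )
                self.leaf_partials[node.index] = L

    def pattern_likelihoods(
        self, props: dict, branch_lengths: np.ndarray, pi: np.ndarray,
        branch_class: dict,
    ) -> np.ndarray:
        """Per-pattern likelihood; props maps class id -> _Propagator.

        branch_class maps node.index -> class id; branch_lengths indexed by
        node.index.  Returns (n_patterns,) of log-likelihood contributions.
        """
        partials = {}
        logscale = np.zeros(self.n_patterns)
        for node in self.nodes:
            if node.is_leaf:
                partials[node.index] = self.leaf_partials[node.index]
                continue
            L = np.ones((self.n_patterns, N_STATES))
            for child in node.children:
                P = props[branch_class[child.index]].probability_matrix(
                    branch_lengths[child.index]
                )
                L = L * (partials[child.index] @ P.T)
            mx = L.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            L /= mx[:, None]
            logscale += np.log(mx)
            partials[node.index] = L
        root_lik = partials[self.tree.root.index] @ pi
        return np.log(np.maximum(root_lik, 1e-300)) + logscale


def _beta_category_omegas(p: float, q: float, k: int) -> np.ndarray:
    """Medians of K equal-probability bins of Beta(p, q)."""
    quantiles = (2 * np.arange(k) + 1) / (2 * k)
    return stats.beta.ppf(quantiles, p, q)


class _ModelParameterization:
    """Maps a flat parameter vector to (class omegas+weights, branch labels)."""

    def __init__(self, spec: CodonModelSpec, tree: TimeTree):
        self.spec = spec
        self.tree = tree
        m = spec.model_id
        self.names: list = []
        self.bounds: list = []
        self.init: list = []
        if spec.kappa is None:
            self._add("kappa", 2.0, (0.2, 50.0))
        # branch labelling: node.index -> omega-label (branch models)
        self.branch_label = {}
        nodes = [n for n in tree.nodes if n is not tree.root]
        if m == "M0":
            self._add("omega", spec.init_omega, (1e-4, 20.0))
            for n in nodes:
                self.branch_label[n.index] = 0
        elif m == "two-ratio":
            self._add("omega_background", spec.init_omega, (1e-4, 20.0))
            self._add("omega_foreground", spec.init_omega, (1e-4, 20.0))
            tag = spec.foreground_tag
            for n in nodes:
                self.branch_label[n.index] = 1 if tag in n.tags else 0
        elif m == "labels":
            # one omega per distinct label, e.g. the four loss-era categories
            labels = sorted(set(spec.branch_label_map.values()))
            self.label_order = labels
            for lab in labels:
                self._add(f"omega_{lab}", spec.init_omega, (1e-4, 20.0))
            for n in nodes:
                lab = spec.branch_label_map.get(n.name)
                if lab is None:
                    raise ValueError(f"branch {n.name!r} missing from label map")
                self.branch_label[n.index] = labels.index(lab)
        elif m == "free-ratio":
            for i, n in enumerate(nodes):
                self._add(f"omega_b{i}", spec.init_omega, (1e-4, 20.0))
                self.branch_label[n.index] = i
        else:  # site models: all branches share classes
            for n in nodes:
                self.branch_label[n.index] = 0
            if m == "M1a":
                self._add("p0", 0.7, (1e-6, 1 - 1e-6))
                self._add("omega0", 0.2, (1e-4, 1.0))
            elif m == "M2a":
                self._add("p0", 0.7, (1e-6, 1 - 1e-6))
                self._add("p1_frac", 0.5, (1e-6, 1 - 1e-6))
                self._add("omega0", 0.2, (1e-4, 1.0))
                self._add("omega2", 2.0, (1.0, 50.0))
            elif m == "M7":
                self._add("beta_p", 0.5, (0.005, 99.0))
                self._add("beta_q", 1.5, (0.005, 99.0))
            elif m == "M8":
                self._add("p0", 0.9, (1e-6, 1 - 1e-6))
                self._add("beta_p", 0.5, (0.005, 99.0))
                self._add("beta_q", 1.5, (0.005, 99.0))
                self._add("omega_s", 2.0, (1.0, 50.0))

    def _add(self, name: str, init: float, bounds: tuple) -> None:
        self.names.append(name)
        self.init.append(init)
        self.bounds.append(bounds)

    @property
    def n_model_params(self) -> int:
        return len(self.names)

    def unpack(self, x: np.ndarray) -> dict:
        vals = dict(zip(self.names, x))
        if self.spec.kappa is not None:
            vals["kappa"] = self.spec.kappa
        return vals

    def classes(self, vals: dict):
        """(omegas per class-label, weights per class) for the mixture.

        Branch models: one class (weight 1) but one omega per branch label.
        Site models: one branch label, several classes with weights.
        """
        m = self.spec.model_id
        if m == "M0":
            return [vals["omega"]], np.array([1.0]), "branch"
        if m == "two-ratio":
            return (
                [vals["omega_background"], vals["omega_foreground"]],
                np.array([1.0]),
                "branch",
            )
        if m == "labels":
            return (
                [vals[f"omega_{lab}"] for lab in self.label_order],
                np.array([1.0]),
                "branch",
            )
        if m == "free-ratio":
            k = len([n for n in self.names if n.startswith("omega_b")])
            return [vals[f"omega_b{i}"] for i in range(k)], np.array([1.0]), "branch"
        if m == "M1a":
            return [vals["omega0"], 1.0], np.array(
                [vals["p0"], 1 - vals["p0"]]
            ), "site"
        if m == "M2a":
            p0 = vals["p0"]
            p1 = (1 - p0) * vals["p1_frac"]
            p2 = 1 - p0 - p1
            return [vals["omega0"], 1.0, vals["omega2"]], np.array(
                [p0, p1, p2]
            ), "site"
        if m == "M7":
            k = self.spec.n_beta_categories
            om = _beta_category_omegas(vals["beta_p"], vals["beta_q"], k)
            return list(om), np.full(k, 1.0 / k), "site"
        if m == "M8":
            k = self.spec.n_beta_categories
            om = list(
                _beta_category_omegas(vals["beta_p"], vals["beta_q"], k)
            ) + [vals["omega_s"]]
            w = np.concatenate(
                [np.full(k, vals["p0"] / k), [1 - vals["p0"]]]
            )
            return om, w, "site"
        raise AssertionError(m)


def fit_model(
    alignment: CodonAlignment,
    tree: TimeTree,
    spec: CodonModelSpec,
    export_site_lnL: bool = False,
) -> FitResult:
    """Fit a codon model by maximum likelihood.

    Branch lengths come from the input tree and are re-optimized unless
    ``spec.fix_branch_lengths``.  Multi-start optimization (``n_starts``
    L-BFGS-B runs from jittered initial points) guards against local optima;
    a fit that never converges is returned flagged, not silently.
    """
    tree = tree.copy()
    taxa = alignment.ids
    tip_set = set(tree.tip_labels)
    if set(taxa) != tip_set:
        missing = set(taxa) ^ tip_set
        raise ValueError(f"alignment/tree taxon mismatch: {sorted(missing)}")
    _, patterns, inverse, counts = _encode_alignment(alignment, taxa)
    pi = codon_frequencies(alignment, spec.codon_freqs)
    pruner = _Pruner(tree, patterns, taxa)
    par = _ModelParameterization(spec, tree)

    branch_nodes = [n for n in tree.nodes if n is not tree.root]
    init_bl = np.array([max(n.length, 1e-4) for n in branch_nodes])
    if not spec.fix_branch_lengths:
        bl_bounds = [(1e-6, 30.0)] * len(branch_nodes)
    bl_index = {n.index: i for i, n in enumerate(branch_nodes)}

    n_patterns = patterns.shape[1]
    cache: dict = {}

    def site_log_liks(x: np.ndarray) -> np.ndarray:
        vals = par.unpack(x[: par.n_model_params])
        if spec.fix_branch_lengths:
            bl = init_bl
        else:
            bl = x[par.n_model_params :]
        omegas, weights, kind = par.classes(vals)
        kappa = vals["kappa"]
        bls = np.zeros(max(bl_index) + 1 if bl_index else 1)
        for idx, i in bl_index.items():
            bls[idx] = bl[i]
        if kind == "branch":
            key = (kappa, tuple(np.round(omegas, 12)))
            props = cache.get(key)
            if props is None:
                props = {
                    k: _Propagator(build_rate_matrix(kappa, om, pi), pi)
                    for k, om in enumerate(omegas)
                }
                if len(cache) > 8:
                    cache.clear()
                cache[key] = props
            return pruner.pattern_likelihoods(props, bls, pi, par.branch_label)
        # site mixture: every branch uses class k in turn
        per_class = np.empty((len(omegas), n_patterns))
        uniform_label = {i: 0 for i in par.branch_label}
        for k, om in enumerate(omegas):
            prop = {0: _Propagator(build_rate_matrix(kappa, om, pi), pi)}
            per_class[k] = pruner.pattern_likelihoods(
                prop, bls, pi, uniform_label
            )
        mx = per_class.max(axis=0)
        lik = (np.exp(per_class - mx) * weights[:, None]).sum(axis=0)
        return np.log(np.maximum(lik, 1e-300)) + mx

    def negloglik(x: np.ndarray) -> float:
        try:
            return -float(counts @ site_log_liks(x))
        except (ValueError, FloatingPointError):
            return 1e12

    bounds = list(par.bounds)
    x0 = np.array(par.init, dtype=float)
    if not spec.fix_branch_lengths:
        bounds += bl_bounds
        x0 = np.concatenate([x0, init_bl])

    rng = np.random.default_rng(spec.seed)
    best = None
    converged = False
    for start in range(max(spec.n_starts, 1)):
        xi = x0.copy()
        if start > 0:
            jitter = rng.uniform(0.5, 2.0, size=xi.shape)
            xi = np.clip(
                xi * jitter,
                [b[0] for b in bounds],
                [b[1] for b in bounds],
            )
        res = optimize.minimize(
            negloglik,
            xi,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": spec.max_iter, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        converged = converged or bool(res.success)

    vals = par.unpack(best.x[: par.n_model_params])
    omegas, weights, kind = par.classes(vals)
    estimates = dict(vals)
    if kind == "site":
        estimates["class_omegas"] = list(np.round(omegas, 6))
        estimates["class_weights"] = list(np.round(weights, 6))
    if not spec.fix_branch_lengths:
        fitted_bl = best.x[par.n_model_params :]
        for node, b in zip(branch_nodes, fitted_bl):
            node.length = float(b)
    n_params = par.n_model_params + (
        0 if spec.fix_branch_lengths else len(branch_nodes)
    )

    site_lnL = site_post = None
    if export_site_lnL:
        pat_lnL = site_log_liks(best.x)
        site_lnL = pat_lnL[inverse]
        if kind == "site":
            site_post = _naive_class_posterior(
                best.x, par, spec, pruner, pi, bl_index, init_bl, inverse
            )
    return FitResult(
        model_id=spec.model_id,
        lnL=-best.fun,
        np=n_params,
        estimates=estimates,
        tree=tree,
        converged=converged,
        site_lnL=site_lnL,
        site_class_posterior=site_post,
        message="" if converged else "optimizer did not report convergence",
    )


def _naive_class_posterior(x, par, spec, pruner, pi, bl_index, init_bl, inverse):
    """Naive empirical-Bayes per-site class posterior (NOT BEB): conditional
    class probabilities at the MLEs, with no prior integration."""
    vals = par.unpack(x[: par.n_model_params])
    omegas, weights, _ = par.classes(vals)
    bl = init_bl if spec.fix_branch_lengths else x[par.n_model_params :]
    bls = np.zeros(max(bl_index) + 1 if bl_index else 1)
    for idx, i in bl_index.items():
        bls[idx] = bl[i]
    uniform_label = {i: 0 for i in par.branch_label}
    per_class = np.empty((len(omegas), pruner.n_patterns))
    for k, om in enumerate(omegas):
        prop = {0: _Propagator(build_rate_matrix(vals["kappa"], om, pi), pi)}
        per_class[k] = pruner.pattern_likelihoods(prop, bls, pi, uniform_label)
    logw = np.log(np.asarray(weights))
    joint = per_class + logw[:, None]
    joint -= joint.max(axis=0)
    post = np.exp(joint)
    post /= post.sum(axis=0)
    return post[:, inverse].T


def lrt(general: FitResult, restricted: FitResult, df: Optional[int] = None) -> LRTResult:
    """Likelihood-ratio test of nested codon models: 2Δ = 2(lnL1 − lnL2)
    against the chi-square upper tail with the parameter-count difference."""
    if df is None:
        df = general.np - restricted.np
    if df <= 0:
        raise ValueError("general model must have more parameters")
    twice_delta = 2.0 * (general.lnL - restricted.lnL)
    warning = ""
    if twice_delta < -1e-4:
        warning = (
            f"restricted lnL exceeds general lnL (2Δ = {twice_delta:.4g}); "
            "likely non-convergence"
        )
        warnings.warn(warning)
    p = float(stats.chi2.sf(max(twice_delta, 0.0), df))
    return LRTResult(twice_delta=twice_delta, df=df, p_value=p, warning=warning)


def label_branches(
    tree: TimeTree,
    tag: str,
    tip_tags: dict,
    include_stem: bool = True,
) -> TimeTree:
    """Attach a foreground tag to branches from a per-tip annotation.

    A terminal branch is tagged when its tip carries the tag; an internal
    branch when every descendant tip does.  ``include_stem=False`` drops the
    maximal (stem) branches of tagged clades, keeping only branches strictly
    inside them.
    """
    if not any(tag in set(v) for v in tip_tags.values()):
        raise ValueError(f"tag {tag!r} absent from annotation")
    out = tree.copy()
    tagged = {}
    for node in out.postorder():
        if node.is_leaf:
            tagged[node] = tag in set(tip_tags.get(node.name, ()))
        else:
            tagged[node] = all(tagged[c] for c in node.children)
    for node in out.preorder():
        if node is out.root or not tagged[node]:
            continue
        if not include_stem and (node.parent is out.root or not tagged[node.parent]):
            continue
        node.tags.add(tag)
    return out
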