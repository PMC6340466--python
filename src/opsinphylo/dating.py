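"""Dating loss of selective constraint on pseudogenized lineages.

The sudden-relaxation model assumes a lineage evolved under its typical
constraint (dN/dS = ω_f < 1) until some moment, after which constraint was
completely relaxed (ω = 1).  A branch spanning the loss ("mixed") shows an
intermediate observed ratio ω_m that is the time-weighted average of the two
eras:

    ω_m · T = ω_f · T_f + 1 · T_p,   with  T = T_f + T_p

so the time since relaxation is  T_p = T · (ω_m − ω_f) / (1 − ω_f).

Branches are first categorized against the placed lesion origins:
``mixed`` (the origin branch itself), ``nonfunctional`` (wholly below an
origin), ``premutation`` (ancestral branches whose descendants are all
pseudogenes — they predate the first-appearance stops), and ``functional``
(everything else).  Category-level ω estimates from the codon-model stage
then resolve each mixed branch into its functional and pseudogenic
components, yielding a loss date in Ma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .io import TimeTree


@dataclass
class BranchCategory:
    branch: str  # child-node name
    category: str  # {functional, premutation, mixed, nonfunctional}


@dataclass
class RelaxationEstimate:
    lineage: str
    T: float  # branch duration, My
    omega_f: float
    omega_m: float
    T_p: float  # time since relaxation, My
    loss_date_ma: Optional[float] = None  # Ma before present
    clamped: bool = False
    note: str = ""

    @property
    def T_f(self) -> float:
        return self.T - self.T_p


def categorize_branches(tree: TimeTree, lesion_origins: list) -> list:
    """Assign every branch to a loss-of-function era category.

    ``lesion_origins`` are placed origins (from the lesion-placement stage);
    only the first (most rootward) origin along any path matters.  With no
    lesions every branch is functional.
    """
    origin_nodes = []
    for origin in lesion_origins:
        node = tree.find(origin.origin_branch)
        origin_nodes.append(node)
    categories = {}
    nodes = [n for n in tree.nodes if n is not tree.root]
    origin_set = set(id(n) for n in origin_nodes)
    for node in nodes:
        below_any = any(tree.is_ancestor(o, node) for o in origin_nodes)
        if below_any:
            # postdates an earlier stop appearance, even if it carries its
            # own (later, private) lesion origin
            categories[node.name] = "nonfunctional"
        elif id(node) in origin_set:
            categories[node.name] = "mixed"
        else:
            categories[node.name] = "functional"
    # premutation: ancestral branches whose tips are all pseudogene carriers
    # (they predate the stop appearances on every path below them)
    carrier_tips = set()
    for origin in lesion_origins:
        carrier_tips.update(origin.carriers)
    for node in nodes:
        if categories[node.name] != "functional":
            continue
        tips = {t.name for t in tree.tips_below(node)}
        if tips and tips <= carrier_tips:
            categories[node.name] = "premutation"
    return [BranchCategory(branch=n.name, category=categories[n.name]) for n in nodes]


def date_relaxation(omega_m: float, omega_f: float, T: float) -> RelaxationEstimate:
    """Solve the era-mixture equation for the time since relaxation.

    Requires 0 ≤ ω_f < 1 (a constraint era must exist) and T > 0.  The raw
    solution is clamped to [0, T]; out-of-range inputs (ω_m below ω_f, or
    above 1) are flagged rather than hidden.
    """
    if not 0.0 <= omega_f < 1.0:
        raise ValueError("omega_f must be in [0, 1): no constraint era otherwise")
    if T <= 0:
        raise ValueError("T must be positive")
    if omega_m < 0:
        raise ValueError("omega_m must be nonnegative")
    raw = T * (omega_m - omega_f) / (1.0 - omega_f)
    tp = min(max(raw, 0.0), T)
    clamped = tp != raw
    note = ""
    if omega_m < omega_f:
        note = "omega_m below functional omega; T_p clamped to 0"
    elif omega_m > 1.0:
        note = "omega_m exceeds 1; T_p clamped to branch duration"
    return RelaxationEstimate(
        lineage="", T=T, omega_f=omega_f, omega_m=omega_m, T_p=tp,
        clamped=clamped, note=note,
    )


def resolve_mixed(
    categories: list,
    category_omegas: dict,
    tree: TimeTree,
    branch_omegas: Optional[dict] = None,
) -> list:
    """Resolve each mixed branch into functional and pseudogenic components.

    ``category_omegas`` maps category → ω (at minimum ``functional``; a
    ``nonfunctional`` entry is reported as the ≈1 diagnostic).  ω_m for a
    mixed branch comes from ``branch_omegas[branch]`` when given, else from
    ``category_omegas['mixed']``.  The tree must be calibrated (lengths in
    My); the loss date is the branch's start age minus T_f, in Ma before
    present.
    """
    if tree.units != "My":
        raise ValueError("resolve_mixed needs a calibrated tree (units='My')")
    ages = tree.node_ages()
    omega_f = category_omegas.get("functional")
    estimates = []
    for cat in categories:
        if cat.category != "mixed":
            continue
        node = tree.find(cat.branch)
        T = node.length
        omega_m = (branch_omegas or {}).get(cat.branch, category_omegas.get("mixed"))
        if omega_f is None or omega_m is None or T <= 0:
            estimates.append(
                RelaxationEstimate(
                    lineage=cat.branch, T=T, omega_f=float("nan"),
                    omega_m=float("nan"), T_p=float("nan"),
                    note="missing category omega or zero-length branch; skipped",
                )
            )
            continue
        est = date_relaxation(omega_m, omega_f, T)
        est.lineage = cat.branch
        start_age = ages[node.parent]
        est.loss_date_ma = start_age - est.T_f
        om_nf = category_omegas.get("nonfunctional")
        if om_nf is not None and abs(om_nf - 1.0) > 0.3:
            est.note = (est.note + "; " if est.note else "") + (
                f"nonfunctional-era omega {om_nf:.3g} deviates from 1"
            )
        estimates.append(est)
    return estimates
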