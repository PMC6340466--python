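"""Spectral tuning of cone opsins from key amino-acid sites.

The peak-absorption wavelength (λmax) of an MWS/LWS pigment is determined,
to good approximation, by the residues at five sites — 180, 197, 277, 285,
308 in bovine-rhodopsin-anchored numbering (the "five-site rule").  The
ancestral vertebrate haplotype SHYTA absorbs at ~560 nm; known haplotypes
are resolved by exact lookup, and unseen ones fall back to summing additive
single-substitution shifts (flagged as extrapolation, since measured
haplotypes are not exactly additive).

SWS1 pigments are classified UV (~360 nm) versus violet/visible (>400 nm)
from the residue at site 86, the dominant tuning site: phenylalanine at 86
gives a UV pigment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .ancestral import AncestralStates
from .io import PositionMap, TimeTree

LWS_SITES = (180, 197, 277, 285, 308)
SWS1_SITES = (46, 49, 52, 86, 90, 93, 97, 113, 114, 116, 118)


@dataclass(frozen=True)
class TuningSiteSet:
    gene: str  # {LWS, SWS1}
    positions: tuple

    def __post_init__(self):
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("site positions must be strictly increasing")
        if self.gene == "LWS" and len(self.positions) != 5:
            raise ValueError("the LWS rule uses exactly five sites")

    @classmethod
    def lws(cls) -> "TuningSiteSet":
        return cls("LWS", LWS_SITES)

    @classmethod
    def sws1(cls) -> "TuningSiteSet":
        return cls("SWS1", SWS1_SITES)


@dataclass
class LambdaTable:
    """λmax assignments: exact haplotype entries take precedence; otherwise
    additive shifts from the SHYTA base are summed.

    The exact entries pin the four haplotypes with published assignments
    (SHYTA 560, AHYTA 555, SHYAA 543, AHYAA 536 nm); AHYAA shows why the
    exact table is needed — it is not the additive sum of its parts.
    Additive shifts for substitutions beyond S180A/T285A come from the
    spectral-tuning mutagenesis literature and are approximate.
    """

    base_haplotype: str = "SHYTA"
    base_nm: float = 560.0
    exact: dict = field(
        default_factory=lambda: {
            "SHYTA": 560.0,
            "AHYTA": 555.0,
            "SHYAA": 543.0,
            "AHYAA": 536.0,
        }
    )
    # shift per (site index in haplotype, derived residue)
    additive_shifts: dict = field(
        default_factory=lambda: {
            (0, "A"): -5.0,  # S180A, from the printed 560→555
            (1, "Y"): -28.0,  # H197Y, literature
            (2, "F"): -8.0,  # Y277F, literature
            (3, "A"): -17.0,  # T285A, from the printed 560→543
            (4, "S"): -27.0,  # A308S, literature
        }
    )


@dataclass
class TuningProfile:
    taxon_or_node: str
    haplotype: str
    lambda_max: Optional[float] = None
    spectral_class: Optional[str] = None  # SWS1: {UV, violet/visible}
    unresolved_sites: list = field(default_factory=list)
    provenance: str = ""  # {exact, additive, unresolved}


def extract_haplotype(
    aa_seq: str, posmap: PositionMap, sites: TuningSiteSet
) -> TuningProfile:
    """Residues at the key reference positions; unmapped or ambiguous
    positions become '?' and are listed as unresolved."""
    chars, unresolved = [], []
    seq = aa_seq.upper()
    for pos in sites.positions:
        qpos = posmap.query_position(pos)
        res = seq[qpos - 1] if qpos is not None and qpos <= len(seq) else None
        if res is None or res in "X-*?":
            chars.append("?")
            unresolved.append(pos)
        else:
            chars.append(res)
    return TuningProfile(
        taxon_or_node="",
        haplotype="".join(chars),
        unresolved_sites=unresolved,
    )


def infer_lws_lambda(
    haplotype: str, table: Optional[LambdaTable] = None
) -> TuningProfile:
    """λmax (nm) for a five-site LWS haplotype.

    Exact table lookup first; otherwise the additive fallback subtracts the
    configured shift for every substitution relative to the base haplotype.
    Unresolved haplotypes give a null λmax with the reason recorded.
    """
    table = table or LambdaTable()
    hap = haplotype.upper()
    if len(hap) != len(table.base_haplotype):
        raise ValueError(
            f"haplotype {hap!r} length != {len(table.base_haplotype)}"
        )
    if "?" in hap:
        return TuningProfile(
            taxon_or_node="",
            haplotype=hap,
            lambda_max=None,
            provenance="unresolved",
        )
    if hap in table.exact:
        return TuningProfile(
            taxon_or_node="", haplotype=hap,
            lambda_max=table.exact[hap], provenance="exact",
        )
    nm = table.base_nm
    for i, (b, h) in enumerate(zip(table.base_haplotype, hap)):
        if h != b:
            nm += table.additive_shifts.get((i, h), 0.0)
    return TuningProfile(
        taxon_or_node="", haplotype=hap, lambda_max=nm, provenance="additive"
    )


def classify_sws1(
    haplotype: str, sites: TuningSiteSet = TuningSiteSet("SWS1", SWS1_SITES)
) -> TuningProfile:
    """UV versus violet/visible class from site 86.

    F at 86 → UV with nominal λmax ~360 nm; any other resolved residue →
    violet/visible (nominal >400 nm, reported as 400.0 with the class
    carrying the inequality).  Classification beyond F86 is an extrapolation
    from the tuning literature and is noted as such.
    """
    if 86 not in sites.positions:
        raise ValueError("site 86 must be in the SWS1 site set")
    idx = sites.positions.index(86)
    hap = haplotype.upper()
    if len(hap) != len(sites.positions):
        raise ValueError("haplotype length must match the site set")
    res = hap[idx]
    if res == "?":
        return TuningProfile(
            taxon_or_node="", haplotype=hap, spectral_class=None,
            unresolved_sites=[86], provenance="unresolved",
        )
    if res == "F":
        return TuningProfile(
            taxon_or_node="", haplotype=hap, lambda_max=360.0,
            spectral_class="UV", provenance="exact",
        )
    return TuningProfile(
        taxon_or_node="", haplotype=hap, lambda_max=400.0,
        spectral_class="violet/visible", provenance="extrapolated",
    )


def ancestral_tuning(
    tree: TimeTree,
    states: AncestralStates,
    site_columns: dict,
    gene: str = "LWS",
    table: Optional[LambdaTable] = None,
    sites: Optional[TuningSiteSet] = None,
) -> dict:
    """Tuning profile for every node from a site-wise reconstruction.

    ``site_columns`` maps each key reference position to its 1-based column
    in the reconstructed sequences.  The root profile is labelled the
    crown-group ancestor.  Unresolved reconstructed sites propagate to '?'.
    """
    sites = sites or (TuningSiteSet.lws() if gene == "LWS" else TuningSiteSet.sws1())
    profiles = {}
    for node in tree.nodes:
        seq = states.states[node.name]
        chars, unresolved = [], []
        for pos in sites.positions:
            col = site_columns.get(pos)
            res = seq[col - 1] if col is not None and col <= len(seq) else "?"
            if res in "?X-*":
                chars.append("?")
                unresolved.append(pos)
            else:
                chars.append(res)
        hap = "".join(chars)
        if gene == "LWS":
            prof = infer_lws_lambda(hap, table) if "?" not in hap else TuningProfile(
                taxon_or_node="", haplotype=hap, provenance="unresolved"
            )
        else:
            prof = classify_sws1(hap, sites)
        prof.taxon_or_node = (
            "crown-group ancestor" if node is tree.root else node.name
        )
        prof.unresolved_sites = unresolved
        profiles[node.name] = prof
    return profiles
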