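"""Open-reading-frame integrity: lesion calling and placement.

A coding sequence is designated a pseudogene when it carries a frameshift
indel or a premature stop codon; in-frame indels and stops in the final
stretch of the ORF (C-terminal truncations can retain function) do not flip
the call by default.  Shared lesions are placed on the tree under Dollo
parsimony — a single origin on the stem of the carriers' clade, flagged
homoplastic when that clade also contains non-carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io import STANDARD_CODE, CodonAlignment, TimeTree, translate


@dataclass
class Lesion:
    taxon: str
    kind: str  # {insertion, deletion, premature_stop, splice_violation}
    codon_column: int  # 1-based, alignment coordinates
    length_nt: int
    causes_frameshift: bool
    exon_index: Optional[int] = None
    note: str = ""

    def __post_init__(self):
        if self.kind in {"insertion", "deletion"}:
            expect = self.length_nt % 3 != 0
            if self.causes_frameshift != expect:
                raise ValueError("causes_frameshift inconsistent with length")
        if self.kind == "premature_stop" and self.length_nt != 3:
            raise ValueError("premature_stop lesions span one codon")

    @property
    def signature(self) -> tuple:
        return (self.kind, self.codon_column, self.length_nt)


@dataclass
class FunctionalityCall:
    taxon: str
    status: str  # {functional, pseudogene}
    lesions: list = field(default_factory=list)


@dataclass
class LesionOrigin:
    signature: tuple
    origin_branch: str  # name of the child node identifying the branch
    carriers: list
    homoplastic: bool = False


def _gap_runs(seq: str, gap: str = "-") -> list:
    """Maximal (start, length) gap runs, 0-based nt columns."""
    runs, start = [], None
    for i, c in enumerate(seq):
        if c == gap and start is None:
            start = i
        elif c != gap and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(seq) - start))
    return runs


def scan_orf(
    alignment: CodonAlignment,
    reference_taxon: Optional[str] = None,
    stop_leniency_fraction: float = 0.10,
    lenient_stop_flips_status: bool = False,
    exon_intervals: Optional[list] = None,
) -> list:
    """Call per-taxon lesions and functional/pseudogene status.

    Indel polarity is defined against ``reference_taxon`` (default: the first
    row whose sequence translates without internal stops).  Gap runs in a
    taxon opposite reference bases are deletions; bases opposite reference
    gaps are insertions.  Stops are called on each taxon's own reading frame
    (gaps removed), so frameshifted frames are scanned as read.  A stop in
    the final ``stop_leniency_fraction`` of the reference ORF is reported but
    does not flip status unless ``lenient_stop_flips_status``.

    ``exon_intervals`` — optional 1-based closed nt intervals on the
    reference ORF, used only to annotate each lesion's exon index.
    """
    gap = alignment.gap_char
    code = alignment.code

    def clean(taxon: str) -> bool:
        aa = translate(alignment.row(taxon).replace(gap, ""), code)
        return "*" not in aa[:-1]

    if reference_taxon is None:
        for t in alignment.ids:
            if clean(t):
                reference_taxon = t
                break
        else:
            raise ValueError("no stop-free reference row available")
    elif not clean(reference_taxon):
        raise ValueError(
            f"reference row {reference_taxon!r} is itself disrupted; "
            "pick another reference"
        )
    ref_row = alignment.row(reference_taxon)
    ref_len = len(ref_row) - ref_row.count(gap)

    def exon_of(ref_nt_pos: int) -> Optional[int]:
        if not exon_intervals:
            return None
        for k, (a, b) in enumerate(exon_intervals, start=1):
            if a <= ref_nt_pos <= b:
                return k
        return None

    # alignment column -> reference nt position (1-based; 0 where ref gapped)
    ref_pos_at = []
    p = 0
    for c in ref_row:
        if c != gap:
            p += 1
        ref_pos_at.append(p)

    calls = []
    for taxon in alignment.ids:
        row = alignment.row(taxon)
        lesions = []
        # deletions: taxon gaps opposite reference bases
        for start, length in _gap_runs(row, gap):
            span = ref_row[start : start + length]
            del_len = sum(1 for c in span if c != gap)
            if del_len == 0:
                continue
            lesions.append(
                Lesion(
                    taxon=taxon,
                    kind="deletion",
                    codon_column=start // 3 + 1,
                    length_nt=del_len,
                    causes_frameshift=del_len % 3 != 0,
                    exon_index=exon_of(max(ref_pos_at[start], 1)),
                )
            )
        # insertions: taxon bases opposite reference gaps
        for start, length in _gap_runs(ref_row, gap):
            span = row[start : start + length]
            ins_len = sum(1 for c in span if c != gap)
            if ins_len == 0:
                continue
            lesions.append(
                Lesion(
                    taxon=taxon,
                    kind="insertion",
                    codon_column=start // 3 + 1,
                    length_nt=ins_len,
                    causes_frameshift=ins_len % 3 != 0,
                    exon_index=exon_of(max(ref_pos_at[start], 1)),
                )
            )
        # stops in the taxon's own reading frame
        ungapped_col = [i for i, c in enumerate(row) if c != gap]
        degapped = "".join(row[i] for i in ungapped_col)
        aa = translate(degapped, code)
        lenient = []
        for k, res in enumerate(aa):
            if res != "*" or k == len(aa) - 1:
                continue  # the 3'-terminal stop is never a lesion
            col = ungapped_col[3 * k]
            ref_pos = ref_pos_at[col]
            in_window = ref_pos > (1 - stop_leniency_fraction) * ref_len
            les = Lesion(
                taxon=taxon,
                kind="premature_stop",
                codon_column=col // 3 + 1,
                length_nt=3,
                causes_frameshift=False,
                exon_index=exon_of(max(ref_pos, 1)),
                note="within 3' leniency window" if in_window else "",
            )
            lesions.append(les)
            if in_window:
                lenient.append(les)
        lesions.sort(key=lambda l: l.codon_column)
        disruptive = [
            l
            for l in lesions
            if (l.kind in {"insertion", "deletion"} and l.causes_frameshift)
            or (
                l.kind == "premature_stop"
                and (lenient_stop_flips_status or l not in lenient)
            )
        ]
        calls.append(
            FunctionalityCall(
                taxon=taxon,
                status="pseudogene" if disruptive else "functional",
                lesions=lesions,
            )
        )
    return calls


def check_splice_sites(genomic_seq: str, exon_intervals: list) -> list:
    """Check the canonical GT/AG rule for each intron.

    ``exon_intervals`` are sorted, non-overlapping, 1-based closed intervals
    on ``genomic_seq``.  Returns one violation record per non-canonical
    intron: (intron_index, donor_dinucleotide, acceptor_dinucleotide).
    """
    seq = genomic_seq.upper()
    prev_end = 0
    for a, b in exon_intervals:
        if a <= prev_end or b < a or b > len(seq):
            raise ValueError(f"bad exon interval ({a}, {b})")
        prev_end = b
    violations = []
    for k in range(len(exon_intervals) - 1):
        intron_start = exon_intervals[k][1] + 1
        intron_end = exon_intervals[k + 1][0] - 1
        if intron_end - intron_start + 1 < 4:
            raise ValueError(f"intron {k + 1} too short for splice signals")
        donor = seq[intron_start - 1 : intron_start + 1]
        acceptor = seq[intron_end - 2 : intron_end]
        if donor != "GT" or acceptor != "AG":
            violations.append(
                {
                    "intron_index": k + 1,
                    "kind": "splice_violation",
                    "donor": donor,
                    "acceptor": acceptor,
                }
            )
    return violations


def place_lesions(calls: list, tree: TimeTree) -> list:
    """Place each distinct lesion signature on the tree by Dollo parsimony.

    The origin is the branch above the carriers' MRCA (a single gain, no
    loss).  If non-carrier tips descend from that branch the lesion is
    flagged homoplastic and left assigned to the carrier terminal branches.
    """
    tips = set(tree.tip_labels)
    by_signature: dict = {}
    for call in calls:
        if call.taxon not in tips:
            raise ValueError(f"taxon {call.taxon!r} not on tree")
        for les in call.lesions:
            by_signature.setdefault(les.signature, set()).add(call.taxon)
    origins = []
    for sig in sorted(by_signature):
        carriers = sorted(by_signature[sig])
        mrca = tree.mrca(carriers)
        below = {t.name for t in tree.tips_below(mrca)}
        if below == set(carriers):
            origins.append(
                LesionOrigin(
                    signature=sig, origin_branch=mrca.name, carriers=carriers
                )
            )
        else:
            for taxon in carriers:
                origins.append(
                    LesionOrigin(
                        signature=sig,
                        origin_branch=taxon,
                        carriers=[taxon],
                        homoplastic=True,
                    )
                )
    return origins
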