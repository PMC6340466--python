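"""Sequence and tree containers, standard-format I/O, and reference numbering.

Sequences travel as :class:`SequenceRecord` lists or, for coding data, a
:class:`CodonAlignment` that enforces codon-column structure.  Trees are held
in a light :class:`TimeTree` whose nodes the simulation and likelihood engines
traverse directly; newick text is parsed with dendropy and converted.

Residue coordinates follow the community convention for opsins: sites are
numbered by alignment to a reference protein (bovine rhodopsin by default),
and a :class:`PositionMap` carries the partial, strictly monotone
query↔reference correspondence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import dendropy
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

NT_ALPHABET = set("ACGTURYSWKMBDHVN-")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")

BASES = "TCAG"
_PURINES = {"A", "G"}


class ParseError(ValueError):
    """Malformed input file."""


@dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    seq: str
    moltype: str = "nt"  # {nt, aa}

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.seq:
            raise ValueError(f"empty sequence for {self.id!r}")
        alphabet = NT_ALPHABET if self.moltype == "nt" else AA_ALPHABET
        bad = set(self.seq.upper()) - alphabet
        if bad:
            raise ValueError(
                f"invalid {self.moltype} characters {sorted(bad)} in {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneticCode:
    """Codon → amino-acid table.  The standard nuclear code is the default."""

    name: str
    table: dict
    stop_codons: frozenset

    @classmethod
    def standard(cls) -> "GeneticCode":
        aas = (
            "FFLLSSSSYY**CC*W"
            "LLLLPPPPHHQQRRRR"
            "IIIMTTTTNNKKSSRR"
            "VVVVAAAADDEEGGGG"
        )
        codons = [a + b + c for a in BASES for b in BASES for c in BASES]
        table = dict(zip(codons, aas))
        return cls(
            name="standard",
            table=table,
            stop_codons=frozenset(c for c, aa in table.items() if aa == "*"),
        )

    @property
    def sense_codons(self) -> list:
        return [c for c in self.table if c not in self.stop_codons]

    def translate_codon(self, codon: str) -> str:
        codon = codon.upper().replace("U", "T")
        return self.table.get(codon, "X")


STANDARD_CODE = GeneticCode.standard()

# 61 sense codons in fixed TCAG order: the state space of the codon models.
SENSE_CODONS = tuple(STANDARD_CODE.sense_codons)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
ALL_CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}


def is_transition(a: str, b: str) -> bool:
    """A↔G or C↔T single-nucleotide change."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


@dataclass
class CodonAlignment:
    """In-frame nucleotide alignment with codon-column structure.

    Row lengths must be equal and divisible by three.  Codon column ``c``
    (1-based) spans nucleotide columns ``3c-2 .. 3c``.
    """

    records: list
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)
    gap_char: str = "-"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        length = len(self.records[0].seq)
        for r in self.records:
            if len(r.seq) != length:
                raise ValueError(
                    f"row {r.id!r} has length {len(r.seq)}, expected {length}"
                )
        if length % 3:
            raise ValueError(f"alignment length {length} not divisible by 3")

    @property
    def ids(self) -> list:
        return [r.id for r in self.records]

    @property
    def n_nt_columns(self) -> int:
        return len(self.records[0].seq)

    @property
    def n_codon_columns(self) -> int:
        return self.n_nt_columns // 3

    def row(self, taxon: str) -> str:
        for r in self.records:
            if r.id == taxon:
                return r.seq
        raise KeyError(taxon)

    def codon(self, taxon: str, column: int) -> str:
        """Codon at 1-based codon column."""
        s = self.row(taxon)
        return s[3 * (column - 1) : 3 * column]

    def codons(self, taxon: str) -> list:
        s = self.row(taxon)
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def subset(self, taxa: Iterable[str]) -> "CodonAlignment":
        keep = set(taxa)
        recs = [r for r in self.records if r.id in keep]
        return CodonAlignment(recs, code=self.code, gap_char=self.gap_char)


def read_fasta(path, moltype: str = "nt") -> list:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order."""
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicated id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).strip()
        if not seq:
            raise ParseError(f"{path}: empty sequence for {rec.id!r}")
        records.append(SequenceRecord(id=rec.id, seq=seq, moltype=moltype))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")


def read_codon_alignment(path, code: GeneticCode = STANDARD_CODE) -> CodonAlignment:
    return CodonAlignment(read_fasta(path, moltype="nt"), code=code)


# ---------------------------------------------------------------------------
# Trees


class TreeNode:
    """Node of a rooted tree; the branch to the parent carries the length."""

    __slots__ = ("name", "length", "parent", "children", "tags", "index")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.parent: Optional["TreeNode"] = None
        self.children: list = []
        self.tags: set = set()
        self.index: int = -1

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.name!r}, {self.length})"


class TimeTree:
    """Rooted tree with nonnegative branch lengths and per-branch tag sets.

    Branch lengths may be in expected substitutions/site or in My; the caller
    declares which via ``units``.  A branch is identified by its child node.
    """

    def __init__(self, root: TreeNode, units: str = "subs"):
        self.root = root
        self.units = units
        self._reindex()
        for node in self.preorder():
            if node is not self.root and node.length < 0:
                raise ValueError(f"negative branch length on {node.name!r}")
        tips = [n.name for n in self.leaves()]
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels")

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list:
        return [n.name for n in self.leaves()]

    def _reindex(self) -> None:
        self._nodes = list(self.postorder())
        for i, n in enumerate(self._nodes):
            n.index = i

    @property
    def nodes(self) -> list:
        return self._nodes

    def find(self, name: str) -> TreeNode:
        for n in self.preorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def mrca(self, taxa: Iterable[str]) -> TreeNode:
        taxa = set(taxa)
        for node in self.postorder():
            below = {leaf.name for leaf in self.tips_below(node)}
            if taxa <= below:
                return node
        raise ValueError(f"taxa {sorted(taxa)} not all on tree")

    def tips_below(self, node: TreeNode) -> list:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(n.children)
        return out

    def is_ancestor(self, anc: TreeNode, node: TreeNode) -> bool:
        p = node.parent
        while p is not None:
            if p is anc:
                return True
            p = p.parent
        return False

    # -- ages (for calibrated trees, units=My) -----------------------------
    def node_ages(self) -> dict:
        """Age of each node above the tips, assuming an ultrametric tree."""
        depth = {self.root: 0.0}
        maxd = 0.0
        for node in self.preorder():
            if node is not self.root:
                depth[node] = depth[node.parent] + node.length
                maxd = max(maxd, depth[node])
        return {n: maxd - d for n, d in depth.items()}

    def copy(self) -> "TimeTree":
        mapping = {}

        def clone(node: TreeNode) -> TreeNode:
            c = TreeNode(node.name, node.length)
            c.tags = set(node.tags)
            mapping[node] = c
            for child in node.children:
                c.add_child(clone(child))
            return c

        return TimeTree(clone(self.root), units=self.units)

    def path_length(self, a: str, b: str) -> float:
        na, nb = self.find(a), self.find(b)
        anc_a = {}
        d, n = 0.0, na
        while n is not None:
            anc_a[n] = d
            d += n.length
            n = n.parent
        d, n = 0.0, nb
        while n not in anc_a:
            d += n.length
            n = n.parent
        return d + anc_a[n]


def _from_dendropy(dtree: dendropy.Tree, units: str) -> TimeTree:
    def convert(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        if length < 0:
            raise ParseError(f"negative branch length on {label!r}")
        node = TreeNode(label, length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return TimeTree(convert(dtree.seed_node), units=units)


def read_newick(source, units: str = "subs") -> TimeTree:
    """Parse a newick tree from a path or string."""
    text = source
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    try:
        dtree = dendropy.Tree.get(
            data=str(text), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"newick parse failed: {exc}") from exc
    return _from_dendropy(dtree, units)


def write_newick(tree: TimeTree, path=None) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            base = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            base = f"({inner})" + (node.name or "")
        if node is tree.root:
            return base
        return f"{base}:{node.length:.10g}"

    text = fmt(tree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Translation


def translate(nt_seq: str, code: GeneticCode = STANDARD_CODE, frame: int = 1) -> str:
    """Translate; gap- or ambiguity-containing codons yield 'X', stops '*'.

    A trailing partial codon is dropped.  Total on the valid nt alphabet.
    """
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2, or 3")
    s = nt_seq.upper().replace("U", "T")[frame - 1 :]
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            out.append("X")
        else:
            out.append(code.table[codon])
    return "".join(out)


# ---------------------------------------------------------------------------
# Reference numbering


@dataclass
class PositionMap:
    """Partial strictly-increasing map query residue ↔ reference residue (1-based)."""

    query_to_ref: dict
    ref_to_query: dict
    identity: float = 0.0

    def __post_init__(self) -> None:
        items = sorted(self.query_to_ref.items())
        refs = [r for _, r in items]
        if any(b <= a for a, b in zip(refs, refs[1:])):
            raise ValueError("position map not strictly increasing")

    def query_position(self, ref_pos: int) -> Optional[int]:
        return self.ref_to_query.get(ref_pos)

    def __len__(self) -> int:
        return len(self.query_to_ref)


def bovine_rhodopsin() -> SequenceRecord:
    """The bundled reference protein anchoring residue numbering."""
    ref = resources.files("opsinphylo.data") / "bovine_rhodopsin.fasta"
    with resources.as_file(ref) as p:
        return read_fasta(p, moltype="aa")[0]


def map_to_reference(
    aa_seq: str,
    reference_aa_seq: Optional[str] = None,
    min_identity: float = 0.15,
) -> PositionMap:
    """Globally align a query protein to the reference and map residue numbers.

    Uses BLOSUM62 with affine gaps (open −11, extend −1).  If alignment
    identity over aligned columns falls below ``min_identity`` the map is
    returned empty with a warning: numbering would be meaningless.
    """
    if reference_aa_seq is None:
        reference_aa_seq = bovine_rhodopsin().seq
    if not aa_seq or not reference_aa_seq:
        raise ValueError("empty sequence")
    query = aa_seq.upper().replace("*", "X").replace("-", "")
    ref = reference_aa_seq.upper().replace("-", "")

    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    # BLOSUM62 has no gap or unusual letters; map them to X's scores
    safe = "".join(c if c in "ACDEFGHIKLMNPQRSTVWYBZX*" else "X" for c in query)
    aln = aligner.align(safe, ref)[0]

    q2r, matches, aligned_cols = {}, 0, 0
    for (qs, qe), (rs, re) in zip(*aln.aligned):
        for off in range(qe - qs):
            qi, ri = qs + off, rs + off
            q2r[qi + 1] = ri + 1
            aligned_cols += 1
            if safe[qi] == ref[ri]:
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    if aligned_cols == 0 or identity < min_identity:
        warnings.warn(
            f"reference alignment identity {identity:.2f} below floor "
            f"{min_identity:.2f}; returning empty position map"
        )
        return PositionMap({}, {}, identity=identity)
    return PositionMap(q2r, {r: q for q, r in q2r.items()}, identity=identity)
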