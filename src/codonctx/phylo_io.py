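"""Alignment and tree input/output with coding-frame validation.

Alignments are in-frame protein-coding nucleotide matrices (FASTA, relaxed
PHYLIP or NEXUS in; FASTA out); trees are rooted Newick with branch lengths
(parsed through dendropy).  Coordinates are 0-based internally and 1-based in
user-facing reports; codon k spans columns 3k..3k+2.  Gaps ``-`` and ``N``
are both treated as missing data downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import dendropy
from Bio import AlignIO, SeqIO

from .degeneracy import NUCLEOTIDES, NUC_CODE, GeneticCode, STANDARD_CODE

__all__ = ["CodingAlignment", "PhyloTree", "read_alignment", "write_alignment",
           "read_tree", "write_tree", "validate_coding", "ValidationReport"]

_ALLOWED = set("ACGTN-")
MISSING = -1


@dataclass
class CodingAlignment:
    """An in-frame nucleotide alignment with codon coordinates.

    ``codes`` is an int8 matrix (taxa x columns) with A,C,G,T = 0..3 and
    missing (``N`` or ``-``) = -1.  Column c belongs to codon position
    ``c % 3 + 1``.
    """

    taxa: List[str]
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or len(self.taxa) != self.codes.shape[0]:
            raise ValueError("taxa/sequence count mismatch")
        if self.codes.shape[1] % 3:
            raise ValueError(
                f"alignment length {self.codes.shape[1]} is not divisible by 3")

    @classmethod
    def from_sequences(cls, taxa, sequences) -> "CodingAlignment":
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        rows = []
        for name, seq in zip(taxa, sequences):
            seq = seq.upper().replace("U", "T")
            bad = set(seq) - _ALLOWED
            if bad:
                col = next(i for i, b in enumerate(seq) if b in bad)
                raise ValueError(
                    f"unknown symbol {seq[col]!r} in taxon {name!r} at column {col + 1}")
            rows.append([NUC_CODE.get(b, MISSING) for b in seq])
        return cls(list(taxa), np.array(rows, dtype=np.int8))

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    @property
    def n_codons(self) -> int:
        return self.codes.shape[1] // 3

    @property
    def position_labels(self) -> np.ndarray:
        """Per-column codon position labels cycling 1, 2, 3."""
        return np.arange(self.n_columns) % 3 + 1

    def sequence(self, i: int) -> str:
        return "".join(NUCLEOTIDES[c] if c >= 0 else "N" for c in self.codes[i])

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.taxa.index(taxon)]


def read_alignment(path, fmt: Optional[str] = None) -> CodingAlignment:
    """Read a coding alignment (``fasta``, ``phylip`` (relaxed) or ``nexus``).

    The format is inferred from the file extension when not given.  Sequences
    are upper-cased and U is mapped to T.
    """
    path = str(path)
    if fmt is None:
        ext = path.rsplit(".", 1)[-1].lower()
        fmt = {"fa": "fasta", "fasta": "fasta", "fas": "fasta",
               "phy": "phylip", "phylip": "phylip",
               "nex": "nexus", "nexus": "nexus"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer alignment format from {path!r}")
    fmt = fmt.lower()
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        taxa = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    elif fmt in ("phylip", "nexus"):
        bio_fmt = "phylip-relaxed" if fmt == "phylip" else "nexus"
        aln = AlignIO.read(path, bio_fmt)
        taxa = [r.id for r in aln]
        seqs = [str(r.seq) for r in aln]
    else:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    if not taxa:
        raise ValueError(f"no sequences found in {path!r}")
    return CodingAlignment.from_sequences(taxa, seqs)


def write_alignment(aln: CodingAlignment, path) -> None:
    """Write the alignment as FASTA (missing states rendered as N)."""
    with open(path, "w") as fh:
        for i, name in enumerate(aln.taxa):
            fh.write(f">{name}\n{aln.sequence(i)}\n")


@dataclass
class ValidationReport:
    """Frame/stop-codon validation outcome; ``ok`` iff no failures."""

    failures: List[str] = field(default_factory=list)
    stop_codons: List[tuple] = field(default_factory=list)  # (taxon, codon 1-based)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_coding(aln: CodingAlignment, code: GeneticCode = STANDARD_CODE,
                    forbid_stops: bool = False) -> ValidationReport:
    """Check reading frame and report in-frame stop codons.

    With ``forbid_stops`` (required for the 61-state codon model) any fully
    resolved stop codon is a validation failure listing taxon and codon index
    (1-based).
    """
    report = ValidationReport()
    if aln.n_columns % 3:
        report.failures.append(
            f"alignment length {aln.n_columns} is not divisible by 3")
        return report
    stops = {code_to_tuple(s) for s in code.stop_codons}
    tri = aln.codes.reshape(aln.n_taxa, aln.n_codons, 3)
    for ti, name in enumerate(aln.taxa):
        resolved = np.all(tri[ti] >= 0, axis=1)
        for ci in np.nonzero(resolved)[0]:
            if tuple(tri[ti, ci]) in stops:
                report.stop_codons.append((name, int(ci) + 1))
                if forbid_stops:
                    report.failures.append(
                        f"stop codon in taxon {name!r} at codon {ci + 1}")
    return report


def code_to_tuple(codon: str) -> tuple:
    return tuple(NUC_CODE[b] for b in codon)


class PhyloTree:
    """A fixed rooted tree with branch lengths, stored as flat arrays.

    Node 0 is the root; nodes are numbered in preorder, so ``parent[i] < i``
    for every non-root node.  ``lengths[i]`` is the branch above node i
    (0 for the root).  Polytomies are preserved.
    """

    def __init__(self, parent: np.ndarray, lengths: np.ndarray,
                 names: List[Optional[str]]):
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.names = list(names)
        n = self.parent.shape[0]
        if self.lengths.shape[0] != n or len(self.names) != n:
            raise ValueError("array length mismatch")
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise ValueError("branch lengths must be finite and nonnegative")
        self.children: List[List[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            if not 0 <= self.parent[i] < i:
                raise ValueError("nodes must be in preorder with a single root")
            self.children[self.parent[i]].append(i)

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def leaves(self) -> List[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_names(self) -> List[str]:
        return [self.names[i] for i in self.leaves]

    @property
    def postorder(self) -> List[int]:
        return list(range(self.n_nodes - 1, -1, -1))

    def check_taxa(self, aln: CodingAlignment) -> None:
        tree_set, aln_set = set(self.leaf_names), set(aln.taxa)
        if tree_set != aln_set:
            missing = sorted(tree_set - aln_set)
            extra = sorted(aln_set - tree_set)
            raise ValueError(
                f"tree/alignment taxa mismatch: tree-only {missing}, alignment-only {extra}")

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True)
        return cls._from_dendropy(dtree)

    @classmethod
    def _from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, lengths, names = [], [], []
        for nd in nodes:
            parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
            lengths.append(0.0 if nd.parent_node is None else
                           (nd.edge.length if nd.edge.length is not None else 0.0))
            names.append(nd.taxon.label if nd.taxon is not None else None)
        return cls(np.array(parent), np.array(lengths), names)

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                label = (self.names[i] or f"n{i}").replace(" ", "_")
                return f"{label}:{self.lengths[i]:.10g}"
            inner = ",".join(render(c) for c in self.children[i])
            if i == 0:
                return f"({inner});"
            return f"({inner}):{self.lengths[i]:.10g}"
        return render(0)

    def copy(self) -> "PhyloTree":
        t = PhyloTree.__new__(PhyloTree)
        t.parent = self.parent.copy()
        t.lengths = self.lengths.copy()
        t.names = list(self.names)
        t.children = [list(c) for c in self.children]
        return t


def read_tree(path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths."""
    with open(path) as fh:
        text = fh.read()
    if text.count("(") != text.count(")"):
        raise ValueError(f"unmatched parentheses in {path!r}")
    return PhyloTree.from_newick(text)


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
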