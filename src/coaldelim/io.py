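"""Alignments, taxon maps and trait tables.

Readers accept the formats the study's matrices circulate in (FASTA, NEXUS,
relaxed PHYLIP); alignment utilities cover concatenation with gap padding,
parsimony-informative site counting, and a UPGMA clock tree that stands in
for external model-based gene-tree estimation when only sequences are at
hand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .trees import Node, UltrametricTree

__all__ = [
    "Alignment",
    "AlignmentError",
    "TaxonMap",
    "TraitTable",
    "read_alignment",
    "write_alignment",
    "concatenate_alignments",
    "count_parsimony_informative",
    "upgma_clock_tree",
    "read_mappings",
    "read_taxon_map",
    "read_trait_table",
]

_FORMATS = {"fasta": "fasta", "nexus": "nexus", "phylip-relaxed": "phylip-relaxed"}
_NUCS = b"ACGT"


class AlignmentError(ValueError):
    """Malformed alignment input."""


@dataclass
class Alignment:
    """Multiple sequence alignment over IUPAC nucleotide symbols.

    Rows are stored as uppercase strings; gaps are ``-`` and ambiguity
    codes are kept verbatim.  All rows must have equal length and taxa
    labels must be unique.
    """

    taxa: list[str]
    rows: list[str]
    locus_name: str = ""
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentError("taxa and rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dup}")
        self.rows = [r.upper() for r in self.rows]
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            for taxon, row in zip(self.taxa, self.rows):
                if len(row) != len(self.rows[0]):
                    raise AlignmentError(
                        f"ragged alignment: row for {taxon!r} has length "
                        f"{len(row)}, expected {len(self.rows[0])}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        """Byte matrix (n_taxa x columns) of uppercase ASCII codes."""
        return np.frombuffer(
            "".join(self.rows).encode(), dtype=np.uint8
        ).reshape(self.n_taxa, self.column_count)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


def read_alignment(path, format: str = "fasta", locus_name: str | None = None) -> Alignment:
    """Read one alignment file; ``format`` is fasta, nexus or phylip-relaxed."""
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {sorted(_FORMATS)}")
    name = locus_name if locus_name is not None else _stem(path)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences found in {path}")
        aln = Alignment(
            taxa=[r.id for r in records],
            rows=[str(r.seq) for r in records],
            locus_name=name,
        )
    else:
        msa = AlignIO.read(str(path), _FORMATS[format])
        aln = Alignment(
            taxa=[r.id for r in msa],
            rows=[str(r.seq) for r in msa],
            locus_name=name,
        )
    return aln


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    """Write an alignment; bit-stable for identical inputs."""
    if format == "fasta":
        with open(path, "w") as fh:
            for taxon, row in zip(aln.taxa, aln.rows):
                fh.write(f">{taxon}\n{row}\n")
    elif format == "phylip-relaxed":
        with open(path, "w") as fh:
            fh.write(f" {aln.n_taxa} {aln.column_count}\n")
            width = max(len(t) for t in aln.taxa) + 2
            for taxon, row in zip(aln.taxa, aln.rows):
                fh.write(f"{taxon:<{width}}{row}\n")
    elif format == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(f"    DIMENSIONS NTAX={aln.n_taxa} NCHAR={aln.column_count};\n")
            fh.write("    FORMAT DATATYPE=DNA MISSING=? GAP=-;\n    MATRIX\n")
            width = max(len(t) for t in aln.taxa) + 2
            for taxon, row in zip(aln.taxa, aln.rows):
                label = f"'{taxon}'" if " " in taxon else taxon
                fh.write(f"    {label:<{width}}{row}\n")
            fh.write("    ;\nEND;\n")
    else:
        raise ValueError(f"unsupported format {format!r}")


def concatenate_alignments(alignments: Sequence[Alignment]) -> Alignment:
    """Concatenate loci over the union of taxa, padding missing taxa with gaps.

    The per-locus column ranges are recorded in ``partitions`` as
    ``(locus_name, start, end)`` half-open intervals.
    """
    if not alignments:
        raise AlignmentError("cannot concatenate an empty list of alignments")
    taxa: list[str] = []
    for aln in alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    blocks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    offset = 0
    for aln in alignments:
        width = aln.column_count
        lookup = dict(zip(aln.taxa, aln.rows))
        for t in taxa:
            blocks[t].append(lookup.get(t, "-" * width))
        partitions.append((aln.locus_name, offset, offset + width))
        offset += width
    return Alignment(
        taxa=taxa,
        rows=["".join(blocks[t]) for t in taxa],
        locus_name="+".join(a.locus_name for a in alignments),
        partitions=partitions,
    )


def count_parsimony_informative(aln: Alignment) -> int:
    """Number of parsimony-informative columns.

    A column is informative when at least two distinct unambiguous
    nucleotide states (A/C/G/T) each occur in at least two sequences; gaps
    and IUPAC ambiguity codes never count as states.
    """
    if aln.n_taxa == 0 or aln.column_count == 0:
        return 0
    arr = aln.to_array()
    counts = np.stack([(arr == c).sum(axis=0) for c in _NUCS])  # 4 x columns
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def upgma_clock_tree(aln: Alignment, correction: str = "raw") -> UltrametricTree:
    """UPGMA tree from pairwise distances; ultrametric by construction.

    p-distances are computed over site pairs where both sequences carry an
    unambiguous A/C/G/T.  With ``correction='jc69'`` the distance is
    ``d = -(3/4) ln(1 - (4/3) p)``; ``p >= 0.75`` is then undefined and
    raises, naming the offending pair.  Node ages are half the UPGMA merge
    heights, so branch lengths stay in expected substitutions per site.
    """
    if correction not in ("raw", "jc69"):
        raise ValueError("correction must be 'raw' or 'jc69'")
    if aln.n_taxa < 2:
        raise AlignmentError("need at least two taxa for a tree")
    arr = aln.to_array()
    valid = np.zeros(arr.shape, dtype=bool)
    for c in _NUCS:
        valid |= arr == c
    n = aln.n_taxa
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise AlignmentError(
                    f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / m
            if correction == "jc69":
                if p >= 0.75:
                    raise AlignmentError(
                        f"JC69 distance undefined for pair "
                        f"({aln.taxa[i]!r}, {aln.taxa[j]!r}): p = {p:.4f} >= 0.75"
                    )
                d = -0.75 * math.log1p(-4.0 * p / 3.0)
            else:
                d = p
            dmat[i, j] = dmat[j, i] = d
    linkage = average(squareform(dmat, checks=False))
    # build nodes; linkage heights are pairwise distances -> age = height / 2
    nodes: list[Node] = [Node(label=t, age=0.0) for t in aln.taxa]
    for height_row in linkage:
        a, b, height = int(height_row[0]), int(height_row[1]), float(height_row[2])
        parent = Node(age=height / 2.0)
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes.append(parent)
    return UltrametricTree(nodes[-1])


# ----------------------------------------------------------------------
# taxon maps and trait tables
# ----------------------------------------------------------------------

class TaxonMap:
    """Assignment of individuals (gene-tree tips) to candidate species."""

    def __init__(self, assignments: Mapping[str, str]):
        self.assignments = dict(assignments)
        self.species = sorted(set(self.assignments.values()))

    @property
    def individuals(self) -> list[str]:
        return list(self.assignments)

    def species_of(self, individual: str) -> str:
        try:
            return self.assignments[individual]
        except KeyError:
            raise KeyError(f"individual {individual!r} missing from taxon map") from None

    def individuals_of(self, species: str) -> list[str]:
        return [i for i, s in self.assignments.items() if s == species]

    def unmatched_tips(self, tree: UltrametricTree) -> list[str]:
        return [t for t in tree.tip_labels if t not in self.assignments]

    def __len__(self) -> int:
        return len(self.assignments)


class TraitTable:
    """Categorical traits per individual; missing values kept as None."""

    def __init__(
        self,
        values: Mapping[str, Mapping[str, str | None]],
        levels: Mapping[str, set[str]] | None = None,
    ):
        self.values = {ind: dict(traits) for ind, traits in values.items()}
        self.trait_names = sorted({t for traits in self.values.values() for t in traits})
        if levels is None:
            levels = {
                name: {
                    v[name]
                    for v in self.values.values()
                    if v.get(name) is not None
                }
                for name in self.trait_names
            }
        self.levels = {k: set(v) for k, v in levels.items()}
        for ind, traits in self.values.items():
            for name, val in traits.items():
                if val is not None and val not in self.levels.get(name, set()):
                    raise ValueError(
                        f"unknown level {val!r} for trait {name!r} "
                        f"(individual {ind!r}); declared levels: "
                        f"{sorted(self.levels.get(name, set()))}"
                    )

    def trait(self, name: str) -> dict[str, str | None]:
        if name not in self.trait_names:
            raise KeyError(f"trait {name!r} not present; have {self.trait_names}")
        return {ind: traits.get(name) for ind, traits in self.values.items()}

    def missing(self, name: str) -> list[str]:
        return [i for i, v in self.trait(name).items() if v is None]

    def __len__(self) -> int:
        return len(self.values)


_MISSING = {"", "na", "nan", "none", "?"}


def read_taxon_map(path) -> TaxonMap:
    """TSV with a header; first column individual, second candidate species."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"empty taxon map file {path}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            ind, sp = parts[0].strip(), parts[1].strip()
            if ind in assignments and assignments[ind] != sp:
                raise ValueError(
                    f"individual {ind!r} assigned to both "
                    f"{assignments[ind]!r} and {sp!r}"
                )
            assignments[ind] = sp
    return TaxonMap(assignments)


def read_trait_table(path, levels: Mapping[str, set[str]] | None = None) -> TraitTable:
    """TSV with a header of trait names; first column individual labels."""
    values: dict[str, dict[str, str | None]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        names = [h.strip() for h in header[1:]]
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            ind = parts[0].strip()
            row: dict[str, str | None] = {}
            for name, raw in zip(names, parts[1:]):
                val = raw.strip()
                row[name] = None if val.lower() in _MISSING else val
            values[ind] = row
    return TraitTable(values, levels=levels)


def read_mappings(
    taxon_map_path, trait_path, trait_levels: Mapping[str, set[str]] | None = None
) -> tuple[TaxonMap, TraitTable]:
    """Read the individual->species map and the trait table together."""
    return read_taxon_map(taxon_map_path), read_trait_table(trait_path, levels=trait_levels)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
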