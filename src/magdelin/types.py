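"""Shared domain types.

These are thin, validated containers; all heavy lifting lives in the
stage modules.  Trees wrap :mod:`dendropy` trees, tables are pandas
DataFrames produced by :mod:`magdelin.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_ALPHABET = set("ACGTN")

QUERY = "query"
REFERENCE = "reference"


class FormatError(ValueError):
    """Raised when an input file violates its declared format or schema."""


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass
class ContigRecord:
    """One assembled sequence with the per-contig quantities curation compares.

    ``counts`` maps sample id -> mapped read count; ``genes`` is a list of
    (gene id, taxonomy label or None) pairs.
    """

    contig_id: str
    length: int
    gc: float
    counts: dict[str, int] = field(default_factory=dict)
    genes: list[tuple[str, Optional[str]]] = field(default_factory=list)
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc <= 1.0):
            raise ValidationError(
                f"contig {self.contig_id}: GC fraction {self.gc} outside [0, 1]"
            )
        if self.length <= 0:
            raise ValidationError(f"contig {self.contig_id}: non-positive length")
        for sample, n in self.counts.items():
            if n < 0:
                raise ValidationError(
                    f"contig {self.contig_id}: negative count in sample {sample}"
                )

    def mean_coverage(self) -> float:
        """Mean per-base coverage averaged over samples (0 if no samples)."""
        if not self.counts:
            return 0.0
        per_sample = [n / self.length for n in self.counts.values()]
        return float(np.mean(per_sample))


@dataclass
class GenomeBin:
    """A named set of contigs plus marker inventory: the MAG unit.

    ``markers`` maps marker family id -> copy count (non-negative int).
    """

    bin_id: str
    contigs: dict[str, ContigRecord]
    markers: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValidationError(f"bin {self.bin_id}: no contigs")
        for marker, copies in self.markers.items():
            if copies < 0 or int(copies) != copies:
                raise ValidationError(
                    f"bin {self.bin_id}: marker {marker} copy count {copies} invalid"
                )

    def consensus_taxonomy(self) -> Optional[str]:
        """Modal taxonomy label over all labeled genes in the bin.

        Ties broken by lexicographic label order; None when no gene is labeled.
        """
        labels = [
            lab
            for contig in self.contigs.values()
            for _, lab in contig.genes
            if lab is not None
        ]
        if not labels:
            return None
        counts = pd.Series(labels).value_counts()
        top = counts[counts == counts.max()]
        return sorted(top.index)[0]


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths (substitutions/site) and tip source tags.

    ``source`` maps tip label -> 'query' or 'reference'.
    """

    tree: dendropy.Tree
    source: dict[str, str]

    def __post_init__(self) -> None:
        tips = self.tip_labels()
        if len(tips) != len(set(tips)):
            raise ValidationError("tip label collision in tree")
        for tip in tips:
            if self.source.get(tip) not in (QUERY, REFERENCE):
                raise ValidationError(f"tip {tip} missing query/reference source tag")

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def n_tips(self) -> int:
        return len(self.tip_labels())


@dataclass
class AlignmentHit:
    """One local protein alignment surviving the score > 0 cut."""

    query_id: str
    subject_id: str
    identity: float  # % of alignment columns (gaps included) that match
    coverage: float  # % of the shorter sequence spanned by the alignment
    score: int

    def passes(self, min_identity: float, min_coverage: float) -> bool:
        return self.identity >= min_identity and self.coverage >= min_coverage


@dataclass
class AAIMatrix:
    """Symmetric genome x genome mean RBH identity with ortholog counts.

    Pairs with zero orthologs are undefined (NaN), never 0 — a zero would
    corrupt group means.  Diagonal is 100 by definition.
    """

    genomes: list[str]
    values: pd.DataFrame  # % identity, NaN where undefined
    orthologs: pd.DataFrame  # integer counts

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not np.allclose(v, v.T, equal_nan=True, atol=1e-9):
            raise ValidationError("AAI matrix not symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValidationError("AAI matrix diagonal must be 100")

    def get(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])


@dataclass
class Lineage:
    """One delineated lineage: a maximal clade under the collapse criterion."""

    lineage_id: str
    members: list[str]
    mean_intra_distance: float
    novel: bool


@dataclass
class CurationReport:
    """Per-contig removal decisions and per-bin quality-gate outcome."""

    bin_id: str
    removed: dict[str, list[str]]  # contig id -> triggering rule names
    deviations: dict[str, dict[str, float]]  # contig id -> rule -> observed value
    completeness: float
    contamination: float
    gate: str  # 'pass' or 'fail'

    def __post_init__(self) -> None:
        for contig, rules in self.removed.items():
            if not rules:
                raise ValidationError(f"removed contig {contig} cites no rule")
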