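"""Readers and writers for all external formats.

Every downstream module consumes only objects produced here: FASTA
(protein / nucleotide) via Biopython, Newick via dendropy, and
tab-separated tables with a header row via pandas.  Tables are validated
against named schemas; unknown columns are preserved but ignored.
Reading is order-stable and deterministic, and write-then-read
round-trips reproduce the in-memory object.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from magdelin.types import (
    NUCLEOTIDE_ALPHABET,
    PROTEIN_ALPHABET,
    QUERY,
    REFERENCE,
    ContigRecord,
    FormatError,
    GenomeBin,
    PhyloTree,
)

# ---------------------------------------------------------------------------
# FASTA


def gc_fraction(sequence: str) -> float:
    """GC fraction of a nucleotide sequence; N is excluded from the denominator."""
    acgt = sum(sequence.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (sequence.count("G") + sequence.count("C")) / acgt


def read_fasta(path: str | Path, alphabet: str) -> list[tuple[str, str]]:
    """Read a FASTA file as ordered (identifier, uppercased sequence) pairs.

    ``alphabet`` is 'protein' (20 standard residues) or 'nucleotide'
    (ACGTN).  Duplicate identifiers and illegal characters are hard errors.
    """
    if alphabet == "protein":
        allowed = PROTEIN_ALPHABET
    elif alphabet == "nucleotide":
        allowed = NUCLEOTIDE_ALPHABET
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        if ident in seen:
            raise FormatError(f"{path}: duplicate identifier {ident!r}")
        seen.add(ident)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {ident!r} is empty")
        for pos, char in enumerate(seq):
            if char not in allowed:
                raise FormatError(
                    f"{path}: record {ident!r}: illegal {alphabet} character "
                    f"{char!r} at position {pos + 1}"
                )
        records.append((ident, seq))
    if not records:
        raise FormatError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=ident, description="") for ident, seq in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


# ---------------------------------------------------------------------------
# Newick


def read_query_ids(path: str | Path) -> set[str]:
    """One genome id per line; blank lines ignored."""
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}


def read_newick(path: str | Path, query_ids: Iterable[str] | str | Path = ()) -> PhyloTree:
    """Parse a rooted Newick tree with branch lengths on all non-root edges.

    Tips listed in ``query_ids`` (a set of ids, or a path to a one-id-per-line
    file) are tagged 'query'; all others 'reference'.
    """
    if isinstance(query_ids, (str, Path)):
        query_ids = read_query_ids(query_ids)
    query_ids = set(query_ids)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: unparseable Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise FormatError(f"{path}: missing branch lengths")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError(f"{path}: tip label collision")
    unknown = query_ids - set(labels)
    if unknown:
        raise FormatError(f"{path}: query ids not in tree: {sorted(unknown)}")
    source = {lab: (QUERY if lab in query_ids else REFERENCE) for lab in labels}
    return PhyloTree(tree=tree, source=source)


def write_newick(ptree: PhyloTree, path: str | Path) -> None:
    text = ptree.tree.as_string(
        schema="newick", suppress_rooting=False, unquoted_underscores=True
    )
    with open(path, "w") as handle:
        handle.write(text)


def write_query_ids(ptree: PhyloTree, path: str | Path) -> None:
    queries = sorted(tip for tip, tag in ptree.source.items() if tag == QUERY)
    with open(path, "w") as handle:
        for tip in queries:
            handle.write(tip + "\n")


# ---------------------------------------------------------------------------
# Tables

#: required columns per schema; None marks the count-matrix special case
TABLE_SCHEMAS: dict[str, Optional[Sequence[str]]] = {
    "counts": None,  # contig_id + one integer column per sample
    "annotation": (
        "protein_id",
        "genome_id",
        "family_id",
        "database",
        "evalue",
        "bitscore",
        "localization",
    ),
    "taxonomy": ("gene_id", "contig_id", "label"),
    "markers": ("genome_id", "marker_id", "copies"),
    "libsizes": ("sample_id", "reads"),
    "clusters": ("member_id", "cluster_id"),
    "sites": ("genome_id", "site_id"),
    "lengths": ("id", "length"),
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a tab-separated table with a header row."""
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if schema == "counts":
        if df.shape[1] < 2 or df.columns[0] != "contig_id":
            raise FormatError(
                f"{path}: counts table needs a leading 'contig_id' column "
                "plus one column per sample"
            )
        out = df.set_index("contig_id")
        if out.index.duplicated().any():
            dup = out.index[out.index.duplicated()][0]
            raise FormatError(f"{path}: duplicate contig_id {dup!r}")
        for col in out.columns:
            try:
                values = out[col].astype(int)
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer count in column {col!r}") from exc
            if (values < 0).any():
                contig = values.index[values < 0][0]
                raise FormatError(
                    f"{path}: negative count at contig {contig!r}, sample {col!r}: "
                    f"{values.loc[contig]}"
                )
            out[col] = values
        return out

    required = TABLE_SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df.copy()
    if schema == "annotation":
        df["evalue"] = df["evalue"].astype(float)
        df["bitscore"] = df["bitscore"].astype(float)
        if (df["evalue"] < 0).any():
            row = df.index[df["evalue"] < 0][0]
            raise FormatError(f"{path}: negative e-value at row {row}")
    elif schema == "markers":
        df["copies"] = df["copies"].astype(int)
        if (df["copies"] < 0).any():
            row = df.index[df["copies"] < 0][0]
            raise FormatError(f"{path}: negative marker copy count at row {row}")
    elif schema == "libsizes":
        df["reads"] = df["reads"].astype(int)
        if (df["reads"] < 0).any():
            raise FormatError(f"{path}: negative library size")
    elif schema == "lengths":
        df["length"] = df["length"].astype(int)
        if (df["length"] < 0).any():
            raise FormatError(f"{path}: negative length")
    elif schema == "taxonomy":
        # empty or '-' labels mean 'unassigned'
        df["label"] = df["label"].replace({"": None, "-": None})
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="")


# ---------------------------------------------------------------------------
# Assembling bins from files


def load_bins(
    bins_dir: str | Path,
    markers: Optional[pd.DataFrame] = None,
    taxonomy: Optional[pd.DataFrame] = None,
    counts: Optional[pd.DataFrame] = None,
) -> dict[str, GenomeBin]:
    """Build GenomeBin objects from per-bin nucleotide FASTAs plus tables.

    Bin ids are FASTA file stems (``<bin_id>.fna``).  Gene-to-contig and
    taxonomy assignments come from the taxonomy table; per-sample read
    counts from the count matrix; marker inventories from the marker table.
    """
    bins_dir = Path(bins_dir)
    gene_map: dict[str, list[tuple[str, Optional[str]]]] = {}
    if taxonomy is not None:
        for row in taxonomy.itertuples(index=False):
            gene_map.setdefault(row.contig_id, []).append((row.gene_id, row.label))
    marker_map: dict[str, dict[str, int]] = {}
    if markers is not None:
        for row in markers.itertuples(index=False):
            marker_map.setdefault(row.genome_id, {})[row.marker_id] = int(row.copies)
    bins: dict[str, GenomeBin] = {}
    for fasta in sorted(bins_dir.glob("*.fna")):
        bin_id = fasta.stem
        contigs: dict[str, ContigRecord] = {}
        for contig_id, seq in read_fasta(fasta, "nucleotide"):
            contig_counts: dict[str, int] = {}
            if counts is not None and contig_id in counts.index:
                contig_counts = {s: int(counts.loc[contig_id, s]) for s in counts.columns}
            contigs[contig_id] = ContigRecord(
                contig_id=contig_id,
                length=len(seq),
                gc=gc_fraction(seq),
                counts=contig_counts,
                genes=gene_map.get(contig_id, []),
                sequence=seq,
            )
        bins[bin_id] = GenomeBin(
            bin_id=bin_id, contigs=contigs, markers=marker_map.get(bin_id, {})
        )
    return bins


def write_bin_fasta(bin_: GenomeBin, path: str | Path) -> None:
    records = [
        (cid, contig.sequence)
        for cid, contig in sorted(bin_.contigs.items())
        if contig.sequence is not None
    ]
    write_fasta(records, path)
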