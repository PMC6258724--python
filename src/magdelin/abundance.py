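"""Normalized abundance tables.

Cluster-level abundance: per-cluster read counts are normalized by the
total length of the cluster's contigs (bp) and by the per-sample library
size (reads), then multiplied by 1000 for readability:

    A[c, s] = counts[c, s] / (L_c * N_s) * 1000

Single-gene abundance uses the same normalization without the x1000
factor.  Contigs without a cluster assignment accumulate in an
'unbinned' row that is reported as raw counts (never normalized by a
cluster length).  ``binned_fraction`` reports the percentage of reads
recruited by binned contigs per sample.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

UNBINNED = "unbinned"


def cluster_counts(
    count_matrix: pd.DataFrame, contig_to_cluster: Mapping[str, str]
) -> pd.DataFrame:
    """Sum member-contig counts per cluster and sample.

    Unassigned contigs accumulate in the reported 'unbinned' row.
    """
    clusters = [contig_to_cluster.get(cid, UNBINNED) for cid in count_matrix.index]
    grouped = count_matrix.groupby(pd.Index(clusters, name="cluster")).sum()
    # all declared clusters appear, even when empty
    declared = sorted(set(contig_to_cluster.values()))
    order = declared + ([UNBINNED] if UNBINNED in grouped.index else [])
    return grouped.reindex(order, fill_value=0)


def normalize_cluster_abundance(
    counts: pd.DataFrame,
    cluster_lengths: Mapping[str, int],
    library_sizes: Mapping[str, int],
) -> pd.DataFrame:
    """counts / (cluster length [bp] x library size [reads]) x 1000."""
    rows = [c for c in counts.index if c != UNBINNED]
    for c in rows:
        if cluster_lengths.get(c, 0) <= 0:
            raise ValueError(f"cluster {c!r}: non-positive total contig length")
    for s in counts.columns:
        if library_sizes.get(s, 0) <= 0:
            raise ValueError(f"sample {s!r}: non-positive library size")
    table = counts.loc[rows].astype(float)
    for c in rows:
        table.loc[c] = table.loc[c] / cluster_lengths[c]
    for s in table.columns:
        table[s] = table[s] / library_sizes[s]
    return table * 1000.0


def gene_abundance(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, int],
    library_sizes: Mapping[str, int],
) -> pd.DataFrame:
    """counts / (gene length [bp] x library size [reads]); no x1000 factor."""
    for g in counts.index:
        if gene_lengths.get(g, 0) <= 0:
            raise ValueError(f"gene {g!r}: non-positive length")
    for s in counts.columns:
        if library_sizes.get(s, 0) <= 0:
            raise ValueError(f"sample {s!r}: non-positive library size")
    table = counts.astype(float)
    for g in counts.index:
        table.loc[g] = table.loc[g] / gene_lengths[g]
    for s in table.columns:
        table[s] = table[s] / library_sizes[s]
    return table


def binned_fraction(
    mapped: Mapping[str, int], totals: Mapping[str, int]
) -> tuple[pd.Series, float]:
    """Per-sample % of reads mapped to binned contigs, plus the cross-sample mean."""
    samples = sorted(totals)
    values = {}
    for s in samples:
        total = totals[s]
        if total <= 0:
            raise ValueError(f"sample {s!r}: non-positive total read count")
        values[s] = 100.0 * mapped.get(s, 0) / total
    series = pd.Series(values, name="binned_pct")
    return series, float(series.mean())
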