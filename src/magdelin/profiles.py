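"""Gene-family presence profiling per phylogenetic cluster and per site.

Multi-database hits for one protein are resolved to a single best hit
(minimum e-value, ties by maximum bit-score, then lexicographic family
id).  Presence is binary: a genome encodes a family when it has at least
one retained hit.  Cluster profiles report the fraction of member
genomes encoding each family, tiered as

    absent   fraction < 0.30
    partial  0.30 <= fraction < 0.50
    core     fraction >= 0.50

(the 30-50% / 50-100% presence bands; the shared 50% boundary is
assigned to the upper tier).  Site profiles report the percentage of a
site's genomes encoding each family and the number of distinct clusters
contributing.  ``secreted_fraction`` is the percentage of an enzyme
class's hits labeled secreted; 'unknown' localization counts in the
denominator only.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

ABSENT = "absent"
PARTIAL = "partial"
CORE = "core"

SECRETED = "secreted"


def resolve_best_hit(hits: pd.DataFrame) -> pd.Series:
    """Best hit among a single protein's rows of an annotation table."""
    if hits.empty:
        raise ValueError("no hits to resolve")
    ordered = hits.sort_values(
        ["evalue", "bitscore", "family_id"], ascending=[True, False, True], kind="mergesort"
    )
    return ordered.iloc[0]


def resolve_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """One retained (best) hit per protein id, deterministic order."""
    resolved = (
        annotations.sort_values(
            ["protein_id", "evalue", "bitscore", "family_id"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        .groupby("protein_id", as_index=False, sort=True)
        .head(1)
        .reset_index(drop=True)
    )
    return resolved


def genome_presence(
    annotations: pd.DataFrame, families: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Genome x family boolean table from resolved annotations.

    True iff the genome has >= 1 retained hit to the family.  ``families``
    restricts and orders the columns (families of interest); by default
    all observed families are used.
    """
    resolved = resolve_annotations(annotations)
    genomes = sorted(annotations["genome_id"].unique())
    if families is None:
        families = sorted(annotations["family_id"].unique())
    else:
        families = list(families)
    table = pd.DataFrame(False, index=genomes, columns=families)
    hits = resolved[resolved["family_id"].isin(set(families))]
    for row in hits.itertuples(index=False):
        table.loc[row.genome_id, row.family_id] = True
    return table


def assign_tier(fraction: float, bounds: tuple[float, float] = (0.30, 0.50)) -> str:
    lo, hi = bounds
    if fraction < lo:
        return ABSENT
    if fraction < hi:
        return PARTIAL
    return CORE


def cluster_fraction(
    presence: pd.DataFrame,
    genome_to_cluster: Mapping[str, str],
    bounds: tuple[float, float] = (0.30, 0.50),
) -> pd.DataFrame:
    """Long-form cluster profile: per cluster and family, the fraction of
    member genomes encoding the family, its tier, and the cluster size."""
    rows = []
    clusters = sorted(set(genome_to_cluster.get(g) for g in presence.index) - {None})
    for cluster in clusters:
        members = [g for g in presence.index if genome_to_cluster.get(g) == cluster]
        size = len(members)
        for family in presence.columns:
            frac = float(presence.loc[members, family].mean()) if size else 0.0
            rows.append(
                {
                    "cluster_id": cluster,
                    "family_id": family,
                    "n_genomes": size,
                    "fraction": frac,
                    "tier": assign_tier(frac, bounds),
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster_id", "family_id", "n_genomes", "fraction", "tier"]
    )


def site_profile(
    presence: pd.DataFrame,
    genome_to_site: Mapping[str, str],
    genome_to_cluster: Mapping[str, str],
    core_genes: Sequence[str],
) -> pd.DataFrame:
    """Per site and core gene family: % of the site's genomes encoding it
    and the number of distinct clusters with >= 1 encoding genome."""
    rows = []
    sites = sorted(set(genome_to_site.get(g) for g in presence.index) - {None})
    for site in sites:
        members = [g for g in presence.index if genome_to_site.get(g) == site]
        n = len(members)
        for family in core_genes:
            if family in presence.columns and n:
                encoding = [g for g in members if presence.loc[g, family]]
            else:
                encoding = []
            clusters = {
                genome_to_cluster[g] for g in encoding if g in genome_to_cluster
            }
            rows.append(
                {
                    "site_id": site,
                    "family_id": family,
                    "n_genomes": n,
                    "pct_genomes": 100.0 * len(encoding) / n if n else 0.0,
                    "n_clusters": len(clusters),
                }
            )
    return pd.DataFrame(
        rows, columns=["site_id", "family_id", "n_genomes", "pct_genomes", "n_clusters"]
    )


def secreted_fraction(
    annotations: pd.DataFrame, family_filter: Optional[Iterable[str]] = None
) -> float:
    """% of (resolved) hits in an enzyme class labeled secreted.

    'unknown' localization counts in the denominator, never the numerator.
    """
    resolved = resolve_annotations(annotations)
    if family_filter is not None:
        resolved = resolved[resolved["family_id"].isin(set(family_filter))]
    if resolved.empty:
        raise ValueError("no hits in the requested enzyme class")
    n_secreted = int((resolved["localization"] == SECRETED).sum())
    return 100.0 * n_secreted / len(resolved)
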