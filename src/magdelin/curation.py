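"""MAG quality gate and contaminant-contig removal.

Quality is estimated from a universal single-copy marker inventory:
completeness is the percentage of marker families present at least once,
contamination the percentage of extra copies.  The gate keeps genomes
that are more than 50% complete with contamination below 10% (both
bounds strict).

Three removal rules flag contaminant contigs, each computed on the
original bin in a single pass (no iteration):

* ``gc``        — GC deviates from the bin mean by more than the
                  configured relative difference (default 25%),
* ``abundance`` — mean per-base coverage (averaged over samples)
                  deviates likewise,
* ``taxonomy``  — the contig has labeled genes and *every* one of them
                  disagrees with the bin's modal taxonomy label.

The "25% difference compared to the mean" rule is applied as a relative
difference |x - mean| / mean; an absolute-difference variant is exposed
via configuration.  The bin mean includes the candidate contig.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Iterable, Mapping

from magdelin.config import RunConfig
from magdelin.types import CurationReport, GenomeBin

PASS = "pass"
FAIL = "fail"


def estimate_completeness(inventory: Mapping[str, int], marker_set: Iterable[str]) -> float:
    """% of marker families with at least one copy."""
    marker_set = list(marker_set)
    if not marker_set:
        raise ValueError("empty marker set")
    present = sum(1 for m in marker_set if inventory.get(m, 0) >= 1)
    return 100.0 * present / len(marker_set)


def estimate_contamination(inventory: Mapping[str, int], marker_set: Iterable[str]) -> float:
    """% of extra marker copies: 100 * sum(max(copies - 1, 0)) / |marker set|."""
    marker_set = list(marker_set)
    if not marker_set:
        raise ValueError("empty marker set")
    extra = sum(max(inventory.get(m, 0) - 1, 0) for m in marker_set)
    return 100.0 * extra / len(marker_set)


def qc_gate(completeness: float, contamination: float) -> str:
    """'pass' iff completeness > 50 and contamination < 10, both strict."""
    return PASS if (completeness > 50.0 and contamination < 10.0) else FAIL


def _deviation(value: float, mean: float, rule: str) -> float:
    if rule == "relative":
        return abs(value - mean) / mean
    return abs(value - mean)


def flag_gc_outliers(
    bin_: GenomeBin, rel_threshold: float = 0.25, rule: str = "relative"
) -> dict[str, float]:
    """Contigs whose GC deviates from the bin mean by more than the threshold.

    Returns flagged contig id -> observed deviation.  Single-contig bins
    cannot be flagged (warning, empty result).
    """
    contigs = bin_.contigs
    if len(contigs) < 2:
        warnings.warn(f"bin {bin_.bin_id}: single contig, GC outlier rule skipped")
        return {}
    mean_gc = sum(c.gc for c in contigs.values()) / len(contigs)
    if mean_gc <= 0:
        warnings.warn(f"bin {bin_.bin_id}: zero mean GC, GC outlier rule skipped")
        return {}
    out = {}
    for cid, contig in contigs.items():
        dev = _deviation(contig.gc, mean_gc, rule)
        if dev > rel_threshold:
            out[cid] = dev
    return out


def flag_abundance_outliers(
    bin_: GenomeBin, rel_threshold: float = 0.25, rule: str = "relative"
) -> dict[str, float]:
    """Same relative-difference rule applied to mean per-base coverage."""
    contigs = bin_.contigs
    if len(contigs) < 2:
        warnings.warn(f"bin {bin_.bin_id}: single contig, abundance rule skipped")
        return {}
    coverages = {cid: c.mean_coverage() for cid, c in contigs.items()}
    mean_cov = sum(coverages.values()) / len(coverages)
    if mean_cov <= 0:
        warnings.warn(f"bin {bin_.bin_id}: no mapped reads, abundance rule skipped")
        return {}
    out = {}
    for cid, cov in coverages.items():
        dev = _deviation(cov, mean_cov, rule)
        if dev > rel_threshold:
            out[cid] = dev
    return out


def flag_taxonomy_outliers(bin_: GenomeBin) -> dict[str, float]:
    """Contigs where every labeled gene disagrees with the bin consensus.

    Contigs without labeled genes are never flagged.  The reported value
    is the fraction of the contig's labeled genes disagreeing (1.0 by
    construction for flagged contigs).
    """
    consensus = bin_.consensus_taxonomy()
    if consensus is None:
        warnings.warn(f"bin {bin_.bin_id}: no labeled genes, taxonomy rule skipped")
        return {}
    out = {}
    for cid, contig in bin_.contigs.items():
        labels = [lab for _, lab in contig.genes if lab is not None]
        if labels and all(lab != consensus for lab in labels):
            out[cid] = 1.0
    return out


def curate_bin(
    bin_: GenomeBin,
    marker_set: Iterable[str],
    config: RunConfig | None = None,
) -> tuple[GenomeBin, CurationReport]:
    """Remove the union of the three flag sets and re-gate the curated bin.

    Flags are computed on the original bin, not iteratively.  Marker
    copies are not re-assigned to contigs, so the inventory (and hence
    completeness/contamination) is recomputed on the bin as curated only
    when the caller supplies contig-resolved markers; here the inventory
    is carried over unchanged, which matches marker tables reported per
    genome.  The curated bin is always emitted, with the gate decision
    recorded even when it fails.
    """
    config = config or RunConfig()
    thr = config.outlier_rel_threshold
    rule = config.outlier_rule
    gc_flags = flag_gc_outliers(bin_, thr, rule)
    ab_flags = flag_abundance_outliers(bin_, thr, rule)
    tax_flags = flag_taxonomy_outliers(bin_)

    removed: dict[str, list[str]] = {}
    deviations: dict[str, dict[str, float]] = {}
    for cid, dev in gc_flags.items():
        removed.setdefault(cid, []).append("gc")
        deviations.setdefault(cid, {})["gc"] = dev
    for cid, dev in ab_flags.items():
        removed.setdefault(cid, []).append("abundance")
        deviations.setdefault(cid, {})["abundance"] = dev
    for cid, dev in tax_flags.items():
        removed.setdefault(cid, []).append("taxonomy")
        deviations.setdefault(cid, {})["taxonomy"] = dev

    surviving = {cid: c for cid, c in bin_.contigs.items() if cid not in removed}
    if not surviving:  # degenerate: keep the original rather than an empty bin
        warnings.warn(f"bin {bin_.bin_id}: all contigs flagged; bin left unmodified")
        surviving = dict(bin_.contigs)
        removed = {}
        deviations = {}
    curated = replace(bin_, contigs=surviving)
    completeness = estimate_completeness(curated.markers, marker_set)
    contamination = estimate_contamination(curated.markers, marker_set)
    report = CurationReport(
        bin_id=bin_.bin_id,
        removed=removed,
        deviations=deviations,
        completeness=completeness,
        contamination=contamination,
        gate=qc_gate(completeness, contamination),
    )
    return curated, report
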