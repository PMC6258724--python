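"""End-to-end orchestration: simulate -> curate -> aai -> delineate ->
abundance -> profile.

Stages run in fixed order, exchange only plain files (so any stage can
be rerun standalone), and are deterministic under a fixed config+seed:
all stage output files are byte-identical across reruns.  The run
summary (``run_summary.json``) additionally records wall times and is
therefore the one output excluded from the byte-identity contract.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Optional

import pandas as pd

from magdelin import abundance as ab_mod
from magdelin import aai as aai_mod
from magdelin import curation as cur_mod
from magdelin import delineate as del_mod
from magdelin import io as mio
from magdelin import profiles as prof_mod
from magdelin import simulate as sim_mod
from magdelin.config import RunConfig

#: gene families treated as core metabolic genes in the bundled scenario
CORE_GENES_DEFAULT = [
    "mcrA", "dsrA", "pflD", "acdA", "nifH", "soxB",
    "glk", "pfk", "pta", "ackA", "cooS", "hydA",
]
#: enzyme families whose secreted fraction is reported
ENZYME_FAMILIES_DEFAULT = ["GH13", "GH23", "CE8", "M28", "S08"]

STAGES = ["simulate", "curate", "aai", "delineate", "abundance", "profile"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


def _stage_record(stage, inputs, outputs, counts, t0, seed):
    return {
        "stage": stage,
        "inputs": sorted(str(p) for p in inputs),
        "outputs": sorted(str(p) for p in outputs),
        "counts": counts,
        "wall_time_s": round(time.monotonic() - t0, 3),
        "seed": seed,
    }


def stage_simulate(config: RunConfig, outdir: Path, params: Optional[sim_mod.ScenarioParams]):
    t0 = time.monotonic()
    params = params or sim_mod.ScenarioParams()
    scenario_dir = outdir / "scenario"
    info = sim_mod.simulate_scenario(params, config.seed, scenario_dir)
    outputs = sorted(str(p) for p in scenario_dir.rglob("*") if p.is_file())
    return _stage_record(
        "simulate",
        [],
        outputs,
        {
            "genomes": info["n_genomes"],
            "bins": info["n_bins"],
            "samples": info["n_samples"],
            "annotation_hits": info["n_annotation_hits"],
        },
        t0,
        config.seed,
    )


def stage_curate(config: RunConfig, scen: Path, outdir: Path):
    t0 = time.monotonic()
    markers = mio.read_table(scen / "markers.tsv", "markers")
    taxonomy = mio.read_table(scen / "taxonomy.tsv", "taxonomy")
    counts = mio.read_table(scen / "counts.tsv", "counts")
    bins = mio.load_bins(scen / "bins", markers, taxonomy, counts)
    curated_dir = outdir / "curated_bins"
    curated_dir.mkdir(parents=True, exist_ok=True)
    report_rows = []
    removed_per_rule = {"gc": 0, "abundance": 0, "taxonomy": 0}
    passed = failed = 0
    for bin_id in sorted(bins):
        curated, report = cur_mod.curate_bin(bins[bin_id], sim_mod.MARKER_SET, config)
        mio.write_bin_fasta(curated, curated_dir / f"{bin_id}.fna")
        for cid, rules in sorted(report.removed.items()):
            for rule in rules:
                removed_per_rule[rule] += 1
            report_rows.append(
                {
                    "bin_id": bin_id,
                    "contig_id": cid,
                    "rules": ",".join(sorted(rules)),
                    "deviations": ";".join(
                        f"{r}={report.deviations[cid][r]:.4f}"
                        for r in sorted(report.deviations[cid])
                    ),
                    "completeness": round(report.completeness, 2),
                    "contamination": round(report.contamination, 2),
                    "gate": report.gate,
                }
            )
        if not report.removed:
            report_rows.append(
                {
                    "bin_id": bin_id,
                    "contig_id": "-",
                    "rules": "-",
                    "deviations": "-",
                    "completeness": round(report.completeness, 2),
                    "contamination": round(report.contamination, 2),
                    "gate": report.gate,
                }
            )
        if report.gate == cur_mod.PASS:
            passed += 1
        else:
            failed += 1
    report_df = pd.DataFrame(
        report_rows,
        columns=[
            "bin_id", "contig_id", "rules", "deviations",
            "completeness", "contamination", "gate",
        ],
    )
    mio.write_table(report_df, outdir / "curation_report.tsv")
    outputs = [outdir / "curation_report.tsv"] + sorted(curated_dir.glob("*.fna"))
    return _stage_record(
        "curate",
        [scen / "bins", scen / "markers.tsv", scen / "taxonomy.tsv", scen / "counts.tsv"],
        outputs,
        {
            "bins_pass": passed,
            "bins_fail": failed,
            "removed_gc": removed_per_rule["gc"],
            "removed_abundance": removed_per_rule["abundance"],
            "removed_taxonomy": removed_per_rule["taxonomy"],
            "contigs_removed": int(report_df["contig_id"].ne("-").sum()),
        },
        t0,
        config.seed,
    )


def stage_aai(config: RunConfig, scen: Path, outdir: Path):
    t0 = time.monotonic()
    proteome_files = sorted((scen / "genomes").glob("*.faa"))
    proteomes = {
        f.stem: dict(mio.read_fasta(f, "protein")) for f in proteome_files
    }
    matrix = aai_mod.build_aai_matrix(
        proteomes, config.min_identity, config.min_coverage,
        aai_mod.Scoring(gap_open=config.gap_open, gap_extend=config.gap_extend),
    )
    aai_mod.save_aai(matrix, outdir / "aai.tsv")
    n_pairs = len(matrix.genomes) * (len(matrix.genomes) - 1) // 2
    return _stage_record(
        "aai",
        proteome_files,
        [outdir / "aai.tsv"],
        {"genomes": len(matrix.genomes), "pairs": n_pairs},
        t0,
        config.seed,
    )


def stage_delineate(config: RunConfig, scen: Path, outdir: Path):
    t0 = time.monotonic()
    ptree = mio.read_newick(scen / "tree.nwk", scen / "query_ids.txt")
    matrix = aai_mod.load_aai(outdir / "aai.tsv")
    lineages = del_mod.collapse_lineages(ptree, config.collapse_threshold)
    report = del_mod.delineation_report(
        lineages, matrix, singleton_floor=config.singleton_aai_floor
    )
    report["mean_intra_distance"] = report["mean_intra_distance"].round(6)
    mio.write_table(report, outdir / "lineages.tsv")
    return _stage_record(
        "delineate",
        [scen / "tree.nwk", scen / "query_ids.txt", outdir / "aai.tsv"],
        [outdir / "lineages.tsv"],
        {
            "lineages": len(report),
            "novel": int(report["novel"].sum()),
            "candidates": int((report["status"] == "candidate").sum()),
        },
        t0,
        config.seed,
    )


def stage_abundance(config: RunConfig, scen: Path, outdir: Path):
    t0 = time.monotonic()
    counts = mio.read_table(scen / "counts.tsv", "counts")
    clusters = mio.read_table(scen / "clusters.tsv", "clusters")
    libsizes_df = mio.read_table(scen / "libsizes.tsv", "libsizes")
    library_sizes = dict(zip(libsizes_df["sample_id"], libsizes_df["reads"]))
    genome_to_cluster = dict(zip(clusters["member_id"], clusters["cluster_id"]))
    # contig -> cluster via the curated bins (contigs surviving curation)
    curated = mio.load_bins(outdir / "curated_bins")
    contig_to_cluster = {}
    cluster_lengths: dict[str, int] = {}
    for bin_id, bin_ in curated.items():
        cluster = genome_to_cluster.get(bin_id)
        if cluster is None:
            continue
        for cid, contig in bin_.contigs.items():
            contig_to_cluster[cid] = cluster
            cluster_lengths[cluster] = cluster_lengths.get(cluster, 0) + contig.length
    ccounts = ab_mod.cluster_counts(counts, contig_to_cluster)
    table = ab_mod.normalize_cluster_abundance(ccounts, cluster_lengths, library_sizes)
    mio.write_table(table.reset_index(names="cluster_id"), outdir / "abundance.tsv")
    mapped = {
        s: int(counts.loc[[c for c in counts.index if c in contig_to_cluster], s].sum())
        for s in counts.columns
    }
    per_sample, mean_pct = ab_mod.binned_fraction(mapped, library_sizes)
    bf = per_sample.reset_index()
    bf.columns = ["sample_id", "binned_pct"]
    bf["binned_pct"] = bf["binned_pct"].round(4)
    mio.write_table(bf, outdir / "binned_fraction.tsv")
    return _stage_record(
        "abundance",
        [scen / "counts.tsv", scen / "clusters.tsv", scen / "libsizes.tsv"],
        [outdir / "abundance.tsv", outdir / "binned_fraction.tsv"],
        {
            "clusters": len(table),
            "samples": len(table.columns),
            "mean_binned_pct": round(mean_pct, 3),
        },
        t0,
        config.seed,
    )


def stage_profile(config: RunConfig, scen: Path, outdir: Path):
    t0 = time.monotonic()
    annotations = mio.read_table(scen / "annotations.tsv", "annotation")
    clusters = mio.read_table(scen / "clusters.tsv", "clusters")
    sites = mio.read_table(scen / "sites.tsv", "sites")
    genome_to_cluster = dict(zip(clusters["member_id"], clusters["cluster_id"]))
    genome_to_site = dict(zip(sites["genome_id"], sites["site_id"]))
    core_genes = list(config.core_genes) or CORE_GENES_DEFAULT
    families = sorted(
        set(core_genes)
        | (set(annotations["family_id"]) - {f for f in annotations["family_id"] if f.startswith("DECOY")})
    )
    presence = prof_mod.genome_presence(annotations, families)
    profile = prof_mod.cluster_fraction(
        presence, genome_to_cluster, (config.tier_partial, config.tier_core)
    )
    profile["fraction"] = profile["fraction"].round(6)
    mio.write_table(profile, outdir / "cluster_profile.tsv")
    site_prof = prof_mod.site_profile(
        presence, genome_to_site, genome_to_cluster, core_genes
    )
    site_prof["pct_genomes"] = site_prof["pct_genomes"].round(4)
    mio.write_table(site_prof, outdir / "site_profile.tsv")
    enzyme_hits = annotations[annotations["family_id"].isin(ENZYME_FAMILIES_DEFAULT)]
    if len(enzyme_hits):
        secreted_pct = prof_mod.secreted_fraction(annotations, ENZYME_FAMILIES_DEFAULT)
    else:
        secreted_pct = float("nan")
    secreted = pd.DataFrame(
        [{"enzyme_class": "CAZyme+peptidase", "secreted_pct": round(secreted_pct, 4)}]
    )
    mio.write_table(secreted, outdir / "secreted.tsv")
    return _stage_record(
        "profile",
        [scen / "annotations.tsv", scen / "clusters.tsv", scen / "sites.tsv"],
        [outdir / "cluster_profile.tsv", outdir / "site_profile.tsv", outdir / "secreted.tsv"],
        {
            "clusters_profiled": int(profile["cluster_id"].nunique()),
            "families": int(profile["family_id"].nunique()),
            "sites": int(site_prof["site_id"].nunique()) if len(site_prof) else 0,
        },
        t0,
        config.seed,
    )


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    params: Optional[sim_mod.ScenarioParams] = None,
) -> dict:
    """Run all stages in fixed order; returns the run summary dict.

    A stage failure raises :class:`StageError` after writing the partial
    summary, so callers can exit non-zero with provenance intact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    scen = outdir / "scenario"
    summary: dict = {"seed": config.seed, "stages": []}

    def save_summary():
        with open(outdir / "run_summary.json", "w") as handle:
            json.dump(summary, handle, indent=2, sort_keys=True)

    stage_fns = [
        ("simulate", lambda: stage_simulate(config, outdir, params)),
        ("curate", lambda: stage_curate(config, scen, outdir)),
        ("aai", lambda: stage_aai(config, scen, outdir)),
        ("delineate", lambda: stage_delineate(config, scen, outdir)),
        ("abundance", lambda: stage_abundance(config, scen, outdir)),
        ("profile", lambda: stage_profile(config, scen, outdir)),
    ]
    for name, fn in stage_fns:
        try:
            summary["stages"].append(fn())
        except Exception as exc:
            summary["failed_stage"] = name
            summary["error"] = str(exc)
            save_summary()
            raise StageError(name, str(exc)) from exc
        save_summary()
    return summary
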