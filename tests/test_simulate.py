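"""Synthetic data generators: determinism, planted structure, truth files."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scistats

from magdelin import io as mio
from magdelin import simulate as sim
from magdelin.types import QUERY, REFERENCE
from tests._oracles import mc_site_identity, path_edges


# ---------------------------------------------------------------------------
# simulate_tree


def test_tree_single_clade_distances_near_scale():
    ptree, truth = sim.simulate_tree(1, 3, 0.1, 1.0, seed=7)
    assert ptree.n_tips() == 3
    from magdelin.delineate import patristic_distances

    d = patristic_distances(ptree)
    tips = list(d.index)
    pair_d = [d.iloc[i, j] for i in range(3) for j in range(i + 1, 3)]
    assert np.mean(pair_d) == pytest.approx(0.1, abs=1e-9)  # exact rescaling
    assert max(pair_d) <= 0.3  # all on the 0.1 scale


def test_tree_clades_monophyletic_and_separated():
    ptree, truth = sim.simulate_tree(3, 4, 0.2, 1.0, seed=11)
    from magdelin.delineate import patristic_distances

    d = patristic_distances(ptree)
    within, between = [], []
    for a in d.index:
        for b in d.index:
            if a >= b:
                continue
            (within if truth.clade_of[a] == truth.clade_of[b] else between).append(
                d.loc[a, b]
            )
    assert max(within) < min(between)


def test_tree_deterministic_newick(tmp_path):
    for k in (1, 2):
        ptree, _ = sim.simulate_tree(2, 2, 0.1, 1.0, seed=1)
        mio.write_newick(ptree, tmp_path / f"t{k}.nwk")
    assert (tmp_path / "t1.nwk").read_bytes() == (tmp_path / "t2.nwk").read_bytes()


def test_tree_equal_scales_rejected():
    with pytest.raises(ValueError, match="intra_scale < inter_scale"):
        sim.simulate_tree(2, 2, 0.5, 0.5, seed=0)


def test_tree_reference_tagging():
    ptree, _ = sim.simulate_tree(2, 3, 0.1, 1.0, seed=3, reference_tips_per_clade=[2, 0])
    tags = ptree.source
    assert sum(1 for t in tags.values() if t == REFERENCE) == 2
    assert all(tags[f"c2_t{k}"] == QUERY for k in (1, 2, 3))


def test_expected_site_identity_matches_mc_oracle():
    ptree, _ = sim.simulate_tree(2, 2, 0.1, 0.9, seed=13)
    tips = sorted(ptree.tip_labels())
    for a, b in [(tips[0], tips[1]), (tips[0], tips[2])]:
        closed = sim.expected_site_identity(ptree, a, b)
        ea, eb = path_edges(ptree.tree, a, b)
        mc = mc_site_identity(ea, eb, n_sites=200_000, seed=5)
        assert closed == pytest.approx(mc, abs=0.005)


# ---------------------------------------------------------------------------
# evolve_proteomes


def test_zero_branch_lengths_identical_proteomes(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("[&R] (a:0.0,b:0.0);\n")
    ptree = mio.read_newick(p, {"a", "b"})
    proteomes = sim.evolve_proteomes(ptree, 5, 50, seed=2)
    seqs_a = sorted(proteomes["a"].values())
    seqs_b = sorted(proteomes["b"].values())
    assert seqs_a == seqs_b
    assert sim.realized_identity(proteomes["a"], proteomes["b"]) == pytest.approx(100.0)


def test_realized_identity_matches_site_oracle():
    ptree, _ = sim.simulate_tree(1, 2, 0.05, 1.0, seed=4)
    proteomes = sim.evolve_proteomes(ptree, 50, 200, seed=9)
    a, b = sorted(proteomes)
    realized = sim.realized_identity(proteomes[a], proteomes[b])
    ea, eb = path_edges(ptree.tree, a, b)
    oracle = 100.0 * mc_site_identity(ea, eb, n_sites=100_000, seed=1)
    assert realized == pytest.approx(oracle, abs=2.0)


def test_evolve_proteomes_deterministic():
    ptree, _ = sim.simulate_tree(2, 2, 0.1, 1.0, seed=6)
    p1 = sim.evolve_proteomes(ptree, 4, 30, seed=8)
    p2 = sim.evolve_proteomes(ptree, 4, 30, seed=8)
    assert p1 == p2


def test_evolve_proteomes_preconditions():
    ptree, _ = sim.simulate_tree(1, 2, 0.1, 1.0, seed=0)
    with pytest.raises(ValueError, match="protein_length"):
        sim.evolve_proteomes(ptree, 5, 9, seed=0)
    with pytest.raises(ValueError, match="n_proteins"):
        sim.evolve_proteomes(ptree, 0, 50, seed=0)


def test_identity_nonincreasing_in_distance():
    """Rank correlation between patristic distance and realized identity
    is negative across 20 tip pairs."""
    ptree, _ = sim.simulate_tree(4, 3, 0.1, 1.5, seed=21)
    proteomes = sim.evolve_proteomes(ptree, 30, 100, seed=22)
    rng = np.random.default_rng(23)
    tips = sorted(proteomes)
    pairs = set()
    while len(pairs) < 20:
        a, b = rng.choice(len(tips), size=2, replace=False)
        pairs.add((tips[min(a, b)], tips[max(a, b)]))
    dist = [sim.patristic_distance(ptree, a, b) for a, b in pairs]
    ident = [sim.realized_identity(proteomes[a], proteomes[b]) for a, b in pairs]
    rho, _ = scistats.spearmanr(dist, ident)
    assert rho < 0


# ---------------------------------------------------------------------------
# simulate_bins


def test_bins_contaminant_count_floor():
    bins, truth = sim.simulate_bins(
        ["g1", "g2"], 10, 0.2, 0.3, 0.4, seed=3
    )
    for g in ("g1", "g2"):
        assert len(truth.contaminants[g]) == 2  # floor(10 * 0.2)


def test_bins_minimum_contig_length():
    bins, _ = sim.simulate_bins(["g1"], 20, 0.1, 0.3, 0.4, seed=5)
    assert all(c.length >= 2000 for c in bins["g1"].contigs.values())


def test_bins_clean_case_no_outliers():
    bins, truth = sim.simulate_bins(["g1"], 12, 0.0, 0.3, 0.4, seed=7)
    assert truth.contaminants["g1"] == []
    gcs = [c.gc for c in bins["g1"].contigs.values()]
    mean_gc = np.mean(gcs)
    assert all(abs(gc - mean_gc) / mean_gc < 0.25 for gc in gcs)


def test_bins_contaminants_displaced_and_foreign():
    bins, truth = sim.simulate_bins(["g1"], 10, 0.2, 0.3, 0.4, seed=9)
    bin_ = bins["g1"]
    mean_gc = np.mean([c.gc for c in bin_.contigs.values()])
    for cid in truth.contaminants["g1"]:
        contig = bin_.contigs[cid]
        assert abs(contig.gc - mean_gc) / mean_gc > 0.25
        labels = [lab for _, lab in contig.genes if lab is not None]
        assert labels and all(lab.startswith("taxon_foreign") for lab in labels)


def test_bins_zero_offset_rejected_with_contaminants():
    with pytest.raises(ValueError, match="gc_offset"):
        sim.simulate_bins(["g1"], 10, 0.2, 0.0, 0.4, seed=1)


def test_bins_marker_inventory_planted():
    bins, truth = sim.simulate_bins(["g1"], 10, 0.1, 0.3, 0.4, seed=13)
    inv = truth.marker_inventory["g1"]
    assert set(inv) == set(sim.MARKER_SET)
    assert bins["g1"].markers == inv
    assert sum(1 for v in inv.values() if v == 0) <= 4
    assert sum(1 for v in inv.values() if v == 2) <= 1


def test_bins_deterministic():
    a, _ = sim.simulate_bins(["g1"], 8, 0.1, 0.3, 0.4, seed=2)
    b, _ = sim.simulate_bins(["g1"], 8, 0.1, 0.3, 0.4, seed=2)
    assert {c.sequence for c in a["g1"].contigs.values()} == {
        c.sequence for c in b["g1"].contigs.values()
    }


# ---------------------------------------------------------------------------
# simulate_counts


def _small_bins(seed=4):
    bins, truth = sim.simulate_bins(["g1", "g2"], 6, 0.0, 0.3, 0.4, seed=seed)
    return bins, truth


def test_counts_columns_sum_to_depth():
    bins, truth = _small_bins()
    counts, _ = sim.simulate_counts(bins, 3, 10_000, seed=5, truth=truth)
    assert (counts.sum(axis=0) == 10_000).all()


def test_counts_deterministic():
    bins, truth = _small_bins()
    a, _ = sim.simulate_counts(bins, 2, 5000, seed=6, truth=truth)
    bins2, truth2 = _small_bins()
    b, _ = sim.simulate_counts(bins2, 2, 5000, seed=6, truth=truth2)
    assert a.equals(b)


def test_counts_follow_planted_abundance():
    """Observed cluster read shares match the planted expectation within 5%
    for well-covered clusters."""
    bins, truth = _small_bins(seed=8)
    depth = 200_000
    counts, truth = sim.simulate_counts(bins, 2, depth, seed=9, truth=truth)
    lengths = {
        cid: c.length for b in bins.values() for cid, c in b.contigs.items()
    }
    cluster_of = {cid: g for g in bins for cid in bins[g].contigs}
    for s in counts.columns:
        expected = {
            g: sum(lengths[cid] for cid in bins[g].contigs)
            * truth.cluster_abundance.loc[g, s]
            for g in bins
        }
        total = sum(expected.values())
        for g in bins:
            exp_reads = depth * expected[g] / total
            obs = counts.loc[[cid for cid in counts.index if cluster_of[cid] == g], s].sum()
            if exp_reads >= 10_000:
                assert abs(obs - exp_reads) / exp_reads < 0.05


def test_abundance_rank_recovery_end_to_end():
    """Normalized abundances rank like the planted cluster abundances."""
    from magdelin import abundance as ab

    for seed in range(10):
        bins, truth = sim.simulate_bins(
            [f"g{k}" for k in range(5)], 8, 0.0, 0.3, 0.4, seed=100 + seed
        )
        counts, truth = sim.simulate_counts(bins, 2, 150_000, seed=200 + seed, truth=truth)
        contig_to_cluster = {cid: g for g in bins for cid in bins[g].contigs}
        lengths = {
            g: sum(c.length for c in bins[g].contigs.values()) for g in bins
        }
        ccounts = ab.cluster_counts(counts, contig_to_cluster)
        table = ab.normalize_cluster_abundance(
            ccounts, lengths, {s: 150_000 for s in counts.columns}
        )
        for s in counts.columns:
            rho, _ = scistats.spearmanr(
                table[s].loc[sorted(bins)], truth.cluster_abundance[s].loc[sorted(bins)]
            )
            assert rho >= 0.9


# ---------------------------------------------------------------------------
# simulate_annotations


def test_annotations_presence_prob_extremes():
    genomes = ["g1", "g2", "g3"]
    prob = {("g1", "famA"): 1.0, ("g2", "famA"): 0.0}
    table, _ = sim.simulate_annotations(genomes, ["famA"], prob, 0.0, seed=3)
    primary = table[table["database"] == "primary_db"]
    assert set(primary["genome_id"]) == {"g1"}


def test_annotations_decoys_strictly_worse():
    prob = {("g1", "famA"): 1.0}
    table, _ = sim.simulate_annotations(["g1"], ["famA"], prob, 0.0, seed=1, decoy_prob=1.0)
    primary = table[table["database"] == "primary_db"].iloc[0]
    decoy = table[table["database"] == "decoy_db"].iloc[0]
    assert decoy["protein_id"] == primary["protein_id"]
    assert decoy["evalue"] > primary["evalue"]
    assert decoy["bitscore"] < primary["bitscore"]
    assert decoy["family_id"].startswith("DECOY")


def test_annotations_secretion_binomial_bound():
    genomes = [f"g{k}" for k in range(200)]
    families = [f"fam{k}" for k in range(50)]
    prob = {(g, f): 1.0 for g in genomes for f in families}
    table, _ = sim.simulate_annotations(genomes, families, prob, 0.02, seed=5, decoy_prob=0.0)
    n = len(table)
    assert n == 10_000
    secreted = int((table["localization"] == "secreted").sum())
    # a secreted label survives unless overwritten by the 5% 'unknown' draw
    p = 0.02 * 0.95
    sd = np.sqrt(n * p * (1 - p))
    assert abs(secreted - n * p) <= 3 * sd


def test_annotations_deterministic():
    prob = {("g1", "famA"): 0.7, ("g1", "famB"): 0.5}
    a, _ = sim.simulate_annotations(["g1"], ["famA", "famB"], prob, 0.1, seed=11)
    b, _ = sim.simulate_annotations(["g1"], ["famA", "famB"], prob, 0.1, seed=11)
    assert a.equals(b)


# ---------------------------------------------------------------------------
# simulate_scenario


def test_scenario_writes_complete_layout(tmp_path):
    params = sim.ScenarioParams(
        n_clades=2, tips_per_clade=2, n_bins=2, n_contigs=6,
        n_samples=2, depth=5000, n_proteins=5, protein_length=60,
        n_reference_clades=1,
    )
    info = sim.simulate_scenario(params, seed=42, outdir=tmp_path / "scen")
    scen = tmp_path / "scen"
    for rel in (
        "tree.nwk", "query_ids.txt", "counts.tsv", "libsizes.tsv",
        "annotations.tsv", "taxonomy.tsv", "markers.tsv", "clusters.tsv",
        "sites.tsv", "truth/clades.tsv", "truth/contaminants.tsv",
        "truth/cluster_abundance.tsv", "truth/presence_prob.tsv",
    ):
        assert (scen / rel).exists(), rel
    assert len(list((scen / "genomes").glob("*.faa"))) == info["n_genomes"]
    assert len(list((scen / "bins").glob("*.fna"))) == info["n_bins"]
    # every emitted file parses back through the package readers
    mio.read_newick(scen / "tree.nwk", scen / "query_ids.txt")
    mio.read_table(scen / "counts.tsv", "counts")
    mio.read_table(scen / "annotations.tsv", "annotation")
    mio.read_table(scen / "markers.tsv", "markers")
    mio.read_table(scen / "taxonomy.tsv", "taxonomy")


def test_scenario_deterministic(tmp_path):
    import hashlib

    def digest(d):
        return {
            str(p.relative_to(d)): hashlib.md5(p.read_bytes()).hexdigest()
            for p in sorted(d.rglob("*"))
            if p.is_file()
        }

    params = sim.ScenarioParams(
        n_clades=2, tips_per_clade=2, n_bins=2, n_contigs=5,
        n_samples=2, depth=2000, n_proteins=4, protein_length=50,
        n_reference_clades=1,
    )
    sim.simulate_scenario(params, seed=7, outdir=tmp_path / "a")
    sim.simulate_scenario(params, seed=7, outdir=tmp_path / "b")
    assert digest(tmp_path / "a") == digest(tmp_path / "b")
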