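"""Quality estimates, the gate, and the three contaminant-removal rules."""

import dataclasses

import pytest

from magdelin import curation as cur
from magdelin.config import RunConfig
from magdelin.simulate import MARKER_SET
from magdelin.types import GenomeBin
from tests.conftest import make_contig


def _inventory(present=37, duplicated=0):
    inv = {m: 0 for m in MARKER_SET}
    for m in MARKER_SET[:present]:
        inv[m] = 1
    for m in MARKER_SET[:duplicated]:
        inv[m] = 2
    return inv


# ---------------------------------------------------------------------------
# Completeness / contamination / gate


def test_completeness_all_present():
    assert cur.estimate_completeness(_inventory(37), MARKER_SET) == pytest.approx(100.0)


def test_completeness_none_present():
    assert cur.estimate_completeness(_inventory(0), MARKER_SET) == pytest.approx(0.0)


def test_completeness_30_of_37():
    assert cur.estimate_completeness(_inventory(30), MARKER_SET) == pytest.approx(
        81.08, abs=0.01
    )


def test_contamination_all_single_copy():
    assert cur.estimate_contamination(_inventory(37), MARKER_SET) == pytest.approx(0.0)


def test_contamination_one_duplicate():
    assert cur.estimate_contamination(
        _inventory(37, duplicated=1), MARKER_SET
    ) == pytest.approx(2.70, abs=0.01)


def test_contamination_every_marker_duplicated():
    inv = {m: 2 for m in MARKER_SET}
    assert cur.estimate_contamination(inv, MARKER_SET) == pytest.approx(100.0)


def test_empty_marker_set_rejected():
    with pytest.raises(ValueError, match="empty marker set"):
        cur.estimate_completeness({}, [])
    with pytest.raises(ValueError, match="empty marker set"):
        cur.estimate_contamination({}, [])


def test_qc_gate_examples():
    assert cur.qc_gate(51.0, 9.0) == "pass"
    assert cur.qc_gate(50.0, 5.0) == "fail"
    assert cur.qc_gate(90.0, 10.0) == "fail"


# ---------------------------------------------------------------------------
# GC rule


def test_gc_outlier_flagged():
    contigs = {
        "c1": make_contig("c1", gc=0.45),
        "c2": make_contig("c2", gc=0.45),
        "c3": make_contig("c3", gc=0.65),
    }
    # bin mean includes the candidate: (0.45+0.45+0.65)/3 = 0.51667
    bin_ = GenomeBin(bin_id="b", contigs=contigs)
    flags = cur.flag_gc_outliers(bin_, 0.25)
    assert set(flags) == {"c3"}
    assert flags["c3"] == pytest.approx(abs(0.65 - 0.51666667) / 0.51666667)


def test_gc_at_mean_not_flagged():
    contigs = {f"c{k}": make_contig(f"c{k}", gc=0.50) for k in range(3)}
    assert cur.flag_gc_outliers(GenomeBin(bin_id="b", contigs=contigs)) == {}


def test_gc_deviation_at_20_percent_not_flagged():
    # deviations of exactly 0.20 relative: below the 0.25 threshold
    contigs = {
        "c1": make_contig("c1", gc=0.40),
        "c2": make_contig("c2", gc=0.60),
    }  # mean 0.50; |x-mean|/mean = 0.20 for both
    assert cur.flag_gc_outliers(GenomeBin(bin_id="b", contigs=contigs), 0.25) == {}


def test_gc_single_contig_warns_empty():
    bin_ = GenomeBin(bin_id="b", contigs={"c1": make_contig("c1", gc=0.5)})
    with pytest.warns(UserWarning, match="single contig"):
        assert cur.flag_gc_outliers(bin_) == {}


def test_gc_absolute_rule_variant():
    contigs = {
        "c1": make_contig("c1", gc=0.35),
        "c2": make_contig("c2", gc=0.65),
    }  # mean 0.50; absolute deviation 0.15 each; relative 0.30 each
    bin_ = GenomeBin(bin_id="b", contigs=contigs)
    assert cur.flag_gc_outliers(bin_, 0.25, rule="absolute") == {}
    assert set(cur.flag_gc_outliers(bin_, 0.25, rule="relative")) == {"c1", "c2"}


# ---------------------------------------------------------------------------
# Abundance rule


def test_abundance_uniform_coverage_not_flagged():
    contigs = {
        f"c{k}": make_contig(f"c{k}", length=2000, counts={"s1": 4000}) for k in range(4)
    }
    assert cur.flag_abundance_outliers(GenomeBin(bin_id="b", contigs=contigs)) == {}


def test_abundance_outlier_flagged():
    # coverages 10, 10, 10, 14 -> mean 11; |14-11|/11 = 0.27 > 0.25
    contigs = {
        "c1": make_contig("c1", length=1000, counts={"s1": 10_000}),
        "c2": make_contig("c2", length=1000, counts={"s1": 10_000}),
        "c3": make_contig("c3", length=1000, counts={"s1": 10_000}),
        "c4": make_contig("c4", length=1000, counts={"s1": 14_000}),
    }
    flags = cur.flag_abundance_outliers(GenomeBin(bin_id="b", contigs=contigs))
    assert set(flags) == {"c4"}
    assert flags["c4"] == pytest.approx(3.0 / 11.0)


def test_abundance_no_reads_warns_empty():
    contigs = {f"c{k}": make_contig(f"c{k}", counts={"s1": 0}) for k in range(3)}
    with pytest.warns(UserWarning, match="no mapped reads"):
        assert cur.flag_abundance_outliers(GenomeBin(bin_id="b", contigs=contigs)) == {}


def test_mean_coverage_averages_samples():
    c = make_contig("c1", length=1000, counts={"s1": 1000, "s2": 3000})
    assert c.mean_coverage() == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# Taxonomy rule


def _tax_bin():
    contigs = {
        "c1": make_contig("c1", genes=[("g1", "X"), ("g2", "X")]),
        "c2": make_contig("c2", genes=[("g3", "X"), ("g4", "X"), ("g5", "Y")]),
        "c3": make_contig("c3", genes=[("g6", "Y"), ("g7", "Y")]),
        "c4": make_contig("c4", genes=[("g8", None)]),
    }
    return GenomeBin(bin_id="b", contigs=contigs)


def test_taxonomy_consensus_is_modal():
    assert _tax_bin().consensus_taxonomy() == "X"


def test_taxonomy_partial_disagreement_not_flagged():
    flags = cur.flag_taxonomy_outliers(_tax_bin())
    assert "c2" not in flags  # has an X gene: not all differ


def test_taxonomy_all_genes_differ_flagged():
    flags = cur.flag_taxonomy_outliers(_tax_bin())
    assert set(flags) == {"c3"}


def test_taxonomy_unlabeled_contig_never_flagged():
    flags = cur.flag_taxonomy_outliers(_tax_bin())
    assert "c4" not in flags


def test_taxonomy_no_labels_warns_empty():
    contigs = {"c1": make_contig("c1", genes=[("g1", None)]),
               "c2": make_contig("c2")}
    with pytest.warns(UserWarning, match="no labeled genes"):
        assert cur.flag_taxonomy_outliers(GenomeBin(bin_id="b", contigs=contigs)) == {}


# ---------------------------------------------------------------------------
# curate_bin


def test_curate_clean_bin_no_removals(clean_bin):
    curated, report = cur.curate_bin(clean_bin, MARKER_SET)
    assert report.removed == {}
    assert curated.contigs == clean_bin.contigs
    assert report.gate == "pass"
    assert report.completeness == pytest.approx(100.0)
    assert report.contamination == pytest.approx(0.0)


def test_curate_removes_union_and_cites_rules(clean_bin):
    contigs = dict(clean_bin.contigs)
    contigs["bad"] = make_contig(
        "bad",
        length=2000,
        gc=0.80,  # GC outlier
        counts={"s1": 2000, "s2": 4000},
        genes=[("bad_g1", "taxon_foreign")],  # taxonomy outlier
    )
    bin_ = GenomeBin(bin_id="b1", contigs=contigs, markers=clean_bin.markers)
    curated, report = cur.curate_bin(bin_, MARKER_SET)
    assert set(report.removed) == {"bad"}
    assert set(report.removed["bad"]) == {"gc", "taxonomy"}
    assert "bad" not in curated.contigs
    assert set(report.deviations["bad"]) == {"gc", "taxonomy"}


def test_curate_idempotent_on_clean_data(clean_bin):
    curated, _ = cur.curate_bin(clean_bin, MARKER_SET)
    curated2, report2 = cur.curate_bin(curated, MARKER_SET)
    assert report2.removed == {}
    assert curated2.contigs == curated.contigs


def test_curate_failing_gate_still_emitted(clean_bin):
    markers = {m: 0 for m in MARKER_SET}  # completeness 0 -> gate fail
    bin_ = dataclasses.replace(clean_bin, markers=markers)
    curated, report = cur.curate_bin(bin_, MARKER_SET)
    assert report.gate == "fail"
    assert curated.contigs  # bin still emitted


def test_curate_all_flagged_keeps_original():
    contigs = {
        "c1": make_contig("c1", genes=[("g1", "X")]),
        "c2": make_contig("c2", genes=[("g2", "Y")]),
    }
    # consensus X (lexicographic tie-break); c2 taxonomy-flagged; craft GC so
    # both are GC outliers too
    contigs["c1"].gc = 0.2
    contigs["c2"].gc = 0.8
    bin_ = GenomeBin(bin_id="b", contigs=contigs)
    with pytest.warns(UserWarning, match="all contigs flagged"):
        curated, report = cur.curate_bin(bin_, MARKER_SET)
    assert set(curated.contigs) == {"c1", "c2"}
    assert report.removed == {}


def test_curate_respects_config_threshold(clean_bin):
    contigs = dict(clean_bin.contigs)
    contigs["mild"] = make_contig(
        "mild", gc=0.56, counts={"s1": 2000, "s2": 4000},
        genes=[("m_g1", "taxon_host")],
    )
    bin_ = GenomeBin(bin_id="b1", contigs=contigs, markers=clean_bin.markers)
    strict = RunConfig(outlier_rel_threshold=0.05)
    _, report = cur.curate_bin(bin_, MARKER_SET, strict)
    assert "mild" in report.removed
    lax = RunConfig(outlier_rel_threshold=0.25)
    _, report2 = cur.curate_bin(bin_, MARKER_SET, lax)
    assert report2.removed == {}


def test_removing_contigs_never_increases_contamination(clean_bin):
    """The genome-level inventory is carried over, so contamination is
    unchanged by contig removal (and never increases)."""
    before = cur.estimate_contamination(clean_bin.markers, MARKER_SET)
    curated, report = cur.curate_bin(clean_bin, MARKER_SET)
    assert report.contamination <= before + 1e-12
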