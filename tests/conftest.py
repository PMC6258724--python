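"""Shared fixtures: small hand-built bins, trees and tables."""

from __future__ import annotations

import numpy as np
import pytest

from magdelin.types import ContigRecord, GenomeBin


def make_contig(cid, length=2500, gc=0.5, counts=None, genes=None):
    return ContigRecord(
        contig_id=cid,
        length=length,
        gc=gc,
        counts=counts or {},
        genes=genes or [],
    )


@pytest.fixture
def clean_bin():
    """Four-contig bin: uniform GC, uniform coverage, consistent taxonomy."""
    contigs = {}
    for k in range(1, 5):
        cid = f"b1_ctg{k:03d}"
        contigs[cid] = make_contig(
            cid,
            length=2000,
            gc=0.50,
            counts={"s1": 2000, "s2": 4000},
            genes=[(f"{cid}_g1", "taxon_host"), (f"{cid}_g2", None)],
        )
    markers = {f"M{k:03d}": 1 for k in range(1, 38)}
    return GenomeBin(bin_id="b1", contigs=contigs, markers=markers)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
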