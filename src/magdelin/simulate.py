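"""Synthetic communities with planted ground truth.

Every generator is a pure function of (parameters, seed), and the
emitted truth records are sufficient to score each downstream stage.

Model choices (desk-scale testability over realism):

* Trees: each clade is a random bifurcating subtree whose edge lengths
  are drawn exponentially and then rescaled so the mean pairwise
  patristic distance among the clade's tips equals ``intra_scale``
  exactly; clades hang off a common root with stem lengths chosen so
  the mean cross-clade distance equals ``inter_scale`` (when clade
  depths permit).
* Proteome evolution: a root proteome is uniform over the 20 residues;
  along a branch of length d each site substitutes independently with
  probability 1 - exp(-d), the replacement uniform over the other 19
  residues.  No rate heterogeneity, no indels; orthologs share their
  position index across genomes.  Under this model the probability that
  two tips share a site's residue has the closed form
  1/20 + (19/20) * prod_e (20*exp(-d_e) - 1) / 19 over the edges e of
  the connecting path (implemented in :func:`expected_site_identity`
  and cross-checked by the Monte-Carlo oracle
  :func:`mc_site_identity`).
* Bins: one bin per genome; host contigs draw GC and coverage tightly
  around per-bin means, contaminants are displaced by at least the
  stated relative offsets (drawn from [1.25x, 1.5x] the offset so the
  planted displacement survives the shift of the bin mean that the
  contaminants themselves cause) and carry foreign taxonomy labels.
  Contaminant count per bin is floor(n_contigs * contaminant_fraction).
* Counts: per-sample multinomial with probabilities proportional to
  contig length x planted cluster abundance x per-contig coverage
  weight; column sums equal the requested depth exactly.
* Annotations: genome x family presence is Bernoulli with per-cluster
  probabilities; decoy secondary hits with strictly worse e-values
  exercise best-hit resolution; hits are secreted with probability
  ``secretion_prob``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from magdelin import io as mio
from magdelin.types import (
    QUERY,
    REFERENCE,
    ContigRecord,
    GenomeBin,
    PhyloTree,
)

#: the universal single-copy marker families used by the completeness estimator
MARKER_SET = [f"M{k:03d}" for k in range(1, 38)]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators; every simulated object
    appears in exactly one record."""

    clade_of: dict[str, str] = field(default_factory=dict)  # genome -> clade
    intra_scale: Optional[float] = None
    inter_scale: Optional[float] = None
    contaminants: dict[str, list[str]] = field(default_factory=dict)  # bin -> contigs
    contig_weights: dict[str, float] = field(default_factory=dict)
    bin_gc_mean: dict[str, float] = field(default_factory=dict)
    marker_inventory: dict[str, dict[str, int]] = field(default_factory=dict)
    cluster_abundance: Optional[pd.DataFrame] = None  # cluster x sample
    presence_prob: dict[tuple[str, str], float] = field(default_factory=dict)
    secretion_prob: Optional[float] = None


# ---------------------------------------------------------------------------
# Trees


def _join_random_topology(
    labels: Sequence[str],
    taxon_namespace: dendropy.TaxonNamespace,
    rng: np.random.Generator,
    scale: float,
) -> dendropy.Node:
    """Random bifurcating subtree over ``labels`` with exponential edge lengths."""
    nodes = []
    for lab in labels:
        leaf = dendropy.Node()
        leaf.taxon = taxon_namespace.require_taxon(label=lab)
        nodes.append(leaf)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.exponential(scale))
        b.edge.length = float(rng.exponential(scale))
        nodes.append(parent)
    return nodes[0]


def _tip_depths(clade_root: dendropy.Node) -> dict[str, float]:
    depths: dict[str, float] = {}

    def walk(node: dendropy.Node, depth: float) -> None:
        if node.is_leaf():
            depths[node.taxon.label] = depth
            return
        for child in node.child_nodes():
            walk(child, depth + child.edge.length)

    walk(clade_root, 0.0)
    return depths


def _clade_pairwise_mean(clade_root: dendropy.Node) -> float:
    """Mean pairwise patristic distance among the clade's tips (path sums)."""
    paths: dict[str, dict[int, float]] = {}

    def walk(node, acc):
        if node.is_leaf():
            paths[node.taxon.label] = dict(acc)
            return
        for child in node.child_nodes():
            acc2 = dict(acc)
            acc2[id(child)] = child.edge.length
            walk(child, acc2)

    walk(clade_root, {})
    tips = sorted(paths)
    if len(tips) < 2:
        return 0.0
    total = 0.0
    n_pairs = 0
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            shared = set(paths[a]) & set(paths[b])
            d = sum(v for k, v in paths[a].items() if k not in shared)
            d += sum(v for k, v in paths[b].items() if k not in shared)
            total += d
            n_pairs += 1
    return total / n_pairs


def _scale_clade(clade_root: dendropy.Node, factor: float) -> None:
    for node in clade_root.preorder_iter():
        if node is not clade_root and node.edge.length is not None:
            node.edge.length *= factor


def simulate_tree(
    n_clades: int,
    tips_per_clade: int,
    intra_scale: float,
    inter_scale: float,
    seed: int,
    reference_tips_per_clade: int | Sequence[int] = 0,
) -> tuple[PhyloTree, PlantedTruth]:
    """Clade-structured random tree with exact planted distance scales.

    Each clade's mean pairwise tip distance equals ``intra_scale``; the
    mean distance between tips of different clades is ``inter_scale``
    whenever mean clade depth < inter_scale / 2 (stems are floored at
    5% of inter_scale otherwise).  The first ``reference_tips_per_clade``
    tips of each clade are tagged reference, the rest query.
    """
    if n_clades < 1 or tips_per_clade < 1:
        raise ValueError("n_clades and tips_per_clade must be >= 1")
    if not (0 < intra_scale < inter_scale):
        raise ValueError(
            f"need 0 < intra_scale < inter_scale, got {intra_scale}, {inter_scale}"
        )
    if isinstance(reference_tips_per_clade, int):
        n_ref = [reference_tips_per_clade] * n_clades
    else:
        n_ref = list(reference_tips_per_clade)
        if len(n_ref) != n_clades:
            raise ValueError("reference_tips_per_clade length != n_clades")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    truth = PlantedTruth(intra_scale=intra_scale, inter_scale=inter_scale)
    source: dict[str, str] = {}
    clade_roots = []
    for ci in range(1, n_clades + 1):
        clade_id = f"c{ci}"
        labels = [f"{clade_id}_t{ti}" for ti in range(1, tips_per_clade + 1)]
        for k, lab in enumerate(labels):
            truth.clade_of[lab] = clade_id
            source[lab] = REFERENCE if k < n_ref[ci - 1] else QUERY
        root = _join_random_topology(labels, tns, rng, intra_scale / 2.0)
        if tips_per_clade > 1:
            mean_d = _clade_pairwise_mean(root)
            if mean_d > 0:
                _scale_clade(root, intra_scale / mean_d)
        clade_roots.append(root)

    if n_clades == 1:
        seed_node = clade_roots[0]
    else:
        seed_node = dendropy.Node()
        for root in clade_roots:
            depths = _tip_depths(root)
            mean_depth = sum(depths.values()) / len(depths)
            stem = max(inter_scale / 2.0 - mean_depth, 0.05 * inter_scale)
            seed_node.add_child(root)
            root.edge.length = stem
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed_node)
    tree.is_rooted = True
    return PhyloTree(tree=tree, source=source), truth


def _path_edges(ptree: PhyloTree, tip_a: str, tip_b: str) -> tuple[list[float], list[float]]:
    """Edge lengths from the MRCA down to each tip."""
    leaves = {leaf.taxon.label: leaf for leaf in ptree.tree.leaf_node_iter()}

    def ancestors(node):
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        return chain

    chain_a = ancestors(leaves[tip_a])
    chain_b = ancestors(leaves[tip_b])
    set_b = {id(n) for n in chain_b}
    mrca = next(n for n in chain_a if id(n) in set_b)

    def edges_down(chain, mrca):
        out = []
        for node in chain:
            if node is mrca:
                break
            out.append(float(node.edge.length))
        return out

    return edges_down(chain_a, mrca), edges_down(chain_b, mrca)


def patristic_distance(ptree: PhyloTree, tip_a: str, tip_b: str) -> float:
    ea, eb = _path_edges(ptree, tip_a, tip_b)
    return sum(ea) + sum(eb)


def expected_site_identity(ptree: PhyloTree, tip_a: str, tip_b: str) -> float:
    """Closed-form per-site identity probability between two tips.

    Per branch of length d the substitution kernel is
    T(d) = exp(-d) I + (1 - exp(-d)) (J - I)/19 (J the all-ones matrix),
    whose non-uniform eigenvalue is (20 exp(-d) - 1)/19; eigenvalues
    multiply along the path, giving
    P(identical) = 1/20 + (19/20) prod_e (20 exp(-d_e) - 1)/19.
    """
    ea, eb = _path_edges(ptree, tip_a, tip_b)
    lam = 1.0
    for d in ea + eb:
        lam *= (20.0 * math.exp(-d) - 1.0) / 19.0
    return 1.0 / 20.0 + (19.0 / 20.0) * lam


def mc_site_identity(
    edges_a: Sequence[float], edges_b: Sequence[float], n_sites: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo site oracle: simulate ``n_sites`` independent sites from a
    uniform ancestor down both edge paths under the generator's per-site
    substitution rule and return the fraction of identical sites."""
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 20, size=n_sites)

    def evolve(state, edges):
        for d in edges:
            mask = rng.random(n_sites) < 1.0 - np.exp(-d)
            shift = rng.integers(1, 20, size=n_sites)
            state = np.where(mask, (state + shift) % 20, state)
        return state

    a = evolve(anc.copy(), edges_a)
    b = evolve(anc.copy(), edges_b)
    return float(np.mean(a == b))


# ---------------------------------------------------------------------------
# Proteomes


def evolve_proteomes(
    ptree: PhyloTree, n_proteins: int, protein_length: int, seed: int
) -> dict[str, dict[str, str]]:
    """Evolve a root proteome down the tree; returns genome -> {protein id: seq}.

    Orthologs share their index across genomes (protein k of genome A is
    the ortholog of protein k of genome B).
    """
    if protein_length < 10:
        raise ValueError("protein_length must be >= 10")
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    n_sites = n_proteins * protein_length
    root_state = rng.integers(0, 20, size=n_sites, dtype=np.int8)
    sequences: dict[str, np.ndarray] = {}

    def walk(node, state):
        for child in node.child_nodes():
            d = float(child.edge.length)
            child_state = state.copy()
            if d > 0:
                mask = rng.random(n_sites) < 1.0 - np.exp(-d)
                shift = rng.integers(1, 20, size=n_sites).astype(np.int8)
                child_state = np.where(mask, (state + shift) % 20, state).astype(np.int8)
            if child.is_leaf():
                sequences[child.taxon.label] = child_state
            else:
                walk(child, child_state)

    root = ptree.tree.seed_node
    if root.is_leaf():
        sequences[root.taxon.label] = root_state
    else:
        walk(root, root_state)

    aa = np.array(list(AA_ORDER))
    out: dict[str, dict[str, str]] = {}
    for genome, state in sequences.items():
        chars = aa[state]
        proteome = {}
        for k in range(n_proteins):
            seq = "".join(chars[k * protein_length : (k + 1) * protein_length])
            proteome[f"{genome}_p{k + 1:04d}"] = seq
        out[genome] = proteome
    return out


def realized_identity(proteome_a: Mapping[str, str], proteome_b: Mapping[str, str]) -> float:
    """Positionwise identity (%) between ortholog pairs (shared index)."""
    seqs_a = [proteome_a[k] for k in sorted(proteome_a)]
    seqs_b = [proteome_b[k] for k in sorted(proteome_b)]
    same = total = 0
    for sa, sb in zip(seqs_a, seqs_b):
        same += sum(1 for x, y in zip(sa, sb) if x == y)
        total += len(sa)
    return 100.0 * same / total


# ---------------------------------------------------------------------------
# Bins


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    bases = np.array(list("ATGC"))
    probs = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    return "".join(rng.choice(bases, size=length, p=probs))


def simulate_bins(
    proteomes: Mapping[str, Mapping[str, str]] | Sequence[str],
    n_contigs: int,
    contaminant_fraction: float,
    gc_offset: float,
    coverage_offset: float,
    seed: int,
    clade_of: Optional[Mapping[str, str]] = None,
    contaminant_mode: str = "both",
    min_contig_length: int = 2000,
    max_missing_markers: int = 4,
    max_duplicated_markers: int = 1,
) -> tuple[dict[str, GenomeBin], PlantedTruth]:
    """One contaminated bin per genome, with planted outlier structure.

    ``contaminant_mode`` selects which signals displace contaminants:
    'gc', 'coverage' or 'both'; foreign taxonomy labels are always
    planted.  floor(n_contigs * contaminant_fraction) contigs per bin
    are contaminants.  All contigs are >= ``min_contig_length`` bp.
    """
    if not (0 <= contaminant_fraction < 0.5):
        raise ValueError("contaminant_fraction must be in [0, 0.5)")
    n_contam = int(math.floor(n_contigs * contaminant_fraction))
    if n_contam > 0:
        if contaminant_mode in ("gc", "both") and gc_offset <= 0:
            raise ValueError("gc_offset must be > 0 when contaminants are planted")
        if contaminant_mode in ("coverage", "both") and coverage_offset <= 0:
            raise ValueError("coverage_offset must be > 0 when contaminants are planted")
    genomes = sorted(proteomes if not isinstance(proteomes, Mapping) else proteomes.keys())
    rng = np.random.default_rng(seed)
    truth = PlantedTruth()
    bins: dict[str, GenomeBin] = {}
    for genome in genomes:
        clade = clade_of.get(genome, genome) if clade_of else genome
        host_label = f"taxon_{clade}"
        gc_mean = float(rng.uniform(0.40, 0.60))
        truth.bin_gc_mean[genome] = gc_mean
        contam_idx = set(range(n_contam))  # planted; order randomized below
        order = rng.permutation(n_contigs)
        contigs: dict[str, ContigRecord] = {}
        planted: list[str] = []
        for pos, slot in enumerate(order):
            cid = f"{genome}_ctg{pos + 1:03d}"
            length = int(min_contig_length + rng.integers(0, 3000))
            is_contam = int(slot) in contam_idx
            # GC target
            gc = gc_mean + float(rng.normal(0.0, 0.01))
            weight = 1.0
            if is_contam:
                if contaminant_mode in ("gc", "both"):
                    disp = float(rng.uniform(1.25 * gc_offset, 1.5 * gc_offset))
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    gc_c = gc_mean * (1.0 + sign * disp)
                    if not (0.05 < gc_c < 0.95):
                        gc_c = gc_mean * (1.0 - sign * disp)
                    gc = gc_c
                if contaminant_mode in ("coverage", "both"):
                    disp = float(rng.uniform(1.25 * coverage_offset, 1.5 * coverage_offset))
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    weight = max(1.0 + sign * disp, 0.1)
            gc = float(np.clip(gc, 0.02, 0.98))
            seq = _random_sequence(length, gc, rng)
            n_genes = int(rng.integers(2, 5))
            genes = []
            for gk in range(1, n_genes + 1):
                gene_id = f"{cid}_g{gk}"
                if is_contam:
                    label = f"taxon_foreign_{genome}"
                else:
                    label = host_label if rng.random() < 0.8 else None
                genes.append((gene_id, label))
            contigs[cid] = ContigRecord(
                contig_id=cid,
                length=length,
                gc=mio.gc_fraction(seq),
                counts={},
                genes=genes,
                sequence=seq,
            )
            truth.contig_weights[cid] = weight
            if is_contam:
                planted.append(cid)
        truth.contaminants[genome] = sorted(planted)
        # marker inventory with planted missing / duplicated markers
        inventory = {m: 1 for m in MARKER_SET}
        n_missing = int(rng.integers(0, max_missing_markers + 1))
        n_dup = int(rng.integers(0, max_duplicated_markers + 1))
        drop = rng.choice(len(MARKER_SET), size=n_missing, replace=False)
        for k in drop:
            inventory[MARKER_SET[k]] = 0
        remaining = [m for m in MARKER_SET if inventory[m] == 1]
        dup = rng.choice(len(remaining), size=min(n_dup, len(remaining)), replace=False)
        for k in dup:
            inventory[remaining[k]] = 2
        truth.marker_inventory[genome] = dict(inventory)
        bins[genome] = GenomeBin(bin_id=genome, contigs=contigs, markers=inventory)
    if clade_of:
        truth.clade_of = {g: clade_of.get(g, g) for g in genomes}
    return bins, truth


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(
    bins: Mapping[str, GenomeBin],
    n_samples: int,
    depth: int,
    seed: int,
    truth: Optional[PlantedTruth] = None,
    cluster_of: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Multinomial per-sample read counts over all contigs.

    Probabilities are proportional to contig length x planted cluster
    abundance x per-contig coverage weight; every column sums to
    ``depth`` exactly.  Cluster abundances are drawn log-normally per
    sample and recorded in the returned truth.
    """
    if n_samples < 1 or depth < 1:
        raise ValueError("n_samples and depth must be >= 1")
    rng = np.random.default_rng(seed)
    truth = truth or PlantedTruth()
    cluster_of = cluster_of or {b: truth.clade_of.get(b, b) for b in bins}
    clusters = sorted(set(cluster_of.values()))
    samples = [f"s{k}" for k in range(1, n_samples + 1)]
    abundance = pd.DataFrame(
        rng.lognormal(mean=0.0, sigma=1.0, size=(len(clusters), n_samples)),
        index=clusters,
        columns=samples,
    )
    truth.cluster_abundance = abundance

    contig_ids = []
    lengths = []
    weights = []
    contig_cluster = []
    for bin_id in sorted(bins):
        for cid in sorted(bins[bin_id].contigs):
            contig = bins[bin_id].contigs[cid]
            contig_ids.append(cid)
            lengths.append(contig.length)
            weights.append(truth.contig_weights.get(cid, 1.0))
            contig_cluster.append(cluster_of[bin_id])
    lengths = np.array(lengths, dtype=float)
    weights = np.array(weights, dtype=float)

    counts = pd.DataFrame(0, index=contig_ids, columns=samples, dtype=int)
    counts.index.name = "contig_id"
    for s in samples:
        ab = np.array([abundance.loc[c, s] for c in contig_cluster])
        probs = lengths * ab * weights
        probs = probs / probs.sum()
        counts[s] = rng.multinomial(depth, probs)
    return counts, truth


def attach_counts(bins: Mapping[str, GenomeBin], counts: pd.DataFrame) -> None:
    """Copy per-sample counts from a count matrix onto the bins' contigs."""
    for bin_ in bins.values():
        for cid, contig in bin_.contigs.items():
            if cid in counts.index:
                contig.counts = {s: int(counts.loc[cid, s]) for s in counts.columns}


# ---------------------------------------------------------------------------
# Annotations


def simulate_annotations(
    genomes: Sequence[str],
    gene_catalog: Sequence[str],
    presence_prob: Mapping[tuple[str, str], float],
    secretion_prob: float,
    seed: int,
    cluster_of: Optional[Mapping[str, str]] = None,
    decoy_prob: float = 0.5,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Annotation table with planted per-cluster gene presence.

    ``presence_prob`` maps (cluster, family) -> Bernoulli probability
    that a member genome encodes the family (missing keys mean 0).
    Each encoded family yields one primary hit; with probability
    ``decoy_prob`` a decoy secondary hit to a DECOY family with a
    strictly worse e-value (and lower bit-score) is added for the same
    protein to exercise best-hit resolution.
    """
    if not (0 <= secretion_prob <= 1):
        raise ValueError("secretion_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cluster_of = cluster_of or {g: g for g in genomes}
    rows = []
    for genome in sorted(genomes):
        cluster = cluster_of[genome]
        for family in gene_catalog:
            p = presence_prob.get((cluster, family), 0.0)
            if rng.random() >= p:
                continue
            protein = f"{genome}|{family}"
            evalue = 10.0 ** -float(rng.uniform(20, 80))
            bitscore = float(np.round(rng.uniform(100, 400), 1))
            loc = "secreted" if rng.random() < secretion_prob else "non-secreted"
            if rng.random() < 0.05:
                loc = "unknown"
            rows.append(
                {
                    "protein_id": protein,
                    "genome_id": genome,
                    "family_id": family,
                    "database": "primary_db",
                    "evalue": evalue,
                    "bitscore": bitscore,
                    "localization": loc,
                }
            )
            if rng.random() < decoy_prob:
                rows.append(
                    {
                        "protein_id": protein,
                        "genome_id": genome,
                        "family_id": f"DECOY{int(rng.integers(1, 100)):03d}",
                        "database": "decoy_db",
                        "evalue": evalue * 10.0 ** float(rng.uniform(2, 6)),
                        "bitscore": float(np.round(bitscore * rng.uniform(0.3, 0.8), 1)),
                        "localization": loc,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "genome_id",
            "family_id",
            "database",
            "evalue",
            "bitscore",
            "localization",
        ],
    )
    truth = PlantedTruth(
        presence_prob=dict(presence_prob), secretion_prob=secretion_prob
    )
    return table, truth


# ---------------------------------------------------------------------------
# Full scenario


@dataclass
class ScenarioParams:
    """Defaults for the bundled synthetic community."""

    n_clades: int = 5
    tips_per_clade: int = 3
    intra_scale: float = 0.3
    inter_scale: float = 1.2
    # clades with a described reference genome inside; the rest are
    # reference-free (novel-lineage candidates)
    n_reference_clades: int = 3
    n_proteins: int = 20
    protein_length: int = 100
    n_bins: int = 8
    n_contigs: int = 10
    contaminant_fraction: float = 0.1
    gc_offset: float = 0.3
    coverage_offset: float = 0.4
    n_samples: int = 4
    depth: int = 100_000
    secretion_prob: float = 0.02
    gene_catalog: tuple[str, ...] = (
        "mcrA", "dsrA", "pflD", "acdA", "nifH", "soxB", "glk", "pfk",
        "pta", "ackA", "cooS", "hydA", "GH13", "GH23", "CE8", "M28", "S08",
    )


def bins_to_taxonomy_table(bins: Mapping[str, GenomeBin]) -> pd.DataFrame:
    rows = []
    for bin_id in sorted(bins):
        for cid in sorted(bins[bin_id].contigs):
            for gene_id, label in bins[bin_id].contigs[cid].genes:
                rows.append(
                    {"gene_id": gene_id, "contig_id": cid, "label": label or "-"}
                )
    return pd.DataFrame(rows, columns=["gene_id", "contig_id", "label"])


def bins_to_marker_table(bins: Mapping[str, GenomeBin]) -> pd.DataFrame:
    rows = []
    for bin_id in sorted(bins):
        for marker, copies in sorted(bins[bin_id].markers.items()):
            rows.append({"genome_id": bin_id, "marker_id": marker, "copies": copies})
    return pd.DataFrame(rows, columns=["genome_id", "marker_id", "copies"])


def simulate_scenario(params: ScenarioParams, seed: int, outdir: str | Path) -> dict:
    """Generate and write a complete synthetic community.

    Writes genomes/*.faa, bins/*.fna, tree.nwk, query_ids.txt,
    counts.tsv, annotations.tsv, taxonomy.tsv, markers.tsv,
    libsizes.tsv, clusters.tsv, sites.tsv and truth/*.tsv; returns a
    summary dict of what was written.
    """
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "bins").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)

    ptree, tree_truth = simulate_tree(
        params.n_clades,
        params.tips_per_clade,
        params.intra_scale,
        params.inter_scale,
        int(seeds[0]),
        reference_tips_per_clade=[1] * min(params.n_reference_clades, params.n_clades)
        + [0] * max(params.n_clades - params.n_reference_clades, 0),
    )
    mio.write_newick(ptree, outdir / "tree.nwk")
    mio.write_query_ids(ptree, outdir / "query_ids.txt")

    proteomes = evolve_proteomes(
        ptree, params.n_proteins, params.protein_length, int(seeds[1])
    )
    query_genomes = sorted(g for g, tag in ptree.source.items() if tag == QUERY)
    for genome in query_genomes:
        mio.write_fasta(sorted(proteomes[genome].items()), outdir / "genomes" / f"{genome}.faa")

    binned_genomes = query_genomes[: params.n_bins]
    bins, bin_truth = simulate_bins(
        {g: proteomes[g] for g in binned_genomes},
        params.n_contigs,
        params.contaminant_fraction,
        params.gc_offset,
        params.coverage_offset,
        int(seeds[2]),
        clade_of=tree_truth.clade_of,
    )
    for bin_id, bin_ in bins.items():
        mio.write_bin_fasta(bin_, outdir / "bins" / f"{bin_id}.fna")
    mio.write_table(bins_to_taxonomy_table(bins), outdir / "taxonomy.tsv")
    mio.write_table(bins_to_marker_table(bins), outdir / "markers.tsv")

    bin_truth.clade_of = tree_truth.clade_of
    counts, count_truth = simulate_counts(
        bins, params.n_samples, params.depth, int(seeds[3]), truth=bin_truth
    )
    attach_counts(bins, counts)
    mio.write_table(counts.reset_index(), outdir / "counts.tsv")
    libsizes = pd.DataFrame(
        {"sample_id": counts.columns, "reads": [params.depth] * len(counts.columns)}
    )
    mio.write_table(libsizes, outdir / "libsizes.tsv")

    clades = sorted(set(tree_truth.clade_of.values()))
    presence_rng = np.random.default_rng(int(seeds[4]))
    presence_prob = {
        (clade, family): float(np.round(presence_rng.uniform(0.05, 0.95), 3))
        for clade in clades
        for family in params.gene_catalog
    }
    annotations, ann_truth = simulate_annotations(
        query_genomes,
        list(params.gene_catalog),
        presence_prob,
        params.secretion_prob,
        int(seeds[4]),
        cluster_of=tree_truth.clade_of,
    )
    mio.write_table(annotations, outdir / "annotations.tsv")

    clusters = pd.DataFrame(
        {
            "member_id": query_genomes,
            "cluster_id": [tree_truth.clade_of[g] for g in query_genomes],
        }
    )
    mio.write_table(clusters, outdir / "clusters.tsv")
    sites = pd.DataFrame(
        {
            "genome_id": query_genomes,
            "site_id": [
                f"site{1 + (k % 2)}" for k in range(len(query_genomes))
            ],
        }
    )
    mio.write_table(sites, outdir / "sites.tsv")

    # truth tables
    mio.write_table(
        pd.DataFrame(
            sorted(tree_truth.clade_of.items()), columns=["genome_id", "clade_id"]
        ),
        outdir / "truth" / "clades.tsv",
    )
    contam_rows = [
        {"bin_id": b, "contig_id": c}
        for b in sorted(bin_truth.contaminants)
        for c in bin_truth.contaminants[b]
    ]
    mio.write_table(
        pd.DataFrame(contam_rows, columns=["bin_id", "contig_id"]),
        outdir / "truth" / "contaminants.tsv",
    )
    ab = count_truth.cluster_abundance.reset_index(names="cluster_id")
    mio.write_table(ab, outdir / "truth" / "cluster_abundance.tsv")
    prob_rows = [
        {"cluster_id": c, "family_id": f, "presence_prob": p}
        for (c, f), p in sorted(presence_prob.items())
    ]
    mio.write_table(
        pd.DataFrame(prob_rows, columns=["cluster_id", "family_id", "presence_prob"]),
        outdir / "truth" / "presence_prob.tsv",
    )
    return {
        "n_genomes": len(query_genomes),
        "n_bins": len(bins),
        "n_samples": params.n_samples,
        "n_annotation_hits": len(annotations),
        "outdir": str(outdir),
    }
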