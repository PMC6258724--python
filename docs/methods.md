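# Methods

This document records the model, the exact algorithmic conventions, the
default parameters, and the numerical/design decisions behind
`magdelin`. The problem sizes used in tests and in the bundled scenario
are the package's own choices, picked to keep desk-scale runs fast while
leaving clear statistical margins.

## 1. Protein alignment and AAI

### Canonical local alignment

Pairwise protein comparison uses an affine-gap local (Smith–Waterman
style) alignment under BLOSUM62 with gap open 11 and gap extend 1: a gap
of length *k* costs `open + (k − 1) · extend`. The dynamic program is a
three-state Gotoh recursion (match/insert-in-a/insert-in-b) implemented
in numba.

Many alignments can share the optimal score, so all reported statistics
come from one *canonical* alignment: the lexicographic maximum of the
vector

```
(score, matches, −columns, diagonal_columns, −gaps_in_a)
```

i.e. among maximum-score alignments prefer more identical matches, then
fewer alignment columns, then more diagonal (substitution) columns, then
fewer gap columns consuming sequence *a*. Because every component is
additive along the alignment, the lexicographic maximum satisfies the
DP optimal-substructure property and the recursion can propagate the
whole tuple. The test suite checks this kernel against two independent
oracles: a pure-Python tuple DP and exhaustive enumeration of *all*
local alignments for tiny inputs.

### Identity, coverage, filters

- **identity** = matches / alignment columns × 100 — gap columns count
  in the denominator.
- **coverage** = aligned residues of the *shorter* sequence / length of
  the shorter sequence × 100.
- A pair is a hit only if the canonical alignment score is > 0.
- Hits must have identity ≥ 30% and coverage ≥ 70% to enter best-hit
  selection (both configurable).

### Best hits, RBH, AAI

The best hit of a query protein is the filtered hit with the highest
score; ties break by higher identity, then lexicographically smaller
subject id (fully deterministic). Reciprocal best hits (RBH) are pairs
(p, q) with q = best(p) in B and p = best(q) in A; both directions reuse
the same per-pair alignment statistics, so AAI is symmetric by
construction. AAI(A, B) is the mean identity over RBH pairs; a pair of
genomes with no RBH has undefined AAI (NaN), which group summaries
exclude while reporting the count of defined pairs.

Group-level novelty: a group is **confirmed** when its within-group mean
AAI exceeds every defined between-group mean involving it. Singleton
groups have no within mean; they are **confirmed_weak** when their best
cross-group AAI falls below a floor (default 50%), otherwise
**indeterminate**.

## 2. Bin curation

### Quality estimates

With a marker set *M* (the bundled set has 37 single-copy families) and
copy counts c(m):

- completeness = 100 · |{m : c(m) ≥ 1}| / |M|
- contamination = 100 · Σ max(c(m) − 1, 0) / |M|

The quality gate is strict: pass iff completeness **> 50** and
contamination **< 10**. (50.0, x) and (x, 10.0) fail for every x.

### Contaminant-removal rules

Three per-contig rules, each expressed as a relative deviation where
applicable (threshold 0.25, i.e. "differs by more than 25%" read as
*relative* difference; the absolute variant is available via
configuration):

- **gc** — |GC(contig) − mean GC of bin| / mean > 0.25. The mean
  includes the candidate contig.
- **abundance** — same rule applied to mean per-base coverage
  (reads / contig length, averaged over samples). Skipped with a
  warning if the bin has no mapped reads.
- **taxonomy** — flag a contig when *every* labeled gene on it differs
  from the bin's modal gene label; contigs without labeled genes are
  never flagged.

Removal is the single-pass **union** of all three rules (no iteration,
so means are not recomputed after removals). If every contig is
flagged, the original bin is kept and a warning is emitted. Quality is
re-estimated on the curated bin; marker inventories are genome-level, so
completeness never drops from contig removal and contamination never
increases.

## 3. Lineage delineation

Patristic distance between two tips is the sum of branch lengths on the
path joining them. Lineages are produced by a pre-order traversal of a
rooted tree: at each node, if the mean pairwise patristic distance among
the node's tips is **< 0.6** (default), the clade becomes one lineage and
the traversal stops there; otherwise it descends. Singleton tips form
singleton lineages, so the result always partitions the tip set, and the
lineage count is non-increasing in the threshold.

Unrooted input trees are midpoint-rooted by an in-package routine: find
the maximum tip-to-tip patristic distance (ties broken by lexicographic
tip labels), walk the path accumulating branch lengths, and root either
inside the edge containing the halfway point (splitting it exactly) or
at the node the halfway point lands on. This routine exists because the
off-the-shelf midpoint rooting in the tree library misplaces the root
when the midpoint coincides exactly with a node (it can root *at* a
leaf, dropping that leaf's branch, or leave a basal trichotomy), which
breaks worked examples such as the star tree and two tight cherries.

A lineage is **novel** when every member is a query genome. Novel
lineages are graded against the AAI matrix (grouping = lineage
membership): `candidate` if confirmed (or confirmed_weak), `tree-only`
otherwise; lineages containing a reference tip are `not-novel`.

## 4. Abundance and profiles

- Cluster abundance: `reads / (cluster length in bp × library size) ×
  1000` per sample; the worked value 1000 reads over a 10⁶ bp cluster in
  a 10⁶-read library is 10⁻⁶. Per-gene abundance uses the same formula
  with gene length and no extra scaling beyond the same ×1000, making a
  1 kb gene's value 1/1000 of a 1 Mb cluster's at equal counts.
- Binned fraction: mapped reads / library size × 100 per sample, with a
  mean over samples.
- Annotation resolution: per protein keep the hit with the smallest
  e-value, ties by larger bit score, then lexicographic family id.
  Genome presence of a family = ≥ 1 retained hit.
- Cluster profile: fraction of member genomes carrying the family,
  tiered `absent` < 0.30 ≤ `partial` < 0.50 ≤ `core` (the 0.50
  boundary is assigned upward, to `core`).
- Site profile: percentage of genomes at a site carrying each core
  gene family.
- Secreted fraction: percentage of annotated enzyme hits whose
  localization label is "secreted"; unlabeled ("unknown") hits stay in
  the denominator.

## 5. The synthetic-community generator

What it emulates:

- **Tree**: K clades of random bifurcating topology with exponential
  branch lengths, rescaled *exactly* so each clade's mean pairwise
  patristic distance equals `intra_scale`; clade stems sized from
  `inter_scale` so cross-clade mean distances sit near `inter_scale`.
  Selected tips can be tagged as described references; the rest are
  queries.
- **Proteomes**: a root proteome of uniform random residues evolves
  down the tree; per branch of length d each site substitutes with
  probability 1 − e^(−d), replacement uniform over the other 19
  residues. Orthologs share indices across genomes. The closed form
  for expected site identity between two tips,
  P = 1/20 + (19/20) · Π_edges (20 e^(−d) − 1)/19,
  is validated against an independent Monte-Carlo oracle.
- **Bins**: one bin per genome; floor(n_contigs × fraction) contaminant
  contigs get a GC displacement uniform in [1.25, 1.5] × `gc_offset`
  (random sign), a coverage weight displaced likewise by
  `coverage_offset`, and foreign taxonomy labels; host contigs get
  small GC jitter (σ = 0.01) and 80%-labeled host genes. Marker
  inventories plant a few missing/duplicated markers.
- **Counts**: per-sample multinomial reads with probabilities ∝ contig
  length × lognormal cluster abundance × contaminant coverage weight;
  every column sums to the requested depth.
- **Annotations**: per genome × family presence draws, decoy (strictly
  worse) hits, and a secreted/other/unknown localization mix.

What it does **not** emulate: indels and rearrangements (substitution
only, so alignments are essentially gap-free at planted identities),
across-site rate variation, horizontal transfer, assembly/binning error
beyond the planted contaminants, chimeric contigs, and read-level
sequencing noise.

## 6. Defaults

| Parameter | Default | Units |
|---|---|---|
| gap open / extend | 11 / 1 | score |
| min identity / coverage | 30 / 70 | % |
| gate completeness / contamination | > 50 / < 10 | % |
| outlier rule / threshold | relative / 0.25 | — |
| collapse threshold | 0.6 | substitutions/site |
| singleton AAI floor | 50 | % |
| tier bounds | 0.30 / 0.50 | fraction |
| scenario | 5 clades × 3 tips, intra 0.3, inter 1.2, 20 proteins × 100 aa, 8 bins × 10 contigs, 10% contaminants, 4 samples × 100 000 reads | — |

## 7. Numerical and design notes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; scenario sub-seeds are drawn below 2³¹. Outputs are
  byte-identical across reruns (the run summary, which records wall
  times, is the sole exception).
- GC fraction excludes ambiguous bases (N) from the denominator.
- Relative outlier deviations divide by the bin mean *including* the
  candidate contig; with few contigs one strong outlier shifts the mean
  noticeably, which the planted displacement margins (≥ 1.25 × offset)
  absorb.
- The identity denominator includes gap columns; since the generator
  plants no indels this matters only for alignments that open gaps to
  chain distant matches, where counting gaps is the conservative choice.
- The 0.50 tier boundary goes upward (core) so the three bands cover
  [0, 1] without overlap and a family in exactly half the genomes counts
  as core.
- Undefined AAI (no RBH) is NaN, excluded from group means rather than
  imputed; group summaries report how many defined pairs they average.

## 8. Limitations

- AAI here uses full all-vs-all optimal alignments; at real proteome
  sizes one would use a heuristic search for candidate pairs. The
  complexity is O(n² · L²) per genome pair.
- Lineage collapsing depends on a rooted tree; midpoint rooting is a
  heuristic and can place the root inside a clade under strongly
  asymmetric trees, changing the traversal order (not the distances).
- Completeness/contamination from 37 markers is coarse (1 marker ≈
  2.7%); the gate is intentionally strict at its boundaries.
- The single-pass removal union does not revisit means after removal;
  heavily contaminated bins (> ~30% outliers) can mask their own
  outliers.
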