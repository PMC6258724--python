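"""Average amino acid identity (AAI) from first principles.

Pipeline: all-vs-all local protein alignment (BLOSUM62, affine gaps)
-> identity/coverage filtered best hits -> reciprocal best hits (RBH)
-> unweighted mean identity over RBH pairs.  Group-level summaries
support the novelty check for candidate lineages: a genome group is
confirmed as novel when its genomes are more similar to each other than
to any other group (within-group mean AAI exceeds every between-group
mean).

A genome pair with zero orthologs has an *undefined* AAI, propagated as
NaN and excluded from group means; it is never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from magdelin import _align
from magdelin.types import AAIMatrix, AlignmentHit

CONFIRMED = "confirmed"
NOT_CONFIRMED = "not_confirmed"
INDETERMINATE = "indeterminate"
CONFIRMED_WEAK = "confirmed_weak"

Proteome = Mapping[str, str]  # protein id -> sequence


@dataclass
class Scoring:
    """Substitution matrix plus affine gap penalties.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.
    """

    matrix: np.ndarray = field(default_factory=lambda: _align.BLOSUM62)
    gap_open: int = 11
    gap_extend: int = 1


DEFAULT_SCORING = Scoring()


def align_pair(
    seq_a: str,
    seq_b: str,
    scoring: Scoring = DEFAULT_SCORING,
    query_id: str = "a",
    subject_id: str = "b",
) -> Optional[AlignmentHit]:
    """Canonical local alignment of two protein sequences.

    Identity is matches / alignment columns (gaps count in the
    denominator) x 100; coverage is aligned residues of the shorter
    sequence / shorter length x 100.  Returns None when the optimal
    local score is <= 0.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    a = _align.encode(seq_a)
    b = _align.encode(seq_b)
    score, matches, columns, diag, gaps_in_a = _align.gotoh_stats(
        a, b, scoring.matrix, scoring.gap_open, scoring.gap_extend
    )
    if score <= 0:
        return None
    consumed_a = diag + gaps_in_a
    consumed_b = columns - gaps_in_a
    consumed_short = consumed_a if len(seq_a) <= len(seq_b) else consumed_b
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity=100.0 * matches / columns,
        coverage=100.0 * consumed_short / min(len(seq_a), len(seq_b)),
        score=int(score),
    )


def _all_pairs(
    proteome_a: Proteome, proteome_b: Proteome, scoring: Scoring
) -> dict[tuple[str, str], AlignmentHit]:
    """Alignment statistics for every positive-scoring protein pair.

    Computed once per (a, b) protein pair; both best-hit directions
    reuse the same numbers, which keeps AAI symmetric by construction.
    """
    enc_a = {pid: _align.encode(seq) for pid, seq in proteome_a.items()}
    enc_b = {pid: _align.encode(seq) for pid, seq in proteome_b.items()}
    hits: dict[tuple[str, str], AlignmentHit] = {}
    for pa in sorted(enc_a):
        for pb in sorted(enc_b):
            score, matches, columns, diag, gaps_in_a = _align.gotoh_stats(
                enc_a[pa], enc_b[pb], scoring.matrix, scoring.gap_open, scoring.gap_extend
            )
            if score <= 0:
                continue
            len_a = len(proteome_a[pa])
            len_b = len(proteome_b[pb])
            consumed_a = diag + gaps_in_a
            consumed_b = columns - gaps_in_a
            consumed_short = consumed_a if len_a <= len_b else consumed_b
            hits[(pa, pb)] = AlignmentHit(
                query_id=pa,
                subject_id=pb,
                identity=100.0 * matches / columns,
                coverage=100.0 * consumed_short / min(len_a, len_b),
                score=int(score),
            )
    return hits


def _select_best(
    candidates: list[AlignmentHit], min_identity: float, min_coverage: float
) -> Optional[AlignmentHit]:
    passing = [h for h in candidates if h.passes(min_identity, min_coverage)]
    if not passing:
        return None
    # highest score, ties by higher identity, then lexicographic subject id
    return min(passing, key=lambda h: (-h.score, -h.identity, h.subject_id))


def best_hits(
    proteome_a: Proteome,
    proteome_b: Proteome,
    min_identity: float = 30.0,
    min_coverage: float = 70.0,
    scoring: Scoring = DEFAULT_SCORING,
    _pairs: Optional[dict[tuple[str, str], AlignmentHit]] = None,
) -> dict[str, AlignmentHit]:
    """Best filtered subject hit per query protein."""
    pairs = _pairs if _pairs is not None else _all_pairs(proteome_a, proteome_b, scoring)
    out: dict[str, AlignmentHit] = {}
    for qa in proteome_a:
        candidates = [h for (pa, _), h in pairs.items() if pa == qa]
        best = _select_best(candidates, min_identity, min_coverage)
        if best is not None:
            out[qa] = best
    return out


def reciprocal_best_hits(
    proteome_a: Proteome,
    proteome_b: Proteome,
    min_identity: float = 30.0,
    min_coverage: float = 70.0,
    scoring: Scoring = DEFAULT_SCORING,
    _pairs: Optional[dict[tuple[str, str], AlignmentHit]] = None,
) -> set[tuple[str, str]]:
    """Ortholog pairs (p, q): q is p's best hit in B and p is q's best in A."""
    pairs = _pairs if _pairs is not None else _all_pairs(proteome_a, proteome_b, scoring)
    forward = best_hits(proteome_a, proteome_b, min_identity, min_coverage, scoring, _pairs=pairs)
    # reverse direction from the same alignment statistics, roles swapped
    reverse: dict[str, AlignmentHit] = {}
    for qb in proteome_b:
        candidates = [
            AlignmentHit(
                query_id=pb,
                subject_id=pa,
                identity=h.identity,
                coverage=h.coverage,
                score=h.score,
            )
            for (pa, pb), h in pairs.items()
            if pb == qb
        ]
        best = _select_best(candidates, min_identity, min_coverage)
        if best is not None:
            reverse[qb] = best
    return {
        (pa, hit.subject_id)
        for pa, hit in forward.items()
        if reverse.get(hit.subject_id) is not None
        and reverse[hit.subject_id].subject_id == pa
    }


def compute_aai(
    proteome_a: Proteome,
    proteome_b: Proteome,
    min_identity: float = 30.0,
    min_coverage: float = 70.0,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[float, int]:
    """(mean RBH identity %, ortholog count); (NaN, 0) when no orthologs."""
    pairs = _all_pairs(proteome_a, proteome_b, scoring)
    rbh = reciprocal_best_hits(
        proteome_a, proteome_b, min_identity, min_coverage, scoring, _pairs=pairs
    )
    if not rbh:
        return float("nan"), 0
    identities = [pairs[(pa, pb)].identity for pa, pb in rbh]
    return float(np.mean(identities)), len(rbh)


def build_aai_matrix(
    proteomes: Mapping[str, Proteome],
    min_identity: float = 30.0,
    min_coverage: float = 70.0,
    scoring: Scoring = DEFAULT_SCORING,
) -> AAIMatrix:
    """All-pairs AAI over a set of proteomes (each pair computed once)."""
    genomes = sorted(proteomes)
    values = pd.DataFrame(np.nan, index=genomes, columns=genomes, dtype=float)
    counts = pd.DataFrame(0, index=genomes, columns=genomes, dtype=int)
    for g in genomes:
        values.loc[g, g] = 100.0
        counts.loc[g, g] = len(proteomes[g])
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            aai, n = compute_aai(
                proteomes[ga], proteomes[gb], min_identity, min_coverage, scoring
            )
            values.loc[ga, gb] = values.loc[gb, ga] = aai
            counts.loc[ga, gb] = counts.loc[gb, ga] = n
    return AAIMatrix(genomes=genomes, values=values, orthologs=counts)


def aai_matrix_to_long(matrix: AAIMatrix) -> pd.DataFrame:
    rows = []
    for i, ga in enumerate(matrix.genomes):
        for gb in matrix.genomes[i + 1 :]:
            rows.append(
                {
                    "genome_a": ga,
                    "genome_b": gb,
                    "aai": matrix.values.loc[ga, gb],
                    "orthologs": int(matrix.orthologs.loc[ga, gb]),
                }
            )
    return pd.DataFrame(rows, columns=["genome_a", "genome_b", "aai", "orthologs"])


def aai_matrix_from_long(df: pd.DataFrame) -> AAIMatrix:
    genomes = sorted(set(df["genome_a"]) | set(df["genome_b"]))
    values = pd.DataFrame(np.nan, index=genomes, columns=genomes, dtype=float)
    counts = pd.DataFrame(0, index=genomes, columns=genomes, dtype=int)
    np.fill_diagonal(values.values, 100.0)
    for row in df.itertuples(index=False):
        aai = float(row.aai) if str(row.aai) not in ("", "nan") else float("nan")
        values.loc[row.genome_a, row.genome_b] = aai
        values.loc[row.genome_b, row.genome_a] = aai
        counts.loc[row.genome_a, row.genome_b] = int(row.orthologs)
        counts.loc[row.genome_b, row.genome_a] = int(row.orthologs)
    return AAIMatrix(genomes=genomes, values=values, orthologs=counts)


# ---------------------------------------------------------------------------
# Group-level novelty confirmation


def group_aai(
    matrix: AAIMatrix, grouping: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-group and between-group mean AAI.

    Within means average all unordered intra-group pairs (diagonal
    excluded); between means average all cross-group pairs.  Undefined
    (NaN) entries are excluded, and the number of defined pairs is
    reported alongside each mean.  Returns (within, between) tables.
    """
    groups = sorted(set(grouping.values()))
    members = {g: sorted(x for x in matrix.genomes if grouping.get(x) == g) for g in groups}
    within_rows = []
    for g in groups:
        vals = [
            matrix.get(a, b)
            for i, a in enumerate(members[g])
            for b in members[g][i + 1 :]
        ]
        defined = [v for v in vals if not np.isnan(v)]
        within_rows.append(
            {
                "group": g,
                "within_aai": float(np.mean(defined)) if defined else float("nan"),
                "n_pairs": len(defined),
            }
        )
    between_rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            vals = [matrix.get(a, b) for a in members[ga] for b in members[gb]]
            defined = [v for v in vals if not np.isnan(v)]
            between_rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "between_aai": float(np.mean(defined)) if defined else float("nan"),
                    "n_pairs": len(defined),
                }
            )
    within = pd.DataFrame(within_rows, columns=["group", "within_aai", "n_pairs"])
    between = pd.DataFrame(
        between_rows, columns=["group_a", "group_b", "between_aai", "n_pairs"]
    )
    return within, between


def overall_between_aai(matrix: AAIMatrix, grouping: Mapping[str, str]) -> dict[str, float]:
    """Two labeled summaries of cross-group AAI over the whole genome set.

    'grand_mean' averages every defined cross-group pair; 'mean_of_group_means'
    averages the per-group-pair between means.
    """
    _, between = group_aai(matrix, grouping)
    defined = between.dropna(subset=["between_aai"])
    grand = (
        float(
            np.average(defined["between_aai"], weights=defined["n_pairs"])
        )
        if len(defined) and defined["n_pairs"].sum() > 0
        else float("nan")
    )
    mean_of_means = float(defined["between_aai"].mean()) if len(defined) else float("nan")
    return {"grand_mean": grand, "mean_of_group_means": mean_of_means}


def confirm_novel_group(
    matrix: AAIMatrix,
    grouping: Mapping[str, str],
    group: str,
    singleton_floor: float = 50.0,
) -> str:
    """Novelty verdict for one group.

    'confirmed' when the within-group mean exceeds every defined
    between-group mean; 'not_confirmed' otherwise.  Singleton groups
    have no within mean: 'confirmed_weak' when their best cross-group
    AAI falls below ``singleton_floor``, else 'indeterminate'.
    """
    within, between = group_aai(matrix, grouping)
    row = within[within["group"] == group]
    if row.empty:
        raise KeyError(f"group {group!r} not in grouping")
    within_mean = float(row["within_aai"].iloc[0])
    cross = between[(between["group_a"] == group) | (between["group_b"] == group)]
    cross_means = cross["between_aai"].dropna()
    if np.isnan(within_mean):
        members = [g for g in matrix.genomes if grouping.get(g) == group]
        others = [g for g in matrix.genomes if grouping.get(g) not in (None, group)]
        best_cross = np.nanmax(
            [[matrix.get(a, b) for b in others] for a in members]
        ) if others else float("nan")
        if not np.isnan(best_cross) and best_cross < singleton_floor:
            return CONFIRMED_WEAK
        return INDETERMINATE
    if cross_means.empty:
        return INDETERMINATE
    return CONFIRMED if within_mean > cross_means.max() else NOT_CONFIRMED


def save_aai(matrix: AAIMatrix, path: str | Path) -> None:
    aai_matrix_to_long(matrix).to_csv(path, sep="\t", index=False, na_rep="nan")


def load_aai(path: str | Path) -> AAIMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"genome_a": str, "genome_b": str})
    return aai_matrix_from_long(df)
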