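"""Attachment and aggregation of externally predicted antioxidant scores.

Each peptide may carry two scores in [0, 1]: FRS (free radical-scavenging) and
CHE (metal-chelating) propensity. Scores are produced by an external predictor
and consumed as-is; only peptides of 3-30 residues are scorable. Aggregation
reports both the fraction of peptide IDs above a threshold and the
intensity-weighted abundance share above it, plus distribution statistics and
cross-fraction overlap decompositions (UpSet semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peptide_io import PeptideTable, collapse_duplicates

__all__ = [
    "PeptideScores",
    "ScoreTable",
    "ThresholdConfig",
    "ScoredTable",
    "AggregationResult",
    "OverlapReport",
    "read_score_table",
    "attach_scores",
    "aggregate",
    "compare_score_means",
    "overlap_analysis",
]

SCORABLE_MIN_LEN = 3
SCORABLE_MAX_LEN = 30


@dataclass(frozen=True)
class PeptideScores:
    frs: float
    che: float

    def __post_init__(self) -> None:
        for name, v in (("frs", self.frs), ("che", self.che)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} score {v} outside [0, 1]")

    def get(self, prop: str) -> float:
        return {"FRS": self.frs, "CHE": self.che}[prop.upper()]


@dataclass(frozen=True)
class ScoreTable:
    """Sequence → (FRS, CHE) score map, restricted to the scorable length range."""

    scores: Mapping[str, PeptideScores]
    scorable_range: tuple[int, int] = (SCORABLE_MIN_LEN, SCORABLE_MAX_LEN)

    def __post_init__(self) -> None:
        lo, hi = self.scorable_range
        for seq in self.scores:
            if not lo <= len(seq) <= hi:
                raise ValueError(
                    f"scored sequence {seq!r} of length {len(seq)} outside "
                    f"scorable range {lo}-{hi}"
                )

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class ThresholdConfig:
    """Score thresholds; comparisons are inclusive (score >= threshold)."""

    frs_threshold: float = 0.43
    che_threshold: float = 0.30

    def __post_init__(self) -> None:
        for v in (self.frs_threshold, self.che_threshold):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")

    def threshold(self, prop: str) -> float:
        return {"FRS": self.frs_threshold, "CHE": self.che_threshold}[prop.upper()]


@dataclass(frozen=True)
class ScoredTable:
    """A peptide table with scores attached where available."""

    table: PeptideTable
    scores: Mapping[str, PeptideScores]  # only for scored sequences
    coverage: float  # scored / total records


@dataclass(frozen=True)
class AggregationResult:
    sample_id: str
    property: str
    n_above: int
    frac_ids_above: float
    intensity_frac_above: float  # renormalized over scored+quantified peptides
    raw_intensity_frac_above: float  # denominator = all quantified peptides
    unscored_intensity_share: float
    mean_score: float
    quartiles: tuple[float, float, float]


def read_score_table(path: str | Path) -> ScoreTable:
    """Read a TSV with columns sequence / FRS / CHE (case-insensitive)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sequence", "frs", "che"):
        if col not in df.columns:
            raise ValueError(f"score table missing column {col!r}")
    scores = {
        str(row.sequence).upper(): PeptideScores(frs=float(row.frs), che=float(row.che))
        for row in df.itertuples(index=False)
    }
    return ScoreTable(scores=scores)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    rows = [
        {"sequence": seq, "FRS": s.frs, "CHE": s.che}
        for seq, s in sorted(table.scores.items())
    ]
    pd.DataFrame(rows, columns=["sequence", "FRS", "CHE"]).to_csv(
        path, sep="\t", index=False
    )


def attach_scores(table: PeptideTable, scores: ScoreTable) -> ScoredTable:
    """Attach scores to peptides within the scorable length range.

    Peptides outside 3-30 residues or absent from the score table are left
    unscored and excluded from score statistics downstream.
    """
    lo, hi = scores.scorable_range
    attached: dict[str, PeptideScores] = {}
    for rec in table.records:
        if lo <= len(rec) <= hi and rec.sequence in scores.scores:
            attached[rec.sequence] = scores.scores[rec.sequence]
    n_scored = sum(1 for rec in table.records if rec.sequence in attached)
    coverage = n_scored / len(table.records) if table.records else 0.0
    return ScoredTable(table=table, scores=attached, coverage=coverage)


def aggregate(
    scored: ScoredTable,
    sample: str,
    prop: str,
    config: ThresholdConfig | None = None,
) -> AggregationResult:
    """Threshold aggregation of one score property for one sample.

    ``intensity_frac_above`` renormalizes weights over scored & quantified
    peptides; ``raw_intensity_frac_above`` keeps all quantified peptides in
    the denominator (the unscored share is reported separately).
    """
    config = config or ThresholdConfig()
    t = config.threshold(prop)
    table = scored.table
    if sample not in table.samples:
        raise KeyError(f"unknown sample {sample!r}")

    score_values = []
    scored_intensity = 0.0
    scored_above_intensity = 0.0
    total_intensity = 0.0
    n_above = 0
    for rec in table.records:
        inten = rec.intensity.get(sample, 0.0)
        total_intensity += inten
        ps = scored.scores.get(rec.sequence)
        if ps is None:
            continue
        value = ps.get(prop)
        score_values.append(value)
        above = value >= t
        if above:
            n_above += 1
        scored_intensity += inten
        if above:
            scored_above_intensity += inten
    if not score_values:
        raise ValueError(f"no scored peptides in sample {sample!r}")
    if total_intensity <= 0:
        raise ValueError(f"no quantified peptides in sample {sample!r}")
    if scored_intensity <= 0:
        raise ValueError(f"no scored, quantified peptides in sample {sample!r}")

    arr = np.asarray(score_values)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return AggregationResult(
        sample_id=sample,
        property=prop.upper(),
        n_above=n_above,
        frac_ids_above=n_above / len(score_values),
        intensity_frac_above=scored_above_intensity / scored_intensity,
        raw_intensity_frac_above=scored_above_intensity / total_intensity,
        unscored_intensity_share=1.0 - scored_intensity / total_intensity,
        mean_score=float(arr.mean()),
        quartiles=(float(q1), float(med), float(q3)),
    )


def compare_score_means(groups: Sequence[Sequence[float]]) -> dict:
    """One-way ANOVA plus Tukey HSD over ≥2 score groups (plumbing, textbook formulas)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    f_stat, p_value = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairs = {
        (i, j): float(tukey.pvalue[i, j])
        for i, j in combinations(range(len(arrays)), 2)
    }
    return {
        "anova_f": float(f_stat),
        "anova_p": float(p_value),
        "tukey_p": pairs,
    }


@dataclass(frozen=True)
class OverlapReport:
    """Exclusive-intersection (UpSet) decomposition of peptide sets."""

    set_names: tuple[str, ...]
    # membership pattern (tuple of bools aligned with set_names) → count
    cells: Mapping[tuple[bool, ...], int] = field(default_factory=dict)
    conserved: int = 0
    unique_per_set: Mapping[str, int] = field(default_factory=dict)
    unique_share_per_set: Mapping[str, float] = field(default_factory=dict)
    set_sizes: Mapping[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pattern, count in sorted(self.cells.items(), reverse=True):
            row = {name: int(flag) for name, flag in zip(self.set_names, pattern)}
            row["count"] = count
            rows.append(row)
        return pd.DataFrame(rows, columns=[*self.set_names, "count"])


def overlap_analysis(peptide_sets: Mapping[str, set[str]]) -> OverlapReport:
    """Decompose ≥2 peptide sets into exclusive intersections.

    Every element of the union lands in exactly one cell keyed by its
    membership pattern, so cell counts sum to the union size.
    """
    if len(peptide_sets) < 2:
        raise ValueError("need at least two sets")
    names = tuple(peptide_sets)
    universe = set().union(*peptide_sets.values())
    cells: dict[tuple[bool, ...], int] = {}
    for element in universe:
        pattern = tuple(element in peptide_sets[name] for name in names)
        cells[pattern] = cells.get(pattern, 0) + 1
    all_in = tuple(True for _ in names)
    conserved = cells.get(all_in, 0)
    unique: dict[str, int] = {}
    unique_share: dict[str, float] = {}
    for i, name in enumerate(names):
        pattern = tuple(j == i for j in range(len(names)))
        unique[name] = cells.get(pattern, 0)
        size = len(peptide_sets[name])
        unique_share[name] = unique[name] / size if size else 0.0
    return OverlapReport(
        set_names=names,
        cells=cells,
        conserved=conserved,
        unique_per_set=unique,
        unique_share_per_set=unique_share,
        set_sizes={name: len(s) for name, s in peptide_sets.items()},
    )


def peptide_sets_from_table(
    table: PeptideTable, samples: Sequence[str] | None = None
) -> dict[str, set[str]]:
    """Sequence-level identification sets per sample (nonzero intensity ⇒ identified)."""
    collapsed = collapse_duplicates(table)
    samples = list(samples) if samples is not None else list(collapsed.samples)
    return {
        sample: {
            rec.sequence
            for rec in collapsed.records
            if rec.intensity.get(sample, 0.0) > 0
        }
        for sample in samples
    }
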