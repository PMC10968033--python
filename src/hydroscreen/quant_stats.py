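"""Intensity-weighted peptide-level summary statistics per sample.

Weighted statistics use each peptide's share of the total MS intensity in a
sample as its weight. The amino-acid composition is computed on the
residue-pool definition:

    p_aa = sum_i w_i * n_{i,aa} / sum_i w_i * L_i

which makes the additive-charge identity exact:

    weighted_mean_charge == weighted_mean_length * sum_aa contribution(aa) * p_aa
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peptide_io import CANONICAL_AA, PeptideTable

__all__ = [
    "ChargeModel",
    "FractionSummary",
    "DEFAULT_LENGTH_BINS",
    "relative_abundance",
    "peptide_charge",
    "weighted_mean",
    "aa_molar_abundance",
    "summarize_fraction",
    "summaries_to_frame",
]

#: pH-7 heuristic per-residue charge contributions.
_DEFAULT_CONTRIBUTIONS: dict[str, float] = {
    "D": -1.0,
    "E": -1.0,
    "R": +1.0,
    "K": +1.0,
    "H": +0.1,
}

#: Default length-histogram bins, inclusive (lo, hi) in residues.
DEFAULT_LENGTH_BINS: tuple[tuple[int, int], ...] = (
    (3, 5),
    (6, 10),
    (11, 20),
    (21, 65),
)


@dataclass(frozen=True)
class ChargeModel:
    """Additive per-residue net-charge model (termini ignored)."""

    contributions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONTRIBUTIONS)
    )

    def __post_init__(self) -> None:
        bad = set(self.contributions) - CANONICAL_AA
        if bad:
            raise ValueError(f"charge contributions for non-canonical letters {sorted(bad)}")

    def contribution(self, aa: str) -> float:
        return self.contributions.get(aa, 0.0)


@dataclass(frozen=True)
class FractionSummary:
    """Per-sample summary: counts, mean length/charge (arithmetic and weighted),
    amino-acid composition and an intensity-weighted length histogram."""

    sample_id: str
    n_peptide_ids: int
    mean_length: float
    weighted_mean_length: float
    mean_charge: float
    weighted_mean_charge: float
    aa_abundance: Mapping[str, float]
    length_histogram: Mapping[tuple[int, int], float]


def relative_abundance(intensities: Sequence[float]) -> np.ndarray:
    """Normalize intensities to weights summing to 1; zero intensities get weight 0."""
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim != 1:
        raise ValueError("intensities must be one-dimensional")
    if np.any(arr < 0):
        raise ValueError("negative intensity")
    total = arr.sum()
    if total <= 0:
        raise ValueError("no quantified peptides in sample")
    return arr / total


def peptide_charge(sequence: str, model: ChargeModel | None = None) -> float:
    """Net charge of a peptide under the additive per-residue model."""
    model = model or ChargeModel()
    bad = set(sequence) - CANONICAL_AA
    if bad:
        raise ValueError(f"non-canonical residue(s) {sorted(bad)} in {sequence!r}")
    return sum(model.contribution(aa) for aa in sequence)


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted mean Σ w_i v_i of values under weights that sum to 1."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError(f"length mismatch: {v.shape} values vs {w.shape} weights")
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    return float(w @ v)


def _weights_for_sample(table: PeptideTable, sample: str) -> np.ndarray:
    if sample not in table.samples:
        raise KeyError(f"unknown sample {sample!r}")
    return relative_abundance([r.intensity.get(sample, 0.0) for r in table.records])


def aa_molar_abundance(table: PeptideTable, sample: str) -> dict[str, float]:
    """Relative molar amino-acid abundance of the intensity-weighted residue pool.

    Returns a map over all 20 canonical letters (zeros included) summing to 1.
    """
    w = _weights_for_sample(table, sample)
    residue_pool: Counter[str] = Counter()
    denom = 0.0
    for rec, wi in zip(table.records, w):
        if wi == 0.0:
            continue
        for aa, count in Counter(rec.sequence).items():
            residue_pool[aa] += wi * count
        denom += wi * len(rec)
    return {aa: residue_pool.get(aa, 0.0) / denom for aa in sorted(CANONICAL_AA)}


def summarize_fraction(
    table: PeptideTable,
    sample: str,
    model: ChargeModel | None = None,
    bins: Sequence[tuple[int, int]] = DEFAULT_LENGTH_BINS,
) -> FractionSummary:
    """Summary statistics for one sample/fraction.

    Arithmetic means run over all records (identification count); weighted
    means run over quantified records only, weighted by intensity share.
    """
    model = model or ChargeModel()
    if not table.records:
        raise ValueError("empty peptide table")
    lengths = np.array([len(r) for r in table.records], dtype=float)
    charges = np.array([peptide_charge(r.sequence, model) for r in table.records])
    w = _weights_for_sample(table, sample)

    hist = {}
    for lo, hi in bins:
        in_bin = (lengths >= lo) & (lengths <= hi)
        hist[(lo, hi)] = float(w[in_bin].sum())
    covered = sum(hist.values())
    if covered > 0:
        hist = {k: v / covered for k, v in hist.items()}

    return FractionSummary(
        sample_id=sample,
        n_peptide_ids=len(table.records),
        mean_length=float(lengths.mean()),
        weighted_mean_length=float(w @ lengths),
        mean_charge=float(charges.mean()),
        weighted_mean_charge=float(w @ charges),
        aa_abundance=aa_molar_abundance(table, sample),
        length_histogram=hist,
    )


def summaries_to_frame(summaries: Sequence[FractionSummary]) -> pd.DataFrame:
    """Assemble summaries into a statistics × samples table (one column per fraction)."""
    columns = {}
    for s in summaries:
        col = {
            "peptide_ids": s.n_peptide_ids,
            "mean_length": s.mean_length,
            "weighted_mean_length": s.weighted_mean_length,
            "mean_charge": s.mean_charge,
            "weighted_mean_charge": s.weighted_mean_charge,
        }
        for aa, frac in s.aa_abundance.items():
            col[f"aa_{aa}"] = frac
        for (lo, hi), share in s.length_histogram.items():
            col[f"len_{lo}_{hi}"] = share
        columns[s.sample_id] = col
    return pd.DataFrame(columns)


def write_summary_tsv(summaries: Sequence[FractionSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, sep="\t", index_label="statistic")
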