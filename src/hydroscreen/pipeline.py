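"""End-to-end study orchestration: simulate (or load) → filter → summarize →
score-aggregate → overlap → SPR fit → assay tables.

A :class:`StudyConfig` fully determines a synthetic study; identical config
and seed produce byte-identical report JSON. Every random draw goes through a
named child of the study seed, so single stages can be re-run reproducibly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import synthetic as syn
from .antiox_scoring import (
    ScoreTable,
    ThresholdConfig,
    aggregate,
    attach_scores,
    overlap_analysis,
    peptide_sets_from_table,
    write_score_table,
)
from .assay_calcs import (
    CalibrationCurve,
    OPAPlate,
    dh_from_plate,
    fit_calibration,
    glycine_equivalents,
    protein_and_yield,
)
from .peptide_io import PeptideRecord, PeptideTable, filter_peptides, write_fasta, write_peptide_table
from .quant_stats import summaries_to_frame, summarize_fraction
from .spr_binding import Isotherm, fit_langmuir, write_isotherm_csv

__all__ = ["StudyConfig", "run_study", "simulate_study", "write_study_inputs", "StageError"]

_RULE_FACTORIES = {
    "alcalase": syn.alcalase_rule,
    "trypsin": syn.trypsin_rule,
    "flavourzyme": syn.flavourzyme_rule,
}

_FRACTION_SHORT = {"<1kDa": "1", "1-3kDa": "13", "3-5kDa": "35", "PPH": "PPH"}


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and sample."""

    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample


class SPRConfig(BaseModel):
    rmax: float = 100.0
    noise_cv: float = 0.02
    concentrations: list[float] = Field(
        default_factory=lambda: list(syn.DEFAULT_SPR_CONCENTRATIONS)
    )
    duplicate_indices: list[int] = Field(default_factory=lambda: [0, 3, 6])
    #: true K_D = kd_scale * exp(-kd_gain * ground-truth CHE mass share)
    kd_scale: float = 12.0
    kd_gain: float = 20.0


class OPAConfig(BaseModel):
    protein_pct: float = 0.2  # % w/v of the diluted hydrolysate
    cal_slope: float = 1.2  # absorbance per mg Ser/mL
    cal_intercept: float = 0.02
    cal_concentrations: list[float] = Field(
        default_factory=lambda: [0.5 / 2**i for i in range(8)]
    )
    gly_cal_slope: float = 0.16  # absorbance per mM Eq Gly
    gly_cal_intercept: float = 0.0
    noise_cv: float = 0.01
    blank_absorbance: float = 0.05
    dilution_factors: list[int] = Field(default_factory=lambda: [1, 2, 4, 8])


class YieldConfig(BaseModel):
    dumas_pct: float = 1.5
    supernatant_g: float = 180.0
    substrate_g: float = 10.0


class StudyConfig(BaseModel):
    """Full specification of a synthetic screening study."""

    seed: int = 1
    n_proteins: int = 20
    mean_protein_length: int = 300
    substrate_copies: int = 2
    chains: dict[str, list[str]] = Field(
        default_factory=lambda: {
            "AF": ["alcalase", "flavourzyme"],
            "TF": ["trypsin", "flavourzyme"],
        }
    )
    fractions: list[str] = Field(
        default_factory=lambda: ["<1kDa", "1-3kDa", "3-5kDa", "PPH"]
    )
    exclude_samples: list[str] = Field(default_factory=lambda: ["TF1"])
    leak_prob: float = 0.2
    leak_fraction: float = 0.2
    ms_noise_cv: float = 0.3
    lys_intensity_boost: float = 1.5
    frs_threshold: float = 0.43
    che_threshold: float = 0.30
    min_len: int = 3
    max_len: int = 65
    spr: SPRConfig = Field(default_factory=SPRConfig)
    opa: OPAConfig = Field(default_factory=OPAConfig)
    yields: YieldConfig = Field(default_factory=YieldConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _child_seed(root: int, *key: str) -> int:
    """Deterministic named child seed derived from the study seed."""
    digest = hashlib.sha256(("/".join(key)).encode()).digest()
    tag = int.from_bytes(digest[:4], "big")
    return int(np.random.SeedSequence([root, tag]).generate_state(1)[0])


def _pool_che_share(pool: Mapping[str, float], scores: ScoreTable, threshold: float) -> float:
    """Ground-truth mass share of the pool with CHE >= threshold.

    Mass-weighted because SPR analyte solutions are dosed by mass (1 mg/mL).
    Unscorable material (free amino acids, >30-mers) counts toward the
    denominator but never toward the numerator.
    """
    total = above = 0.0
    for seq, amount in pool.items():
        mass = amount * syn.peptide_mass(seq)
        total += mass
        ps = scores.scores.get(seq)
        if ps is not None and ps.che >= threshold:
            above += mass
    return above / total if total > 0 else 0.0


def _number_average_mass(pool: Mapping[str, float]) -> float:
    num = sum(a * syn.peptide_mass(s) for s, a in pool.items())
    den = sum(pool.values())
    if den <= 0:
        raise ValueError("empty pool")
    return num / den


def _merge_tables(tables: Mapping[str, PeptideTable]) -> PeptideTable:
    """Union per-fraction single-sample tables into one multi-sample table."""
    samples = tuple(tables)
    merged: dict[str, dict[str, float]] = {}
    for label, table in tables.items():
        for rec in table.records:
            merged.setdefault(rec.sequence, {})[label] = rec.intensity.get(label, 0.0)
    records = tuple(
        PeptideRecord(sequence=seq, intensity=intens)
        for seq, intens in sorted(merged.items())
    )
    return PeptideTable(records=records, samples=samples)


@dataclass
class SimulatedStudy:
    """Every synthetic input plus its ground truth."""

    config: StudyConfig
    db: object  # ProteinDB
    stage_dh: dict[str, list[float]]  # chain → true DH after each stage
    pools: dict[str, dict[str, float]]  # sample → peptide pool
    peptide_table: PeptideTable  # merged, unfiltered MS observation
    scores: ScoreTable
    serine_curve: CalibrationCurve
    glycine_curve: CalibrationCurve
    plates: dict[str, OPAPlate]  # chain → OPA plate
    isotherms: dict[str, Isotherm]  # sample → isotherm
    true_kd: dict[str, float]
    conc_mm: dict[str, float]  # sample → mM Eq Gly at 1 mg/mL (ground truth)
    che_mass_share: dict[str, float]


def simulate_study(config: StudyConfig) -> SimulatedStudy:
    """Generate all study inputs and ground truth from the config and seed."""
    seed = config.seed
    db = syn.make_protein_db(
        config.n_proteins,
        config.mean_protein_length,
        seed=_child_seed(seed, "protein_db"),
    )

    pools: dict[str, dict[str, float]] = {}
    stage_dh: dict[str, list[float]] = {}
    for chain, rule_names in config.chains.items():
        rules = [_RULE_FACTORIES[name]() for name in rule_names]
        states = syn.sequential_digest(
            db, rules, seed=_child_seed(seed, "digest", chain),
            copies=config.substrate_copies,
        )
        stage_dh[chain] = [syn.true_dh(st) for st in states]
        final = states[-1]
        fracs = syn.ultrafilter(
            final,
            leak_prob=config.leak_prob,
            leak_fraction=config.leak_fraction,
            seed=_child_seed(seed, "ultrafilter", chain),
        )
        for frac_label in config.fractions:
            sample = chain + _FRACTION_SHORT.get(frac_label, frac_label)
            if sample in config.exclude_samples:
                continue
            pools[sample] = dict(final.pool) if frac_label == "PPH" else fracs[frac_label]

    tables = {}
    for sample, pool in pools.items():
        params = syn.ObservationParams(
            lys_intensity_boost=config.lys_intensity_boost,
            noise_cv=config.ms_noise_cv,
            rng_seed=_child_seed(seed, "ms", sample),
        )
        tables[sample] = syn.ms_observe(pool, params, sample_id=sample)
    merged = _merge_tables(tables)

    scores = syn.synth_scores(
        set(merged.sequences()), seed=_child_seed(seed, "scores")
    )

    cal_conc, cal_abs = syn.synth_calibration(
        config.opa.cal_slope, config.opa.cal_intercept, config.opa.cal_concentrations
    )
    serine_curve = fit_calibration(cal_conc, cal_abs, analyte="serine")
    gly_conc, gly_abs = syn.synth_calibration(
        config.opa.gly_cal_slope, config.opa.gly_cal_intercept,
        [0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0],
    )
    glycine_curve = fit_calibration(gly_conc, gly_abs, analyte="glycine")

    plates = {
        chain: syn.synth_opa_plate(
            stage_dh[chain][-1],
            config.opa.protein_pct,
            serine_curve,
            dfs=config.opa.dilution_factors,
            noise_cv=config.opa.noise_cv,
            seed=_child_seed(seed, "opa", chain),
            sample_id=chain,
            blank_absorbance=config.opa.blank_absorbance,
        )
        for chain in config.chains
    }

    che_mass_share = {
        sample: _pool_che_share(pool, scores, config.che_threshold)
        for sample, pool in pools.items()
    }
    true_kd = {
        sample: config.spr.kd_scale * float(np.exp(-config.spr.kd_gain * share))
        for sample, share in che_mass_share.items()
    }
    conc_mm = {
        sample: 1000.0 / _number_average_mass(pool)
        for sample, pool in pools.items()
    }
    isotherms = {
        sample: syn.synth_isotherm(
            true_kd[sample],
            config.spr.rmax,
            concentrations=config.spr.concentrations,
            noise_cv=config.spr.noise_cv,
            seed=_child_seed(seed, "spr", sample),
            duplicate_indices=config.spr.duplicate_indices,
            sample_id=sample,
        )
        for sample in pools
    }

    return SimulatedStudy(
        config=config,
        db=db,
        stage_dh=stage_dh,
        pools=pools,
        peptide_table=merged,
        scores=scores,
        serine_curve=serine_curve,
        glycine_curve=glycine_curve,
        plates=plates,
        isotherms=isotherms,
        true_kd=true_kd,
        conc_mm=conc_mm,
        che_mass_share=che_mass_share,
    )


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full synthetic study and return the report as a dict.

    With ``outdir`` the analysis tables (TSV/CSV) and the report JSON are
    written alongside.
    """
    sim = simulate_study(config)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    # --- Table 1 analog: protein/yield + OPA round-trip DH --------------
    table1_rows = {}
    for chain in config.chains:
        protein_g, yield_pct = protein_and_yield(
            config.yields.dumas_pct,
            config.yields.supernatant_g,
            config.yields.substrate_g,
        )
        try:
            dh_mean, dh_sd = dh_from_plate(
                sim.plates[chain], sim.serine_curve, {chain: config.opa.protein_pct}
            )[chain]
        except Exception as exc:
            raise StageError("opa_dh", chain, exc) from exc
        table1_rows[chain] = {
            "stage_dh_true": sim.stage_dh[chain],
            "dh_measured": dh_mean,
            "dh_sd": dh_sd,
            "protein_g": protein_g,
            "yield_pct": yield_pct,
        }
    report["table1"] = table1_rows

    # --- filter + summaries (Table 2 analog) ----------------------------
    filtered, filter_report = filter_peptides(
        sim.peptide_table, min_len=config.min_len, max_len=config.max_len
    )
    report["filter"] = {
        "n_input": filter_report.n_input,
        "n_retained": filter_report.n_retained,
    }
    summaries = []
    for sample in filtered.samples:
        try:
            summaries.append(summarize_fraction(filtered, sample))
        except Exception as exc:
            raise StageError("summarize", sample, exc) from exc
    summary_frame = summaries_to_frame(summaries)
    report["table2"] = json.loads(summary_frame.to_json())

    # --- scores and aggregation (Figure 1 analog) -----------------------
    scored = attach_scores(filtered, sim.scores)
    thresholds = ThresholdConfig(
        frs_threshold=config.frs_threshold, che_threshold=config.che_threshold
    )
    agg_rows = []
    for sample in filtered.samples:
        for prop in ("FRS", "CHE"):
            try:
                r = aggregate(scored, sample, prop, thresholds)
            except Exception as exc:
                raise StageError("aggregate", sample, exc) from exc
            agg_rows.append(
                {
                    "sample": sample,
                    "property": prop,
                    "n_above": r.n_above,
                    "frac_ids_above": r.frac_ids_above,
                    "intensity_frac_above": r.intensity_frac_above,
                    "raw_intensity_frac_above": r.raw_intensity_frac_above,
                    "mean_score": r.mean_score,
                }
            )
    report["aggregation"] = agg_rows

    overlap = overlap_analysis(peptide_sets_from_table(filtered))
    report["overlap"] = {
        "conserved": overlap.conserved,
        "unique_per_set": dict(overlap.unique_per_set),
        "set_sizes": dict(overlap.set_sizes),
    }

    # --- SPR (Table 3 analog) -------------------------------------------
    table3_rows = {}
    for sample in sim.pools:
        gly_abs = (
            config.opa.gly_cal_intercept
            + config.opa.gly_cal_slope * sim.conc_mm[sample]
            + config.opa.blank_absorbance
        )
        conc_measured = glycine_equivalents(
            gly_abs, config.opa.blank_absorbance, sim.glycine_curve
        )
        try:
            fit = fit_langmuir(sim.isotherms[sample])
        except Exception as exc:
            raise StageError("spr_fit", sample, exc) from exc
        table3_rows[sample] = {
            "conc_mm_eq_gly": conc_measured,
            "kd_true": sim.true_kd[sample],
            "kd": fit.kd,
            "se_kd": fit.se_kd,
            "rmax": fit.rmax,
            "saturation_flag": fit.saturation_flag,
            "che_mass_share": sim.che_mass_share[sample],
        }
    report["table3"] = table3_rows

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary_frame.to_csv(outdir / "table2.tsv", sep="\t", index_label="statistic")
        pd.DataFrame(agg_rows).to_csv(outdir / "aggregation.tsv", sep="\t", index=False)
        overlap.to_frame().to_csv(outdir / "upset.csv", index=False)
        pd.DataFrame(table3_rows).T.to_csv(outdir / "table3.tsv", sep="\t", index_label="sample")
        pd.DataFrame(table1_rows).T.to_csv(outdir / "table1.tsv", sep="\t", index_label="chain")
        (outdir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n"
        )
    return report


def write_study_inputs(config: StudyConfig, outdir: str | Path) -> None:
    """Emit a complete synthetic study in the dialects the pipeline reads.

    Writes the substrate FASTA, the merged peptide table TSV, the score TSV,
    per-sample isotherm CSVs, per-chain OPA plate CSVs, the calibration CSVs,
    and a ground-truth JSON for testing.
    """
    sim = simulate_study(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    write_fasta(sim.db, outdir / "substrate.fasta")
    write_peptide_table(sim.peptide_table, outdir / "peptides.tsv")
    write_score_table(sim.scores, outdir / "scores.tsv")
    for sample, isotherm in sim.isotherms.items():
        write_isotherm_csv(isotherm, outdir / f"isotherm_{sample}.csv")
    for chain, plate in sim.plates.items():
        rows = [
            {
                "sample": w.sample_id,
                "df": w.dilution_factor,
                "replicate": w.replicate,
                "absorbance": w.absorbance_340,
            }
            for w in plate.wells
        ]
        rows.append({"sample": "blank", "df": 1, "replicate": 0,
                     "absorbance": plate.blank_absorbance})
        pd.DataFrame(rows).to_csv(outdir / f"opa_plate_{chain}.csv", index=False)
    cal_conc, cal_abs = syn.synth_calibration(
        config.opa.cal_slope, config.opa.cal_intercept, config.opa.cal_concentrations
    )
    pd.DataFrame({"concentration": cal_conc, "absorbance": cal_abs}).to_csv(
        outdir / "serine_calibration.csv", index=False
    )
    ground_truth = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stage_dh_true": sim.stage_dh,
        "true_kd": sim.true_kd,
        "conc_mm_eq_gly": sim.conc_mm,
        "che_mass_share": sim.che_mass_share,
        "pool_sizes": {s: len(p) for s, p in sim.pools.items()},
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps(ground_truth, sort_keys=True, indent=2) + "\n"
    )
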