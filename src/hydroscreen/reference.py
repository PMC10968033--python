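"""Published reference summary for seven potato-protein hydrolysate fractions.

These values come from a published peptidomic screening study of sequential
alcalase/trypsin + Flavourzyme potato-protein hydrolysates fractionated by
ultrafiltration. They serve as an internal-consistency benchmark: multiplying
a fraction's intensity-weighted mean peptide length by the net per-residue
charge computed from its relative molar amino-acid composition (additive
model: Asp/Glu −1, Arg/Lys +1, His +0.1) should reproduce the reported
intensity-weighted mean charge up to rounding of the printed percentages.

``aa_pct`` values are percentages as printed (one decimal); lengths and
charges are intensity-weighted means.
"""

from __future__ import annotations

from .quant_stats import ChargeModel

__all__ = ["REFERENCE_FRACTIONS", "reconstruct_weighted_charge"]

REFERENCE_FRACTIONS: dict[str, dict] = {
    "AF1": {
        "peptide_ids": 3968,
        "mean_length": 6.36,
        "weighted_mean_length": 4.80,
        "mean_charge": -0.41,
        "weighted_mean_charge": -0.30,
        "aa_pct": {
            "A": 4.2, "R": 0.7, "N": 2.1, "D": 4.0, "C": 0.2,
            "Q": 1.4, "E": 2.7, "G": 8.2, "H": 0.6, "I": 1.3,
            "L": 23.5, "K": 0.7, "M": 0.8, "F": 12.8, "P": 14.2,
            "S": 2.9, "T": 3.3, "W": 3.3, "Y": 3.6, "V": 9.4,
        },
    },
    "AF13": {
        "peptide_ids": 5535,
        "mean_length": 7.75,
        "weighted_mean_length": 6.57,
        "mean_charge": -0.68,
        "weighted_mean_charge": -0.64,
        "aa_pct": {
            "A": 3.7, "R": 1.4, "N": 3.5, "D": 7.6, "C": 0.3,
            "Q": 1.9, "E": 4.6, "G": 9.6, "H": 0.7, "I": 3.0,
            "L": 18.3, "K": 1.4, "M": 1.0, "F": 7.8, "P": 12.4,
            "S": 3.4, "T": 4.6, "W": 1.6, "Y": 3.7, "V": 9.6,
        },
    },
    "AF35": {
        "peptide_ids": 5872,
        "mean_length": 8.67,
        "weighted_mean_length": 7.77,
        "mean_charge": -0.82,
        "weighted_mean_charge": -0.83,
        "aa_pct": {
            "A": 4.0, "R": 1.6, "N": 3.8, "D": 8.4, "C": 0.3,
            "Q": 2.0, "E": 5.8, "G": 9.9, "H": 0.6, "I": 4.2,
            "L": 15.4, "K": 2.1, "M": 0.9, "F": 6.4, "P": 11.9,
            "S": 3.8, "T": 5.3, "W": 1.1, "Y": 3.0, "V": 9.4,
        },
    },
    "AFPPH": {
        "peptide_ids": 6032,
        "mean_length": 8.76,
        "weighted_mean_length": 7.79,
        "mean_charge": -0.82,
        "weighted_mean_charge": -0.78,
        "aa_pct": {
            "A": 3.8, "R": 1.5, "N": 3.8, "D": 7.8, "C": 0.6,
            "Q": 2.1, "E": 5.5, "G": 9.7, "H": 0.7, "I": 3.8,
            "L": 15.4, "K": 2.4, "M": 0.8, "F": 6.4, "P": 12.1,
            "S": 4.6, "T": 5.4, "W": 1.3, "Y": 3.3, "V": 8.8,
        },
    },
    "TF13": {
        "peptide_ids": 5241,
        "mean_length": 8.17,
        "weighted_mean_length": 7.91,
        "mean_charge": -0.72,
        "weighted_mean_charge": -0.64,
        "aa_pct": {
            "A": 4.1, "R": 1.6, "N": 4.2, "D": 5.5, "C": 0.1,
            "Q": 1.3, "E": 5.8, "G": 11.3, "H": 0.7, "I": 4.2,
            "L": 15.1, "K": 1.7, "M": 1.1, "F": 6.5, "P": 12.9,
            "S": 4.8, "T": 5.5, "W": 1.1, "Y": 2.7, "V": 9.8,
        },
    },
    "TF35": {
        "peptide_ids": 6085,
        "mean_length": 9.66,
        "weighted_mean_length": 9.50,
        "mean_charge": -1.01,
        "weighted_mean_charge": -0.98,
        "aa_pct": {
            "A": 5.0, "R": 1.9, "N": 4.5, "D": 8.0, "C": 0.3,
            "Q": 1.6, "E": 6.6, "G": 12.4, "H": 0.6, "I": 4.9,
            "L": 11.3, "K": 2.5, "M": 0.9, "F": 4.2, "P": 10.6,
            "S": 5.7, "T": 6.7, "W": 0.7, "Y": 2.7, "V": 9.2,
        },
    },
    "TFPPH": {
        "peptide_ids": 6325,
        "mean_length": 9.79,
        "weighted_mean_length": 9.51,
        "mean_charge": -1.02,
        "weighted_mean_charge": -1.02,
        "aa_pct": {
            "A": 4.8, "R": 1.6, "N": 4.4, "D": 7.9, "C": 0.4,
            "Q": 1.5, "E": 6.9, "G": 11.2, "H": 0.6, "I": 4.9,
            "L": 11.3, "K": 2.7, "M": 1.2, "F": 4.6, "P": 11.0,
            "S": 5.8, "T": 6.4, "W": 0.7, "Y": 2.8, "V": 9.3,
        },
    },
}

#: Reported dissociation constants (mM Eq Gly) and fit SEs for the same fractions.
REFERENCE_BINDING: dict[str, dict] = {
    "AF1": {"conc_mm_eq_gly": 3.53, "kd": 0.72, "se_kd": 0.43},
    "AF13": {"conc_mm_eq_gly": 2.78, "kd": 1.41, "se_kd": 0.87},
    "AF35": {"conc_mm_eq_gly": 2.41, "kd": 2.27, "se_kd": 0.58},
    "AFPPH": {"conc_mm_eq_gly": 2.41, "kd": 6.81, "se_kd": 2.10},
    "TF13": {"conc_mm_eq_gly": 2.82, "kd": 4.85, "se_kd": 2.40},
    "TF35": {"conc_mm_eq_gly": 2.27, "kd": 9.19, "se_kd": 7.80},
    "TFPPH": {"conc_mm_eq_gly": 2.27, "kd": 8.16, "se_kd": 7.50},
}


def reconstruct_weighted_charge(
    fraction: str, model: ChargeModel | None = None
) -> float:
    """Reconstruct a fraction's weighted mean charge from its published
    composition: weighted_mean_length × Σ_aa contribution(aa) · p_aa."""
    model = model or ChargeModel()
    ref = REFERENCE_FRACTIONS[fraction]
    per_residue = sum(
        model.contribution(aa) * pct / 100.0 for aa, pct in ref["aa_pct"].items()
    )
    return ref["weighted_mean_length"] * per_residue
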