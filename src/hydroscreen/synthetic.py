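"""Synthetic hydrolysate study generator.

Produces every input the analysis pipeline consumes, with the statistical
structure the analysis assumes: sequential stochastic protease digestion with
ground-truth DH bookkeeping, ultrafiltration into molecular-weight fractions
with imperfect separation, a length- and Lys-biased MS observation model,
plausible FRS/CHE score tables, Langmuir-shaped isotherms, and OPA plates
generated by inverting the DH calculus.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .antiox_scoring import PeptideScores, ScoreTable
from .assay_calcs import CalibrationCurve, OPAPlate, OPAWell
from .peptide_io import PeptideRecord, PeptideTable, ProteinDB
from .spr_binding import Isotherm

__all__ = [
    "EnzymeRule",
    "DigestState",
    "ObservationParams",
    "ScoreGenParams",
    "DEFAULT_AA_FREQS",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "trypsin_rule",
    "alcalase_rule",
    "flavourzyme_rule",
    "make_protein_db",
    "digest",
    "sequential_digest",
    "true_dh",
    "peptide_mass",
    "ultrafilter",
    "ms_observe",
    "synth_scores",
    "synth_isotherm",
    "synth_opa_plate",
    "synth_calibration",
]

#: Substrate amino-acid frequency profile (potato-protein-like; configurable).
DEFAULT_AA_FREQS: dict[str, float] = {
    "A": 0.038, "R": 0.015, "N": 0.038, "D": 0.078, "C": 0.006,
    "Q": 0.021, "E": 0.055, "G": 0.097, "H": 0.007, "I": 0.038,
    "L": 0.154, "K": 0.024, "M": 0.008, "F": 0.064, "P": 0.121,
    "S": 0.046, "T": 0.054, "W": 0.013, "Y": 0.033, "V": 0.088,
}

#: Average (not monoisotopic) residue masses, Da.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153


@dataclass(frozen=True)
class EnzymeRule:
    """Cleavage rule: endoprotease specificity plus an optional exopeptidase component.

    Endo: each eligible bond (P1 residue in ``p1_residues``, P1' != Pro when
    blocked) is cleaved independently with probability ``p_cut``. Exo: per
    molecule, up to ``exo_rounds`` rounds each remove the N-terminal residue
    with probability ``exo_n_trim_prob``, releasing free amino acids.
    """

    name: str
    p1_residues: frozenset[str] = frozenset()
    block_p1prime_pro: bool = False
    p_cut: float = 0.0
    exo_n_trim_prob: float = 0.0
    exo_rounds: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_cut, self.exo_n_trim_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.p1_residues and self.exo_rounds == 0 and self.p_cut > 0:
            raise ValueError("endo rule needs non-empty p1_residues")


def trypsin_rule(p_cut: float = 1.0, block_pro: bool = True) -> EnzymeRule:
    """Arg/Lys-specific endoprotease (C-terminal cleavage, Pro block by default)."""
    return EnzymeRule(
        name="trypsin",
        p1_residues=frozenset("KR"),
        block_p1prime_pro=block_pro,
        p_cut=p_cut,
    )


def alcalase_rule(p_cut: float = 0.40) -> EnzymeRule:
    """Broad-specificity endoprotease stand-in (declared rule set, not a claim)."""
    return EnzymeRule(
        name="alcalase",
        p1_residues=frozenset("AFLMWYVEQS"),
        block_p1prime_pro=False,
        p_cut=p_cut,
    )


def flavourzyme_rule(
    p_cut: float = 0.08,
    exo_n_trim_prob: float = 0.3,
    exo_rounds: int = 2,
) -> EnzymeRule:
    """Endo+exo cocktail stand-in: moderate broad endo plus N-terminal trimming."""
    return EnzymeRule(
        name="flavourzyme",
        p1_residues=frozenset("AFILMVWYKRDENQSTGH"),
        block_p1prime_pro=False,
        p_cut=p_cut,
        exo_n_trim_prob=exo_n_trim_prob,
        exo_rounds=exo_rounds,
    )


@dataclass
class DigestState:
    """Ground truth of a (possibly multi-stage) digestion."""

    pool: dict[str, float]  # peptide sequence → molar amount
    cleaved_bonds: int
    total_bonds: int
    substrate_db: ProteinDB
    rng_seed: int

    def residue_amount(self) -> float:
        return sum(amount * len(seq) for seq, amount in self.pool.items())


def make_protein_db(
    n_proteins: int,
    mean_length: int,
    seed: int,
    length_sd: float = 30.0,
    aa_freqs: Mapping[str, float] | None = None,
) -> ProteinDB:
    """Random protein database with a configurable amino-acid frequency profile."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    freqs = dict(aa_freqs or DEFAULT_AA_FREQS)
    letters = sorted(freqs)
    p = np.array([freqs[a] for a in letters], dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    entries: dict[str, str] = {}
    for i in range(n_proteins):
        length = max(10, int(round(rng.normal(mean_length, length_sd))))
        seq = "".join(rng.choice(letters, size=length, p=p))
        entries[f"SYN|P{i + 1:04d}"] = seq
    return ProteinDB(entries=entries)


def _eligible_bonds(seq: str, rule: EnzymeRule) -> np.ndarray:
    """0-based indices i of cleavable bonds between residues i and i+1."""
    if not rule.p1_residues or rule.p_cut == 0.0:
        return np.empty(0, dtype=int)
    idx = [
        i
        for i in range(len(seq) - 1)
        if seq[i] in rule.p1_residues
        and not (rule.block_p1prime_pro and seq[i + 1] == "P")
    ]
    return np.asarray(idx, dtype=int)


def _apply_rule(
    pool: Mapping[str, float], rule: EnzymeRule, rng: np.random.Generator
) -> tuple[dict[str, float], int]:
    """One enzyme stage over a molecule pool. Amounts are treated as integer
    molecule counts (rounded); returns the new pool and cleaved-bond count."""
    new_pool: dict[str, float] = {}
    cleaved = 0

    def add(seq: str, amount: float) -> None:
        if amount:
            new_pool[seq] = new_pool.get(seq, 0.0) + amount

    for seq, amount in pool.items():
        n = int(round(amount))
        if n <= 0:
            continue
        bonds = _eligible_bonds(seq, rule)
        # endo: fragment each molecule independently
        fragments: list[str] = []
        if bonds.size:
            cuts = rng.random((n, bonds.size)) < rule.p_cut
            for row in cuts:
                cut_positions = bonds[row] + 1
                cleaved += int(row.sum())
                start = 0
                for pos in cut_positions:
                    fragments.append(seq[start:pos])
                    start = pos
                fragments.append(seq[start:])
        else:
            fragments = [seq] * n

        # exo: N-terminal trimming of each fragment molecule
        if rule.exo_rounds > 0 and rule.exo_n_trim_prob > 0:
            for frag in fragments:
                max_trims = len(frag) - 1
                if max_trims <= 0:
                    add(frag, 1)
                    continue
                t = min(
                    int(rng.binomial(rule.exo_rounds, rule.exo_n_trim_prob)),
                    max_trims,
                )
                cleaved += t
                for aa in frag[:t]:
                    add(aa, 1)
                add(frag[t:], 1)
        else:
            for frag in fragments:
                add(frag, 1)
    return new_pool, cleaved


def digest(
    db: ProteinDB, rule: EnzymeRule, seed: int, copies: int = 1
) -> DigestState:
    """Single-enzyme digestion of a protein database (``copies`` molecules each)."""
    rng = np.random.default_rng(seed)
    pool = {seq: float(copies) for seq in db.entries.values()}
    total_bonds = sum((len(seq) - 1) * copies for seq in db.entries.values())
    new_pool, cleaved = _apply_rule(pool, rule, rng)
    return DigestState(
        pool=new_pool,
        cleaved_bonds=cleaved,
        total_bonds=total_bonds,
        substrate_db=db,
        rng_seed=seed,
    )


def sequential_digest(
    db: ProteinDB,
    rules: Sequence[EnzymeRule],
    seed: int,
    copies: int = 1,
) -> list[DigestState]:
    """Apply enzyme rules in sequence; returns the state after each stage.

    Bond accounting is cumulative, so ``true_dh`` is non-decreasing across
    stages by construction.
    """
    if not rules:
        raise ValueError("need at least one enzyme rule")
    seeds = np.random.SeedSequence(seed).spawn(len(rules))
    total_bonds = sum((len(seq) - 1) * copies for seq in db.entries.values())
    pool: dict[str, float] = {seq: float(copies) for seq in db.entries.values()}
    states: list[DigestState] = []
    cleaved_total = 0
    for rule, ss in zip(rules, seeds):
        rng = np.random.default_rng(ss)
        pool, cleaved = _apply_rule(pool, rule, rng)
        cleaved_total += cleaved
        states.append(
            DigestState(
                pool=pool,
                cleaved_bonds=cleaved_total,
                total_bonds=total_bonds,
                substrate_db=db,
                rng_seed=seed,
            )
        )
    return states


def true_dh(state: DigestState) -> float:
    """Ground-truth degree of hydrolysis: % of peptide bonds cleaved."""
    if state.total_bonds <= 0:
        raise ValueError("substrate has no peptide bonds")
    return 100.0 * state.cleaved_bonds / state.total_bonds


def peptide_mass(sequence: str) -> float:
    """Average molecular mass in Da (residue masses + one water)."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        return sum(AVERAGE_RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from exc


def ultrafilter(
    state: DigestState,
    cutoffs_kda: Sequence[float] = (1.0, 3.0, 5.0),
    leak_prob: float = 0.2,
    leak_fraction: float = 0.2,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Partition the peptide pool into molecular-weight fractions.

    Emulates sequential membrane filtration from the top cutoff down: the
    retentate of the top membrane is labeled ``retentate``, the retentate of
    each lower membrane is the corresponding mass band (``3-5kDa``,
    ``1-3kDa`` for the default cutoffs), and the final permeate is ``<1kDa``.
    Above-cutoff peptides are fully retained at each membrane; separation is
    imperfect in that, with probability ``leak_prob`` per species and
    membrane, a ``leak_fraction`` portion of a below-cutoff peptide's amount
    is also retained — so shorter peptides contaminate the higher-mass
    fractions. Total molar amount is conserved exactly.
    """
    cutoffs = list(cutoffs_kda)
    if cutoffs != sorted(cutoffs):
        raise ValueError("cutoffs must be ascending")
    labels = [f"<{_fmt(cutoffs[0])}kDa"]
    labels += [
        f"{_fmt(lo)}-{_fmt(hi)}kDa" for lo, hi in zip(cutoffs[:-1], cutoffs[1:])
    ]
    labels.append("retentate")
    rng = np.random.default_rng(seed)
    fractions: dict[str, dict[str, float]] = {label: {} for label in labels}

    def add(label: str, seq: str, amount: float) -> None:
        if amount > 0:
            frac = fractions[label]
            frac[seq] = frac.get(seq, 0.0) + amount

    # membranes visited top-down; retentate label per membrane
    membranes = [
        (cutoffs[i], labels[i + 1]) for i in reversed(range(len(cutoffs)))
    ]
    for seq, amount in sorted(state.pool.items()):
        mass_kda = peptide_mass(seq) / 1000.0
        remaining = amount
        for cutoff, retentate_label in membranes:
            if mass_kda >= cutoff:
                add(retentate_label, seq, remaining)
                remaining = 0.0
                break
            if leak_prob > 0 and rng.random() < leak_prob:
                retained = leak_fraction * remaining
                add(retentate_label, seq, retained)
                remaining -= retained
        add(labels[0], seq, remaining)
    return fractions


def _fmt(x: float) -> str:
    return f"{x:g}"


def _default_detect_curve(length: int) -> float:
    """Detection probability vs length: ramp 0.3→0.9 over 3–7, plateau to 40,
    declining to 0.5 at 65. Zero outside 3–65."""
    if length < 3 or length > 65:
        return 0.0
    if length <= 7:
        return 0.3 + (0.9 - 0.3) * (length - 3) / 4.0
    if length <= 40:
        return 0.9
    return 0.9 + (0.5 - 0.9) * (length - 40) / 25.0


@dataclass(frozen=True)
class ObservationParams:
    """MS observation model: detection window, length bias, Lys intensity bias, noise."""

    detect_min_len: int = 3
    detect_max_len: int = 65
    lys_intensity_boost: float = 1.5
    length_detect_curve: Callable[[int], float] = _default_detect_curve
    noise_cv: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lys_intensity_boost < 1.0:
            raise ValueError("lys_intensity_boost must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def detect_prob(self, length: int) -> float:
        if length < self.detect_min_len or length > self.detect_max_len:
            return 0.0
        return float(np.clip(self.length_detect_curve(length), 0.0, 1.0))


def ms_observe(
    pool: Mapping[str, float],
    params: ObservationParams,
    sample_id: str = "S1",
) -> PeptideTable:
    """Biased MS observation of a peptide pool.

    Peptides outside the detection window are never observed; within it,
    detection is Bernoulli per the length curve, and the observed intensity is
    amount × lys_boost^[contains Lys] × lognormal(0, noise_cv).
    """
    rng = np.random.default_rng(params.rng_seed)
    records = []
    for seq, amount in sorted(pool.items()):
        p = params.detect_prob(len(seq))
        if p <= 0.0 or rng.random() >= p:
            continue
        intensity = amount
        if "K" in seq:
            intensity *= params.lys_intensity_boost
        if params.noise_cv > 0:
            intensity *= float(np.exp(rng.normal(0.0, params.noise_cv)))
        records.append(
            PeptideRecord(sequence=seq, intensity={sample_id: intensity})
        )
    return PeptideTable(records=tuple(records), samples=(sample_id,))


@dataclass(frozen=True)
class ScoreGenParams:
    """Beta-distributed score generator whose mean rises with aromatic+His
    content and falls with length."""

    frs_base: float = 0.40
    che_base: float = 0.21
    aromatic_coef: float = 0.45
    length_coef: float = 0.02
    concentration: float = 40.0
    min_len: int = 3
    max_len: int = 30

    def mean_score(self, base: float, sequence: str) -> float:
        arom = sum(sequence.count(a) for a in "FWYH") / len(sequence)
        mu = base + self.aromatic_coef * arom - self.length_coef * (len(sequence) - 3)
        return float(np.clip(mu, 0.02, 0.95))


def synth_scores(
    peptides: Iterable[str],
    params: ScoreGenParams | None = None,
    seed: int = 0,
) -> ScoreTable:
    """Plausible FRS/CHE score table for a peptide set; only 3–30-mers scored."""
    params = params or ScoreGenParams()
    rng = np.random.default_rng(seed)
    scores: dict[str, PeptideScores] = {}
    for seq in sorted(set(peptides)):
        if not params.min_len <= len(seq) <= params.max_len:
            continue
        values = []
        for base in (params.frs_base, params.che_base):
            mu = params.mean_score(base, seq)
            a = mu * params.concentration
            b = (1.0 - mu) * params.concentration
            values.append(float(np.clip(rng.beta(a, b), 0.0, 1.0)))
        scores[seq] = PeptideScores(frs=values[0], che=values[1])
    return ScoreTable(scores=scores)


DEFAULT_SPR_CONCENTRATIONS = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0)


def synth_isotherm(
    kd: float,
    rmax: float,
    concentrations: Sequence[float] = DEFAULT_SPR_CONCENTRATIONS,
    noise_cv: float = 0.0,
    seed: int = 0,
    duplicate_indices: Sequence[int] = (0, 3, 6),
    sample_id: str = "",
) -> Isotherm:
    """Langmuir-shaped isotherm with multiplicative lognormal noise.

    The default design replicates the 1st, 4th and 7th concentrations of the
    seven-point series, giving 10 points.
    """
    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be positive")
    rng = np.random.default_rng(seed)
    design = list(concentrations)
    for i in duplicate_indices:
        design.append(concentrations[i])
    points = []
    for c in design:
        response = rmax * c / (kd + c)
        if noise_cv > 0:
            response *= float(np.exp(rng.normal(0.0, noise_cv)))
        points.append((float(c), float(response)))
    return Isotherm(points=tuple(points), sample_id=sample_id)


def synth_calibration(
    slope: float,
    intercept: float,
    concentrations: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Calibration points on the line absorbance = slope·conc + intercept."""
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    ab = slope * conc + intercept
    if noise_cv > 0:
        ab = ab * np.exp(rng.normal(0.0, noise_cv, size=ab.shape))
    return conc, ab


def synth_opa_plate(
    true_dh_pct: float,
    protein_pct: float,
    curve: CalibrationCurve,
    dfs: Sequence[int] = (1, 2, 4, 8),
    noise_cv: float = 0.0,
    seed: int = 0,
    sample_id: str = "S1",
    blank_absorbance: float = 0.05,
    replicates: int = 2,
) -> OPAPlate:
    """OPA plate generated by inverting the DH calculus.

    serine_eq = true_dh·protein_pct·10/100; per-well absorbance = blank +
    (intercept + slope·serine_eq/df) × lognormal noise, in ``replicates``
    duplicates per dilution factor.
    """
    if not 0.0 < true_dh_pct <= 100.0:
        raise ValueError("true DH must lie in (0, 100]")
    if protein_pct <= 0:
        raise ValueError("protein content must be positive")
    rng = np.random.default_rng(seed)
    serine_eq = true_dh_pct * protein_pct * 10.0 / 100.0
    wells = []
    for df in dfs:
        for rep in range(replicates):
            signal = curve.intercept + curve.slope * serine_eq / df
            if noise_cv > 0:
                signal *= float(np.exp(rng.normal(0.0, noise_cv)))
            wells.append(
                OPAWell(
                    sample_id=sample_id,
                    dilution_factor=int(df),
                    absorbance_340=blank_absorbance + signal,
                    replicate=rep,
                )
            )
    return OPAPlate(wells=tuple(wells), blank_absorbance=blank_absorbance)
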