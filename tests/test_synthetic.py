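from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from hydroscreen.peptide_io import ProteinDB
from hydroscreen.quant_stats import aa_molar_abundance
from hydroscreen.spr_binding import fit_langmuir
from hydroscreen.synthetic import (
    DEFAULT_AA_FREQS,
    DigestState,
    EnzymeRule,
    ObservationParams,
    ScoreGenParams,
    alcalase_rule,
    digest,
    flavourzyme_rule,
    make_protein_db,
    ms_observe,
    peptide_mass,
    sequential_digest,
    synth_isotherm,
    synth_opa_plate,
    synth_scores,
    true_dh,
    trypsin_rule,
    ultrafilter,
)


class TestMakeProteinDB:
    def test_determinism(self):
        a = make_protein_db(3, 100, seed=7)
        b = make_protein_db(3, 100, seed=7)
        assert a.entries == b.entries

    def test_length_contract(self):
        db = make_protein_db(50, 300, seed=1, length_sd=10.0)
        lengths = np.array([len(s) for s in db.entries.values()])
        assert abs(lengths.mean() - 300) < 5
        assert all(300 - 45 <= l <= 300 + 45 for l in lengths)  # 4.5 sd

    def test_composition_chi2(self):
        db = make_protein_db(200, 300, seed=2)
        residues = "".join(db.entries.values())
        assert len(residues) > 50_000
        letters = sorted(DEFAULT_AA_FREQS)
        observed = np.array([residues.count(a) for a in letters])
        total = sum(DEFAULT_AA_FREQS.values())
        expected = np.array(
            [DEFAULT_AA_FREQS[a] / total * len(residues) for a in letters]
        )
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01


class TestDigest:
    def test_trypsin_exact_fragments(self):
        db = ProteinDB(entries={"p": "AKGRMP"})
        state = digest(db, trypsin_rule(p_cut=1.0), seed=0)
        assert state.pool == {"AK": 1.0, "GR": 1.0, "MP": 1.0}
        assert state.cleaved_bonds == 2
        assert state.total_bonds == 5
        assert true_dh(state) == pytest.approx(40.0)

    def test_pro_block(self):
        db = ProteinDB(entries={"p": "AKPG"})
        state = digest(db, trypsin_rule(p_cut=1.0), seed=0)
        assert state.pool == {"AKPG": 1.0}
        assert true_dh(state) == 0.0

    def test_pro_block_disabled(self):
        db = ProteinDB(entries={"p": "AKPG"})
        state = digest(db, trypsin_rule(p_cut=1.0, block_pro=False), seed=0)
        assert state.pool == {"AK": 1.0, "PG": 1.0}

    def test_partial_cut_probability(self):
        seq = "AK" * 10 + "G"  # 10 eligible K bonds (none at C-terminus)
        db = ProteinDB(entries={"p": seq})
        fracs = []
        for seed in range(30):
            state = digest(db, trypsin_rule(p_cut=0.5), seed=seed, copies=1000)
            fracs.append(state.cleaved_bonds / (10 * 1000))
        assert abs(np.mean(fracs) - 0.5) < 0.03

    def test_residue_conservation(self):
        db = make_protein_db(5, 200, seed=3)
        substrate_residues = sum(len(s) for s in db.entries.values()) * 2
        state = digest(db, alcalase_rule(), seed=3, copies=2)
        assert state.residue_amount() == pytest.approx(substrate_residues, abs=1e-9)

    def test_exo_releases_free_aas(self):
        db = ProteinDB(entries={"p": "GGGG"})
        rule = EnzymeRule(name="exo", exo_n_trim_prob=1.0, exo_rounds=3)
        state = digest(db, rule, seed=0)
        assert state.pool == {"G": 4.0}
        assert true_dh(state) == pytest.approx(100.0)


class TestSequentialDigest:
    def test_noop_second_rule(self):
        db = ProteinDB(entries={"p": "AKGRMP"})
        noop = EnzymeRule(name="noop")
        states = sequential_digest(db, [trypsin_rule(p_cut=1.0), noop], seed=0)
        single = digest(db, trypsin_rule(p_cut=1.0), seed=0)
        assert states[-1].pool == single.pool
        assert states[-1].cleaved_bonds == single.cleaved_bonds

    def test_dh_monotone_every_seed(self):
        db = make_protein_db(5, 150, seed=0)
        for seed in range(10):
            states = sequential_digest(
                db, [alcalase_rule(), flavourzyme_rule()], seed=seed
            )
            assert true_dh(states[1]) >= true_dh(states[0])

    def test_default_calibration_matches_sequential_pattern(self):
        # stage-1 DH ≈ 20%, rising to ≈ 38% after stage 2 (±5 points over 20 seeds)
        db = make_protein_db(20, 300, seed=11)
        dh1, dh2 = [], []
        for seed in range(20):
            states = sequential_digest(
                db, [alcalase_rule(), flavourzyme_rule()], seed=seed, copies=2
            )
            dh1.append(true_dh(states[0]))
            dh2.append(true_dh(states[1]))
        assert abs(np.mean(dh1) - 20.0) < 5.0
        assert abs(np.mean(dh2) - 38.0) < 5.0

    def test_residue_conservation_through_stages(self):
        db = make_protein_db(5, 150, seed=0)
        total = sum(len(s) for s in db.entries.values())
        states = sequential_digest(db, [alcalase_rule(), flavourzyme_rule()], seed=4)
        for st in states:
            assert st.residue_amount() == pytest.approx(total, abs=1e-9)


class TestTrueDH:
    def test_values(self):
        db = ProteinDB(entries={"p": "AAAAAA"})
        state = DigestState(pool={}, cleaved_bonds=2, total_bonds=5,
                            substrate_db=db, rng_seed=0)
        assert true_dh(state) == pytest.approx(40.0)
        state = DigestState(pool={}, cleaved_bonds=0, total_bonds=5,
                            substrate_db=db, rng_seed=0)
        assert true_dh(state) == 0.0


class TestPeptideMass:
    def test_gg(self):
        assert peptide_mass("GG") == pytest.approx(132.12, abs=0.01)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            peptide_mass("")

    def test_monotone_under_append(self, rng):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        for i in range(1, len(seq)):
            assert peptide_mass(seq[: i + 1]) > peptide_mass(seq[:i])


def _toy_state(pool):
    db = ProteinDB(entries={"p": "A" * 10})
    total = sum(amount * len(seq) for seq, amount in pool.items())
    return DigestState(pool=pool, cleaved_bonds=0, total_bonds=int(total) - 1,
                       substrate_db=db, rng_seed=0)


class TestUltrafilter:
    def test_no_leak_partitions_by_mass(self):
        pool = {"GG": 5.0, "A" * 15: 2.0, "A" * 45: 1.0, "A" * 80: 1.0}
        fracs = ultrafilter(_toy_state(pool), leak_prob=0.0, seed=0)
        assert fracs["<1kDa"] == {"GG": 5.0}
        assert fracs["1-3kDa"] == {"A" * 15: 2.0}  # 1.08 kDa
        assert fracs["3-5kDa"] == {"A" * 45: 1.0}  # 3.2 kDa
        assert fracs["retentate"] == {"A" * 80: 1.0}  # 5.7 kDa

    def test_amount_conservation_any_seed(self):
        db = make_protein_db(5, 150, seed=0)
        state = sequential_digest(db, [alcalase_rule(), flavourzyme_rule()], seed=1)[-1]
        total = sum(state.pool.values())
        for seed in range(5):
            fracs = ultrafilter(state, leak_prob=0.3, seed=seed)
            assert sum(
                sum(p.values()) for p in fracs.values()
            ) == pytest.approx(total, abs=1e-9)

    def test_residue_conservation(self):
        db = make_protein_db(5, 150, seed=0)
        state = sequential_digest(db, [alcalase_rule(), flavourzyme_rule()], seed=1)[-1]
        residues = state.residue_amount()
        fracs = ultrafilter(state, leak_prob=0.3, seed=7)
        got = sum(
            amount * len(seq)
            for pool in fracs.values()
            for seq, amount in pool.items()
        )
        assert got == pytest.approx(residues, abs=1e-9)

    def test_short_peptides_contaminate_high_fractions(self):
        db = make_protein_db(10, 250, seed=2)
        hits = 0
        for seed in range(20):
            state = sequential_digest(
                db, [alcalase_rule(), flavourzyme_rule()], seed=seed
            )[-1]
            fracs = ultrafilter(state, leak_prob=0.3, seed=seed)
            low, high = fracs["<1kDa"], fracs["3-5kDa"]
            if not high:
                continue

            def awml(pool):
                return sum(a * len(s) for s, a in pool.items()) / sum(pool.values())

            has_short = any(len(s) <= 8 for s in high)
            if awml(high) > awml(low) and has_short:
                hits += 1
        assert hits >= 16  # 80% of seeds

    def test_rejects_unsorted_cutoffs(self):
        with pytest.raises(ValueError):
            ultrafilter(_toy_state({"GG": 1.0}), cutoffs_kda=[3, 1, 5])


class TestMSObserve:
    def test_dipeptides_never_observed(self):
        table = ms_observe({"GG": 10.0, "A": 5.0}, ObservationParams(rng_seed=0))
        assert len(table) == 0

    def test_lys_boost_exact_ratio(self):
        params = ObservationParams(noise_cv=0.0, rng_seed=0,
                                   length_detect_curve=lambda l: 1.0)
        table = ms_observe({"AAAA": 2.0, "AAAK": 2.0}, params)
        by_seq = {r.sequence: r.intensity["S1"] for r in table.records}
        assert by_seq["AAAK"] / by_seq["AAAA"] == pytest.approx(1.5)

    def test_determinism(self):
        pool = {"AAAA": 1.0, "GGGGG": 2.0, "KKKK": 3.0}
        params = ObservationParams(rng_seed=42)
        a = ms_observe(pool, params)
        b = ms_observe(pool, params)
        assert a.records == b.records

    def test_lys_abundance_bias(self):
        # observed intensity-weighted Lys abundance exceeds the pool's truth
        db = make_protein_db(10, 250, seed=5)
        hits = 0
        for seed in range(20):
            state = sequential_digest(
                db, [trypsin_rule(), flavourzyme_rule()], seed=seed
            )[-1]
            pool = {s: a for s, a in state.pool.items() if 3 <= len(s) <= 65}
            truth_n = sum(a * s.count("K") for s, a in pool.items())
            truth_d = sum(a * len(s) for s, a in pool.items())
            table = ms_observe(pool, ObservationParams(rng_seed=seed))
            if len(table) == 0:
                continue
            observed = aa_molar_abundance(table, "S1")["K"]
            hits += observed > truth_n / truth_d
        assert hits > 10


class TestSynthScores:
    def test_31mer_absent(self):
        t = synth_scores({"A" * 31, "AAA"}, seed=0)
        assert "A" * 31 not in t.scores
        assert "AAA" in t.scores

    def test_determinism(self):
        peps = {"AAA", "WWWF", "LLLLLLLL"}
        a = synth_scores(peps, seed=5)
        b = synth_scores(peps, seed=5)
        assert a.scores == b.scores

    def test_aromatic_short_beats_aliphatic_long(self, rng):
        aromatic_short = {
            "".join(rng.choice(list("FWYHL"), size=4)) for _ in range(300)
        }
        aliphatic_long = {
            "".join(rng.choice(list("AVLIG"), size=20)) for _ in range(300)
        }
        diffs = []
        for seed in range(20):
            sa = synth_scores(aromatic_short, seed=seed)
            sb = synth_scores(aliphatic_long, seed=seed)
            mean_a = np.mean([s.che for s in sa.scores.values()])
            mean_b = np.mean([s.che for s in sb.scores.values()])
            diffs.append(mean_a - mean_b)
        assert all(d > 0 for d in diffs)


class TestSynthIsotherm:
    def test_half_saturation_noiseless(self):
        iso = synth_isotherm(2.0, 100.0, concentrations=[0.5, 1.0, 2.0, 4.0, 8.0],
                             noise_cv=0.0, seed=0, duplicate_indices=())
        by_c = dict(iso.points)
        assert by_c[2.0] == pytest.approx(50.0)

    def test_default_design_has_ten_points(self):
        iso = synth_isotherm(1.0, 100.0, seed=0)
        assert len(iso.points) == 10
        conc = list(iso.concentrations)
        assert conc.count(0.25) == 2 and conc.count(2.0) == 2 and conc.count(10.0) == 2

    def test_round_trip_noiseless(self):
        iso = synth_isotherm(1.7, 80.0, noise_cv=0.0, seed=0)
        fit = fit_langmuir(iso)
        assert fit.kd == pytest.approx(1.7, rel=1e-6)
        assert fit.rmax == pytest.approx(80.0, rel=1e-6)


class TestSynthOPAPlate:
    def _curve(self):
        from hydroscreen.assay_calcs import fit_calibration

        conc = np.array([0.5 / 2**i for i in range(8)])
        return fit_calibration(conc, 1.2 * conc + 0.02)

    def test_round_trip(self):
        from hydroscreen.assay_calcs import dh_from_plate

        curve = self._curve()
        plate = synth_opa_plate(25.0, 0.2, curve, noise_cv=0.0, seed=0)
        dh, _ = dh_from_plate(plate, curve, {"S1": 0.2})["S1"]
        assert dh == pytest.approx(25.0, abs=1e-9)

    def test_df8_lowest_absorbance(self):
        plate = synth_opa_plate(38.8, 0.2, self._curve(), noise_cv=0.0, seed=0)
        by_df = {}
        for w in plate.wells:
            by_df.setdefault(w.dilution_factor, w.absorbance_340)
        assert by_df[8] == min(by_df.values())

    def test_determinism(self):
        curve = self._curve()
        a = synth_opa_plate(38.8, 0.2, curve, noise_cv=0.02, seed=9)
        b = synth_opa_plate(38.8, 0.2, curve, noise_cv=0.02, seed=9)
        assert a.wells == b.wells

    def test_rejects_bad_dh(self):
        with pytest.raises(ValueError):
            synth_opa_plate(0.0, 0.2, self._curve())
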