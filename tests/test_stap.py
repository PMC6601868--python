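"""Thermodynamic occupancy model: affinities, occupancy, concentration fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bindevol as bv
from bindevol.stap import (
    PWM,
    StapModel,
    StapTrainingSet,
    fit_gamma,
    occupancy,
    site_affinity,
    stap_score_table,
    read_pwm_file,
    write_pwm_file,
)

from conftest import random_sequences

_COMP = str.maketrans("ACGT", "TGCA")


def brute_force_occupancy(pwm: PWM, seq: str, gamma: float) -> float:
    """Independent oracle: enumerate every window on both strands."""
    L = len(pwm)
    total = 0.0
    for s in (seq, seq.translate(_COMP)[::-1]):
        for i in range(len(s) - L + 1):
            K = site_affinity(pwm, s[i : i + L])
            total += gamma * K / (1.0 + gamma * K)
    return total


def uniform_pwm(L):
    return PWM(name="u", probs=np.full((L, 4), 0.25), pseudocount=0.0)


class TestSiteAffinity:
    def test_uniform_pwm_gives_one(self):
        pwm = uniform_pwm(3)
        for w in ("AAA", "ACG", "TTT"):
            assert site_affinity(pwm, w) == pytest.approx(1.0)

    def test_point_mass_consensus(self):
        probs = np.zeros((2, 4))
        probs[0, 0] = 1.0  # A
        probs[1, 1] = 1.0  # C
        pwm = PWM(name="ac", probs=probs, pseudocount=0.0)
        assert site_affinity(pwm, "AC") == pytest.approx(16.0)
        assert site_affinity(pwm, "TT") == 0.0

    def test_matches_per_position_product(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(4), size=3)
        pwm = PWM(name="x", probs=probs, pseudocount=0.01)
        window = "GAT"
        p = (probs + 0.01) / (probs + 0.01).sum(axis=1, keepdims=True)
        expected = np.prod(
            [p[i, "ACGT".index(b)] / 0.25 for i, b in enumerate(window)]
        )
        assert site_affinity(pwm, window) == pytest.approx(expected, rel=1e-12)

    def test_ambiguity_base_contributes_background(self):
        pwm = bv.default_pwms()["Twi"]
        kn = site_affinity(pwm, "NNNNNNNN")
        assert kn == pytest.approx(1.0)

    def test_consensus_maximizes_affinity(self, twi_pwm):
        rng = np.random.default_rng(1)
        kmax = site_affinity(twi_pwm, twi_pwm.consensus())
        for s in random_sequences(rng, 20, len(twi_pwm)):
            assert site_affinity(twi_pwm, s) <= kmax + 1e-12

    def test_wrong_length_rejected(self, twi_pwm):
        with pytest.raises(ValueError):
            site_affinity(twi_pwm, "ACGT")


class TestOccupancy:
    def test_zero_concentration(self, twi_pwm):
        model = StapModel(pwm=twi_pwm, gamma=0.0)
        assert occupancy(model, "ACGTACGTACGT") == 0.0

    def test_uniform_pwm_analytic(self):
        # L=2 on a 5-mer: 4 windows x 2 strands, each q = 1/(1+1)
        model = StapModel(pwm=uniform_pwm(2), gamma=1.0)
        assert occupancy(model, "ACGTA") == pytest.approx(4.0)

    def test_matches_brute_force(self, twi_pwm):
        rng = np.random.default_rng(7)
        for seq in random_sequences(rng, 5, 50):
            model = StapModel(pwm=twi_pwm, gamma=0.37)
            assert occupancy(model, seq) == pytest.approx(
                brute_force_occupancy(twi_pwm, seq, 0.37), abs=1e-9
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_reverse_complement_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pwm = bv.default_pwms()["Bin"]
        seq = random_sequences(rng, 1, int(rng.integers(10, 80)))[0]
        model = StapModel(pwm=pwm, gamma=float(rng.uniform(0.01, 10)))
        rc = seq.translate(_COMP)[::-1]
        assert occupancy(model, seq) == pytest.approx(
            occupancy(model, rc), rel=1e-9
        )

    def test_bounded_and_monotone_in_gamma(self, twi_pwm):
        rng = np.random.default_rng(9)
        seq = random_sequences(rng, 1, 60)[0]
        bound = 2 * (60 - len(twi_pwm) + 1)
        prev = 0.0
        for g in (0.0, 0.01, 0.1, 1.0, 100.0, 1e6):
            occ = occupancy(StapModel(pwm=twi_pwm, gamma=g), seq)
            assert prev <= occ + 1e-12
            assert occ <= bound
            prev = occ

    def test_short_sequence_rejected(self, twi_pwm):
        with pytest.raises(ValueError):
            occupancy(StapModel(pwm=twi_pwm, gamma=1.0), "ACG")


class TestFitGamma:
    def _training_set(self, rng, pwm, gamma, n=200, noise=0.0):
        from bindevol.stap import _minmax, _occupancies, window_log_affinities

        seqs = random_sequences(rng, n, 150, pwm=pwm, max_sites=4)
        occ = _occupancies([window_log_affinities(pwm, s) for s in seqs], gamma)
        targets = _minmax(occ)
        if noise:
            targets = np.clip(targets + rng.normal(0, noise, n), 0, 1)
        return StapTrainingSet(sequences=seqs, targets=targets)

    def test_noiseless_recovery(self, twi_pwm):
        rng = np.random.default_rng(11)
        train = self._training_set(rng, twi_pwm, gamma=2.0)
        model = fit_gamma(train, twi_pwm)
        assert model.gamma == pytest.approx(2.0, rel=0.05)
        from bindevol.stap import predict_scores

        preds = predict_scores(model, train.sequences)
        r = bv.pearson_with_pvalue(preds, train.targets).r
        assert r >= 0.999

    def test_deterministic(self, twi_pwm):
        rng = np.random.default_rng(12)
        train = self._training_set(rng, twi_pwm, gamma=0.5, noise=0.05)
        g1 = fit_gamma(train, twi_pwm).gamma
        g2 = fit_gamma(train, twi_pwm).gamma
        assert g1 == g2

    def test_constant_targets_rejected(self, twi_pwm):
        train = StapTrainingSet(
            sequences=["ACGTACGTACGT"] * 5, targets=np.full(5, 0.5)
        )
        with pytest.raises(ValueError, match="uninformative"):
            fit_gamma(train, twi_pwm)


class TestCrossval:
    def test_leave_one_out_boundary(self, twi_pwm):
        rng = np.random.default_rng(13)
        seqs = random_sequences(rng, 12, 100, pwm=twi_pwm, max_sites=3)
        targets = np.linspace(0, 1, 12)
        r, gammas, preds = bv.crossval_stap(
            StapTrainingSet(sequences=seqs, targets=targets), twi_pwm, k=12
        )
        assert len(gammas) == 12
        assert preds.shape == (12,)

    def test_bad_fold_counts_rejected(self, twi_pwm):
        train = StapTrainingSet(
            sequences=["ACGTACGTAC"] * 4, targets=np.linspace(0, 1, 4)
        )
        with pytest.raises(ValueError):
            bv.crossval_stap(train, twi_pwm, k=1)
        with pytest.raises(ValueError):
            bv.crossval_stap(train, twi_pwm, k=5)


class TestScoreTable:
    def test_identical_species_zero_delta(self, twi_pwm):
        rng = np.random.default_rng(14)
        seqs = dict(zip("abcd", random_sequences(rng, 4, 100, twi_pwm, 3)))
        models = {"Twi:TP1": StapModel(pwm=twi_pwm, gamma=1.0)}
        t1 = stap_score_table(models, seqs, list("abcd"), "mel")
        t2 = stap_score_table(models, seqs, list("abcd"), "vir")
        from bindevol.scoring import delta_table

        assert (delta_table(t1, t2).values == 0).all()

    def test_destroyed_sites_lower_scores(self, twi_pwm):
        # every reference enhancer carries a planted site; the ortholog of
        # half of them has it scrambled -- only those show a positive dSTAP
        # after the per-species normalization
        rng = np.random.default_rng(15)
        n = 30
        cons = twi_pwm.consensus()
        base = random_sequences(rng, n, 120)
        scrambled = random_sequences(rng, n, len(cons))
        mel, vir = {}, {}
        affected = []
        for i, s in enumerate(base):
            eid = f"e{i}"
            mel[eid] = s[:20] + cons + s[20 + len(cons):]
            if i % 2 == 0:
                vir[eid] = s[:20] + scrambled[i] + s[20 + len(cons):]
                affected.append(True)
            else:
                vir[eid] = mel[eid]
                affected.append(False)
        models = {"Twi:TP1": StapModel(pwm=twi_pwm, gamma=1.0)}
        ids = list(mel)
        t_mel = stap_score_table(models, mel, ids, "mel")
        t_vir = stap_score_table(models, vir, ids, "vir")
        from bindevol.scoring import delta_table

        d = delta_table(t_mel, t_vir).values[:, 0]
        affected = np.array(affected)
        # every conserved ortholog ranks below every affected one
        assert d[affected].min() > d[~affected].max() - 0.05
        assert d[affected].mean() > d[~affected].mean() + 0.1
        assert (d[affected] >= 0).mean() >= 0.8

    def test_output_in_unit_interval(self, twi_pwm, small_cohort):
        models = {"Twi:TP1": StapModel(pwm=twi_pwm, gamma=0.2)}
        t = stap_score_table(
            models, small_cohort.sequences("mel"), small_cohort.ids, "mel"
        )
        assert t.normalized
        assert t.values.min() >= 0.0 and t.values.max() <= 1.0

    def test_missing_sequence_reported(self, twi_pwm):
        models = {"Twi:TP1": StapModel(pwm=twi_pwm, gamma=1.0)}
        with pytest.raises(ValueError, match="missing"):
            stap_score_table(models, {"a": "ACGTACGTAC"}, ["a", "zzz"], "mel")


class TestPwmIO:
    def test_roundtrip(self, tmp_path):
        pwms = bv.default_pwms()
        path = tmp_path / "p.txt"
        write_pwm_file(pwms, path)
        back = read_pwm_file(path)
        assert set(back) == set(pwms)
        for tf in pwms:
            assert back[tf].probs == pytest.approx(pwms[tf].probs, abs=0)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            PWM(name="bad", probs=np.array([[0.5, 0.5, 0.5, 0.5]]))
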