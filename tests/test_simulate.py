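"""Generative model of the synthetic orthologous-enhancer cohorts."""

import numpy as np
import pytest

import bindevol as bv
from bindevol.scoring import delta_table
from bindevol.simulate import (
    ACTIVITY_CLASSES,
    DEFAULT_CONDITIONS,
    condition_tf,
    condition_tp,
)


class TestConfigValidation:
    def test_motif_longer_than_sequence_rejected(self):
        cfg = bv.SimulationConfig(n_pairs=5, seq_length=4)
        with pytest.raises(ValueError, match="shorter than"):
            bv.generate_cohort(cfg)

    @pytest.mark.parametrize(
        "field, value",
        [
            ("substitution_rate", 1.5),
            ("accessibility_autocorr", -0.1),
            ("acc_divergence_sd", -1.0),
            ("n_pairs", -1),
        ],
    )
    def test_out_of_range_parameters_rejected(self, field, value):
        cfg = bv.SimulationConfig(**{field: value})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_default_condition_set(self):
        assert len(DEFAULT_CONDITIONS) == 14
        assert "Tin:TP1" not in DEFAULT_CONDITIONS  # unavailable condition
        by_tf = {}
        for c in DEFAULT_CONDITIONS:
            by_tf.setdefault(condition_tf(c), []).append(condition_tp(c))
        assert by_tf == {
            "Twi": [1, 2, 3],
            "Tin": [2, 3],
            "Mef2": [1, 2, 3, 4, 5],
            "Bap": [3],
            "Bin": [3, 4, 5],
        }


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = dict(n_pairs=30, seq_length=120)
        c1 = bv.generate_cohort(bv.SimulationConfig(seed=7, **cfg))
        c2 = bv.generate_cohort(bv.SimulationConfig(seed=7, **cfg))
        assert [p.seq_mel for p in c1.pairs] == [p.seq_mel for p in c2.pairs]
        assert c1.chip_mel.values == pytest.approx(c2.chip_mel.values, abs=0)
        assert c1.labels == c2.labels

    def test_different_seed_differs(self):
        cfg = dict(n_pairs=30, seq_length=120)
        c1 = bv.generate_cohort(bv.SimulationConfig(seed=7, **cfg))
        c2 = bv.generate_cohort(bv.SimulationConfig(seed=8, **cfg))
        assert [p.seq_mel for p in c1.pairs] != [p.seq_mel for p in c2.pairs]

    def test_subset_reproducible(self):
        # hierarchical per-enhancer streams: a smaller cohort is a prefix
        big = bv.generate_cohort(bv.SimulationConfig(n_pairs=20, seq_length=100, seed=3))
        small = bv.generate_cohort(bv.SimulationConfig(n_pairs=5, seq_length=100, seed=3))
        assert [p.seq_mel for p in big.pairs[:5]] == [p.seq_mel for p in small.pairs]


class TestGenerativeStructure:
    def test_identical_species_under_zero_divergence(self):
        cfg = bv.SimulationConfig(
            n_pairs=25,
            seq_length=150,
            substitution_rate=0.0,
            acc_divergence_sd=0.0,
            chip_noise_sd=0.0,
            seed=2,
        )
        c = bv.generate_cohort(cfg)
        assert all(p.seq_mel == p.seq_vir for p in c.pairs)
        assert c.truth.true_dchip.values == pytest.approx(
            np.zeros_like(c.truth.true_dchip.values), abs=1e-12
        )
        d = delta_table(c.chip_mel, c.chip_vir)
        assert d.values == pytest.approx(np.zeros_like(d.values), abs=1e-12)

    def test_tables_share_ids_and_ranges(self, small_cohort):
        c = small_cohort
        assert c.chip_mel.ids == c.chip_vir.ids == c.acc_mel.ids == c.acc_vir.ids
        assert len(set(c.ids)) == len(c.ids)
        for t in (c.chip_mel, c.chip_vir, c.acc_mel, c.acc_vir):
            assert t.normalized
            assert t.values.min() >= 0 and t.values.max() <= 1
        assert set(c.labels.values()) <= set(ACTIVITY_CLASSES)

    def test_dchip_antisymmetric_under_species_swap(self, small_cohort):
        c = small_cohort
        d1 = delta_table(c.chip_mel, c.chip_vir).values
        d2 = delta_table(c.chip_vir, c.chip_mel).values
        assert (d1 == -d2).all()

    def test_acc_divergence_drives_dchip(self):
        # accessibility-only generative channel: PCC(dAcc, dChIP) positive,
        # increasing with the signal-to-noise ratio (Monte-Carlo, 1000 pairs)
        rs = []
        for noise in (0.3, 0.1, 0.02):
            cfg = bv.SimulationConfig(
                n_pairs=1000,
                seq_length=60,
                site_density=0.0,
                chip_weights=(0.0, 1.0),
                chip_noise_sd=noise,
                seed=6,
            )
            c = bv.generate_cohort(cfg)
            dacc = delta_table(c.acc_mel, c.acc_vir).column("Acc:TP1")
            dchip = delta_table(c.chip_mel, c.chip_vir).column("Twi:TP1")
            rs.append(bv.pearson_with_pvalue(dacc, dchip).r)
        assert rs[0] > 0.2
        assert rs[0] < rs[1] < rs[2]

    def test_substitution_decorrelates_stap(self):
        from bindevol.stap import StapModel, stap_score_table

        pwm = bv.default_pwms()["Twi"]
        models = {"Twi:TP1": StapModel(pwm=pwm, gamma=0.2)}
        rs = {}
        for rate in (0.0, 0.5):
            cfg = bv.SimulationConfig(
                n_pairs=150, seq_length=200, substitution_rate=rate, seed=4
            )
            c = bv.generate_cohort(cfg)
            t_mel = stap_score_table(models, c.sequences("mel"), c.ids, "mel")
            t_vir = stap_score_table(models, c.sequences("vir"), c.ids, "vir")
            rs[rate] = bv.pearson_with_pvalue(
                t_mel.values[:, 0], t_vir.values[:, 0]
            ).r
        assert rs[0.0] == pytest.approx(1.0, abs=1e-9)
        assert rs[0.5] < 0.5  # decays toward the random-sequence baseline

    def test_labels_follow_activity_rule(self, small_cohort):
        c = small_cohort
        rule = c.config.activity_rule
        for eid, cls in c.labels.items():
            i = c.ids.index(eid)
            means = {
                k: np.mean([c.chip_mel.column(cond)[i] for cond in conds])
                for k, conds in rule.items()
            }
            assert max(means, key=means.get) == cls


class TestCohortIO:
    def test_roundtrip_equal_tables(self, tmp_path, small_cohort):
        bv.write_cohort(small_cohort, tmp_path)
        back = bv.read_cohort(tmp_path)
        assert back.ids == small_cohort.ids
        assert back.chip_mel.values == pytest.approx(
            small_cohort.chip_mel.values, abs=0
        )
        assert back.acc_vir.values == pytest.approx(
            small_cohort.acc_vir.values, abs=0
        )
        assert back.labels == small_cohort.labels
        assert all(
            a.seq_vir == b.seq_vir
            for a, b in zip(back.pairs, small_cohort.pairs)
        )

    def test_bedgraph_scores_match_raw_accessibility(self, tmp_path, small_cohort):
        from bindevol.scoring import mean_signal_over_interval, read_bedgraph

        bv.write_cohort(small_cohort, tmp_path)
        track = read_bedgraph(tmp_path / "accessibility_mel_TP3.bedGraph")
        expected = small_cohort.acc_raw_mel.column("Acc:TP3")
        got = [
            mean_signal_over_interval(track, p.interval_mel)
            for p in small_cohort.pairs
        ]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_cohort_valid_files(self, tmp_path):
        c = bv.generate_cohort(bv.SimulationConfig(n_pairs=0, seq_length=50))
        files = bv.write_cohort(c, tmp_path)
        assert files
        back = bv.read_cohort(tmp_path)
        assert back.ids == []
        assert back.chip_mel.columns == list(DEFAULT_CONDITIONS)

    def test_row_counts_match_cohort_size(self, tmp_path):
        n = 137
        c = bv.generate_cohort(bv.SimulationConfig(n_pairs=n, seq_length=80, seed=9))
        bv.write_cohort(c, tmp_path)
        back = bv.read_cohort(tmp_path)
        assert len(back.pairs) == n
        assert len(back.chip_vir.ids) == n
        with open(tmp_path / "enhancers_mel.bed") as fh:
            assert sum(1 for _ in fh) == n
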