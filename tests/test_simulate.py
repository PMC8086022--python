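"""Synthetic cohort generator: determinism, planted parameters, signals."""

import dataclasses

import numpy as np
import pytest

import sleeptopo as st
from sleeptopo.simulate import (GROUP_SEVERITY, GROUPS, HypnogramParams,
                                generate_hypnogram, generate_state_signal)


class TestDeterminism:
    def test_identical_seed_gives_identical_cohort(self):
        spec = st.CohortSpec(n_per_group=5)
        a = st.generate_cohort(spec, seed=3)
        b = st.generate_cohort(spec, seed=3)
        assert a.band_powers.equals(b.band_powers)
        assert all(a.hypnograms[s.id].stages == b.hypnograms[s.id].stages
                   for s in a.subjects)
        assert [s.mmse for s in a.subjects] == [s.mmse for s in b.subjects]

    def test_different_seeds_differ(self):
        spec = st.CohortSpec(n_per_group=5)
        a = st.generate_cohort(spec, seed=3)
        b = st.generate_cohort(spec, seed=4)
        assert not a.band_powers["log10_power"].equals(b.band_powers["log10_power"])


class TestZeroVarianceDegenerate:
    def test_band_powers_equal_group_targets(self):
        spec = st.CohortSpec(n_per_group=2).zero_variance()
        table = st.generate_cohort(spec, seed=0).band_powers
        for row in table.sample(300, random_state=1).itertuples():
            expected = spec.target_log10(row.group, row.state, row.channel, row.band)
            assert row.log10_power == pytest.approx(expected, abs=1e-12)

    def test_mmse_deterministic_in_group(self):
        spec = st.CohortSpec(n_per_group=3).zero_variance()
        subj = st.generate_cohort(spec, seed=0).subjects_frame()
        assert (subj.groupby("group")["mmse"].nunique() == 1).all()
        means = subj.groupby("group")["mmse"].first()
        assert means["AD"] < means["MCI"] < means["HC"]


class TestPlantedRecovery:
    def test_frontal_delta_contrast_recovered_within_3_sem(self):
        """Planted 0.3 log10 AD−HC REM frontal delta contrast, n=200/group."""
        spec = st.CohortSpec(n_per_group=200)
        table = st.generate_cohort(spec, seed=9).band_powers
        sub = table[(table["state"] == "REM") & (table["band"] == "delta")
                    & (table["channel"] == "F3")]
        ad = sub.loc[sub["group"] == "AD", "log10_power"]
        hc = sub.loc[sub["group"] == "HC", "log10_power"]
        diff = ad.mean() - hc.mean()
        sem = np.sqrt(ad.var(ddof=1) / len(ad) + hc.var(ddof=1) / len(hc))
        planted = (spec.target_log10("AD", "REM", "F3", "delta")
                   - spec.target_log10("HC", "REM", "F3", "delta"))
        assert abs(diff - planted) < 3 * sem

    def test_mmse_decreases_with_severity(self, cohort50):
        subj = cohort50.subjects_frame()
        sev = subj["group"].map(GROUP_SEVERITY)
        r = np.corrcoef(sev, subj["mmse"])[0, 1]
        assert r < -0.5


class TestHypnogramGeneration:
    PARAMS = HypnogramParams(
        p_onset=0.5 / 35.9,
        sleep_stage_probs={"N1": 0.10, "N2": 0.60, "N3": 0.10, "R": 0.20},
    )

    def test_absorbing_wake(self):
        p = dataclasses.replace(self.PARAMS, p_onset=0.0)
        h = generate_hypnogram(p, 30.0, 60.0, seed=0)
        assert set(h.stages) == {"W"}

    def test_fixed_seed_reproducible(self):
        a = generate_hypnogram(self.PARAMS, 30.0, 400.0, seed=5)
        b = generate_hypnogram(self.PARAMS, 30.0, 400.0, seed=5)
        assert a.stages == b.stages

    def test_starts_awake_with_valid_codes(self):
        h = generate_hypnogram(self.PARAMS, 30.0, 400.0, seed=1)
        assert h.stages[0] == "W"
        assert set(h.stages) <= {"W", "N1", "N2", "N3", "R"}

    def test_mean_sol_matches_planted_value(self):
        """Monte-Carlo: mean simulated SOL within 3 SEM of 35.9 min."""
        rng = np.random.default_rng(77)
        sols = []
        for _ in range(10_000):
            h = generate_hypnogram(self.PARAMS, 30.0, 480.0, seed=rng)
            m = st.score_macrostructure(h)
            if not np.isnan(m.sol_min):
                sols.append(m.sol_min)
        sols = np.asarray(sols)
        sem = sols.std(ddof=1) / np.sqrt(len(sols))
        assert abs(sols.mean() - 35.9) < 3 * sem

    def test_stage_shares_match_stationary_distribution(self):
        h = generate_hypnogram(self.PARAMS, 30.0, 60_000.0, seed=2)
        m = st.score_macrostructure(h)
        assert m.n3_pct == pytest.approx(10.0, abs=1.5)
        assert m.rem_pct == pytest.approx(20.0, abs=1.5)

    def test_invalid_stage_probs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            HypnogramParams(p_onset=0.1,
                            sleep_stage_probs={"N1": 0.5, "N2": 0.6})
        with pytest.raises(ValueError, match="invalid stages"):
            HypnogramParams(p_onset=0.1, sleep_stage_probs={"N9": 1.0})


class TestStateSignal:
    TARGETS = {ch: {"alpha": 20.0} for ch in st.MONTAGE_1020}

    def test_single_band_recovery_and_leakage(self):
        sig = generate_state_signal(self.TARGETS, 128.0, 300.0, seed=0)
        psd = st.welch_psd(sig)
        alpha = st.band_power(psd, (8, 12))
        other = st.band_power(psd, (16, 25))
        assert np.allclose(alpha, 20.0, rtol=0.05)
        assert np.all(other < 0.05 * 20.0)

    def test_variance_budget(self):
        targets = {ch: {"delta": 30.0, "alpha": 10.0, "beta": 4.0}
                   for ch in ("Cz", "Pz")}
        sig = generate_state_signal(targets, 128.0, 300.0, seed=1,
                                    channels=("Cz", "Pz"))
        assert np.allclose(sig.samples.var(axis=1), 44.0, rtol=0.05)

    def test_all_zero_targets_give_zero_signal(self):
        targets = {ch: {} for ch in ("Cz",)}
        sig = generate_state_signal(targets, 128.0, 10.0, seed=0, channels=("Cz",))
        assert np.all(sig.samples == 0.0)

    def test_doubling_targets_doubles_band_powers(self):
        t1 = {"Cz": {"delta": 8.0, "alpha": 5.0}}
        t2 = {"Cz": {"delta": 16.0, "alpha": 10.0}}
        s1 = generate_state_signal(t1, 128.0, 120.0, seed=4, channels=("Cz",))
        s2 = generate_state_signal(t2, 128.0, 120.0, seed=4, channels=("Cz",))
        p1 = st.band_power(st.welch_psd(s1), (0.5, 5))[0]
        p2 = st.band_power(st.welch_psd(s2), (0.5, 5))[0]
        assert p2 == pytest.approx(2.0 * p1, rel=1e-6)

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            generate_state_signal({"Cz": {"alpha": -1.0}}, 128.0, 10.0,
                                  seed=0, channels=("Cz",))


class TestSpecValidation:
    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="n_per_group"):
            st.CohortSpec(n_per_group=1)

    def test_fs_below_twice_band_edge(self):
        with pytest.raises(ValueError, match="fs"):
            st.CohortSpec(fs=40.0)

    def test_negative_sd_names_field(self):
        with pytest.raises(ValueError, match="subject_sd"):
            st.CohortSpec(subject_sd=-0.1)

    def test_missing_band_target_named(self):
        base = dict(st.simulate.DEFAULT_BASE_LOG10)
        del base[("REM", "sigma")]
        with pytest.raises(ValueError, match="REM.*sigma"):
            st.CohortSpec(base_log10=base)

    def test_unknown_effect_channel(self):
        eff = (st.PlantedEffect("REM", "delta", ("Zz",), 0.1),)
        with pytest.raises(ValueError, match="unknown channels"):
            st.CohortSpec(effects=eff)


def test_export_round_trip(tmp_path, small_cohort):
    small_cohort.to_disk(tmp_path / "c")
    assert (tmp_path / "c" / "subjects.tsv").exists()
    assert (tmp_path / "c" / "manifest.json").exists()
    table = st.read_bandpower_tsv(tmp_path / "c" / "bandpower.tsv")
    assert np.allclose(table["log10_power"],
                       small_cohort.band_powers["log10_power"])
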