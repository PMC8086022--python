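"""Correlation topographies and the Fisher-z severity trend."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import sleeptopo as st


class TestScalarCorrelations:
    def test_perfect_linear_relation(self, rng):
        x = rng.normal(size=30)
        r, p, n = st.pearson(x, 2.0 * x + 1.0)
        assert r == pytest.approx(1.0) and p < 1e-12 and n == 30

    def test_spearman_invariant_to_monotone_transform(self, rng):
        x = rng.uniform(0.1, 5.0, size=25)
        y = np.exp(x)  # monotone, nonlinear
        rho, _, _ = st.spearman(x, y)
        r, _, _ = st.pearson(x, y)
        assert rho == pytest.approx(1.0)
        assert abs(r) < 1.0

    def test_matches_scipy_oracles(self, rng):
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        y[::7] = y[::7] ** 0  # introduce ties for the rank path
        r, p, _ = st.pearson(x, y)
        r_sp, p_sp = sstats.pearsonr(x, y)
        assert r == pytest.approx(r_sp, rel=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-6)
        rho, prho, _ = st.spearman(x, y)
        rho_sp, prho_sp = sstats.spearmanr(x, y)
        assert rho == pytest.approx(rho_sp, rel=1e-12)

    def test_pairwise_complete_filtering(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, np.nan, 5.1]
        r, _, n = st.pearson(x, y)
        assert n == 3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            st.pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            st.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFisherZTrend:
    def test_constant_correlations_give_zero_trend(self):
        out = st.fisher_z_trend({"HC": [0.4], "MCI": [0.4], "AD": [0.4]})
        assert out["beta"].iloc[0] == pytest.approx(0.0)
        assert out["r_squared"].iloc[0] == 0.0  # 0/0 convention

    def test_atanh_identity_triple(self):
        """r = tanh(0), tanh(0.5), tanh(1) → slope 0.5 with perfect fit."""
        out = st.fisher_z_trend({"HC": [0.0], "MCI": [np.tanh(0.5)],
                                 "AD": [np.tanh(1.0)]})
        assert out["beta"].iloc[0] == pytest.approx(0.5, abs=1e-9)
        assert out["r_squared"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_polyfit_oracle(self, rng):
        r = rng.uniform(-0.9, 0.9, size=(12, 3))
        out = st.fisher_z_trend({"HC": r[:, 0], "MCI": r[:, 1], "AD": r[:, 2]})
        for i in range(12):
            z = np.arctanh(r[i])
            slope = np.polyfit([0, 1, 2], z, 1)[0]
            assert out["beta"].iloc[i] == pytest.approx(slope, rel=1e-9)

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError, match="Fisher z"):
            st.fisher_z_trend({"HC": [0.2], "MCI": [0.5], "AD": [1.0]})

    def test_beta_invariant_to_constant_z_shift(self):
        z = np.array([0.1, 0.4, 0.9])
        shifted = np.tanh(np.arctanh(np.tanh(z)) + 0.3)
        b0 = st.fisher_z_trend({"HC": [np.tanh(z[0])], "MCI": [np.tanh(z[1])],
                                "AD": [np.tanh(z[2])]})["beta"].iloc[0]
        b1 = st.fisher_z_trend({"HC": [shifted[0]], "MCI": [shifted[1]],
                                "AD": [shifted[2]]})["beta"].iloc[0]
        assert b1 == pytest.approx(b0, rel=1e-9)


def _wide(rng, n=40, channels=("Fz", "Cz", "Pz")):
    idx = [f"s{i}" for i in range(n)]
    return pd.DataFrame(rng.normal(size=(n, len(channels))), index=idx,
                        columns=channels)


class TestCorrelationMap:
    def test_seed_duplicated_gives_unit_correlation(self, rng):
        wide = _wide(rng)
        seed = wide["Cz"]
        maps = st.correlation_map(seed, {"self": wide[["Cz"]]})
        assert maps["self"].entries["r"].iloc[0] == pytest.approx(1.0)
        assert maps["self"].entries["significant"].all()

    def test_coupled_channels_detected_and_null_not(self, rng):
        wide = _wide(rng)
        seed = pd.Series(rng.normal(size=len(wide)), index=wide.index)
        wide["Fz"] = -0.9 * seed + 0.3 * rng.normal(size=len(wide))
        maps = st.correlation_map(seed, {"m": wide})
        e = maps["m"].entries.set_index("channel")
        assert e.loc["Fz", "significant"] and e.loc["Fz", "r"] < -0.8
        assert not e.loc["Pz", "significant"]

    def test_permuting_seed_destroys_significance(self, rng):
        wide = _wide(rng, n=60)
        seed = wide["Fz"] * 0.8 + 0.2 * rng.normal(size=60)
        hits = 0
        for i in range(30):
            perm = pd.Series(rng.permutation(seed.to_numpy()), index=seed.index)
            maps = st.correlation_map(perm, {"m": wide})
            hits += int(maps["m"].entries["significant"].any())
        assert hits <= 5  # ~q-level false-family rate under permutation

    def test_shared_family_threshold(self, rng):
        wide = _wide(rng)
        seed = pd.Series(rng.normal(size=len(wide)), index=wide.index)
        maps = st.correlation_map(seed, {"a": wide, "b": wide * 2.0})
        assert maps["a"].fdr_threshold == maps["b"].fdr_threshold
        assert maps["a"].family_size == 6


class TestMMSECorrelates:
    def test_constructed_identity(self, rng):
        wide = _wide(rng, n=30)
        mmse = 30.0 - 2.0 * wide["Pz"]
        maps, _ = st.mmse_correlates(mmse, {"feat": wide})
        e = maps["feat"].entries.set_index("channel")
        assert e.loc["Pz", "r"] == pytest.approx(-1.0)

    def test_constant_mmse_rejected(self, rng):
        wide = _wide(rng)
        mmse = pd.Series(28.0, index=wide.index)
        with pytest.raises(ValueError, match="zero variance"):
            st.mmse_correlates(mmse, {"feat": wide})

    def test_independent_mmse_rarely_significant(self, rng):
        """Null calibration: no coupling → few FDR-significant families."""
        hits = 0
        for i in range(40):
            wide = _wide(rng, n=30)
            mmse = pd.Series(rng.integers(20, 31, size=30).astype(float),
                             index=wide.index)
            maps, _ = st.mmse_correlates(mmse, {"feat": wide})
            hits += int(maps["feat"].entries["significant"].any())
        assert hits <= 6

    def test_macro_scalars_use_spearman(self, rng):
        wide = _wide(rng, n=30)
        mmse = pd.Series(rng.normal(25, 3, size=30), index=wide.index)
        sol = pd.Series(np.exp(-mmse / 5.0), index=wide.index)  # monotone in MMSE
        _, scalars = st.mmse_correlates(mmse, {"feat": wide}, {"sol_min": sol})
        row = scalars.set_index("variable").loc["sol_min"]
        assert row["rho"] == pytest.approx(-1.0)

    def test_planted_coupling_ordering(self, cohort50, table50):
        """REM slowing couples to MMSE more strongly than wake slowing."""
        from sleeptopo.slowing import slowing_map
        mmse = cohort50.subjects_frame().set_index("id")["mmse"].astype(float)
        mmse.index.name = "subject"
        feats = {}
        for state in ("REM", "PM_WAKE"):
            tidy = slowing_map(table50, state)
            feats[state] = np.log10(tidy.pivot(index="subject",
                                               columns="channel",
                                               values="slowing_index"))
        maps, _ = st.mmse_correlates(mmse, feats)
        mean_r = {s: maps[s].entries["r"].mean() for s in feats}
        assert mean_r["REM"] < mean_r["PM_WAKE"] < 0
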