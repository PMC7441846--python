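"""Weighted partial correlations, replication panels, critical r."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statetraits as st
from statetraits.replication import SingularControlsError


def _residualization_oracle(y, x, controls, w):
    """Correlate residuals from weighted least-squares fits on the controls."""
    n = len(y)
    W = np.diag(w / w.sum())
    X = np.column_stack([np.ones(n)] + list(controls))

    def resid(v):
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ v)
        return v - X @ beta

    return st.weighted_pearson(resid(np.asarray(x, float)), resid(np.asarray(y, float)), w)


class TestWeightedPartialCorrelation:
    def test_no_controls_reduces_to_weighted_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=15), rng.normal(size=15)
        w = rng.uniform(1, 3, size=15)
        assert st.weighted_partial_correlation(y, x, controls=None, w=w) == pytest.approx(
            st.weighted_pearson(x, y, w), abs=1e-12
        )

    def test_exactly_explained_outcome_is_orthogonal(self):
        rng = np.random.default_rng(1)
        x, c = rng.normal(size=12), rng.normal(size=12)
        w = rng.uniform(1, 2, size=12)
        with pytest.warns(UserWarning, match="exactly explained"):
            r = st.weighted_partial_correlation(3.0 * c - 1.0, x, controls=[c], w=w)
        assert abs(r) < 1e-10

    def test_matches_residualization_oracle(self):
        """Six-unit worked case against the independent residualization route."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            c1, c2 = rng.normal(size=6), rng.normal(size=6)
            x = 0.5 * c1 + rng.normal(size=6)
            y = -0.3 * c1 + 0.4 * x + rng.normal(size=6)
            w = rng.uniform(0.5, 5.0, size=6)
            mine = st.weighted_partial_correlation(y, x, controls=[c1, c2], w=w)
            oracle = _residualization_oracle(y, x, [c1, c2], w)
            assert mine == pytest.approx(oracle, abs=1e-10)

    def test_equal_weights_match_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        for _ in range(10):
            df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("yxab"))
            mine = st.weighted_partial_correlation(
                df["y"], df["x"], controls=df[["a", "b"]], w=pd.Series(1.0, index=df.index)
            )
            oracle = pg.partial_corr(df, x="x", y="y", covar=["a", "b"])["r"].iloc[0]
            assert mine == pytest.approx(oracle, abs=1e-8)

    def test_collinear_controls_named_in_error(self):
        rng = np.random.default_rng(4)
        c = rng.normal(size=10)
        x, y = rng.normal(size=10), rng.normal(size=10)
        controls = pd.DataFrame({"alpha": c, "beta": 2 * c})
        with pytest.raises(SingularControlsError, match="alpha"):
            st.weighted_partial_correlation(y, x, controls=controls, w=np.ones(10))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            st.weighted_partial_correlation(
                [1.0, 2.0, 3.0], [2.0, 1.0, 3.0], controls=[[1.0, 2.0, 4.0]], w=np.ones(3)
            )


class TestBuildPanel:
    @staticmethod
    def _fixture(n_samples=7, n_vars=13, seed=0):
        rng = np.random.default_rng(seed)
        units = [f"U{i}" for i in range(20)]
        traits = [f"T{j}" for j in range(5)]
        tables = {
            f"S{s}": pd.DataFrame(
                rng.normal(size=(20, 5)), index=pd.Index(units, name="unit"), columns=traits
            )
            for s in range(n_samples)
        }
        sociodemo = pd.DataFrame(
            rng.normal(size=(20, n_vars)),
            index=pd.Index(units, name="unit"),
            columns=[f"v{k}" for k in range(n_vars)],
        )
        w = pd.Series(rng.uniform(1, 6, size=20), index=units)
        return tables, sociodemo, w

    def test_cell_count(self):
        tables, sociodemo, w = self._fixture()
        panel = st.build_panel(tables, sociodemo, w)
        assert len(panel) == 7 * 5 * 13

    def test_unpartialled_cells_equal_weighted_pearson(self):
        tables, sociodemo, w = self._fixture(n_samples=2, n_vars=3)
        panel = st.build_panel(tables, sociodemo, w, partialled=False)
        row = panel.iloc[0]
        expected = st.weighted_pearson(
            tables[row["sample"]][row["trait"]], sociodemo[row["variable"]], w
        )
        assert row["r"] == pytest.approx(expected, abs=1e-12)

    def test_panel_recovers_generator_targets(self, twin_inventory_study):
        """A sociodemographic variable built to correlate 0.5 with one trait's
        unit means (and 0 with the rest) shows up in the panel at about
        0.5 * sqrt(ICC2) — the state-score estimate attenuates the latent
        correlation by its own reliability."""
        cfg, bank, responses, truth, census = twin_inventory_study
        cfg2 = cfg.with_seed(cfg.seed)
        spec = st.SociodemoSpec("target_var", {"Conscientiousness": 0.5}, noise_sd=0.4)
        import dataclasses

        cfg2 = dataclasses.replace(cfg2, sociodemo_specs=(spec,))
        sociodemo = st.generate_sociodemographics(cfg2, truth)
        realized = sociodemo.attrs["realized_r"].loc["Conscientiousness", "target_var"]

        scores = st.score_scales(responses, bank, "A")
        table = st.aggregate_states(scores)
        icc2 = st.icc_table(scores).loc["Conscientiousness", "icc2"]
        panel = st.build_panel(
            {"S": table}, sociodemo, census.populations, partialled=True
        )
        got = panel.loc[
            (panel.trait == "Conscientiousness") & (panel.variable == "target_var"), "r"
        ].iloc[0]
        # compare to the realized latent correlation attenuated by sqrt(ICC2);
        # +/- 0.25 is ~2.5 standard errors of a single 51-unit correlation
        assert got == pytest.approx(realized * np.sqrt(icc2), abs=0.25)


class TestReplicationCorrelation:
    @staticmethod
    def _panel(cells, partialled=True):
        rows = [
            {"sample": s, "trait": t, "variable": v, "r": r, "partialled": partialled}
            for (s, t, v), r in cells.items()
        ]
        return pd.DataFrame(rows)

    def test_identical_panels_replicate_perfectly(self):
        rng = np.random.default_rng(5)
        cells = {("S0", "T", f"v{k}"): rng.uniform(-0.5, 0.5) for k in range(6)}
        old = self._panel(cells)
        new = self._panel({("N0", t, v): r for (_, t, v), r in cells.items()})
        r, n = st.replication_correlation(old, new, "T")
        assert r == pytest.approx(1.0)
        assert n == 6

    def test_negated_panel_replicates_at_minus_one(self):
        rng = np.random.default_rng(6)
        cells = {("S0", "T", f"v{k}"): rng.uniform(-0.5, 0.5) for k in range(6)}
        old = self._panel(cells)
        new = self._panel({("N0", t, v): -r for (_, t, v), r in cells.items()})
        r, _ = st.replication_correlation(old, new, "T")
        assert r == pytest.approx(-1.0)

    def test_toy_panel_matches_listed_pairs(self):
        """2 old samples x 1 new sample x 3 variables: Pearson over the six
        explicitly listed pairs."""
        old = self._panel(
            {
                ("S0", "T", "v0"): 0.10, ("S0", "T", "v1"): 0.40, ("S0", "T", "v2"): -0.20,
                ("S1", "T", "v0"): 0.05, ("S1", "T", "v1"): 0.50, ("S1", "T", "v2"): -0.10,
            }
        )
        new = self._panel(
            {("N0", "T", "v0"): 0.20, ("N0", "T", "v1"): 0.30, ("N0", "T", "v2"): -0.25}
        )
        olds = [0.10, 0.40, -0.20, 0.05, 0.50, -0.10]
        news = [0.20, 0.30, -0.25, 0.20, 0.30, -0.25]
        expected = stats.pearsonr(olds, news).statistic
        r, n = st.replication_correlation(old, new, "T")
        assert n == 6
        assert r == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(7)
        cells = {
            (s, "T", f"v{k}"): rng.uniform(-0.6, 0.6)
            for s in ("S0", "S1") for k in range(5)
        }
        new_cells = {("N0", "T", f"v{k}"): rng.uniform(-0.6, 0.6) for k in range(5)}
        old, new = self._panel(cells), self._panel(new_cells)
        r1, _ = st.replication_correlation(old, new, "T")
        r2, _ = st.replication_correlation(
            old.sample(frac=1, random_state=1), new.sample(frac=1, random_state=2), "T"
        )
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_shared_signal_attenuated_by_noise(self):
        """Old and new cells share a common per-variable signal plus
        independent noise: the replication correlation concentrates near
        var(signal) / (var(signal) + var(noise))."""
        rng = np.random.default_rng(8)
        sig_sd, noise_sd = 0.2, 0.1
        theo = sig_sd**2 / (sig_sd**2 + noise_sd**2)
        rs = []
        for _ in range(200):
            signal = rng.normal(0, sig_sd, size=13)
            old = self._panel(
                {
                    (f"S{s}", "T", f"v{k}"): signal[k] + rng.normal(0, noise_sd)
                    for s in range(5) for k in range(13)
                }
            )
            new = self._panel(
                {
                    (f"N{s}", "T", f"v{k}"): signal[k] + rng.normal(0, noise_sd)
                    for s in range(2) for k in range(13)
                }
            )
            rs.append(st.replication_correlation(old, new, "T")[0])
        assert np.mean(rs) == pytest.approx(theo, abs=0.05)

    def test_too_few_pairs_rejected(self):
        old = self._panel({("S0", "T", "v0"): 0.1, ("S0", "T", "v1"): 0.3})
        new = self._panel({("N0", "T", "v0"): 0.2})
        with pytest.raises(ValueError):
            st.replication_correlation(old, new, "T")


class TestCorrelationRange:
    def test_constant_cells_have_zero_range(self):
        panel = TestReplicationCorrelation._panel(
            {("S0", "T", f"v{k}"): 0.25 for k in range(4)}
        )
        assert st.correlation_range(panel, "T") == pytest.approx(0.0)

    def test_arithmetic(self):
        panel = TestReplicationCorrelation._panel(
            {("S0", "T", "v0"): -0.5, ("S0", "T", "v1"): 0.6}
        )
        assert st.correlation_range(panel, "T") == pytest.approx(1.1)

    def test_matches_brute_force_scan_over_pooled_panels(self):
        rng = np.random.default_rng(9)
        old = TestReplicationCorrelation._panel(
            {("S0", "T", f"v{k}"): rng.uniform(-1, 1) for k in range(8)}
        )
        new = TestReplicationCorrelation._panel(
            {("N0", "T", f"v{k}"): rng.uniform(-1, 1) for k in range(8)}
        )
        vals = list(old["r"]) + list(new["r"])
        assert st.correlation_range(old, "T", new) == pytest.approx(
            max(vals) - min(vals), abs=1e-12
        )


class TestCriticalR:
    def test_three_observations_match_t_quantile_oracle(self):
        t = stats.t.ppf(0.975, df=1)
        expected = t / np.sqrt(t**2 + 1)
        assert st.critical_r(3, 0.05) == pytest.approx(expected, abs=1e-12)

    def test_threshold_decreases_with_n(self):
        vals = [st.critical_r(n) for n in (5, 10, 48, 100, 1000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.critical_r(2)
        with pytest.raises(ValueError):
            st.critical_r(48, alpha=1.5)


class TestReplicationSummary:
    def test_summary_aggregates_per_trait(self):
        rng = np.random.default_rng(10)
        old = TestReplicationCorrelation._panel(
            {
                (f"S{s}", t, f"v{k}"): rng.uniform(-0.6, 0.6)
                for s in range(3) for t in ("T1", "T2") for k in range(5)
            }
        )
        new = TestReplicationCorrelation._panel(
            {
                (f"N{s}", t, f"v{k}"): rng.uniform(-0.6, 0.6)
                for s in range(2) for t in ("T1", "T2") for k in range(5)
            }
        )
        out = st.replication_summary(old, new)
        assert list(out.index) == ["T1", "T2"]
        assert (out["n_pairs"] == 3 * 2 * 5).all()
        assert (out["correlation_range"] > 0).all()
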