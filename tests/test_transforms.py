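import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from simulelast import (
    PanelDataset,
    FixedEffectsStructure,
    balance_panel,
    log_transform,
    make_lags,
    within_transform,
)
from simulelast.panel import PanelError
from conftest import random_panel


def _panel_from(records):
    return PanelDataset(pd.DataFrame(records))


class TestLogTransform:
    def test_exact_values_and_missing_propagation(self):
        data = _panel_from([
            {"entity": "A", "period": 1995, "v": np.e},
            {"entity": "A", "period": 1996, "v": 1.0},
            {"entity": "B", "period": 1995, "v": np.nan},
            {"entity": "B", "period": 1996, "v": np.e**2},
        ])
        out = log_transform(data, ["v"])
        v = out.frame.set_index(["entity", "period"])["v"]
        assert v[("A", 1995)] == 1.0
        assert v[("A", 1996)] == 0.0
        assert np.isnan(v[("B", 1995)])
        assert np.isclose(v[("B", 1996)], 2.0)
        assert "log" in out.metadata["v"]

    def test_nonpositive_value_errors_with_cell(self):
        data = _panel_from([
            {"entity": "A", "period": 1995, "v": 1.0},
            {"entity": "A", "period": 1996, "v": 0.0},
            {"entity": "B", "period": 1995, "v": 2.0},
        ])
        with pytest.raises(PanelError, match=r"\('A', 1996\)"):
            log_transform(data, ["v"])

    def test_lognormal_sample_mean_matches_mu(self):
        rng = np.random.default_rng(7)
        n = 4000
        frame = pd.DataFrame({
            "entity": np.repeat([f"E{i}" for i in range(n // 4)], 4),
            "period": np.tile(range(1995, 1999), n // 4),
            "v": rng.lognormal(mean=1.3, sigma=0.5, size=n),
        })
        out = log_transform(PanelDataset(frame), ["v"])
        assert abs(out.frame["v"].mean() - 1.3) < 4 * 0.5 / np.sqrt(n)


class TestWithinTransform:
    def test_balanced_2x2_closed_form(self):
        data = _panel_from([
            {"entity": e, "period": p, "v": v}
            for (e, p, v) in [("A", 1, 1.0), ("A", 2, 4.0), ("B", 1, 2.0), ("B", 2, 9.0)]
        ])
        out = within_transform(data, ["v"])
        f = data.frame
        expected = (
            f["v"]
            - f.groupby("entity")["v"].transform("mean")
            - f.groupby("period")["v"].transform("mean")
            + f["v"].mean()
        )
        assert np.allclose(out.frame["v"], expected, atol=1e-12)

    def test_entity_constant_column_zeroed(self):
        data = _panel_from([
            {"entity": e, "period": p, "v": {"A": 3.0, "B": -1.0}[e]}
            for e in "AB" for p in (1, 2, 3)
        ])
        out = within_transform(data, ["v"], FixedEffectsStructure(True, False))
        assert np.allclose(out.frame["v"], 0.0, atol=1e-12)

    def test_unbalanced_matches_dummy_regression_oracle(self):
        # two-way demeaning == residual from regressing on entity+period dummies
        data = random_panel(seed=3, n_ent=10, n_per=8, missing=0.2, columns=("v",))
        out = within_transform(data, ["v"])
        frame = data.frame.copy()
        fit = smf.ols("v ~ C(entity) + C(period)", data=frame).fit()
        assert np.max(np.abs(out.frame["v"].to_numpy() - fit.resid.to_numpy())) < 1e-8

    def test_idempotent_and_linear(self):
        data = random_panel(seed=9, n_ent=8, n_per=6, missing=0.25, columns=("u", "v"))
        once = within_transform(data, ["u", "v"])
        twice = within_transform(once, ["u", "v"])
        assert np.allclose(once.frame[["u", "v"]], twice.frame[["u", "v"]], atol=1e-8)
        combo = data.frame.copy()
        combo["w"] = 2.0 * combo["u"] - 3.0 * combo["v"]
        t_combo = within_transform(data.with_frame(combo), ["w"]).frame["w"]
        lin = 2.0 * once.frame["u"] - 3.0 * once.frame["v"]
        assert np.allclose(t_combo, lin, atol=1e-8)

    def test_group_means_below_tolerance(self):
        data = random_panel(seed=21, n_ent=9, n_per=7, missing=0.3, columns=("v",))
        out = within_transform(data, ["v"])
        g = out.frame.groupby("entity")["v"].mean()
        h = out.frame.groupby("period")["v"].mean()
        assert np.abs(g).max() < 1e-8 and np.abs(h).max() < 1e-8


class TestLags:
    def test_basic_shift_and_overlong_order(self):
        data = _panel_from([
            {"entity": "A", "period": 1995 + t, "v": float(t + 1)} for t in range(3)
        ] + [{"entity": "B", "period": 1995, "v": 9.0}, {"entity": "B", "period": 1996, "v": 8.0}])
        out = make_lags(data, "v", [1, 3])
        a = out.frame[out.frame.entity == "A"]
        assert np.array_equal(a["v_lag1"].to_numpy(), [np.nan, 1.0, 2.0], equal_nan=True)
        assert a["v_lag3"].isna().all()  # order exceeds span: all missing, no error

    def test_gap_year_breaks_chain(self):
        data = _panel_from([
            {"entity": "A", "period": p, "v": float(p)} for p in (1995, 1996, 1998)
        ] + [{"entity": "B", "period": 1995, "v": 0.0}, {"entity": "B", "period": 1996, "v": 1.0}])
        out = make_lags(data, "v", [1])
        a = out.frame[out.frame.entity == "A"].set_index("period")["v_lag1"]
        assert np.isnan(a[1998])  # 1997 missing -> no lag-1 for 1998
        assert a[1996] == 1995.0

    def test_lag_recovers_ar_coefficient(self):
        rho = 0.6
        rng = np.random.default_rng(12)
        rows = []
        for i in range(40):
            v = 0.0
            for t in range(30):
                v = rho * v + rng.standard_normal()
                rows.append({"entity": f"E{i}", "period": 1900 + t, "v": v})
        data = make_lags(_panel_from(rows), "v", [1])
        f = data.frame.dropna()
        slope = np.polyfit(f["v_lag1"], f["v"], 1)[0]
        assert abs(slope - rho) < 0.05


class TestBalancePanel:
    def test_drops_entity_with_hole(self):
        rows = [
            {"entity": e, "period": p, "v": 1.0}
            for e in ("A", "B", "C") for p in (1995, 1996, 1997)
        ]
        rows = [r for r in rows if not (r["entity"] == "B" and r["period"] == 1996)]
        out = balance_panel(_panel_from(rows), 1995, 1997)
        assert set(out.frame.entity) == {"A", "C"}

    def test_identity_on_balanced(self):
        data = random_panel(seed=2, n_ent=5, n_per=4)
        out = balance_panel(data, 2000, 2003)
        pd.testing.assert_frame_equal(out.frame, data.frame)

    def test_matches_set_comprehension_oracle(self):
        data = random_panel(seed=30, n_ent=12, n_per=6, missing=0.3, columns=("v",))
        first, last = 2000, 2005
        out = balance_panel(data, first, last, columns=["v"])
        f = data.frame.dropna(subset=["v"])
        oracle = {
            e for e in f.entity.unique()
            if set(f.loc[f.entity == e, "period"]) >= set(range(first, last + 1))
        }
        assert set(out.frame.entity) == oracle

    def test_empty_result_errors(self):
        data = random_panel(seed=4, n_ent=4, n_per=3)
        with pytest.raises(PanelError):
            balance_panel(data, 1800, 1900)
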