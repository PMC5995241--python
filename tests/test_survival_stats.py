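"""KM closed forms, log-rank vs hand oracle, Cox vs brute-force likelihood."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from mibc_subtyper.io_formats import ClinicalTable
from mibc_subtyper.survival_stats import (
    build_design,
    cox_fit,
    km_estimate,
    logrank_test,
    stratify_luminal,
)


def _clinical_frame(times, events, **columns):
    """Minimal valid ClinicalTable around given survival data."""
    n = len(times)
    base = {
        "sample_id": [f"P{i}" for i in range(n)],
        "age": pd.array(np.full(n, 65.0), dtype="Float64"),
        "sex": ["M"] * n,
        "stage": ["pT3"] * n,
        "node": ["N0"] * n,
        "metastasis": ["M0"] * n,
        "nac": pd.array([False] * n, dtype="boolean"),
        "ac": pd.array([False] * n, dtype="boolean"),
        "os_time": pd.array(times, dtype="Float64"),
        "os_event": pd.array(events, dtype="boolean"),
        "dss_time": pd.array(times, dtype="Float64"),
        "dss_event": pd.array(events, dtype="boolean"),
    }
    base.update(columns)
    return ClinicalTable(data=pd.DataFrame(base))


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        curve = km_estimate([1, 2, 3], [True, True, True])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_hand_product_limit_with_censoring(self):
        # times 1 (event), 2 (censored), 3 (event)
        curve = km_estimate([1, 2, 3], [True, False, True])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2) == pytest.approx(2 / 3)  # censoring: no drop
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_step_lookup_at_96_months(self):
        curve = km_estimate([10, 50, 100], [True, True, True])
        assert curve.survival_at(96.0) == pytest.approx(1 / 3)
        assert curve.survival_at(5.0) == 1.0  # before the first event

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(30, size=40).round(2)
        curve = km_estimate(times, np.ones(40, dtype=bool))
        for t in (5, 20, 60):
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])


def _hand_logrank_two_groups(t1, e1, t2, e2):
    """Independent O-E tabulation over the pooled event times."""
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    groups = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 0)).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        group = ([1.0, 2.0, 3.0], [True, True, False])
        chi2, df, p = logrank_test([group, group])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_matches_hand_o_minus_e_oracle(self):
        t1, e1 = np.array([1.0, 2.0]), np.array([True, True])
        t2, e2 = np.array([3.0, 4.0]), np.array([True, True])
        chi2, df, _ = logrank_test([(t1, e1), (t2, e2)])
        assert df == 1
        assert chi2 == pytest.approx(_hand_logrank_two_groups(t1, e1, t2, e2),
                                     rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            logrank_test([([1.0], [True]), ([], [])])

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(200):
            t = rng.exponential(40, size=100)
            e = rng.random(100) < 0.7
            g = rng.integers(0, 2, size=100)
            ps.append(logrank_test([(t[g == 0], e[g == 0]),
                                    (t[g == 1], e[g == 1])])[2])
        assert kstest(ps, "uniform").pvalue > 0.01


def _brute_force_cox_beta(times, events, x):
    """Grid-search maximizer of the (no-ties) Cox partial likelihood."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    betas = np.arange(-3, 3, 1e-4)

    def neg_log_pl(beta):
        ll = 0.0
        for i in range(len(times)):
            if not events[i]:
                continue
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    values = np.array([neg_log_pl(b) for b in betas])
    return betas[values.argmin()]


class TestCox:
    def test_matches_brute_force_partial_likelihood(self):
        times = np.array([2.0, 5.0, 7.0, 11.0, 13.0, 17.0])
        events = np.array([True, True, False, True, True, False])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        clinical = _clinical_frame(times, events)
        luminal = pd.Series(x, index=[f"P{i}" for i in range(6)])
        result = cox_fit(clinical, ["luminal"], endpoint="DSS",
                         luminal=luminal)
        beta_hat = float(result.summary.loc["luminal", "coef"])
        beta_grid = _brute_force_cox_beta(times, events, x)
        assert beta_hat == pytest.approx(beta_grid, abs=1e-4)

    def test_recovers_hazard_ratio_two(self):
        rng = np.random.default_rng(42)
        hrs = []
        for _ in range(20):
            n = 1000
            x = rng.integers(0, 2, size=n).astype(float)
            times = rng.exponential(1.0 / (0.01 * 2.0**x))
            censor = rng.uniform(50, 300, size=n)
            observed = np.minimum(times, censor)
            events = times <= censor
            clinical = _clinical_frame(observed, events)
            luminal = pd.Series(x, index=[f"P{i}" for i in range(n)])
            result = cox_fit(clinical, ["luminal"], luminal=luminal)
            hrs.append(result.hazard_ratio("luminal"))
        assert 1.8 <= np.median(hrs) <= 2.2

    def test_constant_covariate_rejected(self):
        clinical = _clinical_frame([1.0, 2.0, 3.0], [True, True, True])
        luminal = pd.Series([1, 1, 1], index=["P0", "P1", "P2"])
        with pytest.raises(ValueError, match="constant"):
            cox_fit(clinical, ["luminal"], luminal=luminal)

    def test_zero_events_rejected(self):
        clinical = _clinical_frame([1.0, 2.0, 3.0], [False, False, False])
        luminal = pd.Series([1, 0, 1], index=["P0", "P1", "P2"])
        with pytest.raises(ValueError, match="zero events"):
            cox_fit(clinical, ["luminal"], luminal=luminal)

    def test_ci_brackets_hazard_ratio(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.integers(0, 2, size=n).astype(float)
        times = rng.exponential(1.0 / (0.01 * 3.0**x))
        clinical = _clinical_frame(times, np.ones(n, dtype=bool))
        luminal = pd.Series(x, index=[f"P{i}" for i in range(n)])
        result = cox_fit(clinical, ["luminal"], luminal=luminal)
        row = result.summary.loc["luminal"]
        assert row["ci_lower"] <= row["hr"] <= row["ci_upper"]


class TestForwardSelection:
    def _simulate(self, rng, n=500, hr=3.0):
        x = rng.integers(0, 2, size=n).astype(float)
        sex = rng.choice(["F", "M"], size=n)
        ac = rng.random(n) < 0.3
        metastasis = rng.choice(["M0", "M+"], size=n)
        times = rng.exponential(1.0 / (0.01 * hr**x))
        censor = rng.uniform(50, 200, size=n)
        observed = np.minimum(times, censor)
        events = times <= censor
        clinical = _clinical_frame(
            observed, events,
            sex=sex, metastasis=metastasis,
            ac=pd.array(ac, dtype="boolean"),
        )
        luminal = pd.Series(x, index=[f"P{i}" for i in range(n)])
        return clinical, luminal

    def test_true_covariate_enters_first(self):
        rng = np.random.default_rng(7)
        first = []
        for _ in range(50):
            clinical, luminal = self._simulate(rng)
            result = cox_fit(clinical, ["luminal", "sex", "metastasis", "ac"],
                             selection="forward", luminal=luminal)
            first.append(result.selection_trace[0]["covariate"])
        assert np.mean([f == "luminal" for f in first]) >= 0.9

    def test_pure_noise_covariates_rarely_enter(self):
        # 3 noise candidates at entry p<0.05: a covariate should enter in
        # roughly 1 - 0.95^3 ~ 14% of datasets, far below half of them
        rng = np.random.default_rng(8)
        entered = 0
        for _ in range(15):
            clinical, luminal = self._simulate(rng, hr=1.0, n=300)
            try:
                cox_fit(clinical, ["sex", "metastasis", "ac"],
                        selection="forward", luminal=luminal)
                entered += 1
            except ValueError as exc:
                assert "no covariate" in str(exc)
        assert entered <= 7


class TestLogrankCoxEquivalence:
    def test_p_values_agree_under_the_null_and_alternative(self):
        # two-group comparisons: log-rank p vs Cox Wald p track each other
        rng = np.random.default_rng(10)
        diffs = []
        for _ in range(60):
            n = 150
            x = rng.integers(0, 2, size=n).astype(float)
            times = rng.exponential(1.0 / (0.01 * 1.5**x))
            events = np.ones(n, dtype=bool)
            p_lr = logrank_test([(times[x == 0], events[x == 0]),
                                 (times[x == 1], events[x == 1])])[2]
            clinical = _clinical_frame(times, events)
            luminal = pd.Series(x, index=[f"P{i}" for i in range(n)])
            p_cox = float(cox_fit(clinical, ["luminal"],
                                  luminal=luminal).summary.loc["luminal", "p"])
            diffs.append(abs(p_lr - p_cox))
        assert np.median(diffs) < 0.01


class TestStratifyAndDesign:
    def test_stratify_examples(self, normalized_small, truth_consensus):
        from mibc_subtyper.subtype_caller import call_subtypes
        assignment = call_subtypes(normalized_small, truth_consensus)
        indicator = stratify_luminal(assignment)
        assert ((assignment.subtypes == "luminal") == (indicator == 1)).all()

    def test_design_drops_missing_rows_with_warning(self):
        clinical = _clinical_frame([1.0, 2.0, 3.0], [True, True, True])
        clinical.data.loc[1, "age"] = pd.NA
        with pytest.warns(UserWarning, match="missing"):
            design = build_design(clinical, ["age"], endpoint="DSS")
        assert len(design) == 2

    def test_stage_dichotomization(self):
        clinical = _clinical_frame([1.0, 2.0, 3.0, 4.0],
                                   [True, True, True, True],
                                   stage=["pT2", "pT3", "pT4", "pTa/pT1/pTis"])
        design = build_design(clinical, ["stage"])
        assert design["stage"].tolist() == [0.0, 1.0, 1.0, 0.0]
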