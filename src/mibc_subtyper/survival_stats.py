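"""Kaplan-Meier estimation, log-rank testing and Cox regression.

Endpoints are overall survival (OS) and disease-specific survival (DSS) in
months.  Covariates follow the study's dichotomizations: pT3-pT4 vs lower
stage, N+ vs N0, M+ vs M0, adjuvant / neoadjuvant chemotherapy yes vs no,
male vs female, age continuous, and luminal vs non-luminal subtype.  Cox
models maximize the Efron-ties partial likelihood; forward selection
enters the candidate with the smallest likelihood-ratio p-value while that
p-value is below 0.05 and stops otherwise.  Wald confidence intervals are
exp(coef +/- 1.96 * SE).  No multiplicity adjustment is applied anywhere:
p < 0.05 is reported as-is, by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .io_formats import ClinicalTable
from .subtype_caller import SubtypeAssignment

ENDPOINTS = ("OS", "DSS")

#: covariate name -> builder over the clinical frame
_ENCODERS = {
    "age": lambda df: df["age"].astype(float),
    "sex": lambda df: (df["sex"] == "M").astype(float),
    "stage": lambda df: df["stage"].isin(["pT3", "pT4"]).astype(float),
    "node": lambda df: (df["node"] == "N+").astype(float),
    "metastasis": lambda df: (df["metastasis"] == "M+").astype(float),
    "nac": lambda df: df["nac"].astype(float),
    "ac": lambda df: df["ac"].astype(float),
}


@dataclass
class SurvivalCurve:
    """Product-limit estimate for one group.

    Censorings occurring exactly at an event time count in the at-risk set
    for the events at that time (the standard convention).
    """

    event_times: np.ndarray
    survival: np.ndarray          # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if ((s < -1e-12) | (s > 1 + 1e-12)).any():
            raise ValueError("survival probabilities must lie in [0, 1]")
        if (np.diff(s) > 1e-12).any():
            raise ValueError("survival must be non-increasing")

    def survival_at(self, t: float) -> float:
        """Step-function lookup: S(t), with S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "survival": self.survival,
            "at_risk": self.at_risk,
            "events": self.events,
            "group": self.label,
        })


@dataclass
class CoxResult:
    """Cox model summary plus the forward-selection trace."""

    summary: pd.DataFrame         # covariate x {coef, hr, ci_lower, ci_upper, p}
    selection_trace: list[dict] = field(default_factory=list)
    ties: str = "efron"
    n: int = 0
    n_events: int = 0
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        s = self.summary
        if len(s) and not ((s["ci_lower"] <= s["hr"] + 1e-12).all()
                           and (s["hr"] <= s["ci_upper"] + 1e-12).all()):
            raise ValueError("confidence bounds must bracket the hazard ratio")
        if len(s) and (s["hr"] <= 0).any():
            raise ValueError("hazard ratios must be positive")

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def km_estimate(times: Sequence[float], events: Sequence[bool],
                label: str = "") -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    survival = np.array([
        float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times
    ])
    return SurvivalCurve(
        event_times=event_times,
        survival=survival,
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        events=event_rows["observed"].to_numpy(dtype=int),
        label=label,
    )


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[bool]]],
                 ) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (chi-square, df, p)."""
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError(f"group {i} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    times, events, labels = map(np.concatenate, (times, events, labels))
    if events.sum() == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(times, labels, events)
    df = len(groups) - 1
    return float(res.test_statistic), df, float(res.p_value)


def stratify_luminal(assignment: SubtypeAssignment) -> pd.Series:
    """Indicator 1 for luminal, 0 for basal/infiltrated."""
    return (assignment.subtypes == "luminal").astype(int).rename("luminal")


def build_design(clinical: ClinicalTable, covariates: Sequence[str],
                 endpoint: str = "DSS",
                 luminal: pd.Series | None = None) -> pd.DataFrame:
    """Design matrix with duration/event columns; rows with missing values
    in the requested covariates or endpoint are dropped explicitly."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    df = clinical.data.set_index("sample_id")
    tcol, ecol = (("os_time", "os_event") if endpoint == "OS"
                  else ("dss_time", "dss_event"))
    out = pd.DataFrame({
        "duration": df[tcol].astype(float),
        "event": df[ecol].astype("boolean"),
    })
    for cov in covariates:
        if cov == "luminal":
            if luminal is None:
                raise ValueError("covariate 'luminal' needs a subtype indicator")
            out["luminal"] = luminal.reindex(out.index).astype(float)
        elif cov in _ENCODERS:
            out[cov] = _ENCODERS[cov](df)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    n_before = len(out)
    out = out.dropna()
    out["event"] = out["event"].astype(bool)
    if len(out) < n_before:
        warnings.warn(
            f"dropped {n_before - len(out)} sample(s) with missing values",
            stacklevel=2,
        )
    return out


def _fit_cph(design: pd.DataFrame, covariates: Sequence[str]) -> CoxPHFitter:
    for cov in covariates:
        if design[cov].nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant: non-identifiable")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design[["duration", "event", *covariates]],
                    duration_col="duration", event_col="event")
    except ConvergenceError as exc:
        raise ValueError(
            "Cox partial likelihood is monotone (complete separation); "
            "consider a penalized fit or coarser covariate coding"
        ) from exc
    if (cph.params_.abs() > 20).any():
        raise ValueError(
            "Cox fit diverged (|coef| > 20), likely complete separation; "
            "consider a penalized fit"
        )
    return cph


def _result_from_fit(cph: CoxPHFitter, trace: list[dict],
                     design: pd.DataFrame) -> CoxResult:
    coefs = cph.params_
    ses = cph.standard_errors_
    summary = pd.DataFrame({
        "coef": coefs,
        "hr": np.exp(coefs),
        "ci_lower": np.exp(coefs - 1.96 * ses),
        "ci_upper": np.exp(coefs + 1.96 * ses),
        "se": ses,
        "p": cph.summary["p"],
    })
    summary.index.name = "covariate"
    return CoxResult(
        summary=summary,
        selection_trace=trace,
        ties="efron",
        n=len(design),
        n_events=int(design["event"].sum()),
        log_likelihood=float(cph.log_likelihood_),
    )


def cox_fit(clinical: ClinicalTable, covariates: Sequence[str],
            endpoint: str = "DSS", selection: str = "none",
            luminal: pd.Series | None = None, ties: str = "efron",
            entry_p: float = 0.05) -> CoxResult:
    """Cox proportional-hazards regression, optionally with forward selection.

    ``selection="forward"`` starts from the empty model and repeatedly
    enters the candidate covariate with the smallest likelihood-ratio
    p-value while that p-value is below ``entry_p`` (no removal step).
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is implemented")
    if selection not in ("none", "forward"):
        raise ValueError(f"unknown selection mode {selection!r}")
    covariates = list(covariates)
    if not covariates:
        raise ValueError("no covariates supplied")
    design = build_design(clinical, covariates, endpoint=endpoint,
                          luminal=luminal)
    if design["event"].sum() == 0:
        raise ValueError("zero events: Cox model is not estimable")

    if selection == "none":
        cph = _fit_cph(design, covariates)
        return _result_from_fit(cph, [], design)

    from scipy.stats import chi2

    selected: list[str] = []
    trace: list[dict] = []
    current_ll: float | None = None  # None until the null ll is known
    while True:
        candidates = [c for c in covariates if c not in selected]
        if not candidates:
            break
        best = None
        for cand in candidates:
            cph = _fit_cph(design, selected + [cand])
            if current_ll is None:
                # recover the null partial log-likelihood from the LRT
                lrt = cph.log_likelihood_ratio_test()
                null_ll = cph.log_likelihood_ - lrt.test_statistic / 2.0
            else:
                null_ll = current_ll
            stat = 2.0 * (cph.log_likelihood_ - null_ll)
            p = float(chi2.sf(max(stat, 0.0), df=1))
            if best is None or p < best[1]:
                best = (cand, p, cph)
        cand, p, cph = best
        if p >= entry_p:
            break
        selected.append(cand)
        current_ll = float(cph.log_likelihood_)
        trace.append({"covariate": cand, "p_entry": p, "step": len(selected)})
    if not selected:
        raise ValueError(
            f"forward selection entered no covariate at p < {entry_p}"
        )
    cph = _fit_cph(design, selected)
    return _result_from_fit(cph, trace, design)


def km_by_group(times: Sequence[float], events: Sequence[bool],
                groups: Sequence[str]) -> dict[str, SurvivalCurve]:
    """One KM curve per group label, keyed by label."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    return {
        str(g): km_estimate(times[groups == g], events[groups == g], label=str(g))
        for g in pd.unique(groups)
    }
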