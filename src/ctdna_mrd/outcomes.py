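"""Post-treatment ctDNA status and survival association.

Residual-disease status is assigned per participant from the filtered plasma
calls: positive when any surviving variant comes from a sample collected
within the post-treatment window (default 213 days ≈ 7 calendar months at
365.25/12 days each); negative when at least one in-window sample exists but
carries no surviving variant; undetermined when no in-window sample exists
at all — a distinct state, excluded listwise from survival contrasts.

Survival association uses the product-limit (Kaplan–Meier) estimator and Cox
proportional-hazards regression (Breslow tie handling by default, Efron
available), reported as hazard ratios with Wald 95% confidence intervals.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning

from .cohort_io import ParticipantRecord, VariantCall
from .errors import DataError

DEFAULT_WINDOW_DAYS = 213  # 7 months at 365.25 / 12 days, rounded


class StatusValue(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class CtdnaStatus:
    participant_id: str
    status: StatusValue
    n_surviving_variants: int
    window_days: int = DEFAULT_WINDOW_DAYS

    @property
    def positive(self) -> bool | None:
        """True/False when determined, None when no in-window sample exists."""
        if self.status is StatusValue.UNDETERMINED:
            return None
        return self.status is StatusValue.POSITIVE


def assign_ctdna_status(
    participant_id: str,
    surviving_calls: Iterable[VariantCall],
    sample_days: Iterable[int],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> CtdnaStatus:
    """Assign post-treatment residual-disease status for one participant.

    ``surviving_calls`` are the participant's pipeline-surviving plasma calls;
    ``sample_days`` lists the collection days of every post-treatment plasma
    sample drawn (with or without variants).  Samples combine by OR: one
    surviving in-window variant makes the participant positive.  The result
    does not depend on the order of calls or samples.
    """
    in_window_samples = [d for d in sample_days if 0 <= d <= window_days]
    in_window_calls = [c for c in surviving_calls
                       if c.participant_id == participant_id
                       and 0 <= c.collection_day <= window_days]
    n = len({(c.sample_id, c.key) for c in in_window_calls})
    if in_window_calls:
        status = StatusValue.POSITIVE
    elif in_window_samples:
        status = StatusValue.NEGATIVE
    else:
        status = StatusValue.UNDETERMINED
    return CtdnaStatus(participant_id, status, n, window_days)


# ---------------------------------------------------------------------------
# Survival fits


@dataclass(frozen=True)
class CurvePoint:
    time: float
    survival: float
    n_at_risk: int
    n_events: int


@dataclass(frozen=True)
class HrEstimate:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class SurvivalFit:
    """Results container: product-limit curve and/or proportional-hazards fit."""

    curve: list[CurvePoint] = field(default_factory=list)
    hr_estimates: list[HrEstimate] = field(default_factory=list)
    loglik: float | None = None
    converged: bool = True
    n: int = 0
    n_events: int = 0

    def survival_at(self, t: float) -> float:
        s = 1.0
        for pt in self.curve:
            if pt.time <= t:
                s = pt.survival
            else:
                break
        return s

    def summary(self) -> str:
        lines = [f"n = {self.n}, events = {self.n_events}, "
                 f"converged = {self.converged}"]
        if self.loglik is not None:
            lines[0] += f", partial log-likelihood = {self.loglik:.4f}"
        if self.hr_estimates:
            lines.append(f"{'covariate':<28}{'HR':>10}{'95% CI':>22}{'p':>10}")
            for h in self.hr_estimates:
                ci = f"({h.ci_low:.2f}, {h.ci_high:.2f})"
                lines.append(f"{h.covariate:<28}{h.hazard_ratio:>10.3f}{ci:>22}{h.p:>10.4f}")
        return "\n".join(lines)


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalFit:
    """Product-limit survival estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    One curve point per distinct observed time (event or censoring); censored
    subjects leave the risk set after their time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise DataError("empty survival input")
    if np.any(times < 0):
        raise DataError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    curve = []
    for t, row in tab.iterrows():
        if t == 0 and row["observed"] == 0 and row["censored"] == 0:
            continue  # lifelines' synthetic t=0 anchor row
        curve.append(CurvePoint(
            time=float(t),
            survival=float(kmf.survival_function_at_times(t).iloc[0]),
            n_at_risk=int(row["at_risk"]),
            n_events=int(row["observed"]),
        ))
    return SurvivalFit(curve=curve, n=int(times.size), n_events=int(events.sum()))


def cox_fit(
    covariates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[bool],
    ties: str = "breslow",
) -> SurvivalFit:
    """Cox proportional-hazards fit maximising the partial likelihood.

    ``covariates`` is a numeric design matrix (categoricals pre-encoded, first
    level as reference).  Constant covariates are rejected; monotone
    likelihood / separation is flagged via ``converged=False`` rather than
    silently reported.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() < 1:
        raise DataError("proportional-hazards fit requires at least one event")
    for col in covariates.columns:
        if covariates[col].nunique(dropna=False) <= 1:
            raise DataError(f"covariate {col!r} is constant across subjects")
    if ties == "efron":
        return _efron_cox_fit(covariates, times, events)
    if ties != "breslow":
        raise DataError(f"unknown tie-handling method {ties!r}")
    df = covariates.reset_index(drop=True).copy()
    df["_time"] = times
    df["_event"] = events.astype(int)

    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            cph.fit(df, duration_col="_time", event_col="_event",
                    fit_options={"step_size": 0.95})
        except (ConvergenceError, ConvergenceWarning):
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter(penalizer=1e-6)
                cph.fit(df, duration_col="_time", event_col="_event")
    summ = cph.summary
    estimates = [
        HrEstimate(
            covariate=str(idx),
            hazard_ratio=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
        )
        for idx, row in summ.iterrows()
    ]
    return SurvivalFit(
        hr_estimates=estimates,
        loglik=float(cph.log_likelihood_),
        converged=converged,
        n=int(times.size),
        n_events=int(events.sum()),
    )


def _efron_neg_loglik(beta, X, times, events):
    """Negative Efron partial log-likelihood (ties get staggered risk sums)."""
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(times[events]):
        d_mask = (times == t) & events
        risk = times >= t
        d = int(d_mask.sum())
        sum_risk = w[risk].sum()
        sum_tied = w[d_mask].sum()
        ll += eta[d_mask].sum()
        for j in range(d):
            ll -= np.log(sum_risk - (j / d) * sum_tied)
    return -ll


def _efron_cox_fit(covariates, times, events):
    from scipy.optimize import minimize

    X = covariates.to_numpy(dtype=float)
    X = X - X.mean(axis=0)           # centring improves conditioning only
    res = minimize(_efron_neg_loglik, np.zeros(X.shape[1]),
                   args=(X, times, events), method="BFGS",
                   options={"gtol": 1e-8})
    beta = res.x
    # Wald CIs from the numerically-differenced observed information
    eps = 1e-5
    k = beta.size
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            pp = beta.copy(); pp[i] += eps; pp[j] += eps
            pm = beta.copy(); pm[i] += eps; pm[j] -= eps
            mp = beta.copy(); mp[i] -= eps; mp[j] += eps
            mm = beta.copy(); mm[i] -= eps; mm[j] -= eps
            hess[i, j] = (_efron_neg_loglik(pp, X, times, events)
                          - _efron_neg_loglik(pm, X, times, events)
                          - _efron_neg_loglik(mp, X, times, events)
                          + _efron_neg_loglik(mm, X, times, events)) / (4 * eps * eps)
    se = np.sqrt(np.diag(np.linalg.inv(hess)))
    from scipy.stats import norm
    z = beta / se
    estimates = [
        HrEstimate(
            covariate=str(col),
            hazard_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - 1.959963984540054 * s)),
            ci_high=float(np.exp(b + 1.959963984540054 * s)),
            p=float(2 * norm.sf(abs(zi))),
        )
        for col, b, s, zi in zip(covariates.columns, beta, se, z)
    ]
    return SurvivalFit(
        hr_estimates=estimates,
        loglik=float(-res.fun),
        converged=bool(res.success),
        n=int(times.size),
        n_events=int(events.sum()),
    )


# ---------------------------------------------------------------------------
# Faceted subgroup analysis


@dataclass
class FacetResult:
    facet: tuple
    n: int
    n_events: int
    reliable: bool
    km_by_status: dict[str, SurvivalFit] = field(default_factory=dict)
    cox: SurvivalFit | None = None
    note: str = ""


def _facet_value(record: ParticipantRecord, name: str):
    if name == "arm":
        return record.arm.value
    if name == "pcr":
        return record.pcr.value
    return getattr(record, name)


def subgroup_analysis(
    statuses: Sequence[CtdnaStatus],
    records: Sequence[ParticipantRecord],
    facets: Sequence[str] = ("arm", "pcr"),
    min_events: int = 2,
) -> list[FacetResult]:
    """KM + Cox (ctDNA status as the covariate) within each facet cell.

    Undetermined-status participants are dropped listwise before faceting.
    Cells with fewer than ``min_events`` events are flagged unreliable and not
    fitted; empty cells are skipped.  Facet assignment partitions the
    determined participants.
    """
    status_by = {s.participant_id: s for s in statuses}
    rows = []
    for r in records:
        s = status_by.get(r.participant_id)
        if s is None or s.positive is None:
            continue
        rows.append((tuple(_facet_value(r, f) for f in facets), r, s))

    cells = sorted({facet for facet, _, _ in rows})
    results = []
    for cell in cells:
        members = [(r, s) for facet, r, s in rows if facet == cell]
        t = np.array([r.event_day if r.event else r.followup_day for r, _ in members],
                     dtype=float)
        e = np.array([r.event for r, _ in members], dtype=bool)
        pos = np.array([s.positive for _, s in members], dtype=bool)
        res = FacetResult(facet=cell, n=len(members), n_events=int(e.sum()),
                          reliable=int(e.sum()) >= min_events)
        if not res.reliable:
            res.note = f"fewer than {min_events} events; no fit"
        else:
            for value, mask in (("positive", pos), ("negative", ~pos)):
                if mask.any():
                    res.km_by_status[value] = km_estimate(t[mask], e[mask])
            if pos.any() and (~pos).any():
                res.cox = cox_fit(pd.DataFrame({"ctdna_positive": pos.astype(float)}), t, e)
            else:
                res.note = "single ctDNA status level; KM only"
        results.append(res)
    return results


def records_to_survival_frame(
    records: Sequence[ParticipantRecord],
    statuses: Sequence[CtdnaStatus],
    covariates: Sequence[str] = ("age_group", "tumour_stage", "node_status"),
    reference_levels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Design matrix for the multivariable fit: dummy-coded clinical
    covariates (first/configured level as reference) plus ctDNA status,
    duration and event columns.  Undetermined statuses are dropped."""
    status_by = {s.participant_id: s for s in statuses}
    refs = dict(reference_levels or {})
    raw = []
    for r in records:
        s = status_by.get(r.participant_id)
        if s is None or s.positive is None:
            continue
        row = {c: str(_facet_value(r, c)) for c in covariates}
        row["ctdna_positive"] = float(s.positive)
        row["_time"] = float(r.event_day if r.event else r.followup_day)
        row["_event"] = int(r.event)
        raw.append(row)
    df = pd.DataFrame(raw)
    for c in covariates:
        levels = sorted(df[c].unique())
        ref = refs.get(c, levels[0])
        ordered = [ref] + [l for l in levels if l != ref]
        df[c] = pd.Categorical(df[c], categories=ordered)
    return pd.get_dummies(df, columns=list(covariates), drop_first=True, dtype=float)
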