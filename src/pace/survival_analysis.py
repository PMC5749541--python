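"""Clinical-outcome association of ex vivo drug responses.

Cox proportional-hazards regression (univariate or with established
covariates), Kaplan-Meier estimation, the two-group log-rank test, and
maximally selected rank statistics for dichotomizing a continuous drug
response.  Drug-response covariates entering a Cox model are pre-scaled so
that one unit of the regressor corresponds to a 10 percent-point change in
viability, making hazard ratios readable as "per 10% viability change".

The maximally selected rank statistic scans every observed response value
inside a quantile window (10-90% by default), computes the standardized
log-rank statistic for the dichotomy x <= c vs x > c at each candidate c, and
reports the cutpoint maximizing |Z|.  Because the maximum over many
correlated candidates inflates the naive log-rank p value, significance is
assessed by a seeded permutation test that re-maximizes on every permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "CoxFit",
    "cox_fit",
    "km_estimate",
    "logrank_test",
    "CutpointResult",
    "maxsel_cutpoint",
    "standardized_logrank",
]

DRUG_SCALE = 10.0  # one Cox regressor unit = 10 percent-viability points


@dataclass
class CoxFit:
    """Fitted Cox model with hazard ratios per covariate."""

    summary: pd.DataFrame  # coef, se, HR, HR CI bounds, p
    log_likelihood: float
    ties_method: str
    scaling_note: str

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])


def cox_fit(
    covariates: pd.DataFrame,
    surv: pd.DataFrame,
    drug_cols: tuple[str, ...] | list[str] = (),
) -> CoxFit:
    """Cox proportional-hazards fit of survival on the given covariates.

    ``surv`` needs columns ``time_days`` and ``event`` indexed like
    ``covariates``.  Columns named in ``drug_cols`` are divided by 10 before
    fitting so their hazard ratios are per 10 percent-viability points.
    Requires at least one event and no constant covariate.  Ties are handled
    with Efron's method (the lifelines implementation).
    """
    common = covariates.dropna(how="any").index.intersection(surv.dropna().index)
    x = covariates.loc[common].astype(float).copy()
    s = surv.loc[common]
    if int(s["event"].sum()) < 1:
        raise ValueError("cox_fit: no observed events")
    const = [c for c in x.columns if x[c].nunique() < 2]
    if const:
        raise ValueError(f"cox_fit: constant covariates: {const}")
    for c in drug_cols:
        if c not in x.columns:
            raise KeyError(f"drug column {c!r} not among covariates")
        x[c] = x[c] / DRUG_SCALE

    frame = x.copy()
    frame["time_days"] = s["time_days"].astype(float)
    frame["event"] = s["event"].astype(int)
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time_days", event_col="event")
    out = pd.DataFrame(
        {
            "coef": cph.params_,
            "se": cph.standard_errors_,
            "hazard_ratio": np.exp(cph.params_),
            "hr_ci_lower": np.exp(cph.params_ - 1.96 * cph.standard_errors_),
            "hr_ci_upper": np.exp(cph.params_ + 1.96 * cph.standard_errors_),
            "p_value": cph.summary["p"],
        }
    )
    note = (
        f"drug-response covariates {list(drug_cols)} scaled so one unit = "
        f"{DRUG_SCALE:g} percent-viability points"
        if drug_cols else "no drug-response scaling applied"
    )
    return CoxFit(
        summary=out,
        log_likelihood=float(cph.log_likelihood_),
        ties_method="efron",
        scaling_note=note,
    )


def km_estimate(surv: pd.DataFrame, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per group.

    Returns, per non-empty group, a step-function frame with columns
    ``time``, ``survival``, ``at_risk``, ``censored``.  Empty groups are
    skipped with a warning.
    """
    import warnings

    groups = groups.reindex(surv.index)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups.dropna()):
        sel = surv[groups == g]
        if sel.empty:
            warnings.warn(f"km_estimate: empty group {g!r} skipped", stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sel["time_days"], sel["event"])
        tbl = kmf.event_table
        frame = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.values,
                "survival": kmf.survival_function_["KM_estimate"].values,
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).values,
                "censored": tbl["censored"].reindex(kmf.survival_function_.index).fillna(0).values,
            }
        )
        out[str(g)] = frame
    if not out:
        warnings.warn("km_estimate: no non-empty groups", stacklevel=2)
    return out


def logrank_test(surv: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p value."""
    groups = groups.reindex(surv.index)
    levels = pd.unique(groups.dropna())
    if len(levels) != 2:
        raise ValueError(f"logrank_test needs exactly 2 non-empty groups, got {len(levels)}")
    a = surv[groups == levels[0]]
    b = surv[groups == levels[1]]
    if a.empty or b.empty:
        raise ValueError("logrank_test: one group is empty")
    res = _ll_logrank(
        a["time_days"], b["time_days"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def standardized_logrank(
    time: np.ndarray, event: np.ndarray, member: np.ndarray
) -> np.ndarray:
    """Standardized log-rank statistic Z = (O - E) / sqrt(V) for group 1 = member.

    ``member`` may be a boolean vector (one dichotomy) or an (n, K) matrix of
    K dichotomies evaluated simultaneously; returns a scalar array of shape ()
    or (K,).  Uses the hypergeometric variance with the finite-population
    correction (n_j - d_j)/(n_j - 1) at each distinct event time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    m = np.asarray(member, dtype=float)
    squeeze = m.ndim == 1
    if squeeze:
        m = m[:, None]

    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    m_sorted = m[order]
    n = len(t_sorted)

    # distinct event times and per-time totals
    ev_times = np.unique(t_sorted[e_sorted == 1])
    # index of first subject still at risk at each event time
    first_at_risk = np.searchsorted(t_sorted, ev_times, side="left")
    # suffix sums of membership: number of group-1 subjects at risk
    suffix = np.vstack([np.cumsum(m_sorted[::-1], axis=0)[::-1], np.zeros((1, m.shape[1]))])
    n1 = suffix[first_at_risk]  # (T, K)
    n_at_risk = (n - first_at_risk).astype(float)  # (T,)

    d_all = np.zeros(len(ev_times))
    d1 = np.zeros((len(ev_times), m.shape[1]))
    ev_idx = np.searchsorted(ev_times, t_sorted)
    for i in range(n):
        if e_sorted[i] == 1:
            j = ev_idx[i]
            d_all[j] += 1
            d1[j] += m_sorted[i]

    frac = n1 / n_at_risk[:, None]
    o_minus_e = (d1 - d_all[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fpc = np.where(n_at_risk > 1, (n_at_risk - d_all) / (n_at_risk - 1), 0.0)
    var = (d_all[:, None] * frac * (1.0 - frac) * fpc[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, o_minus_e / np.sqrt(var), 0.0)
    return z[0] if squeeze else z


@dataclass
class CutpointResult:
    """Maximally selected rank-statistic dichotomization of a drug response."""

    cutpoint: float
    statistic: float  # standardized log-rank Z at the cutpoint
    candidates: np.ndarray
    trace: np.ndarray  # Z at every candidate
    p_value: float  # permutation p, re-maximized per permutation
    n_permutations: int
    seed: int
    group_sizes: tuple[int, int]  # (x <= cut, x > cut)


def maxsel_cutpoint(
    x: pd.Series | np.ndarray,
    surv: pd.DataFrame,
    window: tuple[float, float] = (0.1, 0.9),
    n_perm: int = 1000,
    seed: int = 0,
    min_per_side: int = 5,
) -> CutpointResult:
    """Maximally selected standardized log-rank statistic over cutpoints of x.

    Candidates are the observed values of x inside the quantile ``window``
    with at least ``min_per_side`` samples on each side.  The permutation p
    value shuffles x against (time, event) and re-maximizes |Z| each time.
    """
    if isinstance(x, pd.Series):
        x = x.reindex(surv.index).values
    x = np.asarray(x, dtype=float)
    ok = ~np.isnan(x) & surv["time_days"].notna().values
    x = x[ok]
    time = surv["time_days"].values[ok]
    event = surv["event"].values[ok].astype(int)
    if np.nanstd(x) == 0:
        raise ValueError("maxsel_cutpoint: x is constant")
    lo, hi = np.quantile(x, window[0]), np.quantile(x, window[1])
    cand = np.unique(x[(x >= lo) & (x <= hi)])
    cand = np.array(
        [c for c in cand if min_per_side <= int((x <= c).sum()) <= len(x) - min_per_side]
    )
    if len(cand) < 2:
        raise ValueError(
            f"maxsel_cutpoint: window {window} leaves {len(cand)} candidate cutpoints (<2)"
        )
    member = x[:, None] <= cand[None, :]
    trace = standardized_logrank(time, event, member)
    best = int(np.argmax(np.abs(trace)))
    observed = float(np.abs(trace[best]))

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(x))
        z = standardized_logrank(time, event, member[perm])
        if float(np.max(np.abs(z))) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    cut = float(cand[best])
    return CutpointResult(
        cutpoint=cut,
        statistic=float(trace[best]),
        candidates=cand,
        trace=trace,
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        group_sizes=(int((x <= cut).sum()), int((x > cut).sum())),
    )
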