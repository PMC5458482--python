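"""Survivor methylation signature and dichotomized-biomarker survival
evaluation: Kaplan–Meier curves, log-rank tests, and multivariate Cox
proportional-hazards regression.

The survivor signature contrasts primary tumors from patients dying of
disease before a landmark (default 48 months) with patients surviving
past it, using per-probe group MEANS (the stage comparisons use medians)
and a Mann–Whitney test with BH adjustment.

The Cox fit maximises the Breslow-tie partial likelihood by Newton's
method with step-halving; the Efron tie approximation is available via
``ties="efron"`` (delegated to lifelines).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .io import BetaMatrix
from .screen import bh_adjust, mann_whitney

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# survivor signature


@dataclass
class SignatureResult:
    """Per-probe survivor-signature screen.

    ``table`` columns: mean_short, mean_long, mean_diff (short − long),
    p_raw, p_adj, selected.  ``short_samples`` / ``long_samples`` record
    the group memberships actually used.
    """

    table: pd.DataFrame
    short_samples: tuple[str, ...]
    long_samples: tuple[str, ...]
    cutoff_months: float
    diff_min: float
    q_max: float

    @property
    def selected_probes(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


def survivor_groups(
    sample_sheet: pd.DataFrame,
    cutoff_months: float = 48.0,
    include_censored_as_long: bool = False,
) -> tuple[list[str], list[str]]:
    """Split primary-tumor patients into short and long survivors.

    Short = died of disease before the cutoff; long = survived past it.
    Patients with time exactly at the cutoff, or alive with follow-up
    shorter than the cutoff, are excluded (optionally counted as long).
    """
    prim = sample_sheet[sample_sheet["group"] == "primary"]
    short, long_, excluded = [], [], []
    for _, row in prim.iterrows():
        t, ev = float(row["survival_months"]), bool(row["event"])
        if t < cutoff_months and ev:
            short.append(row["sample_id"])
        elif t > cutoff_months:
            long_.append(row["sample_id"])
        elif t < cutoff_months and include_censored_as_long:
            long_.append(row["sample_id"])
        else:
            excluded.append(row["sample_id"])
    if excluded:
        logger.info("survivor grouping: %d primaries excluded (at cutoff or short follow-up)", len(excluded))
    return short, long_


def survivor_signature(
    bm: BetaMatrix,
    sample_sheet: pd.DataFrame,
    cutoff_months: float = 48.0,
    diff_min: float = 0.2,
    q_max: float = 0.01,
    min_group_n: int = 3,
    include_censored_as_long: bool = False,
) -> SignatureResult:
    """Probes separating short from long survivors among primary tumors.

    Selection requires |mean difference| ≥ diff_min AND BH-adjusted
    Mann–Whitney p < q_max.
    """
    short, long_ = survivor_groups(sample_sheet, cutoff_months, include_censored_as_long)
    if len(short) < min_group_n or len(long_) < min_group_n:
        raise ValueError(
            f"need ≥{min_group_n} patients per survivor group (have {len(short)} short, {len(long_)} long)"
        )
    xs = bm.values[short].to_numpy(dtype=float)
    xl = bm.values[long_].to_numpy(dtype=float)
    ns = (~np.isnan(xs)).sum(axis=1)
    nl = (~np.isnan(xl)).sum(axis=1)
    testable = (ns >= min_group_n) & (nl >= min_group_n)

    mean_short = np.nanmean(xs[testable], axis=1)
    mean_long = np.nanmean(xl[testable], axis=1)
    probes = bm.probe_ids[testable]
    pvals = np.array([
        mann_whitney(xs[bm.probe_ids.get_loc(pid)], xl[bm.probe_ids.get_loc(pid)], min_group_n=min_group_n)
        for pid in probes
    ])
    padj = bh_adjust(pvals)
    diff = mean_short - mean_long
    tab = pd.DataFrame(
        {
            "mean_short": mean_short,
            "mean_long": mean_long,
            "mean_diff": diff,
            "p_raw": pvals,
            "p_adj": padj,
            "selected": (np.abs(diff) >= diff_min) & (padj < q_max),
        },
        index=probes,
    )
    return SignatureResult(tab, tuple(short), tuple(long_), cutoff_months, diff_min, q_max)


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve: rows of (time, survival), S(0) = 1.

    Censored times enter the risk sets but never drop the curve.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("need at least one record")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    out = sf.reset_index()
    out.columns = ["time", "survival"]
    return out


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, two-sided p)."""
    ta, ea = np.asarray(times_a, dtype=float), np.asarray(events_a, dtype=bool)
    tb, eb = np.asarray(times_b, dtype=float), np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise ValueError("no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton)


@dataclass
class CoxResult:
    """Per-covariate estimates plus the convergence report."""

    table: pd.DataFrame  # coef, hr, ci_low, ci_high, se, p, flag
    converged: bool
    n_iter: int
    final_grad_norm: float
    log_likelihood: float


def _breslow_loglik(beta: np.ndarray, x: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Log partial likelihood, gradient and Hessian (Breslow ties)."""
    order = np.argsort(-times, kind="stable")  # decreasing time
    xs = x[order]
    ts = times[order]
    es = events[order]
    eta = xs @ beta
    w = np.exp(eta)

    ll = 0.0
    grad = np.zeros_like(beta)
    hess = np.zeros((len(beta), len(beta)))
    s0 = 0.0
    s1 = np.zeros_like(beta)
    s2 = np.zeros((len(beta), len(beta)))
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        # extend risk set with everyone at this time
        for k in range(i, j):
            s0 += w[k]
            s1 += w[k] * xs[k]
            s2 += w[k] * np.outer(xs[k], xs[k])
        ev = [k for k in range(i, j) if es[k]]
        d = len(ev)
        if d:
            xbar = s1 / s0
            ll += eta[ev].sum() - d * np.log(s0)
            grad += xs[ev].sum(axis=0) - d * xbar
            hess -= d * (s2 / s0 - np.outer(xbar, xbar))
        i = j
    return ll, grad, hess


def cox_fit(
    records: pd.DataFrame,
    covariates=("marker", "breslow_mm", "ulceration"),
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Multivariate Cox regression with hazard ratios and Wald tests.

    Covariates must be numerically encoded (marker high = 1, ulceration
    present = 1, Breslow in mm or pre-dichotomized).  Constant covariates
    are flagged non-identifiable and dropped from the likelihood; a
    monotone likelihood (perfect separation) is flagged non-converged
    instead of reporting a spurious coefficient.
    """
    covariates = list(covariates)
    df = records.dropna(subset=[time_col, event_col] + covariates)
    times = df[time_col].to_numpy(dtype=float)
    events = df[event_col].to_numpy(dtype=bool)
    if not events.any():
        raise ValueError("no events in the data")

    x_full = df[covariates].to_numpy(dtype=float)
    const = np.array([np.all(x_full[:, j] == x_full[0, j]) for j in range(x_full.shape[1])])
    if const.any():
        logger.warning("constant covariates flagged non-identifiable: %s",
                       [c for c, f in zip(covariates, const) if f])
    active = [j for j in range(len(covariates)) if not const[j]]
    x = x_full[:, active]
    center = x.mean(axis=0)
    x = x - center

    if ties == "efron":
        cph = CoxPHFitter()
        cph.fit(df[[time_col, event_col] + [covariates[j] for j in active]],
                duration_col=time_col, event_col=event_col)
        beta = cph.params_.to_numpy()
        se = cph.standard_errors_.to_numpy()
        ll = float(cph.log_likelihood_)
        converged, n_iter, gnorm = True, -1, float("nan")
    elif ties == "breslow":
        beta = np.zeros(len(active))
        converged = False
        gnorm = np.inf
        ll, grad, hess = _breslow_loglik(beta, x, times, events)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                break
            # step-halving to keep the likelihood increasing
            t_step = 1.0
            for _ in range(30):
                new_beta = beta + t_step * step
                new_ll, new_grad, new_hess = _breslow_loglik(new_beta, x, times, events)
                if new_ll >= ll - 1e-12:
                    break
                t_step /= 2
            beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
            gnorm = float(np.linalg.norm(grad))
            if gnorm < tol:
                converged = True
                break
            if np.max(np.abs(beta)) > 20:
                break  # monotone likelihood / separation
        se = np.full(len(active), np.nan)
        if len(active):
            try:
                se = np.sqrt(np.diag(np.linalg.inv(-hess)))
            except np.linalg.LinAlgError:
                pass
        if not converged:
            logger.warning("Cox fit did not converge (possible separation)")
    else:
        raise ValueError(f"unknown ties {ties!r}")

    rows = []
    ai = 0
    for j, cov in enumerate(covariates):
        if const[j]:
            rows.append((cov, np.nan, np.nan, np.nan, np.nan, np.nan, "non-identifiable"))
            continue
        b, s = float(beta[ai]), float(se[ai])
        flag = "ok" if converged else "non-converged"
        z = b / s if s > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        lo, hi = b - 1.96 * s, b + 1.96 * s
        if flag != "ok":
            rows.append((cov, np.nan, np.nan, np.nan, np.nan, np.nan, flag))
        else:
            rows.append((cov, b, float(np.exp(b)), float(np.exp(lo)), float(np.exp(hi)), float(p), flag))
        ai += 1
    table = pd.DataFrame(rows, columns=["covariate", "coef", "hr", "ci_low", "ci_high", "p", "flag"]).set_index("covariate")
    return CoxResult(table, converged, n_iter, float(gnorm) if np.isfinite(gnorm) else float("inf"), float(ll))


# ---------------------------------------------------------------------------
# dichotomization


def dichotomize(values, rule: str = "median") -> pd.Series:
    """Split marker values into {low, high} at a cohort cutoff.

    Rules: "median", "q1", "q3" (quartiles by linear interpolation,
    type-7 convention) or "fixed:<x>".  High means strictly above the
    cutoff; ties at the cutoff go to low.
    """
    s = pd.Series(values, dtype=float)
    v = s.to_numpy()
    if np.all(v == v[0]):
        raise ValueError("all marker values identical; no split possible")
    if rule == "median":
        cut = float(np.quantile(v, 0.5))
    elif rule == "q1":
        cut = float(np.quantile(v, 0.25))
    elif rule == "q3":
        cut = float(np.quantile(v, 0.75))
    elif rule.startswith("fixed:"):
        cut = float(rule.split(":", 1)[1])
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    return pd.Series(np.where(v > cut, "high", "low"), index=s.index, name="marker_level")
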