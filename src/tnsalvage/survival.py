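"""Survival machinery: product-limit estimation, log-rank, Cox regression.

Everything here is implemented from first principles on counting-process data
(left-truncated episodes ``(entry, stop]``), which is what the 24-month
epoch-split analysis needs:

* :func:`km_estimate` — Kaplan–Meier product-limit estimator with Greenwood
  variance and log-log confidence bands.
* :func:`log_rank` — two-group log-rank test (hypergeometric variance, 1 df).
* :func:`cox_fit` — Cox partial-likelihood maximisation with Efron tie
  handling by Newton–Raphson with step-halving; Wald inference from the
  observed information.
* :func:`epoch_split` / :func:`epoch_cox` — counting-process episode splitting
  at a cutpoint and the epoch-partitioned (time-varying-effect) Cox fit, the
  reading of "stratified Cox" consistent with separate early/late-relapse
  hazard ratios.

The convention throughout: at a tied event/censoring time, events precede
censorings (censored subjects remain in the risk set at their own time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError

__all__ = [
    "SurvivalCurve",
    "CoxTerm",
    "CoxResult",
    "LogRankResult",
    "km_estimate",
    "survival_at",
    "km_median",
    "log_rank",
    "cox_fit",
    "epoch_split",
    "epoch_cox",
    "pearson_corr",
    "curve_to_frame",
    "write_curve_csv",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    ci_method: str = "log-log"

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.greenwood_se = np.asarray(self.greenwood_se, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        self.n_events = np.asarray(self.n_events, dtype=int)


@dataclass
class CoxTerm:
    name: str
    epoch: str  # "early", "late" or "all"
    coef: float
    se: float
    hr: float
    hr_ci_low: float
    hr_ci_high: float
    p_value: float


@dataclass
class CoxResult:
    terms: list[CoxTerm]
    log_likelihood: float
    null_log_likelihood: float
    ties_method: str
    converged: bool
    n_events: int
    n_iter: int
    max_score: float
    diagnostics: dict = field(default_factory=dict)

    def term(self, name: str, epoch: str | None = None) -> CoxTerm:
        for t in self.terms:
            if t.name == name and (epoch is None or t.epoch == epoch):
                return t
        raise KeyError((name, epoch))

    def to_dict(self) -> dict:
        return {
            "terms": [vars(t) for t in self.terms],
            "log_likelihood": self.log_likelihood,
            "null_log_likelihood": self.null_log_likelihood,
            "ties_method": self.ties_method,
            "converged": self.converged,
            "n_events": self.n_events,
            "n_iter": self.n_iter,
            "max_score": self.max_score,
        }


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# Kaplan–Meier


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if t.size != d.size:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("times must be positive")

    uniq = np.unique(t[d == 1])
    if uniq.size == 0:
        return SurvivalCurve(
            event_times=np.empty(0), survival=np.empty(0),
            greenwood_se=np.empty(0), n_at_risk=np.empty(0, int),
            n_events=np.empty(0, int),
        )
    ts = np.sort(t)
    # events precede censorings at ties: risk set is everyone with t >= u
    at_risk = t.size - np.searchsorted(ts, uniq, side="left")
    ev_sorted = np.sort(t[d == 1])
    lo = np.searchsorted(ev_sorted, uniq, side="left")
    hi = np.searchsorted(ev_sorted, uniq, side="right")
    n_ev = hi - lo
    frac = n_ev / at_risk
    surv = np.cumprod(1.0 - frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(at_risk > n_ev,
                            n_ev / (at_risk * (at_risk - n_ev)), np.nan)
    gw = np.cumsum(gw_terms)
    se = np.where(np.isfinite(gw), surv * np.sqrt(np.where(np.isfinite(gw), gw, 0.0)), 0.0)
    return SurvivalCurve(
        event_times=uniq, survival=surv, greenwood_se=se,
        n_at_risk=at_risk, n_events=n_ev,
    )


def _loglog_ci(s: float, se: float) -> tuple[float, float]:
    """95% log-log band (guaranteed inside [0, 1])."""
    if s <= 0.0:
        return 0.0, 0.0
    if s >= 1.0 or se == 0.0:
        return s, s
    theta = math.log(-math.log(s))
    sd_theta = se / (s * abs(math.log(s)))
    lo = s ** math.exp(_Z95 * sd_theta)
    hi = s ** math.exp(-_Z95 * sd_theta)
    return lo, hi


def survival_at(curve: SurvivalCurve, t: float) -> tuple[float, float, float]:
    """Step-function evaluation of S(t) with its log-log 95% CI."""
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0, 1.0, 1.0
    s = float(curve.survival[idx])
    se = float(curve.greenwood_se[idx])
    lo, hi = _loglog_ci(s, se)
    return s, lo, hi


@dataclass
class MedianResult:
    reached: bool
    median: float | None
    ci_low: float | None
    ci_high: float | None


def km_median(curve: SurvivalCurve) -> MedianResult:
    """Smallest event time with S(t) <= 0.5; CI by inverting the log-log band.

    The confidence limits follow the Brookmeyer–Crowley construction: the
    lower (upper) limit is the first time at which the upper (lower)
    confidence band drops to 0.5 or below.  Not-reached outcomes are signalled,
    not raised.
    """
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return MedianResult(reached=False, median=None, ci_low=None, ci_high=None)
    med = float(curve.event_times[below[0]])
    lo = hi = None
    for i, t in enumerate(curve.event_times):
        band_lo, band_hi = _loglog_ci(float(curve.survival[i]), float(curve.greenwood_se[i]))
        if lo is None and band_hi <= 0.5:
            lo = float(t)
        if hi is None and band_lo <= 0.5:
            hi = float(t)
    if lo is not None and hi is not None and hi < lo:
        lo, hi = hi, lo
    return MedianResult(reached=True, median=med, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# log-rank


def log_rank(times: Sequence[float], events: Sequence[int],
             groups: Sequence[int]) -> LogRankResult:
    """Two-group log-rank test (O−E with hypergeometric variance, 1 df)."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("exactly two non-empty groups required")
    in1 = g == labels[1]
    o_minus_e = 0.0
    var = 0.0
    for u in np.unique(t[d == 1]):
        at_risk = t >= u
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        dd = int(((t == u) & (d == 1)).sum())
        d1 = int(((t == u) & (d == 1) & in1).sum())
        o_minus_e += d1 - dd * n1 / n
        if n > 1:
            var += dd * (n1 / n) * (1 - n1 / n) * (n - dd) / (n - 1)
    stat = o_minus_e ** 2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(stat, df=1)) if var > 0 else 1.0
    return LogRankResult(statistic=float(stat), df=1, p_value=p)


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties, counting-process data)


def _efron_quantities(beta, entry, stop, event, X):
    """Log partial likelihood, score and observed information (Efron ties)."""
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.mean()  # stabilises exp; leaves the partial likelihood unchanged
    r = np.exp(eta)
    xr = X * r[:, None]
    xxr = X[:, :, None] * X[:, None, :] * r[:, None, None]

    # prefix sums over key-sorted order give  sum_{key < u}  via searchsorted
    def prefix(key):
        order = np.argsort(key, kind="mergesort")
        ks = key[order]
        cr = np.concatenate([[0.0], np.cumsum(r[order])])
        cx = np.concatenate([np.zeros((1, p)), np.cumsum(xr[order], axis=0)])
        cxx = np.concatenate([np.zeros((1, p, p)), np.cumsum(xxr[order], axis=0)])
        return ks, cr, cx, cxx

    ks_e, cr_e, cx_e, cxx_e = prefix(entry)
    ks_s, cr_s, cx_s, cxx_s = prefix(stop)

    ev = event.astype(bool)
    ev_stop = stop[ev]
    uniq, inv = np.unique(ev_stop, return_inverse=True)
    m = uniq.size
    # risk-set sums at each unique event time u:  sum_{entry<u} - sum_{stop<u}
    ie = np.searchsorted(ks_e, uniq, side="left")
    is_ = np.searchsorted(ks_s, uniq, side="left")
    S_R = cr_e[ie] - cr_s[is_]
    U_R = cx_e[ie] - cx_s[is_]
    M_R = cxx_e[ie] - cxx_s[is_]

    # event-group sums
    d_cnt = np.bincount(inv, minlength=m).astype(float)
    S_D = np.bincount(inv, weights=r[ev], minlength=m)
    U_D = np.zeros((m, p))
    M_D = np.zeros((m, p, p))
    eta_D = np.bincount(inv, weights=eta[ev], minlength=m)
    for j in range(p):
        U_D[:, j] = np.bincount(inv, weights=xr[ev, j], minlength=m)
        for k in range(p):
            M_D[:, j, k] = np.bincount(inv, weights=xxr[ev, j, k], minlength=m)

    ll = float(eta_D.sum())
    score = X[ev].sum(axis=0).astype(float)
    info = np.zeros((p, p))
    for i in range(m):
        d = int(d_cnt[i])
        for l in range(d):
            frac = l / d
            phi = S_R[i] - frac * S_D[i]
            u = U_R[i] - frac * U_D[i]
            mm = M_R[i] - frac * M_D[i]
            ll -= math.log(phi)
            v = u / phi
            score -= v
            info += mm / phi - np.outer(v, v)
    return ll, score, info


def cox_fit(
    times: Sequence[float],
    events: Sequence[int],
    covariates,
    names: Sequence[str] | None = None,
    entries: Sequence[float] | None = None,
    epochs: Sequence[str] | None = None,
    ties: str = "efron",
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
    max_iter: int = 50,
) -> CoxResult:
    """Newton–Raphson maximisation of the Efron partial likelihood.

    ``covariates`` is an (n, p) array-like; ``entries`` enables left-truncated
    counting-process episodes (default 0).  Convergence when the largest score
    component falls below ``tol_score`` or the relative log-likelihood change
    below ``tol_loglik``.  A singular or non-improving likelihood raises
    :class:`ConvergenceError` with diagnostics.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is implemented")
    stop = np.asarray(times, dtype=float)
    event = np.asarray(events, dtype=int)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != stop.size:
        X = X.T
    n, p = X.shape
    entry = np.zeros(n) if entries is None else np.asarray(entries, dtype=float)
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if epochs is None:
        epochs = ["all"] * p
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [names[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant covariate(s): {bad}")

    beta = np.zeros(p)
    ll, score, info = _efron_quantities(beta, entry, stop, event, X)
    null_ll = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular information matrix (unidentifiable likelihood)",
                {"iteration": it, "beta": beta.tolist(), "max_score": float(np.abs(score).max())},
            ) from exc
        # step-halving keeps the likelihood monotone
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, score_new, info_new = _efron_quantities(cand, entry, stop, event, X)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            raise ConvergenceError(
                "step-halving failed; likelihood may be monotone in a coefficient",
                {"iteration": it, "beta": beta.tolist(), "max_score": float(np.abs(score).max())},
            )
        rel = abs(ll_new - ll) / (abs(ll) + 1e-300)
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.abs(beta).max() > 20.0:
            raise ConvergenceError(
                "coefficient diverging; monotone partial likelihood "
                "(perfect separation of the event order)",
                {"iteration": it, "beta": beta.tolist(),
                 "max_score": float(np.abs(score).max())},
            )
        ms = float(np.abs(score).max())
        if ms < tol_score or (rel < tol_loglik and ms < 1e-3):
            converged = True
            break
    max_score = float(np.abs(score).max())
    if not converged:
        raise ConvergenceError(
            "Newton-Raphson did not converge",
            {"iterations": it, "beta": beta.tolist(), "max_score": max_score},
        )
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(se)) or np.any(se > 50.0) or np.abs(beta).max() > 15.0:
        raise ConvergenceError(
            "unstable estimate (huge coefficient or standard error); "
            "likely monotone partial likelihood",
            {"beta": beta.tolist(), "se": se.tolist(), "max_score": max_score},
        )
    terms = []
    for j in range(p):
        b, s = float(beta[j]), float(se[j])
        z = b / s if s > 0 else math.inf
        terms.append(CoxTerm(
            name=str(names[j]), epoch=str(epochs[j]), coef=b, se=s,
            hr=math.exp(b), hr_ci_low=math.exp(b - _Z95 * s),
            hr_ci_high=math.exp(b + _Z95 * s),
            p_value=float(2 * stats.norm.sf(abs(z))),
        ))
    return CoxResult(
        terms=terms, log_likelihood=float(ll), null_log_likelihood=float(null_ll),
        ties_method="efron", converged=converged, n_events=int(event.sum()),
        n_iter=it, max_score=max_score,
    )


# ---------------------------------------------------------------------------
# epoch splitting


def epoch_split(df: pd.DataFrame, cutpoint: float,
                time_col: str = "time_to_recurrence",
                event_col: str = "event") -> pd.DataFrame:
    """Split each subject into counting-process episodes at ``cutpoint``.

    Subjects followed beyond the cutpoint contribute an event-free early
    episode ``(0, cut]`` and a late episode ``(cut, time]`` carrying the
    subject's event flag; shorter follow-up yields a single early episode.
    Total events are conserved by construction.
    """
    if cutpoint <= 0:
        raise ValueError("cutpoint must be > 0")
    covs = [c for c in df.columns if c not in (time_col, event_col)]
    rows = []
    for _, row in df.iterrows():
        t, e = float(row[time_col]), int(row[event_col])
        base = {c: row[c] for c in covs}
        if t <= cutpoint:
            rows.append({**base, "entry": 0.0, "stop": t, "event": e, "epoch": "early"})
        else:
            rows.append({**base, "entry": 0.0, "stop": cutpoint, "event": 0, "epoch": "early"})
            rows.append({**base, "entry": cutpoint, "stop": t, "event": e, "epoch": "late"})
    return pd.DataFrame(rows)


def epoch_cox(
    df: pd.DataFrame,
    cutpoint: float,
    covariate_epoch_map: Mapping[str, str],
    time_col: str = "time_to_recurrence",
    event_col: str = "event",
    **fit_kwargs,
) -> CoxResult:
    """Epoch-partitioned Cox fit via episode splitting.

    ``covariate_epoch_map`` maps a covariate column to ``"early"``, ``"late"``
    or ``"all"``; early/late terms are covariate × epoch interactions on the
    episode data.  Interaction columns without variation (e.g. a late term
    when no follow-up extends past the cutpoint) are dropped, so a cutpoint
    beyond the last observed time reduces to a single-epoch fit.
    """
    episodes = epoch_split(df[[time_col, event_col, *covariate_epoch_map]], cutpoint,
                           time_col=time_col, event_col=event_col)
    cols, names, epochs = [], [], []
    for cov, epoch in covariate_epoch_map.items():
        base = episodes[cov].to_numpy(dtype=float)
        if epoch == "all":
            wanted = [("all", base)]
        elif epoch in ("early", "late"):
            wanted = [(epoch, base * (episodes["epoch"] == epoch).to_numpy())]
        else:
            raise ValueError(f"unknown epoch {epoch!r} for covariate {cov!r}")
        for ep, colvals in wanted:
            if np.std(colvals) == 0:
                continue  # no variation: epoch absent from the data
            cols.append(colvals)
            names.append(cov)
            epochs.append(ep)
    if not cols:
        raise ValueError("no identifiable covariate terms after epoch splitting")
    X = np.column_stack(cols)
    return cox_fit(
        episodes["stop"], episodes["event"], X, names=names,
        entries=episodes["entry"], epochs=epochs, **fit_kwargs,
    )


# ---------------------------------------------------------------------------
# correlation and I/O


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def curve_to_frame(curve: SurvivalCurve) -> pd.DataFrame:
    ci = np.array([_loglog_ci(s, se) for s, se in zip(curve.survival, curve.greenwood_se)])
    if ci.size == 0:
        ci = np.empty((0, 2))
    return pd.DataFrame({
        "time": curve.event_times,
        "n_risk": curve.n_at_risk,
        "n_event": curve.n_events,
        "survival": curve.survival,
        "se": curve.greenwood_se,
        "ci_low": ci[:, 0],
        "ci_high": ci[:, 1],
    })


def write_curve_csv(curve: SurvivalCurve, path) -> None:
    curve_to_frame(curve).to_csv(path, index=False)
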