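"""Latent class analysis for binary clinical/biomarker indicators.

A finite mixture of independent Bernoulli items fit by EM: class weights
``pi`` (length K) and item-response probabilities ``rho`` (K × J).  Model
selection is by BIC over K; subjects are assigned by maximum a posteriori
probability.  The association between class membership and recurrence-free
survival is quantified by a Cox fit with the resistant class as exposure.

The default indicator set mirrors the clinical subtype axes: hypertension,
V1 involvement, advanced age, elevated IL-6, default-mode-network
hyperconnectivity, and the constant-pain TN2 phenotype.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cohort import Cohort
from .errors import DegenerateModelWarning
from .survival import CoxResult, cox_fit

__all__ = [
    "IndicatorMatrix",
    "LCAModel",
    "default_thresholds",
    "discretize_features",
    "lca_em",
    "lca_log_likelihood",
    "select_K",
    "class_outcome_association",
]

_RHO_CLAMP = 1e-6


@dataclass
class IndicatorMatrix:
    data: np.ndarray  # (n, J) in {0, 1}
    item_names: list[str]
    thresholds_used: dict

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass
class LCAModel:
    K: int
    pi: np.ndarray
    rho: np.ndarray  # (K, J)
    posterior: np.ndarray  # (n, K)
    log_likelihood: float
    bic: float
    n_restarts: int
    seed: int
    item_names: list[str]
    loglik_history: list[float]

    @property
    def map_labels(self) -> np.ndarray:
        """MAP class per subject; exact posterior ties go to the lower index."""
        return np.argmax(self.posterior, axis=1)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "pi": self.pi.tolist(),
            "rho": self.rho.tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "item_names": self.item_names,
        }


def default_thresholds() -> dict:
    """Item definitions: flag columns pass through; continuous items get cutoffs.

    The DMN cutoff "pooled mean + 0.5 SD" is resolved against the cohort at
    discretisation time (encoded as ``("dmn_hyperconnectivity", None)``).
    """
    return {
        "hypertension": ("hypertension", None),
        "v1_involved": ("v1_involved", None),
        "age_ge_70": ("age", 70.0),
        "il6_ge_20": ("il6", 20.0),
        "dmn_high": ("dmn_hyperconnectivity", None),
        "tn2": ("tn_type", "TN2"),
    }


def discretize_features(cohort: Cohort | pd.DataFrame,
                        thresholds: dict | None = None) -> IndicatorMatrix:
    """Deterministic binary recoding; ``value >= threshold`` codes as 1."""
    table = cohort.table if isinstance(cohort, Cohort) else cohort
    thresholds = thresholds if thresholds is not None else default_thresholds()
    cols = []
    used = {}
    for item, (col, cut) in thresholds.items():
        series = table[col]
        if series.isna().any():
            raise ValueError(
                f"column {col!r} contains missing values; impute before discretising"
            )
        if isinstance(cut, str):
            vals = (series == cut).astype(int).to_numpy()
            used[item] = f"{col} == {cut}"
        elif cut is None and series.dtype != object:
            if set(np.unique(series)) <= {0, 1}:
                vals = series.astype(int).to_numpy()
                used[item] = f"{col} (flag)"
            else:
                c = float(series.mean() + 0.5 * series.std())
                vals = (series >= c).astype(int).to_numpy()
                used[item] = f"{col} >= {c:.4g} (pooled mean + 0.5 SD)"
        else:
            vals = (series >= cut).astype(int).to_numpy()
            used[item] = f"{col} >= {cut}"
        cols.append(vals)
    data = np.column_stack(cols) if cols else np.empty((len(table), 0), dtype=int)
    return IndicatorMatrix(data=data, item_names=list(thresholds), thresholds_used=used)


def lca_log_likelihood(data: np.ndarray, pi: np.ndarray, rho: np.ndarray) -> float:
    """Observed-data log likelihood of the independent-Bernoulli mixture."""
    logp = _log_posterior_numerator(data, pi, rho)
    return float(logsumexp(logp, axis=1).sum())


def _log_posterior_numerator(data, pi, rho):
    rho = np.clip(rho, _RHO_CLAMP, 1 - _RHO_CLAMP)
    # (n, K): log pi_k + sum_j [y log rho + (1-y) log(1-rho)]
    return (np.log(pi)[None, :]
            + data @ np.log(rho).T
            + (1 - data) @ np.log(1 - rho).T)


def lca_em(
    indicators: IndicatorMatrix,
    K: int,
    restarts: int = 20,
    tol: float = 1e-8,
    seed: int = 0,
    max_iter: int = 1000,
) -> LCAModel:
    """Best-of-restarts EM fit of the K-class Bernoulli mixture.

    Each restart initialises ``rho`` uniformly on (0.25, 0.75) and ``pi`` from
    a flat Dirichlet; iteration stops when the relative log-likelihood change
    falls below ``tol``.  The log likelihood is checked to be non-decreasing
    at every step (EM monotonicity), with a small slack for the response-
    probability clamping.
    """
    if K < 1 or restarts < 1:
        raise ValueError("K and restarts must be >= 1")
    data = np.asarray(indicators.data, dtype=float)
    n, J = data.shape
    n_patterns = len({tuple(row) for row in indicators.data.astype(int)})
    if K > n_patterns:
        warnings.warn(
            f"K={K} exceeds the {n_patterns} distinct response patterns; "
            "the model is degenerate",
            DegenerateModelWarning,
        )
    if K == 1:
        pi = np.ones(1)
        rho = data.mean(axis=0, keepdims=True)
        ll = lca_log_likelihood(data, pi, rho)
        return LCAModel(
            K=1, pi=pi, rho=rho, posterior=np.ones((n, 1)), log_likelihood=ll,
            bic=_bic(ll, K, J, n), n_restarts=restarts, seed=seed,
            item_names=indicators.item_names, loglik_history=[ll],
        )

    rng_master = np.random.SeedSequence(seed)
    best = None
    for child in rng_master.spawn(restarts):
        rng = np.random.default_rng(child)
        rho = rng.uniform(0.25, 0.75, size=(K, J))
        pi = rng.dirichlet(np.ones(K))
        ll_prev = -np.inf
        history = []
        for _ in range(max_iter):
            lognum = _log_posterior_numerator(data, pi, rho)
            lse = logsumexp(lognum, axis=1)
            ll = float(lse.sum())
            if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
                raise AssertionError("EM log-likelihood decreased")
            history.append(ll)
            post = np.exp(lognum - lse[:, None])
            pi = post.mean(axis=0)
            pi = np.clip(pi, 1e-12, None)
            pi /= pi.sum()
            denom = post.sum(axis=0)[:, None]
            rho = np.clip((post.T @ data) / denom, _RHO_CLAMP, 1 - _RHO_CLAMP)
            if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * abs(ll_prev):
                break
            ll_prev = ll
        lognum = _log_posterior_numerator(data, pi, rho)
        lse = logsumexp(lognum, axis=1)
        ll = float(lse.sum())
        if best is None or ll > best[0]:
            post = np.exp(lognum - lse[:, None])
            best = (ll, pi, rho, post, history + [ll])
    ll, pi, rho, post, history = best
    return LCAModel(
        K=K, pi=pi, rho=rho, posterior=post, log_likelihood=ll,
        bic=_bic(ll, K, J, n), n_restarts=restarts, seed=seed,
        item_names=indicators.item_names, loglik_history=history,
    )


def _bic(ll: float, K: int, J: int, n: int) -> float:
    params = (K - 1) + K * J
    return -2.0 * ll + params * np.log(n)


def select_K(
    indicators: IndicatorMatrix,
    K_max: int,
    restarts: int = 20,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Fit K = 1..K_max and pick the BIC minimiser."""
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    rows = []
    for K in range(1, K_max + 1):
        model = lca_em(indicators, K, restarts=restarts, seed=seed + K)
        rows.append({
            "K": K,
            "log_likelihood": model.log_likelihood,
            "n_params": (K - 1) + K * len(indicators.item_names),
            "bic": model.bic,
        })
    table = pd.DataFrame(rows)
    k_best = int(table.loc[table["bic"].idxmin(), "K"])
    return k_best, table


def class_outcome_association(
    labels,
    times,
    events,
    resistant_label="resistant",
) -> CoxResult:
    """Cox fit of recurrence on class membership (resistant class = exposure).

    Labels may be strings (``resistant_label`` marks the exposure) or 0/1
    integers (1 = exposure).  Delegates to :func:`tnsalvage.survival.cox_fit`.
    """
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        x = (labels == resistant_label).astype(float)
    else:
        x = labels.astype(float)
    if len(np.unique(x)) != 2:
        raise ValueError("two classes must be present")
    return cox_fit(times, events, x[:, None], names=["resistant_class"])


def permutation_align(truth: np.ndarray, labels: np.ndarray, K: int) -> float:
    """Best agreement between label vectors over all label permutations."""
    best = 0.0
    for perm in itertools.permutations(range(K)):
        mapped = np.asarray(perm)[labels]
        best = max(best, float(np.mean(mapped == truth)))
    return best
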