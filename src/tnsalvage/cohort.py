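"""Seeded synthetic cohort generator for recurrent trigeminal neuralgia salvage studies.

The generator emulates a cohort of patients treated with percutaneous balloon
compression (PBC) after failed microvascular decompression: baseline covariates,
a two-class latent structure ("PBC-sensitive" vs "PBC-resistant"), serum and
imaging biomarkers (IL-6, norepinephrine, a scalar default-mode-network score),
recurrence times from a piecewise-exponential proportional-hazards model with
epoch-specific covariate effects (24-month cutpoint), administrative censoring,
and Bernoulli procedural outcomes.

Two calibration routines tie the generator to printed cohort summaries:

* :func:`calibrate_marginal_survival` solves per-interval baseline hazards so
  that the population-marginal recurrence-free survival passes through a set of
  (time, survival) targets, by sequential root finding with the covariate
  distribution enumerated exactly.
* :func:`calibrate_il6_coupling` solves, by bisection against a Monte-Carlo
  evaluation, the coefficient coupling log IL-6 (linearly) to the latent
  recurrence time so that the cohort-level Pearson correlation between IL-6
  and observed pain-free time hits a target (default −0.65), while
  class-specific arithmetic means of IL-6 are preserved by an explicit
  normalisation constant.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError, ConfigError

__all__ = [
    "PatientRecord",
    "CohortConfig",
    "Cohort",
    "DEFAULT_SURVIVAL_TARGETS",
    "default_config",
    "default_calibrated_config",
    "validate_config",
    "marginal_survival",
    "calibrate_marginal_survival",
    "with_calibrated_hazards",
    "calibrate_il6_coupling",
    "generate_cohort",
    "sample_biomarkers",
    "inject_missingness",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: Marginal recurrence-free survival targets: 1/2/5-year rates plus the median.
DEFAULT_SURVIVAL_TARGETS: tuple[tuple[float, float], ...] = (
    (1.0, 0.821),
    (2.0, 0.684),
    (3.21, 0.5),
    (5.0, 0.452),
)

#: Columns that may legitimately carry injected missingness.
DEFAULT_MASKABLE: tuple[str, ...] = (
    "hypertension",
    "diabetes",
    "il6",
    "symptom_duration",
)

#: Named RNG sub-streams, in a frozen order.  New fields must be appended so
#: that existing fields keep their draws for a given seed.
_STREAMS: tuple[str, ...] = (
    "latent_class",
    "female",
    "hypertension",
    "diabetes",
    "v1_involved",
    "tn_type",
    "age",
    "symptom_duration",
    "event_time",
    "censoring",
    "biomarkers",
    "immediate_relief",
    "facial_numbness",
    "missing",
)


@dataclass
class PatientRecord:
    """One simulated patient."""

    patient_id: str
    age: float
    sex: str
    hypertension: int
    diabetes: int
    v1_involved: int
    v2v3_involved: int
    tn_type: str
    symptom_duration: float
    il6: float
    norepinephrine: float | None
    dmn_hyperconnectivity: float
    latent_class: str
    immediate_relief: int
    time_to_recurrence: float
    event: int
    facial_numbness: int


@dataclass
class CohortConfig:
    """Full specification of the synthetic cohort's data-generating process.

    Probabilities are per-patient Bernoulli parameters; hazards are events per
    year; times are years.  ``baseline_hazards[i]`` applies on
    ``(hazard_knots[i-1], hazard_knots[i]]`` (with knot −1 ≡ 0) and the last
    rate extends beyond the last knot.  ``log_hr_map`` carries per-covariate
    ``(early, late)`` log hazard ratios switching at ``epoch_cutpoint``.
    """

    n: int = 56
    covariate_prevalences: dict = field(
        default_factory=lambda: {
            "female": 36 / 56,
            "hypertension": 26 / 56,
            "diabetes": 5 / 56,
            "v1_involved": 8 / 56,
            "tn1": 43 / 56,
        }
    )
    class_mix: float = 0.5  # probability of the resistant class
    age_by_class: dict = field(
        default_factory=lambda: {"sensitive": (61.4, 13.6), "resistant": (72.8, 13.6)}
    )
    symptom_duration_dist: tuple = (5.54, 1.76)
    epoch_cutpoint: float = 2.0
    hazard_knots: tuple = (1.0, 2.0, 3.21, 5.0)
    baseline_hazards: tuple | None = None
    log_hr_map: dict = field(
        default_factory=lambda: {
            "hypertension": (math.log(2.15), 0.0),
            "v1_involved": (0.0, math.log(3.02)),
            "latent_resistant": (math.log(4.12), math.log(4.12)),
        }
    )
    censoring_window: tuple = (1.0, 6.0)
    il6_mean_by_class: dict = field(
        default_factory=lambda: {"sensitive": 12.0, "resistant": 45.0}
    )
    il6_log_sd: float = 0.4
    il6_coupling: float = 0.0
    il6_norm: dict | None = None  # class -> (mean log latent time, scale A)
    ne_enabled: bool = True
    ne_mean_by_htn: tuple = (297.0, 483.0)  # (normotensive, hypertensive) pg/mL
    ne_log_sd: float = 0.4
    dmn_shift: float = 1.0  # resistant-class mean shift, in SD units
    dmn_sd: float = 1.0
    response_prob: float = 53 / 56
    complication_prob: float = 13 / 56
    missing_rate: float = 0.0


@dataclass
class Cohort:
    """An ordered cohort table plus provenance (seed, config fingerprint)."""

    table: pd.DataFrame
    seed: int
    config_fingerprint: str

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def records(self) -> list[PatientRecord]:
        cols = [f.name for f in PatientRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]
        return [
            PatientRecord(**{c: row[c] for c in cols})
            for _, row in self.table.iterrows()
        ]


# ---------------------------------------------------------------------------
# configuration plumbing


def config_fingerprint(config: CohortConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(config: CohortConfig) -> None:
    """Raise :class:`ConfigError` naming the first offending field."""
    if config.n < 0:
        raise ConfigError("n must be >= 0 (field: n)")
    for name, p in config.covariate_prevalences.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigError(
                f"prevalence of {name!r} must be in [0, 1] "
                f"(field: covariate_prevalences[{name!r}])"
            )
    for fname in ("class_mix", "response_prob", "complication_prob", "missing_rate"):
        v = getattr(config, fname)
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{fname} must be in [0, 1] (field: {fname})")
    if config.baseline_hazards is not None:
        if len(config.baseline_hazards) != len(config.hazard_knots):
            raise ConfigError(
                "baseline_hazards must have one rate per hazard knot "
                "(field: baseline_hazards)"
            )
        if any(h < 0 for h in config.baseline_hazards):
            raise ConfigError("hazards must be >= 0 (field: baseline_hazards)")
    knots = config.hazard_knots
    if any(b <= a for a, b in zip(knots, knots[1:])) or (knots and knots[0] <= 0):
        raise ConfigError("hazard_knots must be positive and increasing (field: hazard_knots)")
    cmin, cmax = config.censoring_window
    if not (cmax > cmin > 0):
        raise ConfigError("censoring window needs max > min > 0 (field: censoring_window)")
    if config.epoch_cutpoint <= 0:
        raise ConfigError("epoch_cutpoint must be > 0 (field: epoch_cutpoint)")
    if config.il6_log_sd < 0 or config.ne_log_sd < 0:
        raise ConfigError("log-sd must be >= 0 (field: il6_log_sd/ne_log_sd)")


def default_config(n: int = 56, **overrides) -> CohortConfig:
    """The study-condition configuration, without calibrated hazards/coupling."""
    return replace(CohortConfig(n=n), **overrides)


# ---------------------------------------------------------------------------
# hazard structure


def _piece_grid(config: CohortConfig):
    """Integration grid: bounds, per-piece baseline rate, per-piece epoch flag.

    Pieces never straddle the epoch cutpoint (the grid is refined there), so a
    piece's covariate multiplier is constant.
    """
    if config.baseline_hazards is None:
        raise ConfigError("baseline_hazards not set; calibrate first (field: baseline_hazards)")
    knots = list(config.hazard_knots)
    rates = list(config.baseline_hazards)
    bounds = [0.0] + knots + [math.inf]
    piece_rates = rates + [rates[-1] if rates else 0.0]
    cut = config.epoch_cutpoint
    if cut not in bounds:
        # split the piece containing the cutpoint
        for i in range(len(bounds) - 1):
            if bounds[i] < cut < bounds[i + 1]:
                bounds.insert(i + 1, cut)
                piece_rates.insert(i, piece_rates[i])
                break
    early = [bounds[i] < cut for i in range(len(bounds) - 1)]
    return np.asarray(bounds), np.asarray(piece_rates, dtype=float), np.asarray(early)


def _hazard_covariate_grid(config: CohortConfig):
    """Exact joint distribution of the hazard-relevant binary covariates.

    Covariates named in ``log_hr_map`` are independent Bernoulli; the latent
    class indicator draws its prevalence from ``class_mix``.
    """
    names = list(config.log_hr_map)
    prevs = []
    for name in names:
        if name == "latent_resistant":
            prevs.append(config.class_mix)
        elif name in config.covariate_prevalences:
            prevs.append(config.covariate_prevalences[name])
        else:
            raise ConfigError(
                f"no prevalence known for hazard covariate {name!r} (field: log_hr_map)"
            )
    combos = []
    for mask in range(2 ** len(names)):
        x = [(mask >> j) & 1 for j in range(len(names))]
        w = math.prod(p if xi else 1.0 - p for p, xi in zip(prevs, x))
        combos.append((w, np.asarray(x, dtype=float)))
    betas_early = np.asarray([config.log_hr_map[n][0] for n in names])
    betas_late = np.asarray([config.log_hr_map[n][1] for n in names])
    return combos, betas_early, betas_late


def _cumhaz_at(config: CohortConfig, t: float, x: np.ndarray,
               betas_early: np.ndarray, betas_late: np.ndarray) -> float:
    bounds, piece_rates, early = _piece_grid(config)
    m_early = math.exp(float(betas_early @ x))
    m_late = math.exp(float(betas_late @ x))
    total = 0.0
    for i in range(len(piece_rates)):
        lo, hi = bounds[i], min(bounds[i + 1], t)
        if hi <= lo:
            break
        total += piece_rates[i] * (hi - lo) * (m_early if early[i] else m_late)
    return total


def marginal_survival(config: CohortConfig, t: float) -> float:
    """Population-marginal S(t), averaging over the covariate distribution.

    Computed by exact enumeration of the (small) joint support of the binary
    hazard covariates — no Monte Carlo error.
    """
    combos, be, bl = _hazard_covariate_grid(config)
    return float(sum(w * math.exp(-_cumhaz_at(config, t, x, be, bl)) for w, x in combos))


def calibrate_marginal_survival(
    targets: Sequence[tuple[float, float]],
    config: CohortConfig,
    tol: float = 1e-3,
) -> tuple[float, ...]:
    """Solve per-interval baseline hazards hitting marginal survival targets.

    One hazard piece per target interval; pieces are solved sequentially by
    root finding (the marginal survival at a target time is strictly
    decreasing in that interval's rate).  Returns the rates; the matching
    knots are the target times.
    """
    times = [t for t, _ in targets]
    survs = [s for _, s in targets]
    if any(b <= a for a, b in zip(times, times[1:])) or times[0] <= 0:
        raise CalibrationError("target times must be positive and increasing")
    if any(not 0.0 < s <= 1.0 for s in survs):
        raise CalibrationError("target survivals must be in (0, 1]")
    if any(b > a for a, b in zip([1.0] + survs, survs)):
        raise CalibrationError("target survivals must be non-increasing (infeasible targets)")

    rates: list[float] = []
    for i, (t_i, s_i) in enumerate(targets):
        trial = replace(
            config,
            hazard_knots=tuple(times[: i + 1]),
            baseline_hazards=None,
        )

        def f(lam: float) -> float:
            cfg = replace(trial, baseline_hazards=tuple(rates + [lam]))
            return marginal_survival(cfg, t_i) - s_i

        if abs(f(0.0)) <= 1e-12:
            rates.append(0.0)
            continue
        hi = 1.0
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e6:  # pragma: no cover - unreachable for valid targets
                raise CalibrationError(f"no bracketing hazard for target at t={t_i}")
        lam = brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-12)
        rates.append(float(lam))

    check = replace(config, hazard_knots=tuple(times), baseline_hazards=tuple(rates))
    for t_i, s_i in targets:
        if abs(marginal_survival(check, t_i) - s_i) > tol:
            raise CalibrationError(f"calibration residual exceeds {tol} at t={t_i}")
    return tuple(rates)


def with_calibrated_hazards(
    config: CohortConfig,
    targets: Sequence[tuple[float, float]] = DEFAULT_SURVIVAL_TARGETS,
) -> CohortConfig:
    rates = calibrate_marginal_survival(targets, config)
    return replace(
        config,
        hazard_knots=tuple(t for t, _ in targets),
        baseline_hazards=rates,
    )


# ---------------------------------------------------------------------------
# event-time sampling


def _sample_event_times(config: CohortConfig, X: Mapping[str, np.ndarray],
                        rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw from the per-patient piecewise-exponential hazard."""
    bounds, piece_rates, early = _piece_grid(config)
    names = list(config.log_hr_map)
    xmat = np.column_stack([X[n] for n in names]) if names else np.zeros((len(next(iter(X.values()))), 0))
    be = np.asarray([config.log_hr_map[n][0] for n in names])
    bl = np.asarray([config.log_hr_map[n][1] for n in names])
    m_early = np.exp(xmat @ be)
    m_late = np.exp(xmat @ bl)
    n = len(m_early)
    target = rng.exponential(size=n)  # unit-exponential cumulative hazard
    t = np.full(n, np.inf)
    acc = np.zeros(n)
    done = np.zeros(n, dtype=bool)
    for i in range(len(piece_rates)):
        mult = m_early if early[i] else m_late
        lam = piece_rates[i] * mult
        width = bounds[i + 1] - bounds[i]
        seg = lam * width  # inf * 0 cannot occur: lam >= 0, width > 0
        with np.errstate(invalid="ignore"):
            hits = (~done) & (acc + seg >= target) & (lam > 0)
        t[hits] = bounds[i] + (target[hits] - acc[hits]) / lam[hits]
        done |= hits
        if np.isinf(width):
            break
        acc = acc + seg
    return t


# ---------------------------------------------------------------------------
# biomarkers


def sample_biomarkers(cohort: Cohort | pd.DataFrame, config: CohortConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Fill IL-6, norepinephrine and DMN columns on a cohort table.

    IL-6 is lognormal with class-specific arithmetic means; when
    ``config.il6_coupling`` is nonzero the log level additionally decreases
    linearly in the (latent) recurrence time, centred and scaled by the
    calibrated constants in ``config.il6_norm``, producing a negative
    IL-6 × pain-free-time correlation.  Norepinephrine means are
    hypertension-specific;
    the DMN score is Gaussian with a class-shifted mean.
    """
    table = cohort.table.copy() if isinstance(cohort, Cohort) else cohort.copy()
    n = len(table)
    resistant = (table["latent_class"] == "resistant").to_numpy()
    eps = rng.standard_normal(n)
    sd = config.il6_log_sd
    c = config.il6_coupling
    il6 = np.empty(n)
    for cls in ("sensitive", "resistant"):
        sel = resistant if cls == "resistant" else ~resistant
        mean = config.il6_mean_by_class[cls]
        if c != 0.0:
            if not config.il6_norm or cls not in config.il6_norm:
                raise ConfigError(
                    "il6_coupling is set but il6_norm is missing; run "
                    "calibrate_il6_coupling (field: il6_norm)"
                )
            m_cls, scale = config.il6_norm[cls]
            tcol = ("latent_event_time" if "latent_event_time" in table.columns
                    else "time_to_recurrence")
            t_lat = table[tcol].to_numpy(dtype=float)[sel]
            il6[sel] = scale * np.exp(-c * (t_lat - m_cls) + sd * eps[sel])
        else:
            il6[sel] = mean * np.exp(sd * eps[sel] - sd * sd / 2.0)
    table["il6"] = il6

    if config.ne_enabled:
        ne_eps = rng.standard_normal(n)
        htn = table["hypertension"].to_numpy().astype(bool)
        means = np.where(htn, config.ne_mean_by_htn[1], config.ne_mean_by_htn[0])
        table["norepinephrine"] = means * np.exp(
            config.ne_log_sd * ne_eps - config.ne_log_sd ** 2 / 2.0
        )
    else:
        table["norepinephrine"] = np.nan

    dmn = rng.standard_normal(n) * config.dmn_sd
    table["dmn_hyperconnectivity"] = dmn + np.where(resistant, config.dmn_shift, 0.0)
    if isinstance(cohort, Cohort):
        return replace(cohort, table=table).table
    return table


def calibrate_il6_coupling(
    config: CohortConfig,
    target_r: float = -0.65,
    n_mc: int = 50_000,
    n_norm: int = 200_000,
    internal_seed: int = 202406,
    c_max: float = 1.5,
) -> CohortConfig:
    """Bisection of the IL-6/time coupling against a Monte-Carlo correlation.

    Common random numbers (one fixed internal seed) make the Monte-Carlo
    correlation a smooth, monotone function of the coupling coefficient, so a
    bracketing root find is reliable.  After the coefficient is fixed, the
    per-class centering and scale constants are re-estimated on a larger draw
    so that arithmetic class means stay on target.
    """
    if config.baseline_hazards is None:
        raise ConfigError("calibrate hazards before the IL-6 coupling (field: baseline_hazards)")

    def _draw(n: int, seed: int):
        ss = np.random.SeedSequence(seed)
        r_class, r_cov, r_t, r_c, r_eps = [np.random.default_rng(s) for s in ss.spawn(5)]
        resistant = r_class.random(n) < config.class_mix
        X = {}
        for name in config.log_hr_map:
            if name == "latent_resistant":
                X[name] = resistant.astype(float)
            else:
                X[name] = (r_cov.random(n) < config.covariate_prevalences[name]).astype(float)
        t_lat = _sample_event_times(config, X, r_t)
        cmin, cmax = config.censoring_window
        censor = r_c.uniform(cmin, cmax, size=n)
        eps = r_eps.standard_normal(n)
        return resistant, t_lat, censor, eps

    def _il6_given(c: float, resistant, t_lat, eps):
        il6 = np.empty(len(t_lat))
        norms = {}
        for cls, sel in (("sensitive", ~resistant), ("resistant", resistant)):
            t = t_lat[sel]
            m = float(t.mean())
            s = np.exp(-c * (t - m) + config.il6_log_sd * eps[sel])
            scale = config.il6_mean_by_class[cls] / float(s.mean())
            il6[sel] = scale * s
            norms[cls] = (m, scale)
        return il6, norms

    resistant, t_lat, censor, eps = _draw(n_mc, internal_seed)
    observed = t_lat <= censor

    def corr_minus_target(c: float) -> float:
        il6, _ = _il6_given(c, resistant, t_lat, eps)
        r = float(np.corrcoef(il6[observed], t_lat[observed])[0, 1])
        return r - target_r

    if corr_minus_target(0.0) <= 0.0:
        raise CalibrationError(
            "correlation already below target with zero coupling; target infeasible"
        )
    if corr_minus_target(c_max) > 0.0:
        raise CalibrationError(f"coupling bound {c_max} too small for target {target_r}")
    c_star = float(brentq(corr_minus_target, 0.0, c_max, xtol=1e-4))

    resistant2, t_lat2, _, eps2 = _draw(n_norm, internal_seed + 1)
    _, norms = _il6_given(c_star, resistant2, t_lat2, eps2)
    return replace(config, il6_coupling=c_star, il6_norm=norms)


@lru_cache(maxsize=1)
def _default_calibration() -> tuple:
    cfg = with_calibrated_hazards(default_config())
    cfg = calibrate_il6_coupling(cfg)
    return cfg.hazard_knots, cfg.baseline_hazards, cfg.il6_coupling, cfg.il6_norm


def default_calibrated_config(n: int = 56, **overrides) -> CohortConfig:
    """Default config with hazards and IL-6 coupling calibrated (cached)."""
    knots, rates, coupling, norm = _default_calibration()
    cfg = default_config(
        n=n,
        hazard_knots=knots,
        baseline_hazards=rates,
        il6_coupling=coupling,
        il6_norm=dict(norm),
    )
    return replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# generation


_SCHEMA = [
    "patient_id", "age", "sex", "hypertension", "diabetes", "v1_involved",
    "v2v3_involved", "tn_type", "symptom_duration", "il6", "norepinephrine",
    "dmn_hyperconnectivity", "latent_class", "immediate_relief",
    "time_to_recurrence", "event", "facial_numbness", "latent_event_time",
]


def generate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Deterministically generate a cohort from (config, seed).

    Each field family draws from its own named RNG sub-stream (spawned from a
    single seed sequence in a frozen order), so extending the schema never
    perturbs previously generated fields.
    """
    validate_config(config)
    if config.baseline_hazards is None:
        raise ConfigError("baseline_hazards not set; calibrate first (field: baseline_hazards)")
    streams = dict(
        zip(_STREAMS, (np.random.default_rng(s)
                       for s in np.random.SeedSequence(seed).spawn(len(_STREAMS))))
    )
    n = config.n
    if n == 0:
        table = pd.DataFrame({c: pd.Series(dtype=object) for c in _SCHEMA})
        return Cohort(table=table, seed=seed, config_fingerprint=config_fingerprint(config))

    prev = config.covariate_prevalences
    resistant = streams["latent_class"].random(n) < config.class_mix
    latent_class = np.where(resistant, "resistant", "sensitive")
    female = streams["female"].random(n) < prev["female"]
    hypertension = (streams["hypertension"].random(n) < prev["hypertension"]).astype(int)
    diabetes = (streams["diabetes"].random(n) < prev["diabetes"]).astype(int)
    v1 = (streams["v1_involved"].random(n) < prev["v1_involved"]).astype(int)
    v2v3 = 1 - v1  # divisions complementary by default; see methods note
    tn1 = streams["tn_type"].random(n) < prev["tn1"]

    age = np.empty(n)
    for cls, sel in (("sensitive", ~resistant), ("resistant", resistant)):
        mu, sd = config.age_by_class[cls]
        age[sel] = streams["age"].standard_normal(int(sel.sum())) * sd + mu
    age = np.clip(age, 18.0, None)

    mu_d, sd_d = config.symptom_duration_dist
    duration = np.clip(streams["symptom_duration"].standard_normal(n) * sd_d + mu_d, 0.1, None)

    X = {}
    for name in config.log_hr_map:
        if name == "latent_resistant":
            X[name] = resistant.astype(float)
        elif name == "hypertension":
            X[name] = hypertension.astype(float)
        elif name == "v1_involved":
            X[name] = v1.astype(float)
        elif name in prev:
            X[name] = (streams["event_time"].random(n) < prev[name]).astype(float)
        else:
            raise ConfigError(f"unknown hazard covariate {name!r} (field: log_hr_map)")
    t_lat = _sample_event_times(config, X, streams["event_time"])
    cmin, cmax = config.censoring_window
    censor = streams["censoring"].uniform(cmin, cmax, size=n)
    event = (t_lat <= censor).astype(int)
    time_obs = np.minimum(t_lat, censor)

    table = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": age,
            "sex": np.where(female, "female", "male"),
            "hypertension": hypertension,
            "diabetes": diabetes,
            "v1_involved": v1,
            "v2v3_involved": v2v3,
            "tn_type": np.where(tn1, "TN1", "TN2"),
            "symptom_duration": duration,
            "latent_class": latent_class,
            "immediate_relief": (streams["immediate_relief"].random(n)
                                 < config.response_prob).astype(int),
            "time_to_recurrence": time_obs,
            "event": event,
            "facial_numbness": (streams["facial_numbness"].random(n)
                                < config.complication_prob).astype(int),
            "latent_event_time": t_lat,
        }
    )
    table = sample_biomarkers(table, config, streams["biomarkers"])
    table = table[_SCHEMA]
    cohort = Cohort(table=table, seed=seed, config_fingerprint=config_fingerprint(config))
    if config.missing_rate > 0:
        cohort = inject_missingness(cohort, config.missing_rate, seed)
    return cohort


def inject_missingness(
    cohort: Cohort,
    rate: float,
    seed: int,
    columns: Sequence[str] = DEFAULT_MASKABLE,
) -> Cohort:
    """Apply an MCAR mask to designated covariate columns.

    Outcome columns (time, event) and identifiers are never maskable.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigError("missing rate must be in [0, 1) (field: missing_rate)")
    forbidden = {"time_to_recurrence", "event", "patient_id", "latent_event_time"}
    bad = forbidden.intersection(columns)
    if bad:
        raise ConfigError(f"columns {sorted(bad)} are not maskable (field: maskable columns)")
    if rate == 0.0:
        return cohort
    table = cohort.table.copy()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x4D49)))
    for col in columns:
        mask = rng.random(len(table)) < rate
        table[col] = table[col].astype(float) if table[col].dtype != object else table[col]
        table.loc[mask, col] = np.nan
    return replace(cohort, table=table)


# ---------------------------------------------------------------------------
# I/O


def write_cohort_csv(cohort: Cohort, path) -> None:
    cohort.table.to_csv(path, index=False)


def read_cohort_csv(path, seed: int = -1, fingerprint: str = "") -> Cohort:
    table = pd.read_csv(path)
    missing = [c for c in _SCHEMA if c not in table.columns]
    if missing:
        raise ConfigError(f"cohort CSV missing columns {missing}")
    return Cohort(table=table, seed=seed, config_fingerprint=fingerprint)
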