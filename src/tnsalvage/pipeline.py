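"""End-to-end orchestration: generate → impute → survival → LCA → cost-utility.

``run_pipeline`` executes the full analysis chain on a synthetic cohort and
returns a :class:`ReportBundle` whose tables mirror the usual clinical-report
structure: baseline characteristics, Cox regression, cost-effectiveness.  The
bundle serialises to a directory of CSV/JSON files with a manifest carrying
seeds, a config fingerprint and per-file checksums, sufficient to reproduce
every number in the bundle.

Missing covariate data are handled by a deliberately simple chained-equations
multiple imputation (linear models with posterior-draw noise for continuous
covariates, logistic models for flags) pooled by Rubin's rules.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import __version__
from .cohort import (
    DEFAULT_MASKABLE,
    Cohort,
    default_calibrated_config,
    generate_cohort,
)
from .errors import BundleError, ConfigError
from .latent import (
    class_outcome_association,
    discretize_features,
    lca_em,
    select_K,
)
from .markov import (
    TABLE_TARGETS,
    build_arm_spec,
    calibrated_inputs,
    compare_arms,
    psa,
    run_cohort_trace,
)
from .survival import (
    CoxResult,
    curve_to_frame,
    epoch_cox,
    km_estimate,
    km_median,
    log_rank,
    survival_at,
)

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "impute_missing",
    "rubin_pool",
    "run_pipeline",
    "write_bundle",
    "read_bundle",
]


@dataclass
class PipelineConfig:
    n: int = 5000
    seed: int = 42
    missing_rate: float = 0.0
    imputation_m: int = 5
    epoch_cutpoint: float = 2.0
    adjust_for_class: bool = True
    lca_k_max: int = 3
    lca_restarts: int = 20
    psa_draws: int = 500
    wtp_max: float = 100_000.0
    output_dir: str = "results"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        if cfg.imputation_m < 1:
            raise ConfigError("imputation_m must be >= 1 (field: imputation_m)")
        return cfg


@dataclass
class ReportBundle:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    km_curve: pd.DataFrame
    cox: dict
    lca: dict
    posterior: pd.DataFrame
    ce: dict
    ceac: pd.DataFrame
    cohort: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# multiple imputation


_PREDICTORS = ("age", "female", "v1_involved", "time_to_recurrence", "event")


def _design(table: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(table)), table["age"].to_numpy(dtype=float),
            (table["sex"] == "female").to_numpy(dtype=float),
            table["v1_involved"].to_numpy(dtype=float),
            table["time_to_recurrence"].to_numpy(dtype=float),
            table["event"].to_numpy(dtype=float)]
    return np.column_stack(cols)


def _impute_continuous(y, obs, X, rng, log_scale):
    yo = np.log(y[obs]) if log_scale else y[obs]
    Xo, Xm = X[obs], X[~obs]
    beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta
    dof = max(len(yo) - X.shape[1], 1)
    sigma = float(np.sqrt(resid @ resid / dof))
    xtx_inv = np.linalg.pinv(Xo.T @ Xo)
    beta_draw = rng.multivariate_normal(beta, sigma ** 2 * xtx_inv)
    pred = Xm @ beta_draw + sigma * rng.standard_normal(Xm.shape[0])
    return np.exp(pred) if log_scale else pred


def _impute_binary(y, obs, X, rng):
    yo = y[obs].astype(float)
    Xo, Xm = X[obs], X[~obs]
    try:
        fit = sm.GLM(yo, Xo, family=sm.families.Binomial()).fit()
        params = rng.multivariate_normal(fit.params, fit.cov_params())
        p = 1.0 / (1.0 + np.exp(-(Xm @ params)))
    except Exception:  # separation or singular design: marginal fallback
        p = np.full(Xm.shape[0], yo.mean())
    return (rng.random(Xm.shape[0]) < p).astype(float)


def impute_missing(cohort: Cohort, m: int = 5, seed: int = 0) -> list[Cohort]:
    """Chained-equations multiple imputation returning ``m`` completed cohorts.

    Covariates with missingness are cycled over for a few sweeps; each model
    draws its coefficients from the asymptotic posterior before predicting,
    so imputations carry between-imputation variability for Rubin pooling.
    Missing outcome values (time or event) are a contract violation.
    """
    if m < 1:
        raise ConfigError("m must be >= 1 (field: imputation_m)")
    table = cohort.table
    for col in ("time_to_recurrence", "event"):
        if table[col].isna().any():
            raise ConfigError(f"missing values in outcome column {col!r} are not allowed")
    incomplete = [c for c in DEFAULT_MASKABLE if c in table and table[c].isna().any()]
    if not incomplete:
        return [cohort] * m
    completed = []
    for j, child in enumerate(np.random.SeedSequence((seed, 0x494D50)).spawn(m)):
        rng = np.random.default_rng(child)
        t = table.copy()
        # initial fill: column means / modes
        for col in incomplete:
            vals = t[col].astype(float)
            t[col] = vals.fillna(float(vals.mean()))
        X = _design(t)
        for _ in range(3):  # chained sweeps
            for col in incomplete:
                obs = ~table[col].isna().to_numpy()
                y = t[col].to_numpy(dtype=float)
                if col in ("hypertension", "diabetes"):
                    y[~obs] = _impute_binary(table[col].to_numpy(dtype=float), obs, X, rng)
                else:
                    y[~obs] = _impute_continuous(
                        table[col].to_numpy(dtype=float), obs, X, rng,
                        log_scale=(col == "il6"),
                    )
                t[col] = y
        completed.append(replace(cohort, table=t))
    return completed


def rubin_pool(estimates, variances) -> dict:
    """Rubin's rules: pooled point, within/between components, total variance."""
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    m = q.size
    pooled = float(q.mean())
    within = float(w.mean())
    between = float(q.var(ddof=1)) if m > 1 else 0.0
    total = within + (1.0 + 1.0 / m) * between
    return {
        "pooled": pooled,
        "within": within,
        "between": between,
        "total_variance": total,
        "se": float(np.sqrt(total)),
        "m": int(m),
    }


def pooled_epoch_cox(cohorts, cutpoint, covariate_epoch_map) -> tuple[CoxResult, dict]:
    """Epoch Cox on each completed cohort, pooled term-by-term."""
    fits = [
        epoch_cox(
            c.table[["time_to_recurrence", "event", *covariate_epoch_map]],
            cutpoint, covariate_epoch_map,
        )
        for c in cohorts
    ]
    pooled = {}
    for i, term in enumerate(fits[0].terms):
        ests = [f.terms[i].coef for f in fits]
        vars_ = [f.terms[i].se ** 2 for f in fits]
        pooled[(term.name, term.epoch)] = rubin_pool(ests, vars_)
    return fits[0], pooled


# ---------------------------------------------------------------------------
# report tables


def _table1(table: pd.DataFrame) -> pd.DataFrame:
    n = len(table)
    rows = [
        ("n", f"{n}"),
        ("Age (years)", f"{table['age'].mean():.2f} ± {table['age'].std():.2f}"),
        ("Symptom duration (years)",
         f"{table['symptom_duration'].mean():.2f} ± {table['symptom_duration'].std():.2f}"),
        ("Female", f"{(table['sex'] == 'female').mean() * 100:.1f}%"),
        ("Hypertension", f"{table['hypertension'].mean() * 100:.1f}%"),
        ("Diabetes", f"{table['diabetes'].mean() * 100:.1f}%"),
        ("V1 involvement", f"{table['v1_involved'].mean() * 100:.1f}%"),
        ("V2/V3 involvement", f"{table['v2v3_involved'].mean() * 100:.1f}%"),
        ("TN1 diagnosis", f"{(table['tn_type'] == 'TN1').mean() * 100:.1f}%"),
        ("Immediate relief (BNI I-III)", f"{table['immediate_relief'].mean() * 100:.1f}%"),
        ("Facial numbness", f"{table['facial_numbness'].mean() * 100:.1f}%"),
    ]
    return pd.DataFrame(rows, columns=["variable", "value"])


def _table2(cox: CoxResult) -> pd.DataFrame:
    rows = []
    for t in cox.terms:
        rows.append({
            "variable": t.name,
            "epoch": t.epoch,
            "hr": round(t.hr, 3),
            "ci_low": round(t.hr_ci_low, 3),
            "ci_high": round(t.hr_ci_high, 3),
            "p_value": t.p_value,
        })
    return pd.DataFrame(rows)


def _table3(traces: dict, inputs) -> pd.DataFrame:
    pbc, gkrs = traces["PBC"], traces["GKRS"]
    reint = {
        "PBC": inputs.five_year_reint_pbc * 100,
        "GKRS": inputs.five_year_reint_gkrs * 100,
    }
    rows = [
        {"metric": "Lifetime cost", "PBC": pbc.discounted_cost,
         "GKRS": gkrs.discounted_cost},
        {"metric": "QALYs gained", "PBC": pbc.discounted_qaly,
         "GKRS": gkrs.discounted_qaly},
        {"metric": "5-year reintervention rate (%)", "PBC": reint["PBC"],
         "GKRS": reint["GKRS"]},
    ]
    df = pd.DataFrame(rows)
    df["difference"] = df["PBC"] - df["GKRS"]
    return df


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full chain deterministically for (config, seed)."""
    if config.n <= 0:
        raise ConfigError("pipeline requires n >= 1 (field: n; stage: generate)")
    stages = []
    cohort_cfg = default_calibrated_config(n=config.n, missing_rate=config.missing_rate)
    cohort = generate_cohort(cohort_cfg, seed=config.seed)
    stages.append("generate")

    cov_map = {"hypertension": "early", "v1_involved": "late"}
    if config.adjust_for_class:
        analysis = cohort.table.copy()
        analysis["latent_resistant"] = (analysis["latent_class"] == "resistant").astype(int)
        cov_map["latent_resistant"] = "all"
    else:
        analysis = cohort.table.copy()

    pooled = None
    if config.missing_rate > 0:
        completed = impute_missing(cohort, m=config.imputation_m, seed=config.seed)
        stages.append("impute")
        comp_tables = []
        for c in completed:
            tt = c.table.copy()
            if config.adjust_for_class:
                tt["latent_resistant"] = (tt["latent_class"] == "resistant").astype(int)
            comp_tables.append(replace(c, table=tt))
        cox, pooled = pooled_epoch_cox(comp_tables, config.epoch_cutpoint, cov_map)
        analysis = comp_tables[0].table
    else:
        cox = epoch_cox(
            analysis[["time_to_recurrence", "event", *cov_map]],
            config.epoch_cutpoint, cov_map,
        )
    stages.append("epoch_cox")

    times = analysis["time_to_recurrence"].to_numpy(dtype=float)
    events = analysis["event"].to_numpy(dtype=int)
    curve = km_estimate(times, events)
    med = km_median(curve)
    lr = log_rank(times, events, analysis["hypertension"].to_numpy())
    stages.append("km")

    indicators = discretize_features(analysis)
    k_best, bic_table = select_K(indicators, config.lca_k_max,
                                 restarts=config.lca_restarts, seed=config.seed)
    model = lca_em(indicators, max(k_best, 2), restarts=config.lca_restarts,
                   seed=config.seed)
    labels = model.map_labels
    # orient: the class with the higher elevated-IL-6 response probability is
    # the resistant (exposure) class
    il6_j = model.item_names.index("il6_ge_20")
    resistant_idx = int(np.argmax(model.rho[:, il6_j]))
    cluster_cox = class_outcome_association(
        (labels == resistant_idx).astype(int), times, events)
    stages.append("lca")

    inputs = calibrated_inputs()
    traces = {arm: run_cohort_trace(build_arm_spec(arm, inputs)) for arm in ("PBC", "GKRS")}
    ce = compare_arms(traces["PBC"], traces["GKRS"])
    psa_res = psa(inputs, n_draws=config.psa_draws, seed=config.seed,
                  wtp_grid=np.linspace(0, config.wtp_max, 21))
    stages.append("cua")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "pipeline_config": asdict(config),
        "cohort_fingerprint": cohort.config_fingerprint,
        "stages": stages,
        "n": config.n,
        "km": {
            "median": med.median, "median_ci": [med.ci_low, med.ci_high],
            "s1": survival_at(curve, 1.0)[0],
            "s2": survival_at(curve, 2.0)[0],
            "s5": survival_at(curve, 5.0)[0],
            "log_rank_hypertension_p": lr.p_value,
        },
        "lca": {"k_best": k_best, "bic_table": bic_table.to_dict("records"),
                "cluster_hr": cluster_cox.term("resistant_class").hr},
        "pooled_cox": {f"{k[0]}[{k[1]}]": v for k, v in (pooled or {}).items()},
    }
    return ReportBundle(
        table1=_table1(analysis),
        table2=_table2(cox),
        table3=_table3(traces, inputs),
        km_curve=curve_to_frame(curve),
        cox=cox.to_dict(),
        lca=model.to_dict(),
        posterior=pd.DataFrame(
            model.posterior, columns=[f"class_{k}" for k in range(model.K)]),
        ce=ce.to_dict(),
        ceac=psa_res.ceac,
        cohort=cohort.table,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# bundle I/O


_BUNDLE_FILES = {
    "table1": "table1.csv",
    "table2": "table2.csv",
    "table3": "table3.csv",
    "km_curve": "km_curve.csv",
    "posterior": "lca_posterior.csv",
    "ceac": "ceac.csv",
    "cohort": "cohort.csv",
    "cox": "cox_results.json",
    "lca": "lca_model.json",
    "ce": "ce_result.json",
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(bundle: ReportBundle, directory) -> Path:
    """Serialise the bundle; the manifest (written last) checksums every file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in _BUNDLE_FILES.items():
        obj = getattr(bundle, attr)
        path = directory / fname
        if fname.endswith(".csv"):
            obj.to_csv(path, index=False)
        else:
            path.write_text(json.dumps(obj, indent=2, default=float))
    manifest = dict(bundle.manifest)
    manifest["checksums"] = {f: _sha256(directory / f) for f in _BUNDLE_FILES.values()}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return directory


def read_bundle(directory) -> ReportBundle:
    """Read a bundle back, verifying schema and checksums."""
    directory = Path(directory)
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise BundleError("bundle manifest missing; refusing to read")
    manifest = json.loads(mpath.read_text())
    checks = manifest.get("checksums")
    if not checks:
        raise BundleError("manifest lacks checksums")
    for fname, digest in checks.items():
        fpath = directory / fname
        if not fpath.exists():
            raise BundleError(f"bundle file {fname} missing")
        if _sha256(fpath) != digest:
            raise BundleError(f"checksum mismatch for {fname}")
    parts = {}
    for attr, fname in _BUNDLE_FILES.items():
        path = directory / fname
        parts[attr] = (pd.read_csv(path) if fname.endswith(".csv")
                       else json.loads(path.read_text()))
    return ReportBundle(manifest=manifest, **parts)
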