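"""Mixed-effects comparison of thin vs normal wall regions.

The sampled metric values are nested: patch nodes within sampled regions
(centre points) within patients.  The working model is

    Y_ij = b0 + b1 * thin_ij + u_patient(i) + u_region(i, j) + eps_ij

with a fixed thin-vs-normal effect b1 (reference level: normal), a random
intercept per patient, and a random intercept per region nested within
patient ("model2").  A simpler structure with crossed patient and
region-type intercepts ("model1") is available for comparison.  Fits use
REML via statsmodels' MixedLM; confidence intervals and p-values for b1 are
Wald-based, matching the symmetric 95% intervals usually reported.

Metrics can be analysed raw, log-transformed, or normalised by the
patient-specific maximum taken over the whole vascular model.  OSI, already
bounded and scale-free, is always analysed raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MODEL1, MODEL2 = "model1", "model2"
TRANSFORMS = ("raw", "log", "patient_max")
#: metrics that must never be transformed (bounded, scale-free)
UNTRANSFORMED_METRICS = ("osi",)


@dataclass
class TransformSpec:
    method: str = "patient_max"
    exempt_metrics: tuple = UNTRANSFORMED_METRICS

    def __post_init__(self):
        if self.method not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.method!r}")


@dataclass
class LMMResult:
    metric: str
    model: str
    transform: str
    beta0: float
    beta1: float
    ci_low: float
    ci_high: float
    p_value: float
    var_patient: float
    var_region: float
    var_residual: float
    aic: float
    n_obs: int
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    singular: bool = False

    def to_dict(self) -> dict:
        return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.__dict__.items()
                if k not in ("residuals", "fitted")}


def apply_transform(
    table: pd.DataFrame,
    spec: TransformSpec | str,
    patient_max: pd.DataFrame | None = None,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Return a transformed copy of the sample table.

    ``patient_max`` (patients x metrics, from :func:`sampling.patient_maxima`)
    is required for the patient_max method: each value is divided by that
    patient's signed maximum over the entire model, so normalised values are
    <= 1 with negative values (e.g. WSSD) preserved.  ``log`` is the natural
    log and demands strictly positive columns.  Exempt metrics (OSI) are
    passed through untouched.
    """
    if isinstance(spec, str):
        spec = TransformSpec(spec)
    out = table.copy()
    if metrics is None:
        metrics = [c for c in table.columns
                   if c not in ("patient_id", "region_type", "region_no", "node_id")]
    for m in metrics:
        if m in spec.exempt_metrics or spec.method == "raw":
            continue
        if spec.method == "log":
            if (out[m] <= 0).any():
                raise ValueError(f"log transform requested on {m!r} "
                                 "but column has values <= 0")
            out[m] = np.log(out[m])
        else:  # patient_max
            if patient_max is None:
                raise ValueError("patient_max transform needs the maxima table")
            mx = table["patient_id"].map(patient_max[m])
            if (mx == 0).any() or mx.isna().any():
                raise ValueError(f"invalid patient maximum for metric {m!r}")
            out[m] = out[m] / mx
    out.attrs["transform"] = spec.method
    return out


def fit_lmm(table: pd.DataFrame, metric: str, model_spec: str = MODEL2,
            transform: str | None = None) -> LMMResult:
    """REML fit of the thin-vs-normal mixed model for one metric.

    model2: random intercepts for patient and for region-within-patient.
    model1: random intercepts for patient and for region type (crossed),
    fitted as variance components within a single grand group.
    """
    import statsmodels.formula.api as smf

    if table["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients")
    if set(table["region_type"].unique()) != {"thin", "normal"}:
        raise ValueError("both region types must be present")

    df = table[["patient_id", "region_type", "region_no", metric]].copy()
    df = df.rename(columns={metric: "y"})
    df["thin"] = (df["region_type"] == "thin").astype(float)

    degenerate = _perfect_fit(df, metric, model_spec,
                              transform or table.attrs.get("transform", "raw"))
    if degenerate is not None:
        return degenerate

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if model_spec == MODEL2:
            md = smf.mixedlm("y ~ thin", df, groups="patient_id",
                             re_formula="1",
                             vc_formula={"region": "0 + C(region_no)"})
        elif model_spec == MODEL1:
            df["_grand"] = 1
            md = smf.mixedlm("y ~ thin", df, groups="_grand", re_formula="0",
                             vc_formula={"patient": "0 + C(patient_id)",
                                         "regiontype": "0 + C(region_type)"})
        else:
            raise ValueError(f"unknown model spec {model_spec!r}")
        res, last_exc = None, None
        for method in ("lbfgs", "powell", "cg"):
            try:
                res = md.fit(reml=True, method=method, maxiter=500)
            except Exception as exc:
                last_exc = exc
                continue
            if res.converged:
                break
    if res is None:
        raise RuntimeError(f"mixed model failed to converge: {last_exc}")
    if not res.converged:
        raise RuntimeError("mixed model did not converge "
                           f"(metric {metric!r}, {model_spec})")
    singular = any("singular" in str(w.message).lower()
                   or "boundary" in str(w.message).lower() for w in caught)

    beta0 = float(res.fe_params["Intercept"])
    beta1 = float(res.fe_params["thin"])
    se = float(res.bse_fe["thin"])
    zcrit = stats.norm.ppf(0.975)
    zval = beta1 / se if se > 0 else np.inf * np.sign(beta1)
    p = float(2 * stats.norm.sf(abs(zval)))

    scale = float(res.scale)
    if model_spec == MODEL2:
        var_patient = float(res.cov_re.iloc[0, 0])
        var_region = float(res.vcomp[0])
    else:
        var_patient = float(res.vcomp[0])
        var_region = float(res.vcomp[1])
    # statsmodels leaves AIC undefined for MixedLM; standard definition:
    # 2k - 2*logLik with k = fixed effects + variance parameters + residual
    k_params = len(res.fe_params) + len(res.vcomp) + res.model.k_re2 + 1
    aic = float(2 * k_params - 2 * res.llf)

    return LMMResult(
        metric=metric, model=model_spec,
        transform=transform or table.attrs.get("transform", "raw"),
        beta0=beta0, beta1=beta1,
        ci_low=beta1 - zcrit * se, ci_high=beta1 + zcrit * se,
        p_value=p, var_patient=max(var_patient, 0.0),
        var_region=max(var_region, 0.0), var_residual=scale,
        aic=aic, n_obs=len(df),
        residuals=np.asarray(res.resid), fitted=np.asarray(res.fittedvalues),
        singular=singular,
    )


def _perfect_fit(df: pd.DataFrame, metric: str, model_spec: str,
                 transform: str) -> LMMResult | None:
    """Exact result when the fixed effects alone fit the data perfectly.

    A zero-residual dataset has an unbounded REML likelihood, which no
    iterative fitter can profile; the coefficients are still well defined
    (plain least squares) and all variances are zero.  The AIC is evaluated
    with the residual variance floored at machine precision relative to the
    response scale, and the result is flagged singular.
    """
    y = df["y"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), df["thin"].to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    scale = max(1.0, np.abs(y).max())
    if not np.allclose(resid, 0.0, atol=1e-10 * scale):
        return None
    n = len(y)
    sigma2 = np.finfo(float).eps * scale ** 2
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 0.0)
    k_params = 2 + (2 if model_spec == MODEL2 else 2) + 1
    return LMMResult(
        metric=metric, model=model_spec, transform=transform,
        beta0=float(beta[0]), beta1=float(beta[1]),
        ci_low=float(beta[1]), ci_high=float(beta[1]),
        p_value=0.0, var_patient=0.0, var_region=0.0, var_residual=0.0,
        aic=float(2 * k_params - 2 * llf), n_obs=n,
        residuals=resid, fitted=X @ beta, singular=True,
    )


def compare_models_aic(results: list[LMMResult]) -> pd.DataFrame:
    """Rank fits of the same data by AIC (ascending), with deltas."""
    if len(results) < 2:
        raise ValueError("need at least two results to compare")
    n = {r.n_obs for r in results}
    if len(n) != 1:
        raise ValueError("AIC not comparable: fits use different row counts")
    df = pd.DataFrame([{"metric": r.metric, "model": r.model,
                        "transform": r.transform, "aic": r.aic}
                       for r in results])
    df = df.sort_values("aic", kind="mergesort").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


@dataclass
class DiagnosticsBundle:
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    order: np.ndarray
    shapiro_stat: float
    shapiro_p: float


def residual_diagnostics(result: LMMResult, n_bins: int = 30) -> DiagnosticsBundle:
    """Q-Q pairs, residual-vs-fitted, histogram and order plots + Shapiro-Wilk."""
    r = np.asarray(result.residuals, dtype=float)
    n = len(r)
    osm = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    counts, edges = np.histogram(r, bins=n_bins)
    sw = stats.shapiro(r if n <= 5000 else r[:5000])
    return DiagnosticsBundle(
        qq_theoretical=osm, qq_sample=np.sort(r),
        fitted=np.asarray(result.fitted), residuals=r,
        hist_counts=counts, hist_edges=edges,
        order=np.arange(n), shapiro_stat=float(sw.statistic),
        shapiro_p=float(sw.pvalue),
    )


def summarize_effects(result: LMMResult) -> dict:
    """Effect report on the normalised scale and as percent of patient max.

    Only meaningful after the patient_max transform, where a coefficient of
    0.033 reads as a 3.3% difference relative to each patient's maximum.
    """
    if result.transform != "patient_max":
        raise ValueError("effect summary requires a patient_max-transformed fit; "
                         f"got {result.transform!r}")
    return {
        "metric": result.metric,
        "normal_mean": result.beta0,
        "difference": result.beta1,
        "thin_mean": result.beta0 + result.beta1,
        "difference_pct_of_max": result.beta1 * 100.0,
        "ci": (result.ci_low, result.ci_high),
        "ci_pct_of_max": (result.ci_low * 100.0, result.ci_high * 100.0),
        "p_value": result.p_value,
    }
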