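"""Covariate-adjusted CVR-structure association models.

Cross-sectional models regress a wave-2 structural outcome on CVR adjusting
for age at wave 2 and sex (plus total grey-matter volume for hippocampal
volume outcomes); longitudinal models regress a standardized change score on
CVR adjusting for age at wave 1, sex, and the inter-wave interval. Effect
sizes are Cohen's f2 (overall model and per predictor), residual normality
is reported via the Shapiro-Wilk test (never used to discard a fit), and
p-values are Benjamini-Hochberg adjusted within each family of four
white-matter tracts per diffusion metric. Single-test outcomes (grey-matter
volume, white-matter hyperintensities) carry no adjusted p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .longitudinal import zscore_wave

TRACTS = ("corpus_callosum", "cingulum_bundle", "internal_capsule", "fornix")
DIFFUSION_METRICS = ("fa", "md", "rd", "l1")

#: Sex is coded as a binary indicator, male = 1, female (reference) = 0.
SEX_CODING = {"F": 0.0, "M": 1.0}


@dataclass(frozen=True)
class ModelSpec:
    """One association model: outcome ~ exposure + covariates."""

    outcome: str
    exposure: str
    covariates: Tuple[str, ...]
    family: Optional[str] = None  # FDR family id, e.g. "fa" (4 tracts)

    def __post_init__(self) -> None:
        if self.exposure in self.covariates:
            raise ValueError("exposure must not appear among the covariates")


@dataclass
class ModelResult:
    """Fit summary for one association model."""

    spec: ModelSpec
    beta: float
    ci_low: float
    ci_high: float
    p: float
    f2_overall: Optional[float]
    f2_exposure: Optional[float]
    shapiro_w: Optional[float]
    shapiro_p: Optional[float]
    n: int
    p_adjusted: Optional[float] = None

    def as_row(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "exposure": self.spec.exposure,
            "covariates": "+".join(self.spec.covariates),
            "family": self.spec.family,
            "n": self.n,
            "beta": self.beta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "f2_overall": self.f2_overall,
            "f2_exposure": self.f2_exposure,
            "shapiro_w": self.shapiro_w,
            "shapiro_p": self.shapiro_p,
        }


def _encode_column(series: pd.Series) -> pd.Series:
    """Numeric view of a design column; sex labels become a male indicator."""
    if series.dtype == object or str(series.dtype) == "category":
        mapped = series.map(SEX_CODING)
        if mapped.isna().any():
            bad = sorted(set(series[mapped.isna()]))
            raise ValueError(f"cannot encode non-numeric values {bad}")
        return mapped.astype(float)
    return series.astype(float)


def fit_association(
    data: pd.DataFrame,
    spec: ModelSpec,
    compute_f2: bool = True,
    compute_shapiro: bool = True,
) -> ModelResult:
    """OLS fit of one association model on complete cases.

    Returns the exposure coefficient with its two-sided t-test p-value and
    95% confidence interval, Cohen's f2 for the whole model and for the
    exposure (R2 increment over the model without it), and the Shapiro-Wilk
    statistic of the residuals.
    """
    columns = [spec.outcome, spec.exposure, *spec.covariates]
    missing = [c for c in columns if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sub = data[columns].dropna()
    n = len(sub)
    n_predictors = 1 + len(spec.covariates)
    if n < n_predictors + 2:
        raise ValueError(
            f"insufficient complete cases (n={n}) for {n_predictors} predictors"
        )
    y = sub[spec.outcome].astype(float).to_numpy()
    X_cols = [_encode_column(sub[c]).to_numpy() for c in (spec.exposure, *spec.covariates)]
    X = sm.add_constant(np.column_stack(X_cols), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    beta_idx = 1  # exposure is the first regressor after the constant

    f2_overall = f2_exposure = None
    if compute_f2:
        f2_overall = cohens_f2(res.rsquared)
        X_red = np.delete(X, beta_idx, axis=1)
        r2_red = sm.OLS(y, X_red).fit().rsquared
        f2_exposure = cohens_f2(res.rsquared, r2_red)

    sw_w = sw_p = None
    if compute_shapiro:
        sw_w, sw_p = stats.shapiro(res.resid)
        sw_w, sw_p = float(sw_w), float(sw_p)

    return ModelResult(
        spec=spec,
        beta=float(res.params[beta_idx]),
        ci_low=float(ci[beta_idx, 0]),
        ci_high=float(ci[beta_idx, 1]),
        p=float(res.pvalues[beta_idx]),
        f2_overall=f2_overall,
        f2_exposure=f2_exposure,
        shapiro_w=sw_w,
        shapiro_p=sw_p,
        n=n,
    )


def cohens_f2(r2_full: float, r2_reduced: Optional[float] = None) -> float:
    """Cohen's f2 effect size.

    Overall model: f2 = R2 / (1 - R2). Per predictor:
    f2 = (R2_full - R2_reduced) / (1 - R2_full), where the reduced model
    drops that predictor.
    """
    if not 0 <= r2_full < 1:
        raise ValueError("R2 must lie in [0, 1)")
    if r2_reduced is None:
        return r2_full / (1.0 - r2_full)
    if not 0 <= r2_reduced <= r2_full:
        raise ValueError("need 0 <= R2_reduced <= R2_full")
    return (r2_full - r2_reduced) / (1.0 - r2_full)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# The full association suite


def _cross_sectional_specs(exposure: str) -> List[ModelSpec]:
    cov = ("age_w2", "sex")
    specs = [
        ModelSpec("gmv_left_hippocampus_w2", "cvr_left_hipp" if exposure == "hippocampal" else exposure, cov + ("gmv_total_w2",), family=None),
        ModelSpec("gmv_right_hippocampus_w2", "cvr_right_hipp" if exposure == "hippocampal" else exposure, cov + ("gmv_total_w2",), family=None),
    ]
    tract_exposure = "cvr_hipp" if exposure == "hippocampal" else exposure
    for m in DIFFUSION_METRICS:
        for t in TRACTS:
            specs.append(ModelSpec(f"{m}_{t}_w2", tract_exposure, cov, family=m))
    specs.append(ModelSpec("log_wmh_pct_w2", tract_exposure, cov, family=None))
    return specs


def _longitudinal_specs(exposure: str) -> List[ModelSpec]:
    cov = ("age_w1", "sex", "interval_years")
    specs = [
        ModelSpec("delta_gmv_left_hippocampus", "cvr_left_hipp" if exposure == "hippocampal" else exposure, cov, family=None),
        ModelSpec("delta_gmv_right_hippocampus", "cvr_right_hipp" if exposure == "hippocampal" else exposure, cov, family=None),
    ]
    tract_exposure = "cvr_hipp" if exposure == "hippocampal" else exposure
    for m in DIFFUSION_METRICS:
        for t in TRACTS:
            specs.append(ModelSpec(f"delta_{m}_{t}", tract_exposure, cov, family=m))
    specs.append(ModelSpec("delta_log_wmh_pct", tract_exposure, cov, family=None))
    return specs


def prepare_longitudinal_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach standardized change scores to a wide two-wave cohort table.

    Every ``<metric>_w1``/``<metric>_w2`` pair of z-scored families (GMV and
    diffusion metrics) yields ``delta_<metric>`` = z-score difference; WMH
    (already log-percent) yields the plain difference.
    """
    out = cohort.copy()
    w1_cols = [c for c in cohort.columns if c.endswith("_w1") and c != "age_w1"]
    for c1 in w1_cols:
        metric = c1[: -len("_w1")]
        c2 = f"{metric}_w2"
        if c2 not in cohort.columns:
            continue
        if metric.startswith("log_wmh"):
            out[f"delta_{metric}"] = cohort[c2] - cohort[c1]
        else:
            z1 = zscore_wave(cohort[c1].to_numpy())
            z2 = zscore_wave(cohort[c2].to_numpy())
            out[f"delta_{metric}"] = z2 - z1
    return out


def run_association_suite(
    data: pd.DataFrame,
    design: str = "cross_sectional",
    exposure: str = "hippocampal",
    compute_f2: bool = True,
    compute_shapiro: bool = True,
) -> pd.DataFrame:
    """Fit the full association design and BH-adjust within tract families.

    ``design`` is ``"cross_sectional"`` (wave-2 outcomes) or
    ``"longitudinal"`` (standardized change outcomes; ``data`` must already
    carry ``delta_`` columns, see :func:`prepare_longitudinal_table`).
    ``exposure`` is ``"hippocampal"`` (left/right hippocampal CVR for the
    hippocampal-volume models, their average for tracts and WMH) or
    ``"whole_brain"`` (the ``cvr_whole_brain`` column throughout).

    Returns one row per model with beta, 95% CI, p, within-family adjusted p
    (NaN for the single-test GMV and WMH models), and Cohen's f2 values.
    """
    if design == "cross_sectional":
        specs = _cross_sectional_specs(
            "hippocampal" if exposure == "hippocampal" else "cvr_whole_brain"
        )
    elif design == "longitudinal":
        specs = _longitudinal_specs(
            "hippocampal" if exposure == "hippocampal" else "cvr_whole_brain"
        )
    else:
        raise ValueError("design must be 'cross_sectional' or 'longitudinal'")

    needed = sorted({c for s in specs for c in (s.outcome, s.exposure, *s.covariates)})
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")

    results = [
        fit_association(data, s, compute_f2=compute_f2, compute_shapiro=compute_shapiro)
        for s in specs
    ]

    by_family: Dict[str, List[ModelResult]] = {}
    for r in results:
        if r.spec.family is not None:
            by_family.setdefault(r.spec.family, []).append(r)
    for fam, members in by_family.items():
        adjusted = bh_adjust([m.p for m in members])
        for m, q in zip(members, adjusted):
            m.p_adjusted = float(q)

    table = pd.DataFrame([r.as_row() for r in results])
    table.attrs["design"] = design
    table.attrs["exposure"] = exposure
    table.attrs["note"] = (
        "Hippocampal-volume models additionally adjust for total grey-matter "
        "volume; reported methods for those models vary between age+sex and "
        "age+sex+total GMV, and the latter is used here."
    )
    return table
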