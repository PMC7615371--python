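"""Cohort-level statistics: dose-response tests for the volunteer arm and
the mixed-effects heart-rate model for the clinical arm.

Volunteer metrics are summarised in non-overlapping 5-minute segments and
rank-correlated with the segment-mean effect-site concentration; heart rate
is additionally regressed on concentration by OLS with 95% CIs, and effect
sizes between baseline and peak-anesthesia windows are Cohen's d.  The
clinical table is artifact-filtered and median-smoothed, then fit with a
linear mixed model: eleven fixed effects (demographics, three drugs and
their pairwise interactions) and a per-patient random intercept, by REML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as st

logger = logging.getLogger("corticocardiac")

HR_BOUNDS = (10.0, 250.0)
MEDIAN_WINDOW_S = 120.0

FIXED_EFFECT_LABELS = [
    "Intercept", "Age", "BMI", "ASA", "Sex = F",
    "Propofol [ug/ml]", "Fentanyl [ng/ml]", "Desflurane [%]",
    "Propofol*Fentanyl", "Propofol*Desflurane", "Fentanyl*Desflurane",
]

GLM_FORMULA = (
    "hr_bpm ~ age + bmi + asa + sex_f + prop_ugml + fent_ngml + des_pct"
    " + prop_ugml:fent_ngml + prop_ugml:des_pct + fent_ngml:des_pct"
)


@dataclass
class SegmentSeries:
    """Paired per-segment metric and concentration values."""

    segment_starts: np.ndarray
    values: np.ndarray
    ce_values: np.ndarray

    def __post_init__(self) -> None:
        if not (self.segment_starts.size == self.values.size == self.ce_values.size):
            raise ValueError("segment series must have equal lengths")


@dataclass
class ClinicalModelFit:
    """Coefficient table of the mixed-effects heart-rate model."""

    table: pd.DataFrame          # rows = fixed effects; estimate/CI/SE/t/p
    random_intercept_var: float  # bpm^2
    n_patients: int
    n_observations: int
    converged: bool

    def __post_init__(self) -> None:
        bad = (self.table["lower"] > self.table["estimate"]) | \
              (self.table["estimate"] > self.table["upper"])
        if bad.any():
            raise ValueError("confidence interval does not bracket its estimate")

    def coefficient(self, label: str) -> pd.Series:
        return self.table.loc[label]


def segment_means(times: np.ndarray, values: np.ndarray, t_start: float,
                  t_end: float, segment_s: float = 300.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Mean of an irregular series over non-overlapping fixed segments.

    Returns (segment start times, per-segment means); empty segments give
    NaN.  Partial trailing segments are dropped.
    """
    starts, means = [], []
    s = t_start
    while s + segment_s <= t_end + 1e-9:
        mask = (times >= s) & (times < s + segment_s)
        starts.append(s)
        means.append(float(np.mean(values[mask])) if mask.any() else float("nan"))
        s += segment_s
    return np.asarray(starts), np.asarray(means)


def spearman_dose_response(series: SegmentSeries) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties, two-sided p) between the
    segment metric and concentration.  NaN on constant input."""
    ok = np.isfinite(series.values) & np.isfinite(series.ce_values)
    v, c = series.values[ok], series.ce_values[ok]
    if v.size < 5:
        raise ValueError("need at least 5 segments")
    if np.ptp(v) == 0 or np.ptp(c) == 0:
        logger.info("spearman_dose_response: constant input")
        return float("nan"), float("nan")
    rho, p = st.spearmanr(c, v)
    return float(rho), float(p)


def linear_dose_response(hr_segments: np.ndarray, ce_segments: np.ndarray
                         ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """OLS of segment-mean heart rate on concentration.

    Returns ``(intercept, slope, intercept_ci, slope_ci)`` with 95% CIs.
    """
    ok = np.isfinite(hr_segments) & np.isfinite(ce_segments)
    y, x = np.asarray(hr_segments)[ok], np.asarray(ce_segments)[ok]
    if y.size < 10:
        raise ValueError("need at least 10 segment pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: constant concentration")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return (float(fit.params[0]), float(fit.params[1]),
            np.asarray(ci[0]), np.asarray(ci[1]))


def effect_size_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Cohen's d, (mean_b − mean_a) / pooled SD.  NaN when the pooled SD
    is zero."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    pooled = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                     / (a.size + b.size - 2))
    if pooled == 0:
        logger.info("effect_size_d: zero pooled SD")
        return float("nan")
    return float((b.mean() - a.mean()) / pooled)


def hr_vs_sw_frequency(mean_hr: np.ndarray, mean_sw_freq: np.ndarray
                       ) -> tuple[float, float]:
    """Pearson correlation (two-sided p) between subjects' mean heart rate
    and mean slow-wave frequency."""
    hr = np.asarray(mean_hr, dtype=float)
    f = np.asarray(mean_sw_freq, dtype=float)
    if hr.size < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(hr) == 0 or np.ptp(f) == 0:
        logger.info("hr_vs_sw_frequency: zero variance")
        return float("nan"), float("nan")
    r, p = st.pearsonr(hr, f)
    return float(r), float(p)


# --------------------------------------------------------------------------
# Clinical arm
# --------------------------------------------------------------------------

def preprocess_clinical_hr(table: pd.DataFrame) -> pd.DataFrame:
    """Artifact-filter and smooth the clinical heart-rate series.

    Heart rates outside [10, 250] bpm are set to missing first; each
    patient's series is then smoothed with a centered 2-minute moving median
    that ignores missing values.  All-missing patients are dropped with a
    warning.  Idempotent: the median filter preserves in-range values'
    range, so a second pass changes nothing structurally.
    """
    out = table.copy()
    hr = out["hr_bpm"].to_numpy(dtype=float)
    bad = (hr < HR_BOUNDS[0]) | (hr > HR_BOUNDS[1])
    if bad.any():
        logger.info("preprocess_clinical_hr: masked %d off-scale values", int(bad.sum()))
    hr[bad] = np.nan
    out["hr_bpm"] = hr

    interval = float(np.median(np.diff(np.unique(out["t_s"]))))
    win = max(1, int(round(MEDIAN_WINDOW_S / interval)))

    def smooth(g: pd.Series) -> pd.Series:
        return g.rolling(win, center=True, min_periods=1).median()

    out["hr_bpm"] = out.groupby("patient_id", group_keys=False)["hr_bpm"].apply(smooth)
    empty = out.groupby("patient_id")["hr_bpm"].apply(lambda s: s.isna().all())
    if empty.any():
        dropped = empty[empty].index.tolist()
        logger.warning("preprocess_clinical_hr: dropped all-missing patients %s", dropped)
        out = out[~out["patient_id"].isin(dropped)]
    return out


def fit_clinical_glm(table: pd.DataFrame,
                     thin_s: float | None = MEDIAN_WINDOW_S) -> ClinicalModelFit:
    """Fit the mixed-effects heart-rate model by REML.

    Fixed effects: age, BMI, ASA (numeric 2/3), sex (female = 1), the three
    drug effect-site concentrations and their pairwise interactions; random
    intercept per patient.  Rows with missing heart rate are dropped.

    The 2-minute moving median leaves roughly one independent heart-rate
    value per window, so by default the samples are thinned to one per
    ``thin_s`` seconds before fitting; this keeps the residual-independence
    assumption behind the Wald intervals honest.  Pass ``thin_s=None`` to
    fit every sample.
    """
    df = table.dropna(subset=["hr_bpm"]).copy()
    # samples whose smoothing window was truncated at a record edge are
    # asymmetric medians; exclude the half-window margins from the fit
    half = MEDIAN_WINDOW_S / 2.0
    margins = df.groupby("patient_id")["t_s"].agg(["min", "max"])
    lo = df["patient_id"].map(margins["min"]) + half
    hi = df["patient_id"].map(margins["max"]) - half
    df = df[(df["t_s"] >= lo) & (df["t_s"] <= hi)]
    if thin_s is not None:
        interval = float(np.median(np.diff(np.unique(df["t_s"]))))
        stride = max(1, int(round(thin_s / interval)))
        df = df[(np.round(df["t_s"] / interval).astype(int) % stride) == 0]
    if df["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients")
    df["sex_f"] = (df["sex"] == "F").astype(float)
    df["asa"] = df["asa"].astype(float)

    model = smf.mixedlm(GLM_FORMULA, df, groups=df["patient_id"])
    fit = model.fit(reml=True)
    if not fit.converged:
        logger.warning("fit_clinical_glm: REML fit did not converge")

    order = ["Intercept", "age", "bmi", "asa", "sex_f",
             "prop_ugml", "fent_ngml", "des_pct",
             "prop_ugml:fent_ngml", "prop_ugml:des_pct", "fent_ngml:des_pct"]
    ci = fit.conf_int(alpha=0.05)
    rows = []
    for name in order:
        rows.append({
            "estimate": float(fit.params[name]),
            "lower": float(ci.loc[name, 0]),
            "upper": float(ci.loc[name, 1]),
            "se": float(fit.bse[name]),
            "t": float(fit.tvalues[name]),
            "p": float(fit.pvalues[name]),
        })
    tab = pd.DataFrame(rows, index=FIXED_EFFECT_LABELS)
    return ClinicalModelFit(
        table=tab,
        random_intercept_var=float(np.asarray(fit.cov_re).ravel()[0]),
        n_patients=int(df["patient_id"].nunique()),
        n_observations=int(df.shape[0]),
        converged=bool(fit.converged),
    )
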