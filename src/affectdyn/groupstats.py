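"""Group-level validation of derivative decoders.

The measure of interest is the true numerical derivative of the decoded
affect series; the predictor is the neurally decoded derivative.  Per
subject we fit an OLS slope with a t-test against zero; at the group level
a linear mixed-effects model with subject-wise random intercepts and
slopes estimates the fixed effect of the decoded derivative.  A two-stage
fallback (one-sample t over per-subject slopes) stands in whenever the
random-effects fit is singular or fails to converge, and is also reported
as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = ["ValidationFit", "per_subject_validation", "group_fixed_effect"]


@dataclass
class ValidationFit:
    fixed_slope: float
    ci95: tuple[float, float]
    p: float
    r2_adj: float  # pooled, from fitted (incl. random effects) vs observed
    r2_adj_marginal: float  # fixed effect only
    per_subject: pd.DataFrame  # subject, slope, p
    n_significant: int
    method: str  # "mixed" | "two-stage"
    meta: dict = field(default_factory=dict)


def per_subject_validation(pairs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """OLS slope of true on decoded per subject, with t-test on the slope.

    ``pairs`` needs columns subject, true, decoded; rows with non-finite
    entries are dropped.  Raises if a subject's decoded series is constant.
    """
    rows = []
    for sid, sub in pairs.groupby("subject"):
        ok = np.isfinite(sub["true"]) & np.isfinite(sub["decoded"])
        sub = sub[ok]
        if len(sub) < 3:
            raise ValueError(f"subject {sid}: fewer than 3 finite pairs")
        x = sub["decoded"].to_numpy(dtype=float)
        y = sub["true"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"subject {sid}: constant decoded series")
        res = stats.linregress(x, y)
        rows.append((sid, float(res.slope), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["subject", "slope", "p"])
    out["significant"] = out["p"] < alpha
    return out


def _adjusted_r2(y: np.ndarray, fitted: np.ndarray, k_params: int) -> float:
    n = y.size
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0 or n - k_params - 1 <= 0:
        return np.nan
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k_params - 1)


def _two_stage(per_sub: pd.DataFrame) -> tuple[float, tuple[float, float], float]:
    slopes = per_sub["slope"].to_numpy(dtype=float)
    mean = float(slopes.mean())
    sem = slopes.std(ddof=1) / np.sqrt(slopes.size)
    tcrit = stats.t.ppf(0.975, slopes.size - 1)
    t_val, p_val = stats.ttest_1samp(slopes, 0.0)
    return mean, (mean - tcrit * sem, mean + tcrit * sem), float(p_val)


def group_fixed_effect(pairs: pd.DataFrame, alpha: float = 0.05) -> ValidationFit:
    """Mixed-effects estimate of the group slope of true on decoded.

    Random intercept and random slope per subject; the fixed effect of the
    decoded derivative is tested against zero (Wald).  Adjusted R-squared is
    computed on pooled fitted-vs-observed values with a parameter-count
    correction (k = 2 fixed parameters); the marginal variant uses the
    fixed effect only.
    """
    data = pairs.copy()
    data = data[np.isfinite(data["true"]) & np.isfinite(data["decoded"])]
    if data["subject"].nunique() < 3:
        raise ValueError("need >= 3 subjects for a group fixed effect")
    per_sub = per_subject_validation(data, alpha=alpha)
    n_sig = int(per_sub["significant"].sum())

    method = "mixed"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "true ~ decoded", data, groups=data["subject"], re_formula="~decoded"
            )
            fit = model.fit(reml=True, method="lbfgs")
        if not np.isfinite(fit.params["decoded"]) or not np.isfinite(
            fit.bse["decoded"]
        ) or fit.bse["decoded"] == 0:
            raise ValueError("singular mixed-effects fit")
        slope = float(fit.params["decoded"])
        ci = fit.conf_int().loc["decoded"]
        ci95 = (float(ci[0]), float(ci[1]))
        p = float(fit.pvalues["decoded"])
        # MixedLM fittedvalues already include the subject random effects
        fitted = np.asarray(fit.fittedvalues)
        y = data["true"].to_numpy(dtype=float)
        r2_adj = _adjusted_r2(y, fitted, k_params=2)
        x = data["decoded"].to_numpy(dtype=float)
        r2_adj_marg = _adjusted_r2(y, float(fit.params["Intercept"]) + slope * x, k_params=2)
    except (ValueError, KeyError, np.linalg.LinAlgError):
        method = "two-stage"
        slope, ci95, p = _two_stage(per_sub)
        x = data["decoded"].to_numpy(dtype=float)
        y = data["true"].to_numpy(dtype=float)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        r2_adj = r2_adj_marg = _adjusted_r2(y, np.asarray(ols.fittedvalues), k_params=2)

    return ValidationFit(
        fixed_slope=slope,
        ci95=ci95,
        p=p,
        r2_adj=float(r2_adj),
        r2_adj_marginal=float(r2_adj_marg),
        per_subject=per_sub,
        n_significant=n_sig,
        method=method,
        meta={"n_subjects": int(data["subject"].nunique()), "n_pairs": int(len(data))},
    )
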