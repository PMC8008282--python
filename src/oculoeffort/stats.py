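"""Inferential layer: correlations, goodness-of-fit, OLS, and nested LMMs.

The mixed model mirrors a two-level nested design: random intercepts for
experimental condition and for participant nested in condition, with fixed
effects of condition (treatment-coded, neutral reference), number of acquired
cues, and their interaction. Models are fitted by maximum likelihood so the
full model can be compared to the intercept-only null with a likelihood-ratio
test. With only three condition levels the condition-level variance is weakly
identified; it may legitimately collapse to zero and is reported as such.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gaze_io import GazeValidationError

__all__ = [
    "CorrTest",
    "GofResult",
    "FixedEffect",
    "LMMResult",
    "pearson_with_t",
    "chisq_gof",
    "fit_simple_regression",
    "fit_lmm",
]


@dataclass(frozen=True)
class CorrTest:
    r: float
    n: int
    t: float
    p: float

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass(frozen=True)
class GofResult:
    chi2: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray


@dataclass(frozen=True)
class FixedEffect:
    name: str
    estimate: float
    se: float
    t: float
    approx_df: float
    p: float


@dataclass(frozen=True)
class OLSFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    f_stat: float
    f_p: float
    n: int


@dataclass
class LMMResult:
    dv: str
    fixed_effects: list[FixedEffect]
    var_participant: float
    var_condition: float
    var_residual: float
    loglik: float
    null_loglik: float
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    pseudo_r2_total: float
    n_obs: int
    converged: bool = True

    def effect(self, name: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(name)


def pearson_with_t(x: np.ndarray, y: np.ndarray) -> CorrTest:
    """Pearson r with its t statistic, t = r sqrt(n-2) / sqrt(1-r^2).

    Pairs with a missing member are dropped; needs n >= 3 complete pairs and
    nonzero variance in both vectors. A perfect correlation yields an
    infinite t with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise GazeValidationError("correlation needs >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise GazeValidationError("degenerate input: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0 - 1e-15:
        return CorrTest(r=math.copysign(1.0, r), n=n, t=math.copysign(math.inf, r), p=0.0)
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df)
    return CorrTest(r=r, n=n, t=t, p=float(p))


def chisq_gof(observed: np.ndarray, probs: np.ndarray) -> GofResult:
    """Chi-square goodness of fit of counts against a probability vector."""
    observed = np.asarray(observed, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if np.any(observed < 0) or observed.sum() <= 0:
        raise GazeValidationError("observed counts must be >= 0 and sum > 0")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise GazeValidationError("probs must sum to 1")
    expected = observed.sum() * probs
    if np.any(expected == 0):
        raise GazeValidationError("expected count of 0 in some cell")
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    dfree = len(observed) - 1
    p = float(sps.chi2.sf(chi2, dfree))
    return GofResult(chi2=chi2, df=dfree, p=p, observed=observed, expected=expected)


def fit_simple_regression(x: np.ndarray, y: np.ndarray) -> OLSFit:
    """Ordinary least squares of y on x with SEs, R-squared and overall F."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise GazeValidationError("regression needs >= 3 points")
    if np.ptp(x) == 0:
        raise GazeValidationError("degenerate design: constant predictor")
    mx, my = x.mean(), y.mean()
    sxx = float(np.sum((x - mx) ** 2))
    sxy = float(np.sum((x - mx) * (y - my)))
    slope = sxy / sxx
    intercept = my - slope * mx
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - my) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dfe = n - 2
    sigma2 = ss_res / dfe if dfe > 0 else 0.0
    slope_se = math.sqrt(sigma2 / sxx)
    intercept_se = math.sqrt(sigma2 * (1.0 / n + mx**2 / sxx))
    if ss_res == 0:
        f_stat, f_p = math.inf, 0.0
    else:
        f_stat = (ss_tot - ss_res) / (ss_res / dfe)
        f_p = float(sps.f.sf(f_stat, 1, dfe))
    return OLSFit(
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=intercept_se,
        r_squared=min(max(r2, 0.0), 1.0),
        f_stat=f_stat,
        f_p=f_p,
        n=n,
    )


_FE_NAME_MAP = {
    "Intercept": "intercept",
    "C(condition, Treatment('neutral'))[T.aversive]": "condition[aversive]",
    "C(condition, Treatment('neutral'))[T.erotic]": "condition[erotic]",
    "n_cues": "n_cues",
    "C(condition, Treatment('neutral'))[T.aversive]:n_cues": "condition[aversive]:n_cues",
    "C(condition, Treatment('neutral'))[T.erotic]:n_cues": "condition[erotic]:n_cues",
}


def _fit_mixedlm(formula: str, data: pd.DataFrame):
    import statsmodels.formula.api as smf

    model = smf.mixedlm(
        formula,
        data=data,
        groups=data["condition"],
        re_formula="1",
        vc_formula={"participant": "0 + C(participant)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=500)
        except Exception:
            res = model.fit(reml=False, method="powell", maxiter=2000)
        if not res.converged:
            res = model.fit(reml=False, method="powell", maxiter=2000)
    return res


def fit_lmm(rows: pd.DataFrame, dv: str, with_fixed: bool = True) -> LMMResult:
    """Two-level nested linear mixed model for one dependent measure.

    ``rows`` must carry columns participant, condition, n_cues and the DV.
    Random intercepts: condition, and participant nested in condition (the
    participant factor is coded within condition groups). Fixed part: either
    intercept only (``with_fixed=False``) or condition + n_cues +
    condition:n_cues with neutral as the reference level. Estimation is ML;
    the LRT compares the full against the intercept-only null on the same
    rows. Wald t statistics use a residual-style df approximation
    (n_obs - n_fixed_parameters); pseudo-R^2 (total) is the squared
    correlation between fitted (fixed + predicted random) and observed
    values.
    """
    required = {"participant", "condition", "n_cues", dv}
    missing = required - set(rows.columns)
    if missing:
        raise GazeValidationError(f"analysis table lacks columns {sorted(missing)}")
    data = rows.dropna(subset=[dv]).copy()
    data["n_cues"] = data["n_cues"].astype(float)
    counts = data.groupby("condition")["participant"].nunique()
    if (counts < 2).any():
        raise GazeValidationError("need >= 2 participants per condition")

    full_formula = f"{dv} ~ C(condition, Treatment('neutral')) * n_cues"
    null_formula = f"{dv} ~ 1"
    res_null = _fit_mixedlm(null_formula, data)
    if with_fixed:
        res = _fit_mixedlm(full_formula, data)
    else:
        res = res_null

    if not res.converged:
        raise RuntimeError(
            f"mixed model for {dv} did not converge: "
            f"{getattr(res, 'optim_results', None)}"
        )

    n_obs = int(res.nobs)
    k_fixed = len(res.fe_params)
    approx_df = max(n_obs - k_fixed, 1)
    fes = []
    for raw_name, est in res.fe_params.items():
        se = float(res.bse_fe[raw_name])
        tval = est / se if se > 0 else math.nan
        p = 2.0 * sps.t.sf(abs(tval), approx_df) if se > 0 else math.nan
        fes.append(
            FixedEffect(
                name=_FE_NAME_MAP.get(raw_name, raw_name),
                estimate=float(est),
                se=se,
                t=float(tval),
                approx_df=float(approx_df),
                p=float(p),
            )
        )

    scale = float(res.scale)
    var_condition = float(res.cov_re.iloc[0, 0]) if res.k_re else 0.0
    var_participant = float(res.vcomp[0]) if len(res.vcomp) else 0.0

    llf_full, llf_null = float(res.llf), float(res_null.llf)
    lrt_chi2 = max(2.0 * (llf_full - llf_null), 0.0)
    lrt_df = k_fixed - 1
    lrt_p = float(sps.chi2.sf(lrt_chi2, lrt_df)) if lrt_df > 0 else 1.0
    fitted = np.asarray(res.fittedvalues, dtype=float)
    endog = np.asarray(data[dv], dtype=float)
    if np.ptp(fitted) == 0 or np.ptp(endog) == 0:
        pseudo_r2 = 0.0
    else:
        pseudo_r2 = float(np.corrcoef(fitted, endog)[0, 1] ** 2)
    return LMMResult(
        dv=dv,
        fixed_effects=fes,
        var_participant=max(var_participant, 0.0),
        var_condition=max(var_condition, 0.0),
        var_residual=scale,
        loglik=llf_full,
        null_loglik=llf_null,
        lrt_chi2=lrt_chi2,
        lrt_df=lrt_df,
        lrt_p=lrt_p,
        pseudo_r2_total=min(max(pseudo_r2, 0.0), 1.0),
        n_obs=n_obs,
        converged=bool(res.converged),
    )
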