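"""The three inferential prongs: indexing, correspondence, flexibility.

* **indexing** -- a random-intercept linear mixed model, NLR ~ 1 + |z| +
  (1 | subject), fitted on single-trial NLRs of the reference or tail
  subset: a positive |z| slope means the response scales with how unlikely
  a tone is.
* **correspondence** -- per-subject trust-region nonlinear least-squares
  fits of a normal curve ``a + normpdf(z, b, c) * d`` (4 parameters) and a
  continuous square approximation ``a + c / (1 + exp((|z - e| - d) * b))``
  (5 parameters) to the 13 z-bin means, compared by paired t-test on
  adjusted r-squared.
* **flexibility** -- pooled OLS polynomial regression (orthogonalized
  centered powers) of order 2 vs order 4 on the five bimodal interval
  means, compared by AIC/BIC: a winning order-4 model with negative
  quadratic and quartic terms signals a two-peaked response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy import stats as sps
from scipy.special import expit

from .errors import InvalidConfigError

logger = logging.getLogger(__name__)

TERM_NAMES = {1: "linear", 2: "quadratic", 3: "cubic", 4: "quartic"}


# ---------------------------------------------------------------------------
# indexing: linear mixed model
# ---------------------------------------------------------------------------


@dataclass
class LMMResult:
    """Fixed-effect summary of the random-intercept model NLR ~ 1 + |z| + (1|subject)."""

    names: tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    df: float
    t_values: np.ndarray
    p_values: np.ndarray
    f_absz: float
    n_obs: int
    n_subjects: int
    group_var: float
    converged: bool

    @property
    def slope(self) -> float:
        return float(self.estimates[1])

    @property
    def slope_p(self) -> float:
        return float(self.p_values[1])

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "estimates": [float(v) for v in self.estimates],
            "se": [float(v) for v in self.se],
            "ci_lower": [float(v) for v in self.ci_lower],
            "ci_upper": [float(v) for v in self.ci_upper],
            "df": float(self.df),
            "t": [float(v) for v in self.t_values],
            "p": [float(v) for v in self.p_values],
            "F_absz": float(self.f_absz),
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "group_var": float(self.group_var),
            "converged": self.converged,
        }


def fit_lmm_absz(
    table: pd.DataFrame,
    subset: str = "tails",
    response: str = "nlr_raw",
    reml: bool = True,
) -> LMMResult:
    """Fit NLR ~ 1 + |z| + (1 | subject) on the requested trial subset.

    ``subset`` is ``reference`` (source_set == "reference") or ``tails``
    (source_set starting with "tail").  Wald t-tests use df = n_obs - p,
    which reproduces the df convention of trial-level mixed-model reports;
    the F statistic for |z| is t squared.  Singular fits (zero
    between-subject variance) fall back to the profiled estimate with a
    warning: estimates then coincide with OLS.
    """
    if subset == "reference":
        data = table[table.source_set.astype(str).eq("reference")]
    elif subset == "tails":
        data = table[table.source_set.astype(str).str.startswith("tail")]
    elif subset == "all":
        data = table
    else:
        raise InvalidConfigError(f"unknown subset {subset!r}")
    data = data[data.retained].dropna(subset=[response, "abs_z"])
    n_subjects = data["subject_id"].nunique()
    if n_subjects < 2:
        raise InvalidConfigError("need >= 2 subjects for a mixed model")

    endog = data[response].to_numpy(dtype=float)
    exog = sm.add_constant(data["abs_z"].to_numpy(dtype=float))
    groups = data["subject_id"].to_numpy()
    model = sm.MixedLM(endog, exog, groups=groups)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=reml)
            converged = bool(fit.converged)
        except Exception:  # singular / non-convergent: profiled fallback
            logger.warning("MixedLM failed; falling back to profiled fit")
            fit = model.fit(reml=reml, method="powell")
            converged = False

    n_obs = len(data)
    p = 2
    dof = n_obs - p
    est = np.asarray(fit.params[:p], dtype=float)
    se = np.asarray(fit.bse[:p], dtype=float)
    t_vals = est / se
    p_vals = 2 * sps.t.sf(np.abs(t_vals), dof)
    t_crit = sps.t.ppf(0.975, dof)
    group_var = float(np.squeeze(fit.cov_re.iloc[0, 0])) if hasattr(fit.cov_re, "iloc") else float(fit.cov_re[0][0])
    return LMMResult(
        names=("(Intercept)", "Abs(z)"),
        estimates=est,
        se=se,
        ci_lower=est - t_crit * se,
        ci_upper=est + t_crit * se,
        df=float(dof),
        t_values=t_vals,
        p_values=p_vals,
        f_absz=float(t_vals[1] ** 2),
        n_obs=n_obs,
        n_subjects=n_subjects,
        group_var=group_var,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# correspondence: normal vs square curve fits
# ---------------------------------------------------------------------------


@dataclass
class CurveFitResult:
    """One per-subject nonlinear curve fit to z-bin means."""

    model: str  # "normal" | "square"
    params: tuple[float, ...]
    r2: float
    adj_r2: float
    n_points: int
    converged: bool
    n_restarts_used: int

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": [float(v) for v in self.params],
            "r2": float(self.r2),
            "adj_r2": float(self.adj_r2),
            "n_points": self.n_points,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }


def normal_curve(z: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    """a + normpdf(z, b, c) * d."""
    return a + sps.norm.pdf(z, b, np.abs(c)) * d


def square_curve(
    z: np.ndarray, a: float, b: float, c: float, d: float, e: float
) -> np.ndarray:
    """a + c / (1 + exp((|z - e| - d) * b)) -- a continuous square approximation.

    Large ``b`` approaches a hard step of height ``c`` over |z - e| < d.
    """
    return a + c * expit(-(np.abs(z - e) - d) * b)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - r2) (n - 1) / (n - p - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _multi_start_fit(fun, starts, bounds, z, y):
    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        try:
            sol = optimize.least_squares(
                fun,
                x0,
                bounds=bounds,
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
                max_nfev=100_000,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost - 1e-15):
            best = sol
    return best, n_used


def fit_normal_curve(bin_means: pd.DataFrame) -> CurveFitResult:
    """Fit ``a + normpdf(z, b, c) * d`` to one subject's z-bin means.

    Deterministic multi-start trust-region least squares (8 starts spanning
    the sign and scale of d and the center b over the data range).
    """
    z = bin_means["bin_center"].to_numpy(dtype=float)
    y = bin_means["mean_negnorm"].to_numpy(dtype=float)
    n = len(z)
    if n < 6:
        raise InvalidConfigError("need >= 6 non-empty bins for curve fitting")

    span = y.max() - y.min() if y.max() > y.min() else 1.0
    zspan = max(z.max() - z.min(), 1.0)
    starts = []
    for b0 in (0.0, float(np.median(z))):
        for c0 in (1.0, zspan / 4):
            for d_sign in (1.0, -1.0):
                d0 = d_sign * span * c0 * np.sqrt(2 * np.pi)
                a0 = y.min() if d_sign > 0 else y.max()
                starts.append([a0, b0, c0, d0])
    lo = [-np.inf, z.min() - zspan, 1e-3, -np.inf]
    hi = [np.inf, z.max() + zspan, 10 * zspan, np.inf]

    def residuals(theta):
        return normal_curve(z, *theta) - y

    best, n_used = _multi_start_fit(residuals, starts, (lo, hi), z, y)
    if best is None:
        return CurveFitResult("normal", (np.nan,) * 4, np.nan, np.nan, n, False, n_used)
    ss_res = float(2 * best.cost)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return CurveFitResult(
        "normal", tuple(float(v) for v in best.x), r2, adjusted_r2(r2, n, 4), n, True, n_used
    )


def fit_square_curve(bin_means: pd.DataFrame) -> CurveFitResult:
    """Fit the continuous square approximation (5 parameters) to z-bin means."""
    z = bin_means["bin_center"].to_numpy(dtype=float)
    y = bin_means["mean_negnorm"].to_numpy(dtype=float)
    n = len(z)
    if n < 6:
        raise InvalidConfigError("need >= 6 non-empty bins for curve fitting")

    span = y.max() - y.min() if y.max() > y.min() else 1.0
    zspan = max(z.max() - z.min(), 1.0)
    starts = []
    for e0 in (0.0, float(np.median(z))):
        for d0 in (1.0, zspan / 4):
            for b0 in (1.0, 4.0):
                starts.append([y.min(), b0, span, d0, e0])
    starts = starts[:8]
    lo = [-np.inf, 1e-3, -np.inf, 1e-3, z.min() - zspan]
    hi = [np.inf, 100.0, np.inf, 10 * zspan, z.max() + zspan]

    def residuals(theta):
        return square_curve(z, *theta) - y

    best, n_used = _multi_start_fit(residuals, starts, (lo, hi), z, y)
    if best is None:
        return CurveFitResult("square", (np.nan,) * 5, np.nan, np.nan, n, False, n_used)
    ss_res = float(2 * best.cost)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return CurveFitResult(
        "square", tuple(float(v) for v in best.x), r2, adjusted_r2(r2, n, 5), n, True, n_used
    )


@dataclass
class PairedComparison:
    """Paired t-test on per-subject fit quality (normal minus square)."""

    metric: str
    mean_normal: float
    sd_normal: float
    mean_square: float
    sd_square: float
    t: float
    df: int
    p: float
    cohen_d: float
    n_pairs: int
    n_normal_wins: int

    def to_dict(self) -> dict:
        return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.__dict__.items()}


def paired_ttest(diff: np.ndarray) -> tuple[float, int, float, float]:
    """Closed-form paired t, df, two-sided p and Cohen's d = mean / SD of differences."""
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:  # identical pairs: no evidence either way
        return 0.0, n - 1, 1.0, 0.0
    d = diff.mean() / sd
    t = d * np.sqrt(n)
    p = 2 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p), float(d)


def compare_adjr2(
    normal_fits: list[CurveFitResult], square_fits: list[CurveFitResult], metric: str = "adj_r2"
) -> PairedComparison:
    """Paired comparison of per-subject normal vs square fit quality.

    Only subjects with both fits converged contribute; Cohen's d is the mean
    difference over the SD of differences (equivalently t / sqrt(n)).
    """
    pairs = [
        (getattr(nf, metric), getattr(sf, metric))
        for nf, sf in zip(normal_fits, square_fits)
        if nf.converged and sf.converged
    ]
    if len(pairs) < 2:
        raise InvalidConfigError("need >= 2 subjects with both fits converged")
    norm_v = np.array([p[0] for p in pairs])
    sq_v = np.array([p[1] for p in pairs])
    t, df, p, d = paired_ttest(norm_v - sq_v)
    return PairedComparison(
        metric=metric,
        mean_normal=float(norm_v.mean()),
        sd_normal=float(norm_v.std(ddof=1)),
        mean_square=float(sq_v.mean()),
        sd_square=float(sq_v.std(ddof=1)),
        t=t,
        df=df,
        p=p,
        cohen_d=d,
        n_pairs=len(pairs),
        n_normal_wins=int((norm_v > sq_v).sum()),
    )


# ---------------------------------------------------------------------------
# flexibility: polynomial order comparison
# ---------------------------------------------------------------------------


@dataclass
class PolyFitResult:
    """One OLS polynomial fit (orthogonalized centered powers)."""

    order: int
    term_names: tuple[str, ...]
    coefficients: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    aic: float
    bic: float
    residual_df: int
    n_obs: int

    def term(self, name: str) -> dict:
        i = self.term_names.index(name)
        return {
            "coef": float(self.coefficients[i]),
            "ci": [float(self.ci_lower[i]), float(self.ci_upper[i])],
            "t": float(self.t_values[i]),
            "p": float(self.p_values[i]),
        }

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "terms": {name: self.term(name) for name in self.term_names},
            "aic": float(self.aic),
            "bic": float(self.bic),
            "residual_df": self.residual_df,
            "n_obs": self.n_obs,
        }


def orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis of the centered predictor (no intercept column).

    Column ``j`` is a degree-(j+1) polynomial orthogonal to all lower
    degrees and the constant, with positive leading coefficient, analogous
    to R's ``poly``.  Coefficient signs are therefore interpretable: a
    negative quartic with a negative quadratic indicates a two-peaked shape.
    """
    xc = x - x.mean()
    v = np.vander(xc, degree + 1, increasing=True)  # 1, x, x^2, ...
    q, r = np.linalg.qr(v)
    # enforce positive leading coefficients so term signs are meaningful
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    return q[:, 1:]


def fit_poly_orders(
    data: pd.DataFrame,
    predictor: str = "interval_rank",
    response: str = "mean_negnorm",
    orders: tuple[int, int] = (2, 4),
    criterion: str = "aic",
) -> dict:
    """Fit competing polynomial orders by OLS and pick a winner by AIC or BIC.

    The predictor is centered and orthogonalized, so each term isolates its
    own degree.  Returns ``{"fits": {order: PolyFitResult}, "winner": order,
    "criterion": str}``.
    """
    if criterion not in ("aic", "bic"):
        raise InvalidConfigError(f"unknown criterion {criterion!r}")
    x = data[predictor].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    fits: dict[int, PolyFitResult] = {}
    for order in orders:
        if len(y) <= order + 1:
            raise InvalidConfigError(f"n_obs={len(y)} too small for order {order}")
        basis = orthogonal_poly(x, order)
        exog = sm.add_constant(basis)
        res = sm.OLS(y, exog).fit()
        ci = res.conf_int()
        fits[order] = PolyFitResult(
            order=order,
            term_names=tuple(TERM_NAMES[j] for j in range(1, order + 1)),
            coefficients=res.params[1:],
            ci_lower=ci[1:, 0],
            ci_upper=ci[1:, 1],
            t_values=res.tvalues[1:],
            p_values=res.pvalues[1:],
            aic=float(res.aic),
            bic=float(res.bic),
            residual_df=int(res.df_resid),
            n_obs=len(y),
        )
    winner = min(orders, key=lambda o: getattr(fits[o], criterion))
    return {"fits": fits, "winner": winner, "criterion": criterion}
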