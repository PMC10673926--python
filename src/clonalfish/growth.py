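"""Per-individual von Bertalanffy growth curves.

The von Bertalanffy growth model describes fish length at age ``t`` (days) as

    L(t) = L_inf * (1 - exp(-K * (t - t0)))

with asymptotic length ``L_inf`` (cm), growth coefficient ``K`` (per day) and
``t0`` (days), the theoretical age at which length is zero.  Curves are fit
per individual by damped (Levenberg-Marquardt) nonlinear least squares with
an analytic Jacobian; ``K > 0`` is enforced by optimising ``log K``.

Predicted sizes from the fitted curves (rather than raw weekly measurements)
supply the size-at-age covariates used throughout the downstream analyses,
e.g. female size at parturition for each brood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConvergenceError, InsufficientDataError, ValidationError

#: canonical column names of the size CSV dialect
SIZE_COLUMNS = ["individual_id", "age_days", "length_cm"]


@dataclass(frozen=True)
class VBParams:
    """Von Bertalanffy parameter triple."""

    L_inf: float  # cm
    K: float      # per day
    t0: float     # days

    def __post_init__(self):
        if not (self.L_inf > 0):
            raise ValidationError(f"L_inf must be > 0, got {self.L_inf}")
        if not (self.K > 0):
            raise ValidationError(f"K must be > 0, got {self.K}")


@dataclass(frozen=True)
class GrowthFit:
    individual_id: str
    params: VBParams
    rss: float
    n_points: int
    converged: bool


def vb_length(t, params: VBParams):
    """Length at age ``t`` (vectorised); may be negative for t < t0."""
    t = np.asarray(t, dtype=float)
    out = params.L_inf * (1.0 - np.exp(-params.K * (t - params.t0)))
    return float(out) if out.ndim == 0 else out


def _exp_term(k: float, t: np.ndarray, t0: float) -> np.ndarray:
    # clipped to keep wild multi-start trials finite
    return np.exp(np.clip(-k * (t - t0), -700.0, 50.0))


def _residuals(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    linf, logk, t0 = theta
    k = math.exp(logk)
    return y - linf * (1.0 - _exp_term(k, t, t0))


def _jacobian(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    linf, logk, t0 = theta
    k = math.exp(logk)
    e = _exp_term(k, t, t0)
    # residual r = y - L(t); dr/dtheta = -dL/dtheta
    return np.column_stack(
        [-(1.0 - e), -linf * k * (t - t0) * e, linf * k * e]
    )


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ford-Walford-style start: L_inf from max length, K and t0 from a
    regression of log(1 - L/L_inf0) on age."""
    linf0 = 1.05 * float(y.max())
    ratio = np.clip(1.0 - y / linf0, 1e-6, None)
    slope, intercept = np.polyfit(t, np.log(ratio), 1)
    k0 = max(-slope, 1e-5)
    t00 = intercept / k0
    # keep the start sane on pathological series
    if not np.isfinite(t00) or abs(t00) > 10 * max(t.max(), 1.0):
        t00 = 0.0
    return np.array([linf0, math.log(k0), t00])


def fit_vb(
    records: pd.DataFrame,
    individual_id: str | None = None,
    ftol: float = 1e-12,
) -> GrowthFit:
    """Fit one individual's growth curve by Levenberg-Marquardt.

    Requires >= 4 records at >= 4 distinct ages.  On non-convergence, three
    perturbed restarts are tried and the best-RSS converged solution is
    returned; a flat (no-growth) series is flagged unconverged rather than
    returning meaningless parameters.
    """
    if individual_id is None:
        ids = records["individual_id"].unique()
        if len(ids) != 1:
            raise ValidationError("records must contain exactly one individual")
        individual_id = str(ids[0])
    t = records["age_days"].to_numpy(dtype=float)
    y = records["length_cm"].to_numpy(dtype=float)
    if len(t) < 4 or len(np.unique(t)) < 4:
        raise InsufficientDataError(
            f"{individual_id}: need >= 4 records at >= 4 distinct ages"
        )
    if np.any(y <= 0):
        raise ValidationError(f"{individual_id}: lengths must be > 0")

    degenerate = float(np.std(y)) < 1e-10
    theta0 = _initial_guess(t, y)
    starts = [theta0]
    for mult in ((1.3, 1.5, 0.0), (0.9, 0.5, 1.0), (1.1, 2.0, -1.0)):
        starts.append(
            np.array(
                [theta0[0] * mult[0], theta0[1] + math.log(mult[1]), mult[2] * 5.0]
            )
        )

    best = None
    for th0 in starts:
        try:
            res = optimize.least_squares(
                _residuals, th0, jac=_jacobian, args=(t, y),
                method="lm", ftol=ftol, xtol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except (ValueError, FloatingPointError):
            continue
        if not res.success or res.x[0] <= 0:
            continue
        rss = float(res.cost * 2.0)
        if best is None or rss < best[1]:
            best = (res.x, rss)
    if best is None or degenerate:
        fallback = VBParams(max(float(y.max()), 1e-6), 1e-6, 0.0)
        return GrowthFit(individual_id, fallback, float("inf"), len(t), False)
    theta, rss = best
    params = VBParams(float(theta[0]), float(math.exp(theta[1])), float(theta[2]))
    return GrowthFit(individual_id, params, rss, len(t), True)


def fit_vb_table(sizes: pd.DataFrame) -> tuple[dict[str, GrowthFit], pd.DataFrame]:
    """Fit every individual in a size table; returns fits keyed by id plus a
    tidy growth-fit table (individual_id, L_inf, K, t0, rss, n_points,
    converged)."""
    fits: dict[str, GrowthFit] = {}
    rows = []
    for ind, sub in sizes.groupby("individual_id", sort=True):
        fit = fit_vb(sub, individual_id=str(ind))
        fits[str(ind)] = fit
        rows.append(
            {
                "individual_id": str(ind),
                "L_inf": fit.params.L_inf,
                "K": fit.params.K,
                "t0": fit.params.t0,
                "rss": fit.rss,
                "n_points": fit.n_points,
                "converged": fit.converged,
            }
        )
    return fits, pd.DataFrame(rows)


def predicted_size_at(fit: GrowthFit, age) -> float | np.ndarray:
    """Predicted length at ``age`` from a converged fit, clamped at 0 with a
    warning for ages at or before t0."""
    if not fit.converged:
        raise ConvergenceError(
            f"{fit.individual_id}: cannot predict from unconverged fit"
        )
    val = vb_length(age, fit.params)
    if np.any(np.asarray(val) < 0):
        warnings.warn(
            f"{fit.individual_id}: predicted size < 0 before t0; clamped to 0",
            stacklevel=2,
        )
        val = np.maximum(val, 0.0)
        if np.ndim(val) == 0:
            val = float(val)
    return val


def k_linf_model(fits_df: pd.DataFrame, mother_ids: pd.Series | dict):
    """Plain regression of L_inf on K and mother ID across individuals.

    Quantifies the inherent coupling between growth rate and asymptotic size
    (faster-growing fish plateau at smaller sizes).  Returns the fitted
    model, its coefficient summary table, and the OLS R^2.
    """
    from . import lmm

    df = fits_df[fits_df["converged"]].copy()
    if len(df) < 5:
        raise InsufficientDataError("k_linf_model needs >= 5 converged fits")
    mothers = pd.Series(mother_ids)
    df["mother_id"] = df["individual_id"].map(mothers).astype(str)
    spec = lmm.ModelSpec("L_inf", ("K", "mother_id"), random_group=None)
    fit = lmm.fit_lmm(df, spec)
    return fit, lmm.summary_table(fit), lmm.r2_ols(fit)
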