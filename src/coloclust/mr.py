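"""Two-sample Mendelian randomization with directionality testing.

Given per-variant effect estimates on an exposure and an outcome from two
GWAS, the inverse-variance-weighted (IVW) estimator regresses outcome effects
on exposure effects through the origin with weights 1/se_outcome^2; Egger
regression frees the intercept (after orienting instruments to the
exposure-increasing allele) to detect directional pleiotropy.  The Steiger
Z-test infers causal direction by comparing the variance the instruments
explain in the exposure versus the outcome: per-variant r^2 is recovered from
summary statistics via the regression identity r^2 = z^2 / (z^2 + n - 2),
summed over instruments, converted to correlations, Fisher-transformed and
differenced.  A positive Z favours exposure -> outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_Z95 = 1.959963985


@dataclass
class InstrumentSet:
    """Aligned per-variant exposure and outcome effects (exposure-increasing
    orientation)."""

    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    n_exposure: int
    n_outcome: int
    eaf: np.ndarray | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = self.beta_exposure.size
        if not all(getattr(self, n).size == k for n in
                   ("se_exposure", "beta_outcome", "se_outcome")):
            raise ValueError("instrument arrays differ in length")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("all standard errors must be positive")

    def __len__(self) -> int:
        return self.beta_exposure.size

    def swapped(self) -> "InstrumentSet":
        """Exchange the exposure and outcome roles."""
        return InstrumentSet(
            beta_exposure=self.beta_outcome, se_exposure=self.se_outcome,
            beta_outcome=self.beta_exposure, se_outcome=self.se_exposure,
            n_exposure=self.n_outcome, n_outcome=self.n_exposure,
            eaf=self.eaf, ids=self.ids,
        )


@dataclass
class MRReport:
    """Estimates, pleiotropy diagnostics and directionality for one pair."""

    ivw_beta: float
    ivw_se: float
    ivw_p: float
    egger_beta: float | None
    egger_se: float | None
    egger_p: float | None
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_p: float | None
    rsq_gx: float
    rsq_gy: float
    steiger_z: float
    steiger_p: float
    inferred_direction: str
    pearson_r: float
    n_instruments: int

    def summary(self) -> str:
        lines = [
            f"MR report ({self.n_instruments} instruments)",
            f"  IVW:    beta {self.ivw_beta:+.4f} (se {self.ivw_se:.4f}), p={self.ivw_p:.3g}",
        ]
        if self.egger_beta is not None:
            lines.append(
                f"  Egger:  beta {self.egger_beta:+.4f} (se {self.egger_se:.4f}), "
                f"p={self.egger_p:.3g}; intercept {self.egger_intercept:+.4f}, "
                f"p={self.egger_intercept_p:.3g}")
        lines += [
            f"  Steiger: r2(g,x)={self.rsq_gx:.4g}, r2(g,y)={self.rsq_gy:.4g}, "
            f"Z={self.steiger_z:+.2f}, p={self.steiger_p:.3g}",
            f"  inferred direction: {self.inferred_direction}",
            f"  effect-size correlation (Pearson r): {self.pearson_r:.3f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def ivw(instruments: InstrumentSet, multiplicative: bool = False) -> tuple[float, float, float]:
    """Fixed-effects IVW estimate: weighted regression through the origin.

    Weights are 1/se_outcome^2.  With ``multiplicative=True`` the standard
    error is inflated by the residual dispersion (floored at 1).
    """
    k = len(instruments)
    if k < 1:
        raise ValueError("need at least one instrument")
    bx, by = instruments.beta_exposure, instruments.beta_outcome
    w = 1.0 / instruments.se_outcome**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se = 1.0 / np.sqrt(sxx)
    if multiplicative and k > 1:
        scale = float(np.sum(w * (by - beta * bx) ** 2) / (k - 1))
        se *= max(1.0, np.sqrt(scale))
    p = 2 * stats.norm.sf(abs(beta / se))
    return beta, float(se), float(p)


def egger(instruments: InstrumentSet):
    """MR-Egger: weighted regression with a free pleiotropy intercept.

    Instruments are first oriented so every exposure effect is positive.
    Standard errors use the residual dispersion floored at 1 and p-values a
    t distribution with k - 2 degrees of freedom.  Returns (slope, slope_se,
    slope_p, intercept, intercept_se, intercept_p).
    """
    k = len(instruments)
    if k < 3:
        raise ValueError("Egger regression needs at least 3 instruments")
    sign = np.where(instruments.beta_exposure < 0, -1.0, 1.0)
    bx = instruments.beta_exposure * sign
    by = instruments.beta_outcome * sign
    w = 1.0 / instruments.se_outcome**2
    X = np.column_stack([np.ones(k), bx])
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * by)
    coef = np.linalg.solve(XtWX, XtWy)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov = np.linalg.inv(XtWX) * max(1.0, sigma2)
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=k - 2)
    return (float(coef[1]), float(se[1]), float(pvals[1]),
            float(coef[0]), float(se[0]), float(pvals[0]))


def steiger(instruments: InstrumentSet) -> tuple[float, float, str]:
    """Directionality test comparing instrument r^2 on exposure vs outcome.

    Per-variant r^2 = z^2/(z^2 + n - 2) (exact for simple linear regression),
    summed over instruments and capped at 1 (with a warning); the summed
    correlations are Fisher-transformed and differenced:

        Z = (atanh r_gx - atanh r_gy) / sqrt(1/(n_x - 3) + 1/(n_y - 3))

    Z > 0 infers exposure -> outcome.
    """
    nx, ny = instruments.n_exposure, instruments.n_outcome
    if nx <= 3 or ny <= 3:
        raise ValueError("sample sizes must exceed 3 for the Fisher transform")
    zx = instruments.beta_exposure / instruments.se_exposure
    zy = instruments.beta_outcome / instruments.se_outcome
    r2x = float(np.sum(zx**2 / (zx**2 + nx - 2)))
    r2y = float(np.sum(zy**2 / (zy**2 + ny - 2)))
    if r2x > 1 or r2y > 1:
        logger.warning("summed instrument r^2 exceeds 1 (%.3f, %.3f); capped", r2x, r2y)
    r2x, r2y = min(r2x, 1.0), min(r2y, 1.0)
    rx, ry = np.sqrt(r2x), np.sqrt(r2y)
    denom = np.sqrt(1.0 / (nx - 3) + 1.0 / (ny - 3))
    z = (np.arctanh(min(rx, 1 - 1e-15)) - np.arctanh(min(ry, 1 - 1e-15))) / denom
    p = 2 * stats.norm.sf(abs(z))
    direction = "exposure->outcome" if z > 0 else ("outcome->exposure" if z < 0 else "undetermined")
    return float(z), float(p), direction


def effect_correlation(instruments: InstrumentSet) -> float:
    """Pearson correlation between exposure and outcome effect sizes
    (the dose-response diagnostic).  NaN when either side has zero variance."""
    if len(instruments) < 3:
        raise ValueError("need at least 3 instruments")
    bx, by = instruments.beta_exposure, instruments.beta_outcome
    if bx.std() == 0 or by.std() == 0:
        logger.warning("effect_correlation undefined: zero variance in effect sizes")
        return float("nan")
    return float(np.corrcoef(bx, by)[0, 1])


class MRModel:
    """Model object bundling the MR estimators for one exposure-outcome pair."""

    def __init__(self, instruments: InstrumentSet, multiplicative_ivw: bool = False):
        self.instruments = instruments
        self.multiplicative_ivw = multiplicative_ivw

    def fit(self) -> MRReport:
        iv = self.instruments
        ivw_b, ivw_se, ivw_p = ivw(iv, multiplicative=self.multiplicative_ivw)
        if len(iv) >= 3:
            eg = egger(iv)
            pearson = effect_correlation(iv)
        else:
            eg = (None,) * 6
            pearson = float("nan")
        # r^2 components recomputed for the report
        zx = iv.beta_exposure / iv.se_exposure
        zy = iv.beta_outcome / iv.se_outcome
        r2x = min(float(np.sum(zx**2 / (zx**2 + iv.n_exposure - 2))), 1.0)
        r2y = min(float(np.sum(zy**2 / (zy**2 + iv.n_outcome - 2))), 1.0)
        st_z, st_p, direction = steiger(iv)
        return MRReport(
            ivw_beta=ivw_b, ivw_se=ivw_se, ivw_p=ivw_p,
            egger_beta=eg[0], egger_se=eg[1], egger_p=eg[2],
            egger_intercept=eg[3], egger_intercept_se=eg[4], egger_intercept_p=eg[5],
            rsq_gx=r2x, rsq_gy=r2y,
            steiger_z=st_z, steiger_p=st_p, inferred_direction=direction,
            pearson_r=pearson, n_instruments=len(iv),
        )


def mr_report(instruments: InstrumentSet, **kwargs) -> MRReport:
    """Convenience wrapper: ``MRModel(instruments, **kwargs).fit()``."""
    return MRModel(instruments, **kwargs).fit()
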