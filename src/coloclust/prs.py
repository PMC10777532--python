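"""Partitioned polygenic risk scores and their outcome associations.

A score is the dosage-weighted sum of risk alleles over one cluster's
variants (weights are index-trait meta-analysis effect sizes oriented to the
effect-increasing allele), standardized to mean 0 / SD 1 within the analysed
sample.  Associations with continuous outcomes use ordinary least squares and
with binary outcomes logistic regression, both adjusted for covariates, with
Bonferroni-corrected significance flags and a top-versus-bottom quantile
contrast mirroring the 90th-vs-10th percentile comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import Cohort

logger = logging.getLogger(__name__)


@dataclass
class PRSModel:
    """Weights defining one (cluster or overall) polygenic score."""

    label: str
    weights: dict[str, float]           # variant id -> effect size

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite weight in PRS model {self.label!r}")

    @property
    def variants(self) -> list[str]:
        return list(self.weights)


@dataclass
class AssocConfig:
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "bmi", "cohort"])
    alpha: float = 0.05
    m_tests: int = 6
    top_q: float = 0.9
    bottom_q: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.bottom_q < 1 and 0 < self.top_q < 1 and self.top_q > self.bottom_q):
            raise ValueError("require 0 < bottom_q < top_q < 1")

    @property
    def threshold(self) -> float:
        return self.alpha / self.m_tests


def bonferroni_threshold(alpha: float = 0.05, m_tests: int = 6) -> float:
    """Multiple-testing-corrected significance level alpha / m."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests


@dataclass
class AssocResult:
    """One score-outcome association (beta in outcome SD, or odds ratio)."""

    label: str
    outcome: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    significant_after_bonferroni: bool
    binary: bool = False

    def summary(self) -> str:
        kind = "OR" if self.binary else "beta"
        star = " *" if self.significant_after_bonferroni else ""
        return (f"{self.label} -> {self.outcome}: {kind} {self.estimate:.3f} "
                f"(95% CI {self.ci_low:.3f}-{self.ci_high:.3f}), p={self.p:.3g}, "
                f"n={self.n}{star}")


# ---------------------------------------------------------------------------
# Score construction
# ---------------------------------------------------------------------------


def build_prs(cohort: Cohort, model: PRSModel) -> np.ndarray:
    """Standardized per-individual score: sum of dosage x weight over variants.

    All model variants must be columns of the dosage table.  Missing dosage
    values are mean-imputed (the column mean estimates 2 x allele frequency),
    with a logged count.  A zero-variance raw score is a degenerate model and
    raises.
    """
    missing_cols = [v for v in model.variants if v not in cohort.dosages.columns]
    if missing_cols:
        raise KeyError(f"variants missing from dosage table: {missing_cols[:5]}")
    dos = cohort.dosages[model.variants].to_numpy(dtype=float)
    n_missing = int(np.isnan(dos).sum())
    if n_missing:
        logger.info("build_prs(%s): mean-imputing %d missing dosages", model.label, n_missing)
        col_means = np.nanmean(dos, axis=0)
        dos = np.where(np.isnan(dos), col_means, dos)
    raw = dos @ np.array([model.weights[v] for v in model.variants], dtype=float)
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError(f"PRS model {model.label!r} yields zero-variance scores")
    return (raw - raw.mean()) / sd


# ---------------------------------------------------------------------------
# Association testing
# ---------------------------------------------------------------------------


def _design(score: np.ndarray, covariates: pd.DataFrame, cfg: AssocConfig,
            outcome_name: str) -> pd.DataFrame:
    cols = [c for c in cfg.covariates if c in covariates.columns]
    # BMI is never its own covariate.
    if outcome_name.lower() == "bmi":
        cols = [c for c in cols if c.lower() != "bmi"]
    X = pd.DataFrame({"score": np.asarray(score, dtype=float)})
    for c in cols:
        X[c] = covariates[c].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        cmat = np.corrcoef(X.to_numpy().T)
        for i in range(len(cmat)):
            for j in range(i + 1, len(cmat)):
                if abs(cmat[i, j]) > 1 - 1e-10:
                    raise ValueError(
                        f"collinear covariates: {X.columns[i]!r} and {X.columns[j]!r}")
        raise ValueError("design matrix is rank deficient")
    return sm.add_constant(X)


def test_association(score: np.ndarray, outcome: np.ndarray | pd.Series,
                     covariates: pd.DataFrame, cfg: AssocConfig | None = None,
                     binary: bool = False, label: str = "prs",
                     outcome_name: str = "outcome") -> AssocResult:
    """Covariate-adjusted association of a standardized score with an outcome.

    Continuous outcomes: OLS with Wald confidence interval (beta in outcome
    SD units when the outcome is standardized).  Binary outcomes: logistic
    regression, estimate reported as an odds ratio with a Wald interval on
    the log-odds scale.
    """
    cfg = cfg or AssocConfig()
    y = np.asarray(outcome, dtype=float)
    n = y.size
    if n <= len(cfg.covariates) + 2:
        raise ValueError("sample too small for the covariate set")
    X = _design(score, covariates, cfg, outcome_name)
    if binary:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = sm.Logit(y, X).fit(disp=0)
        except Exception as exc:
            raise ValueError(f"logistic fit failed (possible perfect separation): {exc}") from exc
        if not np.all(np.isfinite(fit.bse)):
            raise ValueError("logistic fit produced non-finite standard errors "
                             "(perfect separation diagnostic)")
        b, se_b = fit.params["score"], fit.bse["score"]
        p = float(fit.pvalues["score"])
        est, lo, hi = np.exp(b), np.exp(b - 1.959963985 * se_b), np.exp(b + 1.959963985 * se_b)
    else:
        fit = sm.OLS(y, X).fit()
        b, se_b = fit.params["score"], fit.bse["score"]
        p = float(fit.pvalues["score"])
        est, lo, hi = b, b - 1.959963985 * se_b, b + 1.959963985 * se_b
    return AssocResult(
        label=label, outcome=outcome_name, estimate=float(est), se=float(se_b),
        ci_low=float(lo), ci_high=float(hi), p=p, n=int(n),
        significant_after_bonferroni=p < cfg.threshold, binary=binary,
    )


def decile_contrast(score: np.ndarray, outcome: np.ndarray | pd.Series,
                    covariates: pd.DataFrame, cfg: AssocConfig | None = None,
                    binary: bool = False, label: str = "prs",
                    outcome_name: str = "outcome") -> AssocResult:
    """Top-vs-bottom quantile contrast of the score distribution.

    Restricts to individuals at or above the ``top_q`` quantile versus at or
    below ``bottom_q`` and regresses the outcome on the tail-membership
    indicator with covariates.
    """
    cfg = cfg or AssocConfig()
    score = np.asarray(score, dtype=float)
    hi_cut = np.quantile(score, cfg.top_q)
    lo_cut = np.quantile(score, cfg.bottom_q)
    top = score >= hi_cut
    bottom = score <= lo_cut
    if top.sum() < 30 or bottom.sum() < 30:
        raise ValueError(f"tails too small (top={int(top.sum())}, bottom={int(bottom.sum())})")
    sel = top | bottom
    indicator = top[sel].astype(float)
    y = np.asarray(outcome, dtype=float)[sel]
    covs = covariates.loc[sel].reset_index(drop=True)
    return test_association(indicator, y, covs, cfg, binary=binary,
                            label=f"{label}_tail", outcome_name=outcome_name)
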