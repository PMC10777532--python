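"""Summary-statistic sum-of-single-effects fine-mapping with credible sets.

The model assumes at most L causal signals in a region.  Working on the
z-score scale with unit standard errors, each effect l is fitted by Bayesian
single-effect regression against the residual z-scores (the observed z minus
the LD-propagated contribution of the other effects), giving a posterior
inclusion probability vector alpha_l over variants.  Iterating the L updates
to convergence yields, per effect, a credible set: the smallest set of
variants (by descending alpha) whose cumulative posterior mass reaches the
coverage target.  Sets that are impure (weak LD among members, indicating the
mass is smeared over unlinked variants) or whose single-effect Bayes factor
does not beat the null are discarded.

`coloc_susie` colocalizes credible-set pairs from two fits by running the
pairwise hypothesis enumeration on the per-effect log-ABF vectors, which is
how regions with multiple causal variants are resolved into per-signal
colocalization events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .gwas_io import LDMatrix

logger = logging.getLogger(__name__)


@dataclass
class SusieConfig:
    L: int = 10
    prior_w: float = 25.0       # prior effect variance on the z^2 scale
    coverage: float = 0.95
    purity_min: float = 0.5
    tol: float = 1e-4
    max_iter: int = 200


@dataclass
class CredibleSet:
    """One independent signal's credible set."""

    effect: int                 # which of the L effects produced it
    indices: tuple[int, ...]    # variant positions, descending alpha
    ids: tuple[str, ...]
    coverage: float             # posterior mass actually captured
    purity: float               # min |r| among members
    lbf: float                  # log Bayes factor of the whole effect

    @property
    def lead_index(self) -> int:
        return self.indices[0]


@dataclass
class SusieFit:
    """Result of a sum-of-single-effects fit (the Results object of SusieRSS)."""

    alpha: np.ndarray           # L x M posterior inclusion matrix
    lbf_variable: np.ndarray    # L x M per-variant log ABFs at convergence
    lbf_effect: np.ndarray      # L log Bayes factors per effect
    mu: np.ndarray              # L x M posterior means of the single effects
    credible_sets: list[CredibleSet]
    converged: bool
    iterations: int
    ids: list[str]
    prior_w: float
    delta_history: list[float] = field(default_factory=list)

    @property
    def pip(self) -> np.ndarray:
        """Marginal posterior inclusion probability per variant."""
        return 1.0 - np.prod(1.0 - self.alpha, axis=0)

    def summary(self) -> str:
        lines = [
            f"SuSiE fit: {self.alpha.shape[0]} effects x {self.alpha.shape[1]} variants, "
            f"{'converged' if self.converged else 'NOT converged'} in {self.iterations} iterations",
            f"{len(self.credible_sets)} credible set(s):",
        ]
        for cs in self.credible_sets:
            lines.append(
                f"  effect {cs.effect}: {len(cs.indices)} variants, coverage {cs.coverage:.3f}, "
                f"purity {cs.purity:.3f}, lbf {cs.lbf:.2f}, lead {cs.ids[0]}")
        return "\n".join(lines)


class SusieRSS:
    """Sum-of-single-effects model on summary z-scores (Model object).

    Parameters mirror :class:`SusieConfig`; ``fit()`` returns a
    :class:`SusieFit`.
    """

    def __init__(self, z: np.ndarray, ld: LDMatrix, L: int = 10, prior_w: float = 25.0,
                 coverage: float = 0.95, purity_min: float = 0.5, tol: float = 1e-4,
                 max_iter: int = 200):
        z = np.asarray(z, dtype=float)
        if not np.all(np.isfinite(z)):
            bad = int(np.flatnonzero(~np.isfinite(z))[0])
            raise ValueError(f"non-finite z-score at variant {ld.ids[bad]}")
        if z.shape != (len(ld),):
            raise ValueError("z length does not match LD dimension")
        if L < 1:
            raise ValueError("L must be >= 1")
        self.z = z
        self.ld = ld
        self.cfg = SusieConfig(L=L, prior_w=prior_w, coverage=coverage,
                               purity_min=purity_min, tol=tol, max_iter=max_iter)

    def fit(self) -> SusieFit:
        z, R = self.z, self.ld.r
        cfg = self.cfg
        m = z.size
        L = cfg.L
        W = cfg.prior_w
        shrink = W / (1.0 + W)          # posterior shrinkage with unit SE
        log_null = 0.5 * np.log(1.0 / (1.0 + W))

        alpha = np.full((L, m), 1.0 / m)
        mu = np.zeros((L, m))
        b = alpha * mu                  # per-effect posterior mean vectors
        lbf_variable = np.zeros((L, m))
        delta_history: list[float] = []
        converged = False
        it = 0
        for it in range(1, cfg.max_iter + 1):
            alpha_old = alpha.copy()
            total = b.sum(axis=0)
            for l in range(L):
                resid = z - R @ (total - b[l])
                labf = log_null + 0.5 * resid**2 * shrink
                lbf_variable[l] = labf
                a = np.exp(labf - logsumexp(labf))
                alpha[l] = a
                mu[l] = shrink * resid
                new_bl = a * mu[l]
                total += new_bl - b[l]
                b[l] = new_bl
            delta = float(np.max(np.abs(alpha - alpha_old)))
            delta_history.append(delta)
            if delta < cfg.tol:
                converged = True
                break

        lbf_effect = logsumexp(lbf_variable, axis=1) - np.log(m)
        sets = self._credible_sets(alpha, lbf_effect)
        return SusieFit(alpha=alpha, lbf_variable=lbf_variable, lbf_effect=lbf_effect,
                        mu=mu, credible_sets=sets, converged=converged, iterations=it,
                        ids=list(self.ld.ids), prior_w=W, delta_history=delta_history)

    def _credible_sets(self, alpha: np.ndarray, lbf_effect: np.ndarray) -> list[CredibleSet]:
        cfg = self.cfg
        R = self.ld.r
        sets: list[CredibleSet] = []
        seen: set[tuple[int, ...]] = set()
        for l in range(alpha.shape[0]):
            if lbf_effect[l] <= 0:      # effect does not beat the null
                continue
            order = np.argsort(alpha[l])[::-1]
            cum = np.cumsum(alpha[l][order])
            k = int(np.searchsorted(cum, cfg.coverage) + 1)
            k = min(k, alpha.shape[1])
            members = tuple(int(i) for i in order[:k])
            key = tuple(sorted(members))
            if key in seen:
                continue
            sub = np.abs(R[np.ix_(members, members)])
            purity = float(sub.min()) if len(members) > 1 else 1.0
            if purity < cfg.purity_min:
                logger.debug("effect %d: credible set discarded (purity %.3f)", l, purity)
                continue
            seen.add(key)
            sets.append(CredibleSet(
                effect=l, indices=members,
                ids=tuple(self.ld.ids[i] for i in members),
                coverage=float(cum[k - 1]), purity=purity, lbf=float(lbf_effect[l]),
            ))
        return sets


def susie_rss(z: np.ndarray, ld: LDMatrix, L: int = 10, prior_w: float = 25.0,
              coverage: float = 0.95, purity_min: float = 0.5, tol: float = 1e-4,
              max_iter: int = 200) -> SusieFit:
    """Functional wrapper around :class:`SusieRSS`."""
    return SusieRSS(z, ld, L=L, prior_w=prior_w, coverage=coverage,
                    purity_min=purity_min, tol=tol, max_iter=max_iter).fit()


def coloc_susie(fit1: SusieFit, fit2: SusieFit, priors=None) -> list:
    """Colocalize every credible-set pair of two fits over the same variants.

    For each (set a of fit1, set b of fit2) the pairwise hypothesis
    enumeration runs on the two effects' per-variant log-ABF vectors; one
    event is returned per pair with PP.H4 above the threshold.  The lead is
    fit1's highest-alpha variant within set a.
    """
    from .coloc import ColocEvent, ColocPriors, coloc_from_labf

    priors = priors or ColocPriors()
    if fit1.ids != fit2.ids:
        raise ValueError("fits do not share a variant ordering")
    events = []
    for cs1 in fit1.credible_sets:
        for cs2 in fit2.credible_sets:
            pp, _ = coloc_from_labf(fit1.lbf_variable[cs1.effect],
                                    fit2.lbf_variable[cs2.effect], priors)
            if pp["PP.H4"] > priors.pp_h4_threshold:
                events.append(ColocEvent(
                    region_id=None, traits=("trait1", "trait2"), method="susie",
                    lead_id=fit1.ids[cs1.lead_index], pp=pp,
                    credible_set=(cs1.effect, cs2.effect),
                ))
    return events
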