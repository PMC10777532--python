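"""Bayesian colocalization of GWAS association signals.

Pairwise colocalization enumerates, under a single-causal-variant assumption,
all variant-level configurations for two traits and aggregates them into the
five global hypotheses

    H0 no association, H1/H2 one trait only, H3 both traits with distinct
    causal variants, H4 both traits sharing one causal variant,

with per-variant evidence given by Wakefield's approximate Bayes factor
computed from the effect estimate and its standard error.  The multi-trait
analogue factorizes the decision into a regional posterior P_R (every trait
has a causal variant in the region) and an alignment posterior P_A (given
that, it is the same variant); a region colocalizes when P_R * P_A > 0.60 and
the association p-value at the candidate variant clears 1e-5 in every
retained trait.

`run_region_workflow` chains the stages used on real data: multi-trait
screening for single-signal regions, sum-of-single-effects fine-mapping plus
credible-set colocalization for multi-signal (or ambiguous) regions, and a
single-causal-variant pairwise fallback when fine-mapping yields no credible
sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .gwas_io import RegionPanel

logger = logging.getLogger(__name__)


@dataclass
class ColocPriors:
    """Prior probabilities for colocalization hypotheses.

    p1/p2: prior that a variant is associated with trait 1/2 only; p12: with
    both.  W is the prior variance of the (standardized-scale) effect size in
    the Wakefield approximate Bayes factor.  prior_c / prior_d are the
    multi-trait priors for "all traits share one causal variant" and "all
    traits causal at independent variants"; when left None they default to
    p12 (per shared variant) and p1 ** n_traits (per independent
    configuration).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    W: float = 0.04
    prior_c: float | None = None
    prior_d: float | None = None
    pp_h4_threshold: float = 0.6
    pr_pa_threshold: float = 0.60
    min_p_gate: float = 1e-5
    gate_all_traits: bool = True

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 must not exceed min(p1, p2)")
        if self.W <= 0:
            raise ValueError("W must be positive")

    def multi(self, n_traits: int) -> tuple[float, float]:
        pc = self.prior_c if self.prior_c is not None else self.p12
        pd_ = self.prior_d if self.prior_d is not None else self.p1 ** n_traits
        return pc, pd_


@dataclass
class ColocEvent:
    """Posterior evidence that a set of traits shares a causal variant."""

    region_id: str | None
    traits: tuple[str, ...]
    method: str                      # multitrait | susie | abf-fallback
    lead_id: str | None
    pp: dict[str, float] | None = None   # PP.H0..PP.H4 for pairwise methods
    pr: float | None = None
    pa: float | None = None
    min_trait_p: float | None = None
    accepted: bool = False
    credible_set: tuple[int, int] | None = None  # (effect index trait1, trait2)

    @property
    def pp_h4(self) -> float | None:
        return None if self.pp is None else self.pp["PP.H4"]


# ---------------------------------------------------------------------------
# Wakefield approximate Bayes factor
# ---------------------------------------------------------------------------


def wakefield_labf(beta, se, W: float = 0.04):
    """Log approximate Bayes factor for association at one variant.

    With V = se^2 and z = beta/se:  labf = 0.5 * [log(V / (V + W)) +
    z^2 * W / (V + W)].  Strictly increasing in |z| at fixed V and W, and
    symmetric in the sign of beta.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if W <= 0:
        raise ValueError("W must be positive")
    V = se**2
    z2 = (beta / se) ** 2
    return 0.5 * (np.log(V / (V + W)) + z2 * W / (V + W))


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, stable for large magnitudes."""
    if b > a:
        raise ValueError("logdiffexp requires a >= b")
    if a == b:
        return -np.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_from_labf(
    l1: np.ndarray,
    l2: np.ndarray,
    priors: ColocPriors,
    snp_ids: list[str] | None = None,
) -> tuple[dict[str, float], int]:
    """Enumerate the five hypotheses from two per-variant log-ABF vectors.

    Returns the normalized posteriors and the index of the variant with the
    largest H4 contribution (the colocalization lead).  All sums are carried
    out in log space.
    """
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("log-ABF vectors differ in length")
    if l1.size < 2:
        raise ValueError("need at least 2 variants to enumerate hypotheses")
    ls1 = float(logsumexp(l1))
    ls2 = float(logsumexp(l2))
    ls12 = float(logsumexp(l1 + l2))
    lH0 = 0.0
    lH1 = math.log(priors.p1) + ls1
    lH2 = math.log(priors.p2) + ls2
    lH3 = math.log(priors.p1) + math.log(priors.p2) + _logdiffexp(ls1 + ls2, ls12)
    lH4 = math.log(priors.p12) + ls12
    lall = np.array([lH0, lH1, lH2, lH3, lH4])
    post = np.exp(lall - logsumexp(lall))
    pp = {f"PP.H{i}": float(post[i]) for i in range(5)}
    lead = int(np.argmax(l1 + l2))
    return pp, lead


def coloc_abf(t1, t2, priors: ColocPriors | None = None, region_id: str | None = None,
              trait_labels: tuple[str, str] = ("trait1", "trait2")) -> ColocEvent:
    """Pairwise colocalization under the single-causal-variant assumption.

    ``t1``/``t2`` are aligned summary-statistic DataFrames (canonical columns,
    identical SNP order — the RegionPanel guarantee).
    """
    priors = priors or ColocPriors()
    if list(t1["SNP"]) != list(t2["SNP"]):
        raise ValueError("trait records are not aligned on the same variants")
    if len(t1) < 2:
        raise ValueError("region has fewer than 2 variants; skipped")
    l1 = wakefield_labf(t1["BETA"].to_numpy(), t1["SE"].to_numpy(), priors.W)
    l2 = wakefield_labf(t2["BETA"].to_numpy(), t2["SE"].to_numpy(), priors.W)
    pp, lead = coloc_from_labf(l1, l2, priors)
    min_p = float(min(t1["P"].iloc[lead], t2["P"].iloc[lead]))
    return ColocEvent(
        region_id=region_id,
        traits=trait_labels,
        method="abf-fallback",
        lead_id=str(t1["SNP"].iloc[lead]),
        pp=pp,
        min_trait_p=min_p,
        accepted=pp["PP.H4"] > priors.pp_h4_threshold,
    )


# ---------------------------------------------------------------------------
# Multi-trait colocalization
# ---------------------------------------------------------------------------


def _multitrait_posteriors(labf: dict[str, np.ndarray], priors: ColocPriors):
    traits = list(labf)
    L = np.vstack([labf[t] for t in traits])
    log_s = logsumexp(L, axis=1)                 # per-trait total evidence
    log_c = float(logsumexp(L.sum(axis=0)))      # shared-variant evidence
    pc, pd_ = priors.multi(len(traits))
    num = math.log(pc) + log_c
    den = logsumexp([num, math.log(pd_) + float(log_s.sum())])
    pa = math.exp(num - den)
    pi1 = priors.p1 + priors.p12
    # P_R = prod_t pi1*S_t / (1 + pi1*S_t), computed stably in log space.
    log_pi1s = math.log(pi1) + log_s
    pr = math.exp(float(np.sum(log_pi1s - np.logaddexp(0.0, log_pi1s))))
    cand = int(np.argmax(L.sum(axis=0)))
    return pr, pa, cand


def multitrait_coloc(panel: RegionPanel, priors: ColocPriors | None = None) -> ColocEvent:
    """Test all panel traits simultaneously for a shared causal variant.

    Computes the regional (P_R) and alignment (P_A) posteriors for the full
    trait set; if P_R * P_A fails the 0.60 threshold (or the per-trait p-value
    gate at the candidate variant fails), traits are greedily dropped — each
    step removes the trait whose removal most improves P_R * P_A (or, when
    only the gate fails, the trait with the worst candidate p-value) — until
    acceptance or only one trait remains.
    """
    priors = priors or ColocPriors()
    if len(panel.traits) < 2:
        raise ValueError("multi-trait colocalization needs at least 2 traits")
    labf_all = {
        t: wakefield_labf(panel.records[t]["BETA"].to_numpy(),
                          panel.records[t]["SE"].to_numpy(), priors.W)
        for t in panel.traits
    }

    def evaluate(traits: list[str]):
        pr, pa, cand = _multitrait_posteriors({t: labf_all[t] for t in traits}, priors)
        pvals = {t: float(panel.records[t]["P"].iloc[cand]) for t in traits}
        if priors.gate_all_traits:
            gate_ok = all(p < priors.min_p_gate for p in pvals.values())
        else:
            gate_ok = any(p < priors.min_p_gate for p in pvals.values())
        return pr, pa, cand, pvals, gate_ok

    traits = list(panel.traits)
    while True:
        pr, pa, cand, pvals, gate_ok = evaluate(traits)
        accepted = pr * pa > priors.pr_pa_threshold and gate_ok
        if accepted or len(traits) <= 2:
            break
        if pr * pa > priors.pr_pa_threshold:
            # Posterior criterion met but the p gate fails: drop the trait
            # with the weakest association at the candidate variant.
            worst = max(traits, key=lambda t: pvals[t])
            traits = [t for t in traits if t != worst]
            continue
        best_subset, best_score = None, -1.0
        for t_drop in traits:
            sub = [t for t in traits if t != t_drop]
            pr_s, pa_s, *_ = evaluate(sub)
            if pr_s * pa_s > best_score:
                best_score, best_subset = pr_s * pa_s, sub
        traits = best_subset

    return ColocEvent(
        region_id=panel.region.region_id,
        traits=tuple(traits),
        method="multitrait",
        lead_id=panel.variant_ids[cand],
        pr=pr,
        pa=pa,
        min_trait_p=min(pvals.values()) if pvals else None,
        accepted=accepted,
        pp=None,
    )


# ---------------------------------------------------------------------------
# Staged regional workflow
# ---------------------------------------------------------------------------


def run_region_workflow(
    panel: RegionPanel,
    priors: ColocPriors | None = None,
    susie_cfg=None,
) -> list[ColocEvent]:
    """Staged colocalization for one region.

    Stage A (single-signal regions): multi-trait test; emit the event when
    accepted.  Stage B (multi-signal regions, or Stage A with a high regional
    posterior P_R > 0.8 that nonetheless failed the joint threshold):
    per-trait sum-of-single-effects fine-mapping and credible-set-pair
    colocalization of the index trait against every other trait; emit pairs
    with PP.H4 > 0.6.  Stage C (index-trait fine-mapping finds no credible
    sets): pairwise single-causal-variant colocalization as fallback.  Every
    emitted event also clears the per-variant p-value gate; every non-emission
    is logged with its stage and reason.
    """
    from .finemap import SusieConfig, susie_rss, coloc_susie

    priors = priors or ColocPriors()
    susie_cfg = susie_cfg or SusieConfig()
    rid = panel.region.region_id
    events: list[ColocEvent] = []

    if panel.region.n_signals == 1:
        ev = multitrait_coloc(panel, priors)
        if ev.accepted:
            return [ev]
        if not (ev.pr is not None and ev.pr > 0.8):
            logger.info("region %s: stage A rejected (P_R=%.3f, P_R*P_A=%.3f)",
                        rid, ev.pr or 0.0, (ev.pr or 0) * (ev.pa or 0))
            return []
        logger.info("region %s: stage A ambiguous (P_R=%.3f > 0.8); escalating to fine-mapping",
                    rid, ev.pr)

    other_traits = [t for t in panel.traits if t != panel.index_trait]
    fits = {}
    for t in panel.traits:
        z = panel.z(t)
        fits[t] = susie_rss(z, panel.ld, L=susie_cfg.L, prior_w=susie_cfg.prior_w,
                            coverage=susie_cfg.coverage, purity_min=susie_cfg.purity_min,
                            tol=susie_cfg.tol, max_iter=susie_cfg.max_iter)
    index_fit = fits[panel.index_trait]

    if index_fit.credible_sets:
        for t in other_traits:
            pair_events = coloc_susie(index_fit, fits[t], priors)
            for ev in pair_events:
                ev.region_id = rid
                ev.traits = (panel.index_trait, t)
                p_idx = float(panel.records[panel.index_trait].set_index("SNP")["P"].loc[ev.lead_id])
                p_t = float(panel.records[t].set_index("SNP")["P"].loc[ev.lead_id])
                ev.min_trait_p = min(p_idx, p_t)
                gate = (max(p_idx, p_t) if priors.gate_all_traits else ev.min_trait_p)
                if ev.pp["PP.H4"] > priors.pp_h4_threshold and gate < priors.min_p_gate:
                    ev.accepted = True
                    events.append(ev)
                else:
                    logger.info("region %s: stage B pair (%s) not emitted "
                                "(PP.H4=%.3f, gate p=%.2e)", rid, t, ev.pp["PP.H4"], gate)
        return events

    logger.info("region %s: no index-trait credible sets; stage C single-causal fallback", rid)
    for t in other_traits:
        ev = coloc_abf(panel.records[panel.index_trait], panel.records[t], priors,
                       region_id=rid, trait_labels=(panel.index_trait, t))
        lead_pos = panel.variant_ids.index(ev.lead_id)
        p_idx = float(panel.records[panel.index_trait]["P"].iloc[lead_pos])
        p_t = float(panel.records[t]["P"].iloc[lead_pos])
        gate = max(p_idx, p_t) if priors.gate_all_traits else min(p_idx, p_t)
        if ev.pp["PP.H4"] > priors.pp_h4_threshold and gate < priors.min_p_gate:
            ev.accepted = True
            events.append(ev)
        else:
            logger.info("region %s: stage C pair (%s) not emitted (PP.H4=%.3f, gate p=%.2e)",
                        rid, t, ev.pp["PP.H4"], gate)
    return events
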