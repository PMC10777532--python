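"""Calibration and recovery experiments on synthetic data.

Each function simulates data under known conditions, runs the corresponding
analysis stage, and returns summary metrics.  The same experiments back the
test suite and the reproduction script, so every reported number is computed
at run time from a seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import network, prs, synthetic
from .coloc import ColocPriors, coloc_abf, multitrait_coloc
from .finemap import susie_rss
from .gwas_io import LDMatrix, RegionPanel, RegionSpec, Variant
from .mr import MRModel, ivw
from .pipeline import run_pipeline
from .synthetic import default_scenario, make_scenario


def bonferroni_thresholds() -> dict[str, float]:
    """The study-wide multiple-testing thresholds: 6 scores in adults,
    3 in the pediatric validation."""
    return {
        "adult": prs.bonferroni_threshold(0.05, 6),
        "pediatric": prs.bonferroni_threshold(0.05, 3),
    }


# ---------------------------------------------------------------------------
# Colocalization calibration
# ---------------------------------------------------------------------------


def _shared_region(ld: LDMatrix, rng: np.random.Generator, lam: float, n: int,
                   site: int | None = None, distinct: bool = False):
    m = len(ld)
    site = int(rng.integers(m)) if site is None else site
    lam1 = np.zeros(m)
    lam1[site] = lam
    if distinct:
        other = (site + m // 2) % m
        lam2 = np.zeros(m)
        lam2[other] = lam
    else:
        lam2 = lam1
    t1 = synthetic.simulate_region_sumstats(ld, lam1, n, seed=rng)
    t2 = synthetic.simulate_region_sumstats(ld, lam2, n, seed=rng)
    return t1, t2


def coloc_calibration(n_reps: int = 200, n_null: int = 200, m: int = 150,
                      rho: float = 0.8, lam: float = 8.0, n: int = 50_000,
                      seed: int = 0) -> dict[str, float]:
    """Power and false-positive rate of pairwise colocalization.

    Shared-causal regions (non-centrality ``lam`` at a random variant in both
    traits) should give PP.H4 > 0.6 nearly always; null regions (all lambda
    0) should essentially never yield an accepted event (PP.H4 > 0.6 plus the
    per-variant p gate).
    """
    rng = np.random.default_rng(seed)
    priors = ColocPriors()
    ld = synthetic.simulate_ld(m, rho)
    hits = 0
    for _ in range(n_reps):
        t1, t2 = _shared_region(ld, rng, lam, n)
        ev = coloc_abf(t1, t2, priors)
        hits += ev.pp["PP.H4"] > 0.6
    false = 0
    for _ in range(n_null):
        t1 = synthetic.simulate_region_sumstats(ld, np.zeros(m), n, seed=rng)
        t2 = synthetic.simulate_region_sumstats(ld, np.zeros(m), n, seed=rng)
        ev = coloc_abf(t1, t2, priors)
        false += ev.pp["PP.H4"] > 0.6 and ev.min_trait_p < priors.min_p_gate
    return {
        "h4_power_pct": 100.0 * hits / n_reps,
        "null_false_event_pct": 100.0 * false / n_null,
        "n_reps": n_reps,
    }


def _panel_from_frames(frames: dict[str, pd.DataFrame], ld: LDMatrix) -> RegionPanel:
    lead = Variant("v0", "1", 1_000_000, "A", "G", 0.5)
    region = RegionSpec.from_lead(lead, region_id="sim")
    return RegionPanel(region=region, traits=list(frames), records=frames, ld=ld,
                       index_trait=list(frames)[0])


def pairwise_concordance(n_reps: int = 200, m: int = 150, rho: float = 0.8,
                         lam: float = 8.0, n: int = 50_000, seed: int = 0) -> dict[str, float]:
    """Decision agreement between the 2-trait multi-trait test and pairwise
    colocalization on a mix of shared-causal and distinct-causal regions."""
    rng = np.random.default_rng(seed)
    priors = ColocPriors()
    ld = synthetic.simulate_ld(m, rho)
    agree = 0
    for rep in range(n_reps):
        distinct = rep % 2 == 1
        t1, t2 = _shared_region(ld, rng, lam, n, distinct=distinct)
        ev_pair = coloc_abf(t1, t2, priors)
        pair_accept = ev_pair.pp["PP.H4"] > 0.6 and ev_pair.min_trait_p < priors.min_p_gate
        panel = _panel_from_frames({"t1": t1, "t2": t2}, ld)
        ev_multi = multitrait_coloc(panel, priors)
        agree += pair_accept == ev_multi.accepted
    return {"concordance_pct": 100.0 * agree / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# Fine-mapping
# ---------------------------------------------------------------------------


def susie_two_signal_recovery(n_reps: int = 100, m: int = 150, rho: float = 0.8,
                              lam: float = 8.0, sites: tuple[int, int] = (10, 90),
                              seed: int = 0) -> dict[str, float]:
    """Recovery of two independent planted signals in separate LD blocks.

    A success is a fit with exactly two credible sets, each containing its
    true causal variant.
    """
    rng = np.random.default_rng(seed)
    ld = synthetic.simulate_ld(m, rho, blocks=2)
    lam_vec = np.zeros(m)
    lam_vec[list(sites)] = lam
    chol = np.linalg.cholesky(ld.r)
    mean = ld.r @ lam_vec
    ok = 0
    for _ in range(n_reps):
        z = mean + chol @ rng.standard_normal(m)
        fit = susie_rss(z, ld)
        sets = [set(cs.indices) for cs in fit.credible_sets]
        ok += (len(sets) == 2
               and any(sites[0] in s for s in sets)
               and any(sites[1] in s for s in sets)
               and not any(sites[0] in s and sites[1] in s for s in sets))
    return {"recovery_pct": 100.0 * ok / n_reps, "n_reps": n_reps}


def susie_l1_analytic_agreement(m: int = 100, rho: float = 0.6, lam: float = 5.0,
                                seed: int = 0) -> dict[str, float]:
    """With L = 1 the posterior inclusion vector must equal the normalized
    single-effect ABFs computed directly from z."""
    from scipy.special import logsumexp

    rng = np.random.default_rng(seed)
    ld = synthetic.simulate_ld(m, rho)
    lam_vec = np.zeros(m)
    lam_vec[m // 2] = lam
    z = ld.r @ lam_vec + np.linalg.cholesky(ld.r) @ rng.standard_normal(m)
    fit = susie_rss(z, ld, L=1)
    W = fit.prior_w
    labf = 0.5 * (np.log(1 / (1 + W)) + z**2 * W / (1 + W))
    expected = np.exp(labf - logsumexp(labf))
    return {"max_abs_diff": float(np.max(np.abs(fit.alpha[0] - expected)))}


# ---------------------------------------------------------------------------
# Network stage oracles and recovery
# ---------------------------------------------------------------------------


def brute_force_min_degree_threshold(corr: np.ndarray) -> float:
    """Independent oracle: scan every unique |off-diagonal| value descending
    and return the first at which the thresholded graph has min degree >= 1."""
    A = np.asarray(corr, dtype=float)
    A = np.abs((A + A.T) / 2.0)
    np.fill_diagonal(A, 0.0)
    keep = A.max(axis=1) > 0
    A = A[np.ix_(keep, keep)]
    values = np.unique(A[np.triu_indices_from(A, k=1)])
    for c in sorted(values[values > 0], reverse=True):
        adj = A >= c
        if adj.sum(axis=1).min() >= 1:
            return float(c)
    raise ValueError("no cutoff keeps all vertices connected")


def threshold_oracle_agreement(n_mats: int = 100, size: int = 12, seed: int = 0) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_mats):
        x = rng.standard_normal((size, 6))
        corr = np.corrcoef(x)
        agree += network.min_degree_threshold(corr) == brute_force_min_degree_threshold(corr)
    return {"agreement_pct": 100.0 * agree / n_mats, "n_reps": n_mats}


def brute_force_modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    """Independent oracle via networkx's weighted modularity."""
    import networkx as nx

    g = nx.from_numpy_array(np.asarray(adj, dtype=float))
    communities = [
        {i for i in range(len(labels)) if labels[i] == c} for c in np.unique(labels)
    ]
    return float(nx.community.modularity(g, communities, weight="weight"))


def modularity_oracle_agreement(n_graphs: int = 100, size: int = 15, seed: int = 0) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        adj = rng.random((size, size)) * (rng.random((size, size)) < 0.4)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        if adj.sum() == 0:
            adj[0, 1] = adj[1, 0] = 1.0
        labels = rng.integers(0, 4, size)
        diff = abs(network.modularity(adj, labels) - brute_force_modularity(adj, labels))
        worst = max(worst, diff)
    return {"max_abs_diff": worst, "n_reps": n_graphs}


def two_triangle_modularity() -> float:
    """Two unit-weight triangles joined by one edge, communities = triangles."""
    adj = np.zeros((6, 6))
    for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]:
        adj[i, j] = adj[j, i] = 1.0
    return network.modularity(adj, np.array([0, 0, 0, 1, 1, 1]))


def cluster_recovery(n_seeds: int = 20, per_cluster: int = 10, seed: int = 0) -> dict[str, float]:
    """Adjusted Rand index of spinglass clustering against the planted
    3-cluster signature plan (30 variants), across independent seeds."""
    plan = default_scenario().cluster_plan
    traits = ["bmi", "whr", "trig", "fg", "hdl"]
    zmat, truth = synthetic.simulate_zmatrix(plan, traits, per_cluster=per_cluster, seed=seed)
    corr = network.snp_correlation(zmat)
    cutoff = network.min_degree_threshold(corr)
    aris = []
    for s in range(n_seeds):
        cfg = network.ClusterConfig(seed=seed + 1000 * s, n_restarts=5)
        sol = network.spinglass_cluster(corr, cutoff, cfg)
        aris.append(adjusted_rand_score(truth.to_numpy(), sol.labels(list(zmat.index))))
    return {"min_ari": float(np.min(aris)), "mean_ari": float(np.mean(aris)),
            "n_reps": n_seeds}


# ---------------------------------------------------------------------------
# PRS and MR recovery
# ---------------------------------------------------------------------------


def prs_recovery(n_cohorts: int = 50, n_ind: int = 20_000, n_variants: int = 20,
                 effect: float = 0.08, seed: int = 0) -> dict[str, float]:
    """Recovery of a planted per-SD score effect and CI coverage."""
    rng = np.random.default_rng(seed)
    betas, covered = [], 0
    for c in range(n_cohorts):
        eaf = rng.uniform(0.1, 0.9, n_variants)
        variants = pd.DataFrame({"SNP": [f"v{i}" for i in range(n_variants)], "EAF": eaf})
        weights = rng.normal(0.05, 0.02, n_variants)
        cohort = synthetic.simulate_cohort(
            n_ind, variants, weights, effect_on_outcome=effect,
            seed=int(rng.integers(2**31 - 1)))
        model = prs.PRSModel("sim", dict(zip(variants["SNP"], weights)))
        score = prs.build_prs(cohort, model)
        res = prs.test_association(score, cohort.phenotypes["y_cont"], cohort.covariates)
        betas.append(res.estimate)
        covered += res.ci_low <= effect <= res.ci_high
    return {
        "mean_beta": float(np.mean(betas)),
        "ci_coverage": covered / n_cohorts,
        "n_reps": n_cohorts,
    }


def mr_recovery(slope: float = 0.55, n_reps_ivw: int = 500, n_reps_steiger: int = 200,
                seed: int = 0) -> dict[str, float]:
    """IVW slope recovery and Steiger direction recovery (both causal
    orientations)."""
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_reps_ivw):
        iv = synthetic.simulate_instruments(
            n_instruments=50, slope=slope, r2_total=0.02, n_exposure=1_000_000,
            n_outcome=50_000, seed=int(rng.integers(2**31 - 1)))
        estimates.append(ivw(iv)[0])
    forward = reverse = 0
    for _ in range(n_reps_steiger):
        iv = synthetic.simulate_instruments(
            n_instruments=50, slope=0.5, r2_total=0.02, n_exposure=50_000,
            n_outcome=50_000, direction="forward", seed=int(rng.integers(2**31 - 1)))
        forward += MRModel(iv).fit().inferred_direction == "exposure->outcome"
        iv = synthetic.simulate_instruments(
            n_instruments=50, slope=0.5, r2_total=0.02, n_exposure=50_000,
            n_outcome=50_000, direction="reverse", seed=int(rng.integers(2**31 - 1)))
        reverse += MRModel(iv).fit().inferred_direction == "outcome->exposure"
    return {
        "ivw_mean": float(np.mean(estimates)),
        "steiger_forward_pct": 100.0 * forward / n_reps_steiger,
        "steiger_reverse_pct": 100.0 * reverse / n_reps_steiger,
        "n_reps": n_reps_ivw,
    }


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------


def end_to_end(tmp_dir, seed: int = 0) -> dict[str, float]:
    """Run the full pipeline on the default planted scenario and compare
    every stage against the truth table."""
    from pathlib import Path

    spec = default_scenario(seed=seed)
    data = make_scenario(spec, Path(tmp_dir) / "data", force=True)
    result = run_pipeline(data, seed=seed)

    truth = pd.read_csv(data / "truth.tsv", sep="\t")
    positive_regions = set(truth.loc[truth["COLOCALIZED"] == 1, "REGION_ID"])
    all_regions = {f"region{r}" for r in range(spec.n_regions)}
    negative_regions = all_regions - positive_regions
    detected = {ev.region_id for ev in result.events}
    sensitivity = 100.0 * len(detected & positive_regions) / len(positive_regions)
    false_pct = 100.0 * len(detected & negative_regions) / max(1, len(negative_regions))

    metrics = {
        "sensitivity_pct": sensitivity,
        "false_region_pct": false_pct,
        "n_events": len(result.events),
        "n_reps": spec.n_regions,
    }

    if result.solution is not None:
        lead_truth = truth.loc[truth["COLOCALIZED"] == 1].drop_duplicates("LEAD_SNP")
        lead_cluster = dict(zip(lead_truth["LEAD_SNP"], lead_truth["CLUSTER"]))
        ids = [v for v in result.solution.membership if v in lead_cluster]
        if ids:
            metrics["cluster_ari"] = float(adjusted_rand_score(
                [lead_cluster[v] for v in ids], result.solution.labels(ids)))
        metrics["k_retained"] = len(result.solution.retained)
        metrics["modularity"] = result.solution.modularity

        # sign agreement between recovered signatures and the planted plan
        if result.signature is not None and ids:
            match = total = 0
            sig = result.signature.set_index(["CLUSTER", "TRAIT"])["MEAN_Z"]
            for c in result.solution.retained:
                members = [v for v in result.solution.retained_members()[c] if v in lead_cluster]
                labels = [lead_cluster[v] for v in members if lead_cluster[v] in spec.cluster_plan]
                if not labels:
                    continue
                planted = spec.cluster_plan[pd.Series(labels).mode().iloc[0]]
                for trait, mu in planted.items():
                    if (c, trait) in sig.index:
                        total += 1
                        match += np.sign(sig.loc[(c, trait)]) == np.sign(mu)
            metrics["signature_sign_match_pct"] = 100.0 * match / total if total else 0.0

    cont = [r for r in result.prs_results if not r.binary]
    metrics["prs_positive_sign_pct"] = (
        100.0 * np.mean([r.estimate > 0 for r in cont]) if cont else 0.0)
    if result.mr_reports:
        sign_ok = []
        for (c, trait), rep in result.mr_reports.items():
            members = result.solution.retained_members()[c]
            lead_truth = truth.loc[truth["COLOCALIZED"] == 1].drop_duplicates("LEAD_SNP")
            lead_cluster = dict(zip(lead_truth["LEAD_SNP"], lead_truth["CLUSTER"]))
            counts = pd.Series([lead_cluster[v] for v in members if v in lead_cluster])
            counts = counts[counts.isin(list(spec.cluster_plan))]
            if counts.empty:
                continue
            planted_cluster = counts.mode().iloc[0]
            planted_sign = np.sign(spec.cluster_plan[planted_cluster].get(trait, 0.0))
            if planted_sign != 0:
                sign_ok.append(np.sign(rep.ivw_beta) == planted_sign)
        metrics["mr_sign_match_pct"] = 100.0 * np.mean(sign_ok) if sign_ok else 0.0
    return metrics
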