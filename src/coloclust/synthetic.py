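"""Synthetic GWAS summary statistics, LD, cluster signatures and cohorts.

Everything downstream of the consortium downloads is testable against data
generated here.  Summary statistics are simulated directly on the z scale:
within a region with LD correlation matrix R and per-variant non-centrality
vector lambda (non-zero at planted causal variants), the marginal z-scores
follow

    z ~ MVN(R @ lambda, R)

which is the standard large-sample distribution of GWAS z-statistics for a
standardized trait.  Betas and standard errors are recovered as z/sqrt(n) and
1/sqrt(n), exactly the sufficient statistics the colocalization machinery
consumes.  Shared causal indices across traits encode true colocalization;
the truth table records them for every region.

Individual-level cohorts (dosages, phenotypes, covariates) are simulated
separately for polygenic-score validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import LDMatrix, CANONICAL_COLUMNS

logger = logging.getLogger(__name__)

_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------


@dataclass
class TraitSpec:
    label: str
    n: int
    is_binary: bool = False


@dataclass
class ScenarioSpec:
    """Full description of a synthetic multi-trait GWAS dataset.

    ``causal_plan`` maps region index -> {trait label: (causal variant index,
    non-centrality lambda)}; traits sharing a causal index in a region are
    truly colocalized there.  ``cluster_plan`` maps cluster label -> {trait:
    mean z effect} and ``region_cluster`` assigns colocalized regions to
    planted clusters, so the network-clustering stage has a known truth.
    """

    n_regions: int
    variants_per_region: int
    ld_rho: float
    traits: list[TraitSpec]
    causal_plan: dict[int, dict[str, tuple[int, float]]]
    cluster_plan: dict[str, dict[str, float]]
    region_cluster: dict[int, str | None]
    index_trait: str
    ld_blocks: int = 1
    palindromic_rate: float = 0.05
    seed: int = 0
    #: optional second conditionally independent signal per region
    extra_signals: dict[int, dict[str, tuple[int, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = {t.label for t in self.traits}
        for rid, plan in self.causal_plan.items():
            for trait, (j, lam) in plan.items():
                if trait not in labels:
                    raise ValueError(f"causal_plan region {rid}: unknown trait {trait!r}")
                if not 0 <= j < self.variants_per_region:
                    raise ValueError(f"causal index {j} outside [0, {self.variants_per_region})")
                if not np.isfinite(lam):
                    raise ValueError("non-finite effect size in causal_plan")

    @property
    def trait_labels(self) -> list[str]:
        return [t.label for t in self.traits]

    def colocalized_regions(self) -> dict[int, list[str]]:
        """Regions where the index trait shares its causal variant with at
        least one other trait, mapped to the sharing traits."""
        out: dict[int, list[str]] = {}
        for rid, plan in self.causal_plan.items():
            idx_sites = {j for t, (j, lam) in plan.items() if t == self.index_trait and lam != 0}
            shared = sorted(
                t for t, (j, lam) in plan.items()
                if t != self.index_trait and lam != 0 and j in idx_sites
            )
            if shared:
                out[rid] = shared
        return out


def default_scenario(seed: int = 0) -> ScenarioSpec:
    """The default study conditions: 15 regions x 150 variants, 6 traits,
    3 planted clusters, AR(1) LD with rho = 0.8.

    Trait sample sizes straddle the 60,000 gate (two traits below).  The
    index trait ("t2d") carries non-centrality 10 at each planted signal;
    colocalized metabolic traits carry +/-8 following their cluster
    signature.  Regions 0-9 carry the cluster structure (two of them with two
    independent signals each), regions 12-14 are colocalized "oddballs" whose
    trait profiles match no cluster — real pleiotropy networks always contain
    such variants (they end up in very small communities that the size filter
    drops, and they anchor the correlation cutoff at a realistic level).
    Region 10 has distinct causal variants for index and metabolic trait and
    region 11 is an index-only null; both are negative controls for
    colocalization.
    """
    traits = [
        TraitSpec("t2d", 74_124),
        TraitSpec("bmi", 250_000),
        TraitSpec("whr", 210_000),
        TraitSpec("trig", 62_000),
        TraitSpec("fg", 55_000),
        TraitSpec("hdl", 48_000),
    ]
    cluster_plan = {
        "adiposity": {"bmi": 8.0, "whr": 8.0},
        "lipodystrophy": {"bmi": -8.0, "whr": 8.0, "trig": 8.0, "hdl": -8.0},
        "glycemic": {"fg": 8.0},
    }
    region_cluster: dict[int, str | None] = {}
    causal_plan: dict[int, dict[str, tuple[int, float]]] = {}

    def plant(rid: int, cluster: str, site: int) -> None:
        plan = causal_plan.setdefault(rid, {})
        plan[("t2d")] = (site, 10.0)
        for trait, eff in cluster_plan[cluster].items():
            plan[trait] = (site, eff)
        region_cluster[rid] = cluster

    for rid in range(4):
        plant(rid, "adiposity", site=75)
    for rid in range(4, 8):
        plant(rid, "lipodystrophy", site=75)
    # Two-signal glycemic regions: both index signals colocalize with fg.
    for rid in (8, 9):
        causal_plan[rid] = {}
        region_cluster[rid] = "glycemic"
    # encoded separately below (a plan maps trait -> single site, so the second
    # signal is carried by _extra_signals)
    causal_plan[8] = {"t2d": (30, 10.0), "fg": (30, 8.0)}
    causal_plan[9] = {"t2d": (30, 10.0), "fg": (30, 8.0)}
    # Region 10: index and bmi have *distinct* causal variants (no colocalization).
    causal_plan[10] = {"t2d": (40, 10.0), "bmi": (110, 8.0)}
    region_cluster[10] = None
    # Region 11: index-only signal.
    causal_plan[11] = {"t2d": (75, 10.0)}
    region_cluster[11] = None
    # Regions 12-14: colocalized oddballs belonging to no cluster.
    for k, (rid, profile) in enumerate(zip((12, 13, 14), DEFAULT_ODDBALLS)):
        causal_plan[rid] = {"t2d": (75, 10.0)}
        for trait, eff in profile.items():
            causal_plan[rid][trait] = (75, eff)
        region_cluster[rid] = f"odd{k}"

    spec = ScenarioSpec(
        n_regions=15,
        variants_per_region=150,
        ld_rho=0.8,
        traits=traits,
        causal_plan=causal_plan,
        cluster_plan=cluster_plan,
        region_cluster=region_cluster,
        index_trait="t2d",
        seed=seed,
    )
    # Second conditionally independent signal in the two glycemic regions.
    spec.extra_signals = {8: {"t2d": (120, 10.0), "fg": (120, 8.0)},
                          9: {"t2d": (120, 10.0), "fg": (120, 8.0)}}
    return spec


# ---------------------------------------------------------------------------
# Low-level simulators
# ---------------------------------------------------------------------------


def simulate_ld(m: int, rho: float, blocks: int = 1, seed: int | None = None,
                ids: list[str] | None = None) -> LDMatrix:
    """Block-diagonal AR(1) LD: within a block r[i, j] = rho^|i-j|.

    AR(1) correlation matrices are positive definite for 0 <= rho < 1.  The
    ``seed`` argument is accepted for interface uniformity; the construction
    is deterministic.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    r = np.zeros((m, m))
    bounds = np.linspace(0, m, blocks + 1).astype(int)
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        k = b1 - b0
        idx = np.arange(k)
        r[b0:b1, b0:b1] = rho ** np.abs(idx[:, None] - idx[None, :])
    if ids is None:
        ids = [f"v{i}" for i in range(m)]
    return LDMatrix(ids, r)


def simulate_region_sumstats(
    ld: LDMatrix,
    lambdas: np.ndarray,
    n: int,
    eafs: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
    chrom: str = "1",
    positions: np.ndarray | None = None,
    alleles: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Draw one trait's marginal summary statistics for a region.

    z ~ MVN(R @ lambda, R); beta = z/sqrt(n), se = 1/sqrt(n) (standardized
    trait scale); p is the two-sided normal tail of z.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = len(ld)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.shape != (m,):
        raise ValueError(f"lambdas length {lambdas.shape} != LD dimension {m}")
    try:
        chol = np.linalg.cholesky(ld.r)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"LD matrix not positive definite: {exc}") from exc
    z = ld.r @ lambdas + chol @ rng.standard_normal(m)
    if eafs is None:
        eafs = rng.uniform(0.05, 0.95, size=m)
    if positions is None:
        positions = 1_000_000 + 3_000 * np.arange(m)
    if alleles is None:
        alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]
    sqrt_n = np.sqrt(n)
    df = pd.DataFrame({
        "SNP": ld.ids,
        "CHR": chrom,
        "POS": np.asarray(positions, dtype=int),
        "EA": [a for a, _ in alleles],
        "OA": [b for _, b in alleles],
        "EAF": np.asarray(eafs, dtype=float),
        "BETA": z / sqrt_n,
        "SE": np.full(m, 1.0 / sqrt_n),
        "P": 2 * stats.norm.sf(np.abs(z)),
        "N": n,
        "Z": z,
    })
    return df


# ---------------------------------------------------------------------------
# Whole-scenario dataset writer
# ---------------------------------------------------------------------------


def _region_signals(spec: ScenarioSpec, rid: int) -> list[dict[str, tuple[int, float]]]:
    signals = []
    if rid in spec.causal_plan:
        signals.append(spec.causal_plan[rid])
    extra = getattr(spec, "extra_signals", {})
    if rid in extra:
        signals.append(extra[rid])
    return signals


def make_scenario(spec: ScenarioSpec, out_dir: str | Path, force: bool = False) -> Path:
    """Write a complete dataset in the formats the I/O layer reads.

    Produces ``sumstats_<trait>.tsv`` per trait, ``leads.tsv``, one LD file
    per region under ``ld/``, a ``truth.tsv`` table recording planted causal
    sites, colocalization and cluster labels, and ``manifest.yaml``.  Output
    is byte-identical for a fixed spec and seed.
    """
    import yaml

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    (out / "ld").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(spec.seed)
    leads_rows, truth_rows = [], []
    per_trait_frames: dict[str, list[pd.DataFrame]] = {t.label: [] for t in spec.traits}

    for rid in range(spec.n_regions):
        m = spec.variants_per_region
        ids = [f"rs{rid}_{i}" for i in range(m)]
        chrom = str(rid + 1)
        positions = 1_000_000 + 3_000 * np.arange(m)
        ld = simulate_ld(m, spec.ld_rho, blocks=spec.ld_blocks, ids=ids)
        eafs = rng.uniform(0.05, 0.95, size=m)

        signals = _region_signals(spec, rid)
        causal_sites = {j for plan in signals for (j, lam) in plan.values() if lam != 0}

        # Allele pairs; a fixed fraction of non-causal variants are planted as
        # ambiguous palindromic (A/T or C/G with eaf near 0.5).
        alleles = [_ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))] for _ in range(m)]
        pal_candidates = [i for i in range(m) if i not in causal_sites]
        n_pal = int(round(spec.palindromic_rate * m))
        pal_idx = rng.choice(pal_candidates, size=min(n_pal, len(pal_candidates)), replace=False)
        for i in pal_idx:
            alleles[i] = _PALINDROMIC_PAIRS[int(rng.integers(len(_PALINDROMIC_PAIRS)))]
            eafs[i] = rng.uniform(0.42, 0.58)

        for trait in spec.traits:
            lambdas = np.zeros(m)
            for plan in signals:
                if trait.label in plan:
                    j, lam = plan[trait.label]
                    lambdas[j] += lam
            df = simulate_region_sumstats(
                ld, lambdas, trait.n, eafs=eafs, seed=rng,
                chrom=chrom, positions=positions, alleles=alleles,
            )
            df.insert(0, "REGION_ID", f"region{rid}")
            if trait.label != spec.index_trait:
                # Flip the reported allele orientation for a random subset so
                # harmonization is actually exercised.
                flip = rng.random(m) < 0.2
                df.loc[flip, ["EA", "OA"]] = df.loc[flip, ["OA", "EA"]].to_numpy()
                df.loc[flip, "BETA"] = -df.loc[flip, "BETA"]
                df.loc[flip, "Z"] = -df.loc[flip, "Z"]
                df.loc[flip, "EAF"] = 1.0 - df.loc[flip, "EAF"]
            per_trait_frames[trait.label].append(df)

        from .gwas_io import write_ld
        write_ld(ld, out / "ld" / f"region{rid}.ld.tsv")

        shared = spec.colocalized_regions().get(rid, [])
        for sig_no, plan in enumerate(signals):
            if spec.index_trait not in plan:
                continue
            j, lam = plan[spec.index_trait]
            leads_rows.append({
                "SNP": ids[j], "CHR": chrom, "POS": int(positions[j]), "REGION_ID": f"region{rid}",
            })
            for trait_label, (jt, lamt) in plan.items():
                truth_rows.append({
                    "REGION_ID": f"region{rid}",
                    "SIGNAL": sig_no,
                    "LEAD_SNP": ids[j],
                    "TRAIT": trait_label,
                    "CAUSAL_SNP": ids[jt],
                    "LAMBDA": lamt,
                    "COLOCALIZED": int(trait_label != spec.index_trait and jt == j and lamt != 0),
                    "CLUSTER": spec.region_cluster.get(rid) or "",
                })

    for trait in spec.traits:
        pd.concat(per_trait_frames[trait.label], ignore_index=True).drop(columns=["Z"]).to_csv(
            out / f"sumstats_{trait.label}.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(leads_rows).to_csv(out / "leads.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.10g")

    manifest = {
        "index_trait": spec.index_trait,
        "traits": [{"label": t.label, "n": t.n, "is_binary": t.is_binary} for t in spec.traits],
        "n_regions": spec.n_regions,
        "variants_per_region": spec.variants_per_region,
        "ld_rho": spec.ld_rho,
        "seed": spec.seed,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Individual-level dosages, phenotypes and covariates."""

    dosages: pd.DataFrame        # individuals x variants, entries in [0, 2]
    phenotypes: pd.DataFrame     # continuous and/or binary outcomes
    covariates: pd.DataFrame     # age, sex, cohort indicator, bmi
    true_score: np.ndarray | None = None


def simulate_cohort(
    n_ind: int,
    variants: pd.DataFrame,
    true_weights: np.ndarray,
    effect_on_outcome: float = 0.0,
    covariate_effects: dict[str, float] | None = None,
    binary_prevalence: float | None = None,
    seed: int | None = None,
) -> Cohort:
    """Simulate genotype dosages and outcomes driven by a true genetic score.

    ``variants`` needs columns SNP and EAF.  Dosages are Binomial(2, eaf).
    The continuous outcome is ``effect_on_outcome * standardized true score +
    covariate terms + N(0, 1)``; when ``binary_prevalence`` is given, a binary
    outcome is added through a logistic link whose intercept fixes the
    baseline prevalence.
    """
    covariate_effects = covariate_effects if covariate_effects is not None else {
        "age": 0.01, "sex": 0.1, "bmi": 0.2, "cohort": 0.05}
    if n_ind < len(covariate_effects) + 2:
        raise ValueError("cohort too small for the covariate set")
    rng = np.random.default_rng(seed)
    eaf = variants["EAF"].to_numpy(dtype=float)
    dosages = rng.binomial(2, eaf, size=(n_ind, len(eaf))).astype(float)
    dos = pd.DataFrame(dosages, columns=list(variants["SNP"]))

    covs = pd.DataFrame({
        "age": rng.normal(60, 8, n_ind),
        "sex": rng.integers(0, 2, n_ind).astype(float),
        "bmi": rng.normal(0, 1, n_ind),
        "cohort": rng.integers(0, 3, n_ind).astype(float),
    })
    raw = dosages @ np.asarray(true_weights, dtype=float)
    sd = raw.std(ddof=0)
    score = (raw - raw.mean()) / sd if sd > 0 else raw * 0.0

    cov_term = sum(b * (covs[c] - covs[c].mean()).to_numpy() for c, b in covariate_effects.items())
    cov_term = np.asarray(cov_term, dtype=float) if covariate_effects else np.zeros(n_ind)
    pheno = pd.DataFrame({
        "y_cont": effect_on_outcome * score + cov_term + rng.standard_normal(n_ind)})
    if binary_prevalence is not None:
        intercept = np.log(binary_prevalence / (1 - binary_prevalence))
        eta = intercept + effect_on_outcome * score + cov_term
        pheno["y_bin"] = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return Cohort(dosages=dos, phenotypes=pheno, covariates=covs, true_score=score)


# ---------------------------------------------------------------------------
# Direct simulators for the clustering and MR stages
# ---------------------------------------------------------------------------


#: Idiosyncratic variant profiles planted alongside the main clusters: their
#: pleiotropy patterns match no cluster (their strongest correlations to the
#: cluster signatures are negative and moderate), which is what keeps the
#: min-degree correlation cutoff realistic and yields the tiny surplus
#: communities that the size filter later excludes.
DEFAULT_ODDBALLS: list[dict[str, float]] = [
    {"bmi": -6.0, "hdl": 6.0},
    {"whr": -6.0, "fg": -6.0, "hdl": 6.0},
    {"whr": -6.0, "trig": 6.0},
]


def simulate_zmatrix(
    cluster_plan: dict[str, dict[str, float]],
    traits: list[str],
    per_cluster: int = 9,
    noise_sd: float = 0.8,
    magnitude_range: tuple[float, float] = (0.8, 1.2),
    oddballs: list[dict[str, float]] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Variant x trait z-score matrix with planted cluster signatures.

    Each cluster contributes ``per_cluster`` variants whose nonzero entries
    are the cluster's signature means scaled by a per-entry magnitude factor
    (loci differ in effect size) plus N(0, noise_sd) noise; entries at traits
    outside the signature are exactly 0, as in a gated sparse matrix.  A few
    ``oddballs`` — variants with idiosyncratic profiles belonging to no
    cluster, each its own truth label — are planted by default, emulating the
    variants that end up in very small communities in real data.  Returns the
    matrix and the true label per variant.
    """
    rng = np.random.default_rng(seed)
    oddballs = DEFAULT_ODDBALLS if oddballs is None else oddballs
    lo, hi = magnitude_range
    rows, labels, ids = [], [], []
    for cname, signature in cluster_plan.items():
        for i in range(per_cluster):
            row = np.zeros(len(traits))
            for t, mu in signature.items():
                row[traits.index(t)] = mu * rng.uniform(lo, hi) + noise_sd * rng.standard_normal()
            rows.append(row)
            labels.append(cname)
            ids.append(f"{cname}_{i}")
    for k, signature in enumerate(oddballs):
        row = np.zeros(len(traits))
        for t, mu in signature.items():
            if t in traits:
                row[traits.index(t)] = mu + noise_sd * rng.standard_normal()
        rows.append(row)
        labels.append(f"odd{k}")
        ids.append(f"odd{k}_0")
    zmat = pd.DataFrame(rows, index=ids, columns=traits)
    return zmat, pd.Series(labels, index=ids, name="CLUSTER")


def simulate_instruments(
    n_instruments: int = 50,
    slope: float = 0.5,
    r2_total: float = 0.02,
    n_exposure: int = 50_000,
    n_outcome: int = 50_000,
    direction: str = "forward",
    pleiotropy_intercept: float = 0.0,
    seed: int | None = None,
):
    """Simulate a two-sample MR instrument set with a known causal structure.

    ``forward``: instruments act on the exposure (jointly explaining
    ``r2_total`` of its variance) and affect the outcome only through it with
    the given causal ``slope``.  ``reverse``: instruments act on the outcome
    and the exposure is downstream, so the g-exposure effects are attenuated
    copies of the g-outcome effects — the configuration a directionality test
    must flag as outcome -> exposure.
    """
    from .mr import InstrumentSet

    rng = np.random.default_rng(seed)
    # heterogeneous per-variant explained variance (loci differ in effect size)
    share = rng.uniform(0.2, 1.8, n_instruments)
    share /= share.sum()
    b_true = np.sqrt(r2_total * share) * rng.choice([-1.0, 1.0], size=n_instruments)
    se_x = np.full(n_instruments, 1.0 / np.sqrt(n_exposure))
    se_y = np.full(n_instruments, 1.0 / np.sqrt(n_outcome))
    if direction == "forward":
        bx_true = b_true
        by_true = slope * b_true + pleiotropy_intercept * np.sign(b_true)
    elif direction == "reverse":
        by_true = b_true
        bx_true = slope * b_true
    else:
        raise ValueError("direction must be 'forward' or 'reverse'")
    return InstrumentSet(
        beta_exposure=bx_true + se_x * rng.standard_normal(n_instruments),
        se_exposure=se_x,
        beta_outcome=by_true + se_y * rng.standard_normal(n_instruments),
        se_outcome=se_y,
        n_exposure=n_exposure,
        n_outcome=n_outcome,
    )
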