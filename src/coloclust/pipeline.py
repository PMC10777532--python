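"""End-to-end orchestration: dataset -> panels -> colocalization events ->
Z matrix -> clusters -> partitioned polygenic scores -> MR directionality.

`run_pipeline` consumes a dataset directory in the layout written by
:func:`coloclust.synthetic.make_scenario` (per-trait summary-statistic TSVs,
a lead table, per-region LD matrices and a manifest) and runs every stage,
optionally writing the standard TSV outputs.  The PRS and MR validation
stages operate on a cohort simulated from the dataset itself, since the
analysis is self-contained: dosages are drawn at the clustered variants and
the outcome is driven by the index-trait genetic score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwas_io, network, prs, synthetic
from .coloc import ColocEvent, ColocPriors, run_region_workflow
from .finemap import SusieConfig
from .mr import InstrumentSet, MRModel, MRReport
from .network import ClusterConfig, ClusterSolution, ZMatrixConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    panels: dict[str, gwas_io.RegionPanel]
    events: list[ColocEvent]
    zmatrix: pd.DataFrame | None
    correlation: pd.DataFrame | None
    cutoff: float | None
    solution: ClusterSolution | None
    signature: pd.DataFrame | None
    prs_results: list[prs.AssocResult]
    mr_reports: dict[tuple[int, str], MRReport]
    index_trait: str

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.events:
            row = {
                "REGION_ID": ev.region_id, "METHOD": ev.method,
                "TRAITS": ",".join(ev.traits), "LEAD_SNP": ev.lead_id,
                "PR": ev.pr, "PA": ev.pa, "MIN_P": ev.min_trait_p,
            }
            for h in range(5):
                row[f"PP_H{h}"] = None if ev.pp is None else ev.pp[f"PP.H{h}"]
            rows.append(row)
        return pd.DataFrame(rows)


def build_panels(data_dir: str | Path, window: int = 500_000,
                 harmonize_cfg: gwas_io.HarmonizeConfig | None = None,
                 ) -> tuple[dict[str, gwas_io.RegionPanel], str, dict[str, pd.DataFrame]]:
    """Read a dataset directory and harmonize one panel per region id.

    Returns (panels keyed by region id, index trait, full per-trait summary
    statistics for later z lookups — harmonized orientation is taken from the
    panels themselves).
    """
    data = Path(data_dir)
    manifest = yaml.safe_load((data / "manifest.yaml").read_text())
    index_trait = manifest["index_trait"]
    traits = [t["label"] for t in manifest["traits"]]
    sumstats = {t: gwas_io.read_sumstats(data / f"sumstats_{t}.tsv") for t in traits}
    leads = gwas_io.read_leads(data / "leads.tsv")

    panels: dict[str, gwas_io.RegionPanel] = {}
    for rid, group in leads.groupby("REGION_ID", sort=True):
        # Anchor the region on the strongest index-trait lead.
        idx_df = sumstats[index_trait]
        strengths = [
            abs(float(idx_df.loc[idx_df["SNP"] == s, "Z"].iloc[0])) for s in group["SNP"]
        ]
        anchor = group.iloc[int(np.argmax(strengths))]
        lead = gwas_io.Variant(str(anchor.SNP), str(anchor.CHR), int(anchor.POS), "A", "G")
        region = gwas_io.RegionSpec.from_lead(lead, window=window, region_id=str(rid))
        region.n_signals = int(
            sum(region.contains(str(r.CHR), int(r.POS)) for r in group.itertuples()))
        per_trait = {}
        for t in traits:
            df = sumstats[t]
            sel = (df["CHR"] == lead.chrom) & df["POS"].between(region.start, region.end)
            per_trait[t] = df.loc[sel].reset_index(drop=True)
        ld = gwas_io.read_ld(data / "ld" / f"{rid}.ld.tsv")
        panel = gwas_io.harmonize_region(per_trait, index_trait, ld, region=region)
        if panel is None:
            continue
        # The effect-increasing lead variant with full allele annotation.
        idx_rec = panel.records[index_trait].set_index("SNP", drop=False)
        if lead.id in idx_rec.index:
            row = idx_rec.loc[lead.id]
            region.lead = gwas_io.Variant(str(row.SNP), str(row.CHR), int(row.POS),
                                          str(row.EA), str(row.OA), float(row.EAF))
        panel = gwas_io.resolve_palindromic(panel, harmonize_cfg)
        panels[str(rid)] = panel
    return panels, index_trait, sumstats


def harmonized_lookup(panels: dict[str, gwas_io.RegionPanel]) -> dict[str, pd.DataFrame]:
    """Per-trait harmonized records concatenated across regions, for z lookups."""
    frames: dict[str, list[pd.DataFrame]] = {}
    for panel in panels.values():
        for t, df in panel.records.items():
            frames.setdefault(t, []).append(df)
    return {t: pd.concat(dfs, ignore_index=True).drop_duplicates("SNP").set_index("SNP")
            for t, dfs in frames.items()}


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path | None = None,
    priors: ColocPriors | None = None,
    susie_cfg: SusieConfig | None = None,
    zmatrix_cfg: ZMatrixConfig | None = None,
    cluster_cfg: ClusterConfig | None = None,
    cohort_n: int = 20_000,
    cohort_effect: float = 0.3,
    seed: int = 0,
) -> PipelineResult:
    """Run every analysis stage on a dataset directory."""
    priors = priors or ColocPriors()
    susie_cfg = susie_cfg or SusieConfig()
    zmatrix_cfg = zmatrix_cfg or ZMatrixConfig()
    cluster_cfg = cluster_cfg or ClusterConfig(seed=seed)

    panels, index_trait, _ = build_panels(data_dir)
    events: list[ColocEvent] = []
    for rid in sorted(panels):
        events.extend(run_region_workflow(panels[rid], priors, susie_cfg))
    logger.info("%d colocalization events across %d regions",
                len(events), len({e.region_id for e in events}))

    zmat = corr = solution = signature = None
    cutoff = None
    prs_results: list[prs.AssocResult] = []
    mr_reports: dict[tuple[int, str], MRReport] = {}
    lookup = harmonized_lookup(panels)

    if events:
        zmat = network.build_zmatrix(events, lookup, zmatrix_cfg, index_trait=index_trait)
        if len(zmat) >= 2 and zmat.shape[1] >= 2:
            corr = network.snp_correlation(zmat)
            cutoff = network.min_degree_threshold(corr)
            try:
                solution = network.spinglass_cluster(corr, cutoff, cluster_cfg)
                signature = network.summarize_clusters(zmat, solution)
            except ValueError as exc:   # e.g. only negative-weight edges survive
                logger.warning("clustering stage skipped: %s", exc)

    if solution is not None and solution.retained:
        rng_seed = seed + 1
        idx_lookup = lookup[index_trait]
        clustered = [v for v, c in solution.membership.items() if c in solution.retained]
        weights = {v: float(idx_lookup.loc[v, "BETA"]) for v in clustered}
        var_table = pd.DataFrame({
            "SNP": clustered,
            "EAF": [float(idx_lookup.loc[v, "EAF"]) for v in clustered],
        })
        cohort = synthetic.simulate_cohort(
            cohort_n, var_table, np.array([weights[v] for v in clustered]),
            effect_on_outcome=cohort_effect, binary_prevalence=0.1, seed=rng_seed)
        cfg = prs.AssocConfig(m_tests=max(1, len(solution.retained) + 1))
        models = [prs.PRSModel("overall", weights)]
        for c, members in solution.retained_members().items():
            models.append(prs.PRSModel(f"cluster{c}", {v: weights[v] for v in members}))
        for model in models:
            score = prs.build_prs(cohort, model)
            prs_results.append(prs.test_association(
                score, cohort.phenotypes["y_cont"], cohort.covariates, cfg,
                label=model.label, outcome_name="y_cont"))
            prs_results.append(prs.test_association(
                score, cohort.phenotypes["y_bin"], cohort.covariates, cfg,
                binary=True, label=model.label, outcome_name="y_bin"))

        # MR per retained cluster: index trait as exposure, the cluster's
        # strongest-signature trait as outcome, cluster variants as instruments.
        sig_wide = signature.pivot(index="CLUSTER", columns="TRAIT", values="MEAN_Z")
        for c, members in solution.retained_members().items():
            if len(members) < 3:
                continue
            top_trait = sig_wide.loc[c].abs().idxmax()
            t_lookup = lookup[top_trait]
            ok = [v for v in members if v in t_lookup.index and v in idx_lookup.index]
            if len(ok) < 3:
                continue
            iv = InstrumentSet(
                beta_exposure=idx_lookup.loc[ok, "BETA"].to_numpy(dtype=float),
                se_exposure=idx_lookup.loc[ok, "SE"].to_numpy(dtype=float),
                beta_outcome=t_lookup.loc[ok, "BETA"].to_numpy(dtype=float),
                se_outcome=t_lookup.loc[ok, "SE"].to_numpy(dtype=float),
                n_exposure=int(idx_lookup.loc[ok, "N"].iloc[0]),
                n_outcome=int(t_lookup.loc[ok, "N"].iloc[0]),
                ids=ok,
            )
            mr_reports[(c, str(top_trait))] = MRModel(iv).fit()

    result = PipelineResult(
        panels=panels, events=events, zmatrix=zmat, correlation=corr, cutoff=cutoff,
        solution=solution, signature=signature, prs_results=prs_results,
        mr_reports=mr_reports, index_trait=index_trait,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.events_frame().to_csv(out / "coloc_events.tsv", sep="\t", index=False,
                                 float_format="%.6g")
    if result.zmatrix is not None:
        result.zmatrix.to_csv(out / "zmatrix.tsv", sep="\t", float_format="%.6g")
    if result.solution is not None:
        pd.DataFrame({
            "SNP": list(result.solution.membership),
            "CLUSTER": list(result.solution.membership.values()),
            "RETAINED": [int(c in result.solution.retained)
                         for c in result.solution.membership.values()],
        }).to_csv(out / "clusters.tsv", sep="\t", index=False)
    if result.signature is not None:
        result.signature.to_csv(out / "signatures.tsv", sep="\t", index=False,
                                float_format="%.6g")
    if result.prs_results:
        pd.DataFrame([{
            "MODEL": r.label, "OUTCOME": r.outcome, "N": r.n, "ESTIMATE": r.estimate,
            "CI_LOW": r.ci_low, "CI_HIGH": r.ci_high, "P": r.p,
            "SIG_BONF": int(r.significant_after_bonferroni),
        } for r in result.prs_results]).to_csv(out / "prs_assoc.tsv", sep="\t", index=False,
                                               float_format="%.6g")
    if result.mr_reports:
        pd.DataFrame([{
            "CLUSTER": c, "OUTCOME": t, "IVW_BETA": r.ivw_beta, "IVW_SE": r.ivw_se,
            "IVW_P": r.ivw_p, "EGGER_BETA": r.egger_beta, "EGGER_INTERCEPT": r.egger_intercept,
            "STEIGER_Z": r.steiger_z, "DIRECTION": r.inferred_direction,
            "PEARSON_R": r.pearson_r,
        } for (c, t), r in result.mr_reports.items()]).to_csv(
            out / "mr.tsv", sep="\t", index=False, float_format="%.6g")
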