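"""Reading, validation, regionalization and allele harmonization of GWAS summary statistics.

The unit of downstream analysis is the :class:`RegionPanel`: summary statistics for
several traits over a common, identically ordered variant set within one ~1 Mbp
region, together with an LD correlation matrix in the same order.  All effect
sizes in a panel are oriented to the allele that increases the index trait
(e.g. the disease-risk-increasing allele), so that a positive z-score for any
trait means "the risk allele raises this trait".

Coordinates are 1-based and region intervals are closed ``[start, end]``,
following GWAS summary-statistic convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column names for summary-statistic tables.
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

VALID_ALLELES = frozenset("ACGT")

#: Strand-ambiguous allele pairs (complement of each allele is the other one).
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))


class ConfigurationError(ValueError):
    """A required column or configuration value is missing or inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """A biallelic variant with its effect-allele orientation.

    ``effect_allele`` is the allele whose dosage the effect size refers to;
    ``eaf`` is that allele's frequency (may be NaN when unknown).
    """

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float = float("nan")

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"invalid alleles {self.effect_allele}/{self.other_allele} for {self.id}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"effect and other allele identical for {self.id}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1 for {self.id}")
        if not np.isnan(self.eaf) and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"eaf out of [0, 1] for {self.id}")

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in PALINDROMIC_PAIRS

    def flipped(self) -> "Variant":
        """Swap the allele orientation (effect <-> other, eaf -> 1 - eaf)."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf if not np.isnan(self.eaf) else self.eaf,
        )


@dataclass
class RegionSpec:
    """A fine-mapping/colocalization region anchored on a lead variant.

    ``n_signals`` counts the conditionally independent lead variants that fall
    inside the region; regions with more than one are analysed with
    multi-effect fine-mapping downstream.
    """

    lead: Variant | None
    start: int
    end: int
    window: int = 500_000
    n_signals: int = 1
    region_id: str | None = None

    @classmethod
    def from_lead(cls, lead: Variant, window: int = 500_000, region_id: str | None = None) -> "RegionSpec":
        return cls(
            lead=lead,
            start=max(1, lead.pos - window),
            end=lead.pos + window,
            window=window,
            region_id=region_id,
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.lead is not None and chrom == self.lead.chrom and self.start <= pos <= self.end


@dataclass
class LDMatrix:
    """Square matrix of pairwise genotype correlations r over an ordered variant list."""

    ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {m} variants")
        if m and not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if m and not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if m and (np.abs(self.r) > 1 + 1e-8).any():
            raise ValueError("LD correlations outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: list[str]) -> "LDMatrix":
        """Restrict to ``ids`` (kept in the order given)."""
        index = {v: i for i, v in enumerate(self.ids)}
        try:
            idx = [index[v] for v in ids]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]} not in LD matrix") from None
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])

    def r2(self, id1: str, id2: str) -> float:
        index = {v: i for i, v in enumerate(self.ids)}
        return float(self.r[index[id1], index[id2]] ** 2)


@dataclass
class HarmonizeConfig:
    """Palindromic-variant and proxy-substitution policy.

    Palindromic (A/T, C/G) variants with minor-allele frequency strictly inside
    ``(palindromic_maf_low, palindromic_maf_high)`` cannot be strand-resolved
    from allele labels and are removed; a removed lead is replaced by its best
    LD proxy when r^2 exceeds ``proxy_r2_min``.
    """

    palindromic_maf_low: float = 0.40
    palindromic_maf_high: float = 0.60
    proxy_r2_min: float = 0.80

    def __post_init__(self) -> None:
        if not 0 <= self.palindromic_maf_low < self.palindromic_maf_high <= 1:
            raise ConfigurationError("require 0 <= maf_low < maf_high <= 1")
        if not 0 < self.proxy_r2_min <= 1:
            raise ConfigurationError("proxy_r2_min must be in (0, 1]")


@dataclass
class RegionPanel:
    """Harmonized multi-trait summary statistics plus LD for one region.

    ``records`` maps trait label -> DataFrame with canonical columns plus Z,
    all sharing one ordered variant set identical to ``ld.ids``, oriented to
    the index trait's effect-increasing allele.
    """

    region: RegionSpec
    traits: list[str]
    records: dict[str, pd.DataFrame]
    ld: LDMatrix
    index_trait: str
    n_mismatch: int = 0
    n_palindromic_removed: int = 0

    def __post_init__(self) -> None:
        for trait, df in self.records.items():
            if list(df["SNP"]) != list(self.ld.ids):
                raise ValueError(f"panel variant order for trait {trait!r} does not match LD order")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.ld.ids)

    def z(self, trait: str) -> np.ndarray:
        return self.records[trait]["Z"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def read_sumstats(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-delimited summary-statistic file into canonical form.

    ``column_map`` maps canonical names (SNP, CHR, POS, EA, OA, EAF, BETA, SE,
    P, N) to the file's column names when they differ.  Rows with missing
    BETA/SE are dropped and rows with SE <= 0 rejected; both counts are logged
    and recorded in ``df.attrs`` (``n_dropped_missing``, ``n_rejected_se``).
    A Z column (BETA/SE) is added.
    """
    column_map = column_map or {}
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in df.columns:
            raise ConfigurationError(f"column {src!r} (for {canon}) missing from {path}")
        rename[src] = canon
    df = df.rename(columns=rename)[CANONICAL_COLUMNS].copy()
    df["CHR"] = df["CHR"].astype(str)
    df["EA"] = df["EA"].str.upper()
    df["OA"] = df["OA"].str.upper()

    n0 = len(df)
    df = df.dropna(subset=["BETA", "SE"])
    n_missing = n0 - len(df)
    bad_se = df["SE"] <= 0
    n_rejected = int(bad_se.sum())
    df = df.loc[~bad_se].reset_index(drop=True)
    if n_missing:
        logger.info("%s: dropped %d rows with missing beta/se", path, n_missing)
    if n_rejected:
        logger.info("%s: rejected %d rows with se <= 0", path, n_rejected)

    df["Z"] = df["BETA"] / df["SE"]
    df.attrs["n_dropped_missing"] = n_missing
    df.attrs["n_rejected_se"] = n_rejected
    return df


def read_leads(path: str | Path) -> pd.DataFrame:
    """Read a lead-variant table (SNP, CHR, POS and optional REGION_ID)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    for col in ("SNP", "CHR", "POS"):
        if col not in df.columns:
            raise ConfigurationError(f"lead table {path} missing column {col}")
    if "REGION_ID" not in df.columns:
        df["REGION_ID"] = [f"region{i}" for i in range(len(df))]
    df["REGION_ID"] = df["REGION_ID"].astype(str)
    return df


def read_ld(path: str | Path) -> LDMatrix:
    """Read an LD matrix: TSV with variant ids as first row and column, or an
    ``.npz`` container with arrays ``r`` and ``ids``."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as npz:
            return LDMatrix([str(v) for v in npz["ids"]], npz["r"])
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix([str(v) for v in df.index], df.to_numpy(dtype=float))


def write_ld(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.ids, columns=ld.ids).to_csv(path, sep="\t", float_format="%.10g")


def define_regions(leads: pd.DataFrame | list[Variant], window: int = 500_000) -> list[RegionSpec]:
    """One region per lead variant: ``[max(1, pos - window), pos + window]``.

    ``n_signals`` is the number of input leads (including the anchor itself)
    falling inside the region on the same chromosome.
    """
    if isinstance(leads, pd.DataFrame):
        variants = [
            Variant(
                id=str(row.SNP), chrom=str(row.CHR), pos=int(row.POS),
                effect_allele=getattr(row, "EA", "A"), other_allele=getattr(row, "OA", "G"),
            )
            for row in leads.itertuples()
        ]
        region_ids = (
            [str(r) for r in leads["REGION_ID"]] if "REGION_ID" in leads.columns else [None] * len(variants)
        )
    else:
        variants = list(leads)
        region_ids = [None] * len(variants)
    if not variants:
        raise ValueError("lead list is empty")
    regions = []
    for v, rid in zip(variants, region_ids):
        spec = RegionSpec.from_lead(v, window=window, region_id=rid)
        spec.n_signals = sum(1 for u in variants if spec.contains(u.chrom, u.pos))
        regions.append(spec)
    return regions


def _flip_rows(df: pd.DataFrame, mask: np.ndarray | pd.Series) -> pd.DataFrame:
    """Flip allele orientation for the masked rows: swap alleles, negate
    BETA/Z, complement EAF."""
    df = df.copy()
    mask = np.asarray(mask, dtype=bool)
    ea = df["EA"].to_numpy().copy()
    oa = df["OA"].to_numpy().copy()
    df.loc[mask, "EA"] = oa[mask]
    df.loc[mask, "OA"] = ea[mask]
    df.loc[mask, "BETA"] = -df.loc[mask, "BETA"]
    df.loc[mask, "Z"] = -df.loc[mask, "Z"]
    df.loc[mask, "EAF"] = 1.0 - df.loc[mask, "EAF"]
    return df


def harmonize_region(
    per_trait_records: dict[str, pd.DataFrame],
    index_trait: str,
    ld: LDMatrix,
    region: RegionSpec | None = None,
) -> RegionPanel | None:
    """Align all traits onto a common variant set oriented to the index trait.

    The panel's variant set is the intersection across traits (and the LD
    matrix), ordered as in the LD matrix.  Every variant is oriented so the
    index-trait beta is non-negative; other traits are reconciled by allele
    identity or swap only (strand flips are never attempted — strand-ambiguous
    variants are handled separately by :func:`resolve_palindromic`).  Variants
    whose allele pair cannot be reconciled are dropped and counted.

    Returns ``None`` (with a logged reason) when the intersection is empty.
    """
    if index_trait not in per_trait_records:
        raise ConfigurationError(f"index trait {index_trait!r} not among traits")

    shared: set[str] | None = None
    for df in per_trait_records.values():
        ids = set(df["SNP"])
        shared = ids if shared is None else shared & ids
    shared &= set(ld.ids)
    ordered = [v for v in ld.ids if v in shared]
    if not ordered:
        logger.warning("region %s skipped: empty variant intersection across traits",
                       region.region_id if region else "?")
        return None

    # Index trait: orient each variant to the effect-increasing allele.
    idx = per_trait_records[index_trait].set_index("SNP", drop=False).loc[ordered].reset_index(drop=True)
    idx = _flip_rows(idx, idx["BETA"].to_numpy() < 0)

    aligned: dict[str, pd.DataFrame] = {index_trait: idx}
    dropped: set[str] = set()
    ref_ea = idx["EA"].to_numpy()
    ref_oa = idx["OA"].to_numpy()
    for trait, df in per_trait_records.items():
        if trait == index_trait:
            continue
        sub = df.set_index("SNP", drop=False).loc[ordered].reset_index(drop=True)
        ea, oa = sub["EA"].to_numpy(), sub["OA"].to_numpy()
        direct = (ea == ref_ea) & (oa == ref_oa)
        swapped = (ea == ref_oa) & (oa == ref_ea)
        bad = ~(direct | swapped)
        if bad.any():
            dropped.update(np.asarray(ordered)[bad])
        aligned[trait] = _flip_rows(sub, swapped)

    n_mismatch = len(dropped)
    if n_mismatch:
        logger.info("region %s: dropped %d variants with irreconcilable alleles",
                    region.region_id if region else "?", n_mismatch)
        ordered = [v for v in ordered if v not in dropped]
        if not ordered:
            logger.warning("region %s skipped: no variants left after allele reconciliation",
                           region.region_id if region else "?")
            return None
        for trait in aligned:
            aligned[trait] = (
                aligned[trait].set_index("SNP", drop=False).loc[ordered].reset_index(drop=True)
            )

    if region is None:
        lead_row = aligned[index_trait].iloc[int(np.argmax(np.abs(aligned[index_trait]["Z"])))]
        lead = Variant(str(lead_row.SNP), str(lead_row.CHR), int(lead_row.POS),
                       str(lead_row.EA), str(lead_row.OA), float(lead_row.EAF))
        region = RegionSpec.from_lead(lead)

    return RegionPanel(
        region=region,
        traits=list(aligned),
        records=aligned,
        ld=ld.subset(ordered),
        index_trait=index_trait,
        n_mismatch=n_mismatch,
    )


def resolve_palindromic(panel: RegionPanel, cfg: HarmonizeConfig | None = None) -> RegionPanel:
    """Remove strand-ambiguous palindromic variants; proxy-substitute removed leads.

    A/T and C/G variants whose index-trait minor-allele frequency lies strictly
    inside the ambiguity band are removed from the panel.  If the region lead
    is removed, the non-palindromic variant with maximal r^2 to it is
    substituted as lead provided r^2 > ``proxy_r2_min``; otherwise the lead is
    dropped (``region.lead = None``) and logged.  Variants with missing EAF are
    exempt from the palindromic test (logged) but otherwise retained.
    """
    cfg = cfg or HarmonizeConfig()
    idx = panel.records[panel.index_trait]
    ea, oa = idx["EA"].to_numpy(), idx["OA"].to_numpy()
    pairs = [frozenset((a, b)) for a, b in zip(ea, oa)]
    is_pal = np.array([p in PALINDROMIC_PAIRS for p in pairs])
    eaf = idx["EAF"].to_numpy(dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    missing = np.isnan(eaf)
    if (is_pal & missing).any():
        logger.info("region %s: %d palindromic variants with missing EAF retained",
                    panel.region.region_id, int((is_pal & missing).sum()))
    ambiguous = is_pal & ~missing & (maf > cfg.palindromic_maf_low) & (maf < cfg.palindromic_maf_high)
    if not ambiguous.any():
        return panel

    removed_ids = set(np.asarray(panel.variant_ids)[ambiguous])
    kept = [v for v in panel.variant_ids if v not in removed_ids]
    region = replace(panel.region)
    if panel.region.lead is not None and panel.region.lead.id in removed_ids:
        lead_id = panel.region.lead.id
        li = panel.variant_ids.index(lead_id)
        r2 = panel.ld.r[li] ** 2
        candidates = [(r2[panel.variant_ids.index(v)], v) for v in kept]
        if candidates:
            best_r2, best_id = max(candidates)
        else:
            best_r2, best_id = 0.0, None
        if best_id is not None and best_r2 > cfg.proxy_r2_min:
            row = idx.set_index("SNP", drop=False).loc[best_id]
            region.lead = Variant(str(row.SNP), str(row.CHR), int(row.POS),
                                  str(row.EA), str(row.OA), float(row.EAF))
            logger.info("region %s: palindromic lead %s replaced by proxy %s (r2=%.3f)",
                        panel.region.region_id, lead_id, best_id, best_r2)
        else:
            region.lead = None
            logger.warning("region %s: palindromic lead %s dropped (best proxy r2=%.3f <= %.2f)",
                           panel.region.region_id, lead_id, best_r2, cfg.proxy_r2_min)

    if not kept:
        logger.warning("region %s: all variants palindromic-ambiguous", panel.region.region_id)
    records = {
        t: df.set_index("SNP", drop=False).loc[kept].reset_index(drop=True)
        for t, df in panel.records.items()
    }
    return RegionPanel(
        region=region,
        traits=panel.traits,
        records=records,
        ld=panel.ld.subset(kept),
        index_trait=panel.index_trait,
        n_mismatch=panel.n_mismatch,
        n_palindromic_removed=panel.n_palindromic_removed + len(removed_ids),
    )


# ---------------------------------------------------------------------------
# Panel serialization (one directory per region)
# ---------------------------------------------------------------------------


def save_panel(panel: RegionPanel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for trait, df in panel.records.items():
        df.to_csv(out / f"records_{trait}.tsv", sep="\t", index=False, float_format="%.10g")
    write_ld(panel.ld, out / "ld.tsv")
    lead = panel.region.lead
    meta = {
        "region_id": panel.region.region_id,
        "start": panel.region.start,
        "end": panel.region.end,
        "window": panel.region.window,
        "n_signals": panel.region.n_signals,
        "index_trait": panel.index_trait,
        "traits": panel.traits,
        "lead": None if lead is None else {
            "id": lead.id, "chrom": lead.chrom, "pos": lead.pos,
            "effect_allele": lead.effect_allele, "other_allele": lead.other_allele,
            "eaf": None if np.isnan(lead.eaf) else lead.eaf,
        },
    }
    (out / "region.json").write_text(json.dumps(meta, indent=1))


def load_panel(panel_dir: str | Path) -> RegionPanel:
    panel_dir = Path(panel_dir)
    meta = json.loads((panel_dir / "region.json").read_text())
    lead = None
    if meta["lead"] is not None:
        d = meta["lead"]
        lead = Variant(d["id"], d["chrom"], d["pos"], d["effect_allele"], d["other_allele"],
                       float("nan") if d["eaf"] is None else d["eaf"])
    region = RegionSpec(lead=lead, start=meta["start"], end=meta["end"], window=meta["window"],
                        n_signals=meta["n_signals"], region_id=meta["region_id"])
    records = {
        t: pd.read_csv(panel_dir / f"records_{t}.tsv", sep="\t", dtype={"CHR": str})
        for t in meta["traits"]
    }
    return RegionPanel(region=region, traits=meta["traits"], records=records,
                       ld=read_ld(panel_dir / "ld.tsv"), index_trait=meta["index_trait"])
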