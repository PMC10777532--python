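"""Summary-statistic reading, region definition and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from coloclust import gwas_io
from coloclust.gwas_io import (ConfigurationError, HarmonizeConfig, LDMatrix, RegionSpec,
                               Variant, define_regions, harmonize_region, read_sumstats,
                               resolve_palindromic)
from conftest import make_sumstats_frame


def _write(tmp_path, df, name="ss.tsv"):
    p = tmp_path / name
    df.to_csv(p, sep="\t", index=False)
    return p


class TestReadSumstats:
    def _base_frame(self):
        return pd.DataFrame({
            "SNP": ["rs1"], "CHR": [1], "POS": [100], "EA": ["a"], "OA": ["g"],
            "EAF": [0.3], "BETA": [0.1], "SE": [0.02], "P": [5e-7], "N": [50000],
        })

    def test_z_computed_and_alleles_uppercased(self, tmp_path):
        df = read_sumstats(_write(tmp_path, self._base_frame()))
        assert df.loc[0, "Z"] == pytest.approx(5.0)
        assert df.loc[0, "EA"] == "A" and df.loc[0, "OA"] == "G"

    def test_nonpositive_se_rejected_and_counted(self, tmp_path):
        base = self._base_frame()
        bad = base.copy()
        bad.loc[0, ["SNP", "SE"]] = ["rs2", 0.0]
        df = read_sumstats(_write(tmp_path, pd.concat([base, bad])))
        assert list(df["SNP"]) == ["rs1"]
        assert df.attrs["n_rejected_se"] == 1

    def test_missing_beta_dropped_and_counted(self, tmp_path):
        base = self._base_frame()
        bad = base.copy()
        bad.loc[0, ["SNP", "BETA"]] = ["rs2", np.nan]
        df = read_sumstats(_write(tmp_path, pd.concat([base, bad])))
        assert df.attrs["n_dropped_missing"] == 1 and len(df) == 1

    def test_order_preserved(self, tmp_path):
        rows = pd.concat([self._base_frame().assign(SNP=f"rs{i}") for i in range(10)])
        df = read_sumstats(_write(tmp_path, rows))
        assert list(df["SNP"]) == [f"rs{i}" for i in range(10)]

    def test_column_alias_mapping(self, tmp_path):
        renamed = self._base_frame().rename(columns={"SNP": "rsid", "BETA": "effect"})
        df = read_sumstats(_write(tmp_path, renamed),
                           column_map={"SNP": "rsid", "BETA": "effect"})
        assert df.loc[0, "SNP"] == "rs1"

    def test_missing_mapped_column_raises(self, tmp_path):
        with pytest.raises(ConfigurationError, match="BETA"):
            read_sumstats(_write(tmp_path, self._base_frame().drop(columns="BETA")))


class TestDefineRegions:
    def test_window_around_lead(self):
        lead = Variant("rs1", "1", 1_000_000, "A", "G")
        (r,) = define_regions([lead], window=500_000)
        assert (r.start, r.end) == (500_000, 1_500_000)

    def test_start_clamped_to_one(self):
        (r,) = define_regions([Variant("rs1", "1", 200_000, "A", "G")])
        assert r.start == 1

    def test_n_signals_counts_interval_membership(self):
        # brute-force check over all pairwise inclusion combinations
        leads = [Variant("rs1", "1", 1_000_000, "A", "G"),
                 Variant("rs2", "1", 1_300_000, "A", "G"),
                 Variant("rs3", "2", 1_000_000, "A", "G")]
        regions = define_regions(leads, window=500_000)
        for spec in regions:
            expected = sum(1 for u in leads if spec.contains(u.chrom, u.pos))
            assert spec.n_signals == expected
        assert regions[0].n_signals == 2 and regions[2].n_signals == 1

    def test_empty_leads_rejected(self):
        with pytest.raises(ValueError):
            define_regions([])


def _two_trait_input(index_betas=(-0.1, 0.2, 0.3)):
    ids = ["v0", "v1", "v2"]
    ld = LDMatrix(ids, np.eye(3))
    t1 = make_sumstats_frame(ids, index_betas, [0.02] * 3)
    t2 = make_sumstats_frame(ids, [0.05, -0.04, 0.07], [0.02] * 3)
    return {"t2d": t1, "bmi": t2}, ld


class TestHarmonize:
    def test_index_oriented_to_effect_increasing_allele(self):
        frames, ld = _two_trait_input()
        panel = harmonize_region(frames, "t2d", ld)
        idx = panel.records["t2d"]
        assert (idx["BETA"] >= 0).all()
        # v0 had beta -0.1 with A/G: emitted as G/A with +0.1, eaf complemented
        row = idx.set_index("SNP").loc["v0"]
        assert (row["EA"], row["OA"]) == ("G", "A")
        assert row["BETA"] == pytest.approx(0.1)
        assert row["EAF"] == pytest.approx(0.7)
        # the other trait is flipped consistently at v0
        assert panel.records["bmi"].set_index("SNP").loc["v0", "BETA"] == pytest.approx(-0.05)

    def test_irreconcilable_alleles_dropped_and_counted(self):
        frames, ld = _two_trait_input()
        frames["bmi"].loc[1, ["EA", "OA"]] = ["T", "C"]
        panel = harmonize_region(frames, "t2d", ld)
        assert panel.n_mismatch == 1
        assert "v1" not in panel.variant_ids

    def test_variant_set_is_intersection(self):
        ids = ["a", "b", "c", "d"]
        ld = LDMatrix(ids, np.eye(4))
        frames = {
            "t2d": make_sumstats_frame(["a", "b", "c"], [0.1] * 3, [0.02] * 3),
            "x": make_sumstats_frame(["a", "b"], [0.1] * 2, [0.02] * 2),
            "y": make_sumstats_frame(["a", "b", "d"], [0.1] * 3, [0.02] * 3),
        }
        panel = harmonize_region(frames, "t2d", ld)
        assert panel.variant_ids == ["a", "b"]

    def test_empty_intersection_returns_none(self):
        ld = LDMatrix(["a", "b"], np.eye(2))
        frames = {
            "t2d": make_sumstats_frame(["a"], [0.1], [0.02]),
            "x": make_sumstats_frame(["b"], [0.1], [0.02]),
        }
        assert harmonize_region(frames, "t2d", ld) is None

    def test_idempotent(self):
        frames, ld = _two_trait_input()
        panel = harmonize_region(frames, "t2d", ld)
        again = harmonize_region(panel.records, "t2d", panel.ld)
        for t in panel.traits:
            pd.testing.assert_frame_equal(panel.records[t], again.records[t])

    def test_flip_consistency(self):
        """Negating all betas and swapping alleles in the input yields an
        identical panel."""
        frames, ld = _two_trait_input()
        flipped = {}
        for t, df in frames.items():
            df = df.copy()
            df[["EA", "OA"]] = df[["OA", "EA"]].to_numpy()
            df["BETA"] = -df["BETA"]
            df["Z"] = -df["Z"]
            df["EAF"] = 1 - df["EAF"]
            flipped[t] = df
        p1 = harmonize_region(frames, "t2d", ld)
        p2 = harmonize_region(flipped, "t2d", ld)
        for t in p1.traits:
            pd.testing.assert_frame_equal(p1.records[t], p2.records[t])

    def test_variant_order_matches_ld(self, tiny_scenario):
        from coloclust.pipeline import build_panels

        _, data = tiny_scenario
        panels, _, _ = build_panels(data)
        for panel in panels.values():
            for df in panel.records.values():
                assert list(df["SNP"]) == panel.ld.ids


class TestResolvePalindromic:
    def _panel(self, eafs, alleles, r=None):
        ids = [f"v{i}" for i in range(len(eafs))]
        m = len(ids)
        ld = LDMatrix(ids, np.eye(m) if r is None else r)
        ea = [a for a, _ in alleles]
        oa = [b for _, b in alleles]
        frames = {"t2d": make_sumstats_frame(ids, [0.1] * m, [0.02] * m,
                                             ea=ea, oa=oa, eaf=list(eafs))}
        lead = Variant(ids[0], "1", 1_000_000, ea[0], oa[0], eafs[0])
        region = RegionSpec.from_lead(lead, region_id="r")
        return harmonize_region(frames, "t2d", ld, region=region)

    def test_ambiguous_palindromic_removed(self):
        panel = self._panel([0.3, 0.50], [("A", "G"), ("A", "T")])
        out = resolve_palindromic(panel)
        assert out.variant_ids == ["v0"]
        assert out.n_palindromic_removed == 1

    def test_unambiguous_palindromic_retained(self):
        panel = self._panel([0.3, 0.10], [("A", "G"), ("A", "T")])
        out = resolve_palindromic(panel)
        assert out.variant_ids == ["v0", "v1"]

    def test_missing_eaf_exempt(self):
        panel = self._panel([0.3, np.nan], [("A", "G"), ("A", "T")])
        out = resolve_palindromic(panel)
        assert "v1" in out.variant_ids

    def test_removed_lead_replaced_by_best_proxy(self):
        r = np.array([[1.0, 0.9, 0.3], [0.9, 1.0, 0.3], [0.3, 0.3, 1.0]])
        panel = self._panel([0.5, 0.3, 0.3], [("A", "T"), ("A", "G"), ("C", "T")], r=r)
        out = resolve_palindromic(panel)
        assert out.region.lead.id == "v1"  # r^2 = 0.81 > 0.8

    def test_removed_lead_without_proxy_dropped(self):
        r = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.3], [0.3, 0.3, 1.0]])
        panel = self._panel([0.5, 0.3, 0.3], [("A", "T"), ("A", "G"), ("C", "T")], r=r)
        out = resolve_palindromic(panel)
        assert out.region.lead is None


class TestTypes:
    def test_variant_invariants(self):
        with pytest.raises(ValueError):
            Variant("v", "1", 10, "A", "A")
        with pytest.raises(ValueError):
            Variant("v", "1", 0, "A", "G")
        with pytest.raises(ValueError):
            Variant("v", "1", 10, "A", "G", eaf=1.5)

    def test_ld_matrix_invariants(self):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[2.0, 0.5], [0.5, 1.0]]))

    def test_harmonize_config_invariants(self):
        with pytest.raises(ConfigurationError):
            HarmonizeConfig(palindromic_maf_low=0.7, palindromic_maf_high=0.6)
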