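"""Bayes factors, hypothesis enumeration and the staged region workflow."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coloclust import synthetic
from coloclust.coloc import (ColocPriors, coloc_abf, coloc_from_labf, multitrait_coloc,
                             run_region_workflow, wakefield_labf)
from coloclust.gwas_io import LDMatrix, RegionPanel, RegionSpec, Variant
from conftest import make_sumstats_frame


class TestWakefieldLabf:
    def test_zero_z_closed_form(self):
        # V = 0.01, W = 0.04: labf = 0.5 * log(0.01/0.05)
        assert wakefield_labf(0.0, 0.1, 0.04) == pytest.approx(0.5 * np.log(0.2))

    def test_strong_signal_closed_form(self):
        assert wakefield_labf(0.1, 0.02, 0.04) == pytest.approx(10.0687, abs=1e-4)

    def test_sign_symmetry_and_monotonicity(self):
        assert wakefield_labf(0.3, 0.05) == wakefield_labf(-0.3, 0.05)
        zs = np.linspace(0, 10, 50)
        vals = wakefield_labf(zs * 0.05, 0.05)
        assert np.all(np.diff(vals) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wakefield_labf(0.1, 0.0)
        with pytest.raises(ValueError):
            wakefield_labf(0.1, 0.1, W=0.0)


class TestColocEnumeration:
    def test_uninformative_data_returns_prior_masses(self):
        m = 10
        priors = ColocPriors()
        pp, _ = coloc_from_labf(np.zeros(m), np.zeros(m), priors)
        masses = np.array([
            1.0,
            priors.p1 * m,
            priors.p2 * m,
            priors.p1 * priors.p2 * m * (m - 1),
            priors.p12 * m,
        ])
        expected = masses / masses.sum()
        for i in range(5):
            assert pp[f"PP.H{i}"] == pytest.approx(expected[i], rel=1e-9)

    def test_swap_symmetry(self, rng):
        l1, l2 = rng.normal(0, 3, 20), rng.normal(0, 3, 20)
        a, _ = coloc_from_labf(l1, l2, ColocPriors())
        b, _ = coloc_from_labf(l2, l1, ColocPriors())
        assert a["PP.H1"] == pytest.approx(b["PP.H2"])
        assert a["PP.H2"] == pytest.approx(b["PP.H1"])
        for h in ("PP.H0", "PP.H3", "PP.H4"):
            assert a[h] == pytest.approx(b[h])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-30, 30), min_size=2, max_size=40),
           st.lists(st.floats(-30, 30), min_size=2, max_size=40))
    def test_posteriors_sum_to_one(self, l1, l2):
        k = min(len(l1), len(l2))
        pp, _ = coloc_from_labf(np.array(l1[:k]), np.array(l2[:k]), ColocPriors())
        assert sum(pp.values()) == pytest.approx(1.0, abs=1e-8)

    def test_h4_nondecreasing_in_p12(self, rng):
        l1 = rng.normal(0, 4, 30)
        l2 = l1 + rng.normal(0, 0.5, 30)
        h4 = [coloc_from_labf(l1, l2, ColocPriors(p12=p))[0]["PP.H4"]
              for p in (1e-7, 1e-6, 1e-5, 1e-4)]
        assert np.all(np.diff(h4) >= 0)

    def test_logspace_matches_naive_summation(self, rng):
        l1, l2 = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        priors = ColocPriors()
        pp, _ = coloc_from_labf(l1, l2, priors)
        a1, a2 = np.exp(l1), np.exp(l2)
        s1, s2, s12 = a1.sum(), a2.sum(), (a1 * a2).sum()
        masses = np.array([1.0, priors.p1 * s1, priors.p2 * s2,
                           priors.p1 * priors.p2 * (s1 * s2 - s12), priors.p12 * s12])
        expected = masses / masses.sum()
        for i in range(5):
            assert pp[f"PP.H{i}"] == pytest.approx(expected[i], abs=1e-10)

    def test_shared_signal_strongly_colocalizes(self, ar1_ld, rng):
        lam = np.zeros(150)
        lam[75] = 8.0
        t1 = synthetic.simulate_region_sumstats(ar1_ld, lam, 50_000, seed=rng)
        t2 = synthetic.simulate_region_sumstats(ar1_ld, lam, 50_000, seed=rng)
        ev = coloc_abf(t1, t2)
        assert ev.pp["PP.H4"] > 0.6
        assert abs(int(ev.lead_id[1:]) - 75) <= 5  # lead in tight LD with truth

    def test_too_few_variants_rejected(self):
        t = make_sumstats_frame(["a"], [0.1], [0.02])
        with pytest.raises(ValueError):
            coloc_abf(t, t)


def _panel(frames, ld, n_signals=1):
    lead = Variant(ld.ids[0], "1", 1_000_000, "A", "G", 0.3)
    region = RegionSpec.from_lead(lead, region_id="r")
    region.n_signals = n_signals
    return RegionPanel(region=region, traits=list(frames), records=frames, ld=ld,
                       index_trait=list(frames)[0])


class TestMultitraitColoc:
    def _shared_panel(self, ld, rng, traits=3, lam_val=8.0):
        lam = np.zeros(len(ld))
        lam[75] = lam_val
        frames = {}
        for i in range(traits):
            frames[f"t{i}"] = synthetic.simulate_region_sumstats(ld, lam, 50_000, seed=rng)
        return _panel(frames, ld)

    def test_all_traits_shared_accepted(self, ar1_ld, rng):
        panel = self._shared_panel(ar1_ld, rng)
        ev = multitrait_coloc(panel)
        assert ev.accepted and ev.pr * ev.pa > 0.60
        assert set(ev.traits) == {"t0", "t1", "t2"}

    def test_null_trait_dropped_first(self, ar1_ld, rng):
        panel = self._shared_panel(ar1_ld, rng, traits=2)
        panel.records["null"] = synthetic.simulate_region_sumstats(
            ar1_ld, np.zeros(150), 50_000, seed=rng)
        panel.traits = ["t0", "t1", "null"]
        ev = multitrait_coloc(panel)
        assert ev.accepted and "null" not in ev.traits

    def test_needs_two_traits(self, ar1_ld, rng):
        panel = self._shared_panel(ar1_ld, rng, traits=1)
        with pytest.raises(ValueError):
            multitrait_coloc(panel)


class TestRegionWorkflow:
    def test_null_region_emits_nothing(self, ar1_ld, rng):
        frames = {t: synthetic.simulate_region_sumstats(ar1_ld, np.zeros(150), 50_000, seed=rng)
                  for t in ("t2d", "bmi")}
        assert run_region_workflow(_panel(frames, ar1_ld)) == []

    def test_two_signal_region_resolved_by_finemapping(self, rng):
        ld = synthetic.simulate_ld(150, 0.8, blocks=2)
        lam_idx = np.zeros(150)
        lam_idx[[30, 110]] = 10.0
        lam_b = np.zeros(150)
        lam_b[30] = 8.0  # trait B shares only the first signal
        frames = {
            "t2d": synthetic.simulate_region_sumstats(ld, lam_idx, 74_000, seed=rng),
            "bmi": synthetic.simulate_region_sumstats(ld, lam_b, 100_000, seed=rng),
        }
        events = run_region_workflow(_panel(frames, ld, n_signals=2))
        assert len(events) == 1
        ev = events[0]
        assert ev.method == "susie"
        assert abs(int(ev.lead_id[1:]) - 30) <= 5

    def test_weak_signal_falls_back_to_single_causal(self, ar1_ld, rng):
        # strong enough to flag the region (P_R > 0.8) but too diffuse for
        # credible sets: moderate signal smeared by using a mismatched prior
        lam = np.zeros(150)
        lam[75] = 8.0
        frames = {
            "t2d": synthetic.simulate_region_sumstats(ar1_ld, lam, 74_000, seed=rng),
            "bmi": synthetic.simulate_region_sumstats(ar1_ld, lam, 100_000, seed=rng),
        }
        panel = _panel(frames, ar1_ld, n_signals=2)  # forces the fine-mapping path
        from coloclust.finemap import SusieConfig

        # absurdly high purity bar discards every credible set -> stage C
        events = run_region_workflow(panel, susie_cfg=SusieConfig(purity_min=1.1))
        assert events and all(ev.method == "abf-fallback" for ev in events)

    def test_false_positive_control_on_null_regions(self, ar1_ld):
        rng = np.random.default_rng(99)
        n_events = 0
        for _ in range(100):
            frames = {
                t: synthetic.simulate_region_sumstats(ar1_ld, np.zeros(150), 50_000, seed=rng)
                for t in ("t2d", "bmi")
            }
            n_events += bool(run_region_workflow(_panel(frames, ar1_ld)))
        assert n_events <= 1  # <= 1% of regions
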