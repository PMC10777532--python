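import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coloclust import synthetic
from coloclust.gwas_io import LDMatrix


@pytest.fixture(scope="session")
def ar1_ld():
    """150-variant AR(1) LD (rho = 0.8), the standard single-block region."""
    return synthetic.simulate_ld(150, 0.8)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_sumstats_frame(
    ids, betas, ses, chrom="1", pos0=1_000_000, ea="A", oa="G", eaf=0.3, n=50_000
):
    """Hand-build a canonical summary-statistic table for unit tests."""
    m = len(ids)
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    return pd.DataFrame({
        "SNP": ids,
        "CHR": chrom,
        "POS": pos0 + 1000 * np.arange(m),
        "EA": [ea] * m if isinstance(ea, str) else list(ea),
        "OA": [oa] * m if isinstance(oa, str) else list(oa),
        "EAF": eaf if np.ndim(eaf) else [eaf] * m,
        "BETA": betas,
        "SE": ses,
        "P": 2 * stats.norm.sf(np.abs(betas / ses)),
        "N": n,
        "Z": betas / ses,
    })


@pytest.fixture(scope="session")
def tiny_scenario(tmp_path_factory):
    """A 4-region, 60-variant, 3-trait dataset on disk with planted truth."""
    traits = [
        synthetic.TraitSpec("t2d", 74_000),
        synthetic.TraitSpec("bmi", 100_000),
        synthetic.TraitSpec("fg", 50_000),
    ]
    causal_plan = {
        0: {"t2d": (30, 10.0), "bmi": (30, 8.0)},       # colocalized
        1: {"t2d": (30, 10.0), "fg": (30, 8.0)},        # colocalized
        2: {"t2d": (20, 10.0), "bmi": (45, 8.0)},       # distinct causal variants
        3: {"t2d": (30, 10.0)},                         # index-only
    }
    spec = synthetic.ScenarioSpec(
        n_regions=4, variants_per_region=60, ld_rho=0.8, traits=traits,
        causal_plan=causal_plan,
        cluster_plan={"a": {"bmi": 8.0}, "b": {"fg": 8.0}},
        region_cluster={0: "a", 1: "b", 2: None, 3: None},
        index_trait="t2d", seed=7,
    )
    out = tmp_path_factory.mktemp("tiny") / "data"
    synthetic.make_scenario(spec, out)
    return spec, out
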