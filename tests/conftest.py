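import numpy as np
import pandas as pd
import pytest

from epimediate import MethylationMatrix, SimulationConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


def make_methylation(beta: np.ndarray, chrom="chr1", spacing=100,
                     start=1_000_000) -> MethylationMatrix:
    """Wrap a raw array as a MethylationMatrix with evenly spaced CpGs."""
    n, m = beta.shape
    cpgs = [f"cg{i:04d}" for i in range(m)]
    df = pd.DataFrame(beta, columns=cpgs,
                      index=[f"S{i:04d}" for i in range(n)])
    ann = pd.DataFrame({"chrom": chrom,
                        "pos": start + spacing * np.arange(m)}, index=cpgs)
    ann.index.name = "cpg"
    return MethylationMatrix(beta=df, annotation=ann)


@pytest.fixture(scope="session")
def default_cohort():
    """One defaults-shaped cohort pair, shared across read-only tests."""
    from epimediate import simulate_clinical_cohort, simulate_reference_panel
    cfg = SimulationConfig(n_panel=600, n_cohort=400, n_cpg=300, seed=1209)
    panel, truth = simulate_reference_panel(cfg)
    cohort = simulate_clinical_cohort(cfg, truth)
    return cfg, panel, truth, cohort
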