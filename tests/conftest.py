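import numpy as np
import pandas as pd
import pytest

from casevar import CohortStudy, SimulationConfig, simulate_study


def make_study(genotypes, phenotype=None, sex=None, cohort=None,
               chrom=None, pos=None, a1="A", a2="G"):
    """Build a CohortStudy from explicit arrays, for hand-worked examples."""
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    phenotype = (np.full(n, np.nan) if phenotype is None
                 else np.asarray(phenotype, dtype=float))
    sex = np.ones(n, dtype=int) if sex is None else np.asarray(sex, dtype=int)
    cohort = ["c0"] * n if cohort is None else list(cohort)
    samples = pd.DataFrame({
        "fid": [f"F{i}" for i in range(n)],
        "iid": [f"I{i}" for i in range(n)],
        "sex": sex, "phenotype": phenotype, "cohort": cohort,
    })
    variants = pd.DataFrame({
        "snp": [f"snp{j}" for j in range(m)],
        "chrom": ["1"] * m if chrom is None else list(chrom),
        "pos": list(range(1, m + 1)) if pos is None else list(pos),
        "a1": a1, "a2": a2,
    })
    return CohortStudy(g, samples, variants)


@pytest.fixture(scope="session")
def two_cohort_study():
    """A moderate ascertained two-cohort study with mild polygenic signal,
    shared by tests that only need realistic structure."""
    cfg = SimulationConfig(
        n_population=3500, m_snps=80, n_cohorts=2,
        n_cases=[120, 120], n_controls=[480, 480],
        maf_range=(0.1, 0.5), h2_liability=0.1, prevalence=0.2,
        n_causal_additive=20, sex_effect=0.2,
        cohort_effects=[0.0, 0.3], seed=42)
    return simulate_study(cfg)
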