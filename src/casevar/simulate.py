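"""Multi-cohort case-control simulation under the liability-threshold model.

Disease status arises when a latent liability exceeds the threshold implied
by the population prevalence K. Liability is composed of polygenic additive
effects (scaled so their realized variance fraction equals ``h2_liability``),
sex and cohort fixed effects, optional variance-QTL terms driven by a latent
binary exposure (the gene-environment mechanism a variance scan is meant to
flag without observing the exposure), and a Gaussian residual. Cohorts are
then ascertained to target case/control counts, emulating case-control
enrichment relative to a rare-disease prevalence.

All randomness descends from a single seed through spawned child generators,
so any sub-stream is reproducible in isolation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CohortStudy,
    SimulationConfig,
    SimulationShortfallError,
    VQtlSpec,
)
from .plinkio import write_plink

__all__ = ["simulate_genotypes", "simulate_study", "write_fixture", "table1_config"]

#: Case/control counts and male fractions of a six-cohort immune-disease
#: chip study (UK, US, two Swedish, Dutch and Spanish collections) used as
#: the default multi-cohort emulation target.
TABLE1_COHORTS = pd.DataFrame({
    "cohort": ["UK", "US", "SEE", "SEU", "NL", "ES"],
    "n_cases": [997, 593, 982, 237, 299, 215],
    "n_controls": [8414, 2118, 1927, 941, 1991, 394],
    "male_pct": [55.0, 67.4, 72.1, 68.7, 45.3, 68.0],
})


def simulate_genotypes(
    m_snps: int,
    n_samples: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int | np.random.Generator = 0,
    missing_rate: float = 0.0,
    mafs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw independent biallelic genotypes under Hardy-Weinberg equilibrium.

    Each SNP's allele frequency is sampled uniformly in ``maf_range``
    (or taken from ``mafs``); genotypes are Binomial(2, p). Returns
    ``(genotypes, mafs)`` where genotypes is ``(n_samples, m_snps)`` float
    with ``NaN`` for missing entries.
    """
    if m_snps < 1 or n_samples < 2:
        raise ValueError("need m_snps >= 1 and n_samples >= 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if mafs is None:
        lo, hi = maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        mafs = rng.uniform(lo, hi, size=m_snps)
    else:
        mafs = np.asarray(mafs, dtype=float)
        if mafs.shape != (m_snps,):
            raise ValueError("mafs must have length m_snps")
    g = rng.binomial(2, mafs[None, :], size=(n_samples, m_snps)).astype(float)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = np.nan
    return g, mafs


def _broadcast(config: SimulationConfig, name: str) -> list:
    return config.per_cohort(name)


def simulate_study(config: SimulationConfig) -> CohortStudy:
    """Simulate a multi-cohort case-control study with known ground truth.

    The returned study's ``truth`` dict records causal variant indices and
    effects, the per-sample latent exposures of each variance-QTL, the
    liabilities, the threshold, and the realized additive variance
    fraction — everything recovery tests need.
    """
    root = np.random.SeedSequence(config.seed)
    ss_freq, ss_geno, ss_pheno, ss_asc = root.spawn(4)
    rng_freq = np.random.default_rng(ss_freq)
    rng_pheno = np.random.default_rng(ss_pheno)
    rng_asc = np.random.default_rng(ss_asc)

    m = config.m_snps
    lo, hi = config.maf_range
    mafs = rng_freq.uniform(lo, hi, size=m)
    for v in config.vqtl_spec:
        if not 0 <= v.snp_index < m:
            raise ValueError(f"vqtl snp_index {v.snp_index} out of range")
        mafs[v.snp_index] = v.maf

    pops = _broadcast(config, "n_population")
    n_cases_t = _broadcast(config, "n_cases")
    n_controls_t = _broadcast(config, "n_controls")
    male_fracs = _broadcast(config, "male_fraction")
    cohort_effects = (list(config.cohort_effects)
                      if config.cohort_effects is not None
                      else [0.0] * config.n_cohorts)
    cohort_names = [f"cohort{c}" for c in range(config.n_cohorts)]

    n_pop_total = int(sum(pops))
    geno_rngs = [np.random.default_rng(s) for s in ss_geno.spawn(config.n_cohorts)]

    # genotypes per cohort share the panel allele frequencies
    geno_blocks = []
    for c in range(config.n_cohorts):
        g, _ = simulate_genotypes(m, int(pops[c]), seed=geno_rngs[c],
                                  missing_rate=config.missing_rate, mafs=mafs)
        geno_blocks.append(g)
    genotypes = np.vstack(geno_blocks)
    cohort_idx = np.repeat(np.arange(config.n_cohorts),
                           [int(p) for p in pops])

    # --- liability components -----------------------------------------
    vqtl_idx = {v.snp_index for v in config.vqtl_spec}
    candidates = np.setdiff1d(np.arange(m), np.fromiter(vqtl_idx, int, len(vqtl_idx)))
    if config.n_causal_additive > candidates.size:
        raise ValueError("not enough non-vQTL SNPs for the additive architecture")
    causal_idx = np.sort(rng_pheno.choice(candidates, size=config.n_causal_additive,
                                          replace=False))
    g_add = np.zeros(n_pop_total)
    causal_betas = np.zeros(config.n_causal_additive)
    if config.h2_liability > 0 and config.n_causal_additive > 0:
        causal_betas = rng_pheno.normal(size=config.n_causal_additive)
        gc = np.nan_to_num(genotypes[:, causal_idx] - 2 * mafs[causal_idx])
        g_add = gc @ causal_betas
        sd = g_add.std()
        if sd > 0:
            # scale realized additive values to variance exactly h2
            g_add *= np.sqrt(config.h2_liability) / sd
    sigma_e = np.sqrt(1.0 - config.h2_liability)
    resid = rng_pheno.normal(scale=sigma_e, size=n_pop_total)

    sex = np.where(
        rng_pheno.random(n_pop_total) < np.array(male_fracs)[cohort_idx],
        1, 2)  # 1=male, 2=female
    fixed = config.sex_effect * (sex == 1) + np.array(cohort_effects)[cohort_idx]

    exposures = np.zeros((n_pop_total, len(config.vqtl_spec)))
    vqtl_term = np.zeros(n_pop_total)
    for j, v in enumerate(config.vqtl_spec):
        e = (rng_pheno.random(n_pop_total) < v.exposure_prevalence).astype(float)
        exposures[:, j] = e
        gv = np.nan_to_num(genotypes[:, v.snp_index])
        vqtl_term += v.beta_additive * gv + v.beta_gxe * gv * e

    liability = fixed + g_add + vqtl_term + resid
    # threshold on the unit-variance (g + e) core; fixed and vQTL terms
    # shift individuals relative to it
    threshold = stats.norm.ppf(1.0 - config.prevalence)
    case = liability > threshold

    # --- ascertainment -------------------------------------------------
    keep = np.arange(n_pop_total)
    if n_cases_t[0] is not None:
        chosen = []
        for c in range(config.n_cohorts):
            in_c = np.where(cohort_idx == c)[0]
            cases_c = in_c[case[in_c]]
            ctrls_c = in_c[~case[in_c]]
            want_case, want_ctrl = int(n_cases_t[c]), int(n_controls_t[c])
            if cases_c.size < want_case or ctrls_c.size < want_ctrl:
                raise SimulationShortfallError(
                    f"cohort {cohort_names[c]}: simulated {cases_c.size} cases / "
                    f"{ctrls_c.size} controls, need {want_case}/{want_ctrl}; "
                    f"increase n_population or prevalence")
            chosen.append(rng_asc.choice(cases_c, want_case, replace=False))
            chosen.append(rng_asc.choice(ctrls_c, want_ctrl, replace=False))
        keep = np.sort(np.concatenate(chosen))

    samples = pd.DataFrame({
        "fid": [f"F{i}" for i in keep],
        "iid": [f"I{i}" for i in keep],
        "sex": sex[keep],
        "phenotype": case[keep].astype(float),
        "cohort": [cohort_names[c] for c in cohort_idx[keep]],
    })
    variants = pd.DataFrame({
        "snp": [f"snp{i}" for i in range(m)],
        "chrom": _spread_chromosomes(m),
        "pos": _positions(m),
        "a1": "A", "a2": "G",
    })
    var_add = float(np.var(g_add))
    truth = {
        "causal_idx": causal_idx,
        "causal_betas": causal_betas,
        "mafs": mafs,
        "vqtl_spec": list(config.vqtl_spec),
        "exposures": exposures[keep],
        "liability": liability[keep],
        "threshold": threshold,
        "population_case_fraction": float(case.mean()),
        "realized_h2_liability": var_add / (var_add + sigma_e ** 2),
        "config": config,
    }
    return CohortStudy(genotypes[keep], samples, variants, truth)


def _spread_chromosomes(m: int) -> np.ndarray:
    """Distribute SNPs over autosomes 1..22 in contiguous blocks."""
    per = -(-m // 22)
    chroms = np.repeat([str(c) for c in range(1, 23)], per)[:m]
    return chroms


def _positions(m: int) -> np.ndarray:
    """Positions spaced 20 kb apart, restarting per chromosome."""
    chroms = _spread_chromosomes(m)
    pos = np.zeros(m, dtype=int)
    for c in np.unique(chroms):
        idx = np.where(chroms == c)[0]
        pos[idx] = 1 + 20_000 * np.arange(idx.size)
    return pos


def write_fixture(study: CohortStudy, directory: str,
                  prefix: str = "study") -> str:
    """Write a study as a PLINK bed/bim/fam triple plus covariate table;
    returns the path prefix."""
    import os

    if study.n_samples < 1 or study.n_variants < 1:
        raise ValueError("cannot write an empty study")
    os.makedirs(directory, exist_ok=True)
    path_prefix = os.path.join(directory, prefix)
    write_plink(study, path_prefix)
    return path_prefix


def table1_config(m_snps: int = 50, prevalence: float = 0.2,
                  h2_liability: float = 0.045, seed: int = 0,
                  oversample: float = 1.4, **overrides) -> SimulationConfig:
    """A six-cohort config with the reference study's ascertained case and
    control counts and per-cohort male fractions.

    ``prevalence`` defaults to 0.2 here (not the disease's 0.01) purely so
    the pre-ascertainment population stays small; the ascertained counts —
    the quantity the structural checks use — do not depend on it.
    """
    t = TABLE1_COHORTS
    pops = [int(np.ceil(max(c / prevalence, n / (1 - prevalence)) * oversample))
            for c, n in zip(t["n_cases"], t["n_controls"])]
    kw = dict(
        n_population=pops,
        m_snps=m_snps,
        n_cohorts=6,
        n_cases=list(t["n_cases"]),
        n_controls=list(t["n_controls"]),
        male_fraction=[p / 100 for p in t["male_pct"]],
        prevalence=prevalence,
        h2_liability=h2_liability,
        n_causal_additive=min(m_snps // 2, 100) if h2_liability > 0 else 0,
        maf_range=(0.05, 0.5),
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def study_summary(study: CohortStudy) -> dict:
    """Combined-data totals in the format of the reference study's cohort
    table: sample/case/control counts and the male percentage."""
    ph = study.samples["phenotype"]
    return {
        "n_samples": int(len(study.samples)),
        "n_cases": int((ph == 1.0).sum()),
        "n_controls": int((ph == 0.0).sum()),
        "male_pct": float(100.0 * (study.samples["sex"] == 1).mean()),
    }


def expected_summary(config: SimulationConfig) -> dict:
    """Arithmetic (no simulation) expectation of :func:`study_summary`
    under ascertainment: totals of the per-cohort targets and the
    target-count-weighted male percentage."""
    cases = config.per_cohort("n_cases")
    ctrls = config.per_cohort("n_controls")
    males = config.per_cohort("male_fraction")
    if cases[0] is None:
        raise ValueError("expected_summary requires ascertainment targets")
    ns = [c + n for c, n in zip(cases, ctrls)]
    total = sum(ns)
    return {
        "n_samples": total,
        "n_cases": int(sum(cases)),
        "n_controls": int(sum(ctrls)),
        "male_pct": float(100.0 * sum(n * f for n, f in zip(ns, males)) / total),
    }
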