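"""Shared containers for the two-stage case-control vGWAS pipeline.

The universal carrier between stages is :class:`CohortStudy`: a
sample-by-variant minor-allele dosage matrix (``NaN`` = missing) plus
per-sample metadata (sex, cohort, case/control status) and per-variant
metadata (id, chromosome, position, alleles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

# Sex coding follows the PLINK .fam dialect.
SEX_MALE = 1
SEX_FEMALE = 2
SEX_UNKNOWN = 0

# Phenotype on the analysis (0/1) scale; NaN = missing.
CONTROL = 0.0
CASE = 1.0

#: Autosomes; variants elsewhere are excluded during QC.
AUTOSOMES = frozenset(str(c) for c in range(1, 23))

SAMPLE_COLUMNS = ("fid", "iid", "sex", "phenotype", "cohort")
VARIANT_COLUMNS = ("snp", "chrom", "pos", "a1", "a2")


class SimulationShortfallError(RuntimeError):
    """Raised when a simulated population cannot supply the requested
    number of ascertained cases or controls."""


class PlinkFormatError(ValueError):
    """Raised on malformed bed/bim/fam input."""


class EmptyStudyError(ValueError):
    """Raised when QC removes every sample or every variant."""


@dataclass
class CohortStudy:
    """Genotypes plus sample and variant metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_variants)`` float array of allele-1 (minor-allele)
        dosages in {0, 1, 2}; missing genotypes are ``NaN``.
    samples
        Data frame with columns ``fid, iid, sex, phenotype, cohort``.
        ``sex`` uses 1=male / 2=female / 0=unknown; ``phenotype`` is
        1.0=case / 0.0=control / NaN=missing.
    variants
        Data frame with columns ``snp, chrom, pos, a1, a2`` (1-based
        positions, chromosome as string).
    truth
        Optional ground-truth bookkeeping attached by the simulator
        (causal indices, latent exposures, liabilities).
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x variants)")
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError(
                f"genotype rows ({n}) != sample records ({len(self.samples)})"
            )
        if len(self.variants) != m:
            raise ValueError(
                f"genotype columns ({m}) != variant records ({len(self.variants)})"
            )
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"samples missing column {col!r}")
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variants missing column {col!r}")
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.samples["iid"].astype(str))

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.variants["snp"].astype(str))

    @property
    def phenotype(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy(dtype=float)

    # -- slicing --------------------------------------------------------
    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "CohortStudy":
        """Positional subset of samples and/or variants (copy)."""
        g = self.genotypes
        samples = self.samples
        variants = self.variants
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            g = g[sample_idx, :]
            samples = samples.iloc[sample_idx]
        if variant_idx is not None:
            variant_idx = np.asarray(variant_idx)
            g = g[:, variant_idx]
            variants = variants.iloc[variant_idx]
        return CohortStudy(g.copy(), samples.copy(), variants.copy(), self.truth)

    def select_samples_by_id(self, ids: Sequence[str]) -> "CohortStudy":
        pos = pd.Index(self.samples["iid"].astype(str)).get_indexer(ids)
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"sample ids not in study: {missing[:5]}")
        return self.subset(sample_idx=pos)

    def variant_index(self, snp: str) -> int:
        pos = self.variant_ids.get_indexer([snp])[0]
        if pos < 0:
            raise KeyError(f"variant {snp!r} not in study")
        return int(pos)


@dataclass
class VQtlSpec:
    """A planted variance-QTL: a SNP whose per-allele interaction with a
    latent binary exposure creates residual-variance heterogeneity across
    genotype groups (the signature the Brown-Forsythe scan detects)."""

    snp_index: int
    maf: float
    exposure_prevalence: float
    beta_gxe: float
    beta_additive: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("vQTL maf must be in (0, 0.5]")
        if not 0.0 < self.exposure_prevalence < 1.0:
            raise ValueError("exposure_prevalence must be in (0, 1)")


@dataclass
class SimulationConfig:
    """Parameters of a multi-cohort case-control liability simulation.

    ``n_population``, ``n_cases``, ``n_controls`` and ``male_fraction``
    accept either a scalar (applied to every cohort) or one value per
    cohort. ``n_cases=None`` disables ascertainment: the study is the
    whole simulated population (a population sample).
    """

    n_population: int | Sequence[int]
    m_snps: int
    n_cohorts: int = 1
    n_cases: int | Sequence[int] | None = None
    n_controls: int | Sequence[int] | None = None
    maf_range: tuple[float, float] = (0.01, 0.5)
    h2_liability: float = 0.045
    prevalence: float = 0.01
    n_causal_additive: int = 0
    vqtl_spec: list[VQtlSpec] = field(default_factory=list)
    sex_effect: float = 0.0
    cohort_effects: Sequence[float] | None = None
    male_fraction: float | Sequence[float] = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence K must be in (0, 1)")
        if not 0.0 <= self.h2_liability < 1.0:
            raise ValueError("h2_liability must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.m_snps < 1 or self.n_cohorts < 1:
            raise ValueError("m_snps and n_cohorts must be >= 1")
        if self.n_causal_additive > self.m_snps:
            raise ValueError("n_causal_additive exceeds m_snps")
        if (self.n_cases is None) != (self.n_controls is None):
            raise ValueError("n_cases and n_controls must be given together")
        if self.cohort_effects is not None and len(self.cohort_effects) != self.n_cohorts:
            raise ValueError("cohort_effects length must equal n_cohorts")
        # Feasibility of ascertainment in expectation, per cohort.
        if self.n_cases is not None:
            for pop, ncase in zip(self.per_cohort("n_population"),
                                  self.per_cohort("n_cases")):
                if ncase > self.prevalence * pop:
                    raise ValueError(
                        f"n_cases={ncase} exceeds expected cases "
                        f"K*n_population={self.prevalence * pop:.1f} in a cohort"
                    )

    def per_cohort(self, name: str) -> list:
        """Broadcast a scalar-or-sequence field to one value per cohort."""
        v = getattr(self, name)
        if v is None:
            return [None] * self.n_cohorts
        if np.isscalar(v):
            return [v] * self.n_cohorts
        v = list(v)
        if len(v) != self.n_cohorts:
            raise ValueError(f"{name} must be scalar or length n_cohorts")
        return v

    @classmethod
    def from_file(cls, path: str) -> "SimulationConfig":
        """Load a config from YAML or JSON mirroring the field names."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)  # YAML is a superset of JSON
        vqtls = [VQtlSpec(**v) for v in raw.pop("vqtl_spec", [])]
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(vqtl_spec=vqtls, **raw)

    def to_file(self, path: str) -> None:
        import yaml

        d = dict(self.__dict__)
        d["vqtl_spec"] = [dict(v.__dict__) for v in self.vqtl_spec]
        d["maf_range"] = list(self.maf_range)
        if d["cohort_effects"] is not None:
            d["cohort_effects"] = list(d["cohort_effects"])
        for k, v in list(d.items()):
            if isinstance(v, np.generic):
                d[k] = v.item()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class QcThresholds:
    """Per-cohort quality-control thresholds (kept iff strictly better):
    MAF > maf_min, SNP call rate > snp_call_min, sample call rate >
    sample_call_min, HWE exact P >= hwe_p_min."""

    maf_min: float = 0.01
    snp_call_min: float = 0.95
    sample_call_min: float = 0.99
    hwe_p_min: float = 1.0e-4
    hwe_controls_only: bool = False

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_call_min", "sample_call_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QcReport:
    """Counts of removals per QC criterion."""

    samples_low_call: int = 0
    variants_low_maf: int = 0
    variants_low_call: int = 0
    variants_hwe_fail: int = 0
    variants_nonautosomal: int = 0
    variants_removed_total: int = 0
    variants_unresolvable_alleles: int = 0  # used by merge_cohorts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"criterion": list(self.__dict__), "count_removed": list(self.__dict__.values())}
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class GRM:
    """Genetic relationship matrix with its sample index."""

    matrix: np.ndarray
    sample_ids: pd.Index
    m_snps_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.sample_ids = pd.Index(self.sample_ids)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM dimension does not match sample index")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def subset_ids(self, ids: Sequence[str]) -> "GRM":
        pos = self.sample_ids.get_indexer(ids)
        if (pos < 0).any():
            raise KeyError("sample ids not present in GRM")
        return GRM(self.matrix[np.ix_(pos, pos)], pd.Index(ids), self.m_snps_used)


@dataclass
class LiabilityFit:
    """Stage-one result: variance components on the observed 0/1 scale,
    fixed effects, BLUP polygenic predictions and the non-additive
    residuals that become the trait of the variance scan."""

    sigma2_g: float
    sigma2_e: float
    h2_observed: float
    h2_liability: float
    fixed_effects: pd.Series
    blup: np.ndarray
    residuals: pd.Series  # indexed by sample iid
    converged: bool
    n_iterations: int
    loglik_path: list[float] = field(default_factory=list)
    prevalence: float | None = None
    sample_case_fraction: float | None = None


@dataclass
class VGwasResult:
    """Stage-two result: per-variant Brown-Forsythe statistics with the
    companion additive-GWAS p-values and inflation diagnostics."""

    table: pd.DataFrame  # snp chrom pos k_observed t2 df p_vgwas p_additive skip_reason
    genome_wide: float = 5.0e-8
    chip_wide: float = 2.5e-5
    lambda_gc: float = float("nan")

    def lead_snps(self, window_bp: int = 1_000_000,
                  max_p: float | None = None) -> pd.DataFrame:
        """Greedy 1-Mb clumping: repeatedly take the smallest-p variant and
        suppress others within ``window_bp`` on the same chromosome."""
        t = self.table.dropna(subset=["p_vgwas"]).sort_values("p_vgwas")
        if max_p is not None:
            t = t[t["p_vgwas"] <= max_p]
        leads = []
        taken: list[tuple[str, int]] = []
        for _, row in t.iterrows():
            if any(c == row["chrom"] and abs(int(row["pos"]) - p) <= window_bp
                   for c, p in taken):
                continue
            leads.append(row)
            taken.append((row["chrom"], int(row["pos"])))
        return pd.DataFrame(leads).reset_index(drop=True)

    def to_tsv(self, path: str) -> None:
        out = self.table.rename(
            columns={"snp": "SNP", "chrom": "CHR", "pos": "BP",
                     "k_observed": "K_GROUPS", "t2": "T2", "df": "DF",
                     "p_vgwas": "P_VGWAS", "p_additive": "P_GWAS"}
        )
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class CVReport:
    """Discovery/validation bookkeeping over split-half iterations.

    ``records`` holds one row per (snp, iteration, half) with the vGWAS P;
    ``summary`` one row per snp with counts over iterations."""

    records: pd.DataFrame  # snp iter half p discovered_gw discovered_chip validated
    summary: pd.DataFrame  # snp n_discovered_genomewide n_discovered_chipwide n_validated
    iterations: int
    seed: int
    failed_iterations: list[int] = field(default_factory=list)

    def to_tsv(self, path: str) -> None:
        out = self.records.rename(columns=str.upper)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class InteractionResult:
    """Likelihood-ratio test of the genotype-by-factor block in the
    logistic disease model."""

    snp_g: str
    factor: str
    df: int
    lrt_stat: float
    p: float
    beta_g: pd.Series
    beta_f: pd.Series
    beta_gf: pd.Series
    wald_p: float | None = None
    bonferroni_alpha: float | None = None
    estimable: bool = True
    dropped_cells: int = 0
    ll_full: float = float("nan")
    ll_reduced: float = float("nan")

    @property
    def significant_nominal(self) -> bool:
        return self.estimable and self.p < 0.05

    @property
    def significant_adjusted(self) -> bool:
        return (self.estimable and self.bonferroni_alpha is not None
                and self.p < self.bonferroni_alpha)


def interaction_results_to_frame(results: list[InteractionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "SNP": r.snp_g, "FACTOR": r.factor, "DF": r.df, "LRT": r.lrt_stat,
            "P": r.p, "P_ADJ_ALPHA": r.bonferroni_alpha,
            "FLAGS": ";".join(
                f for f, on in [("nominal", r.significant_nominal),
                                ("adjusted", r.significant_adjusted),
                                ("non_estimable", not r.estimable)] if on
            ),
        })
    return pd.DataFrame(rows)
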