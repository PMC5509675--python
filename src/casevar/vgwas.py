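"""Stage two: Brown-Forsythe variance-heterogeneity scan on the stage-one
residuals, a companion additive logistic GWAS, thresholding and genomic
inflation diagnostics.

The per-SNP statistic compares residual spread across genotype groups via
absolute deviations from each group's median:

    T2 = (N - k) * sum_j n_j (Zbar_j - Zbar)^2
         -----------------------------------
         (k - 1)  * sum_i (Z_i - Zbar_{g(i)})^2

with Z_i = |y_i - median(y in group g(i))|, k retained genotype groups and
N retained samples. P-values come from the F(k-1, N-k) reference
distribution; the chi-square limit (k-1)*T2 ~ chi2_{k-1} is the large-N
behaviour and is exercised as a property of the statistic rather than used
for inference.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortStudy, VGwasResult

__all__ = ["brown_forsythe_stat", "vgwas_scan", "additive_gwas_scan",
           "genomic_inflation", "MonomorphicVariantError",
           "DegenerateGroupsError"]

GENOME_WIDE = 5.0e-8
CHIP_WIDE = 2.5e-5


class MonomorphicVariantError(ValueError):
    """Fewer than two genotype groups survive the group-size floor."""


class DegenerateGroupsError(ValueError):
    """All within-group deviations identical; the statistic is undefined."""


def brown_forsythe_stat(
    residuals: np.ndarray,
    genotypes: np.ndarray,
    group_min: int = 2,
) -> tuple[float, int, float]:
    """Brown-Forsythe (median-centred Levene) test of equal residual
    variance across genotype groups.

    Missing genotypes or residuals are excluded pairwise; genotype groups
    with fewer than ``group_min`` members are dropped (their samples
    excluded and k reduced). Returns ``(T2, df, p)`` with df = k - 1 and p
    from F(k-1, N-k).
    """
    y = np.asarray(residuals, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    if y.shape != g.shape:
        raise ValueError("residuals and genotypes must be aligned 1-D arrays")
    ok = ~(np.isnan(y) | np.isnan(g))
    y, g = y[ok], g[ok]

    groups = []
    for val in (0.0, 1.0, 2.0):
        yj = y[g == val]
        if yj.size >= group_min:
            groups.append(yj)
    k = len(groups)
    if k < 2:
        raise MonomorphicVariantError(
            f"only {k} genotype group(s) of size >= {group_min}")

    z_groups = [np.abs(yj - np.median(yj)) for yj in groups]
    n_j = np.array([zj.size for zj in z_groups])
    n = int(n_j.sum())
    zbar_j = np.array([zj.mean() for zj in z_groups])
    zbar = float(np.concatenate(z_groups).mean())
    numer = (n - k) * float(np.sum(n_j * (zbar_j - zbar) ** 2))
    denom = (k - 1) * float(sum(np.sum((zj - zb) ** 2)
                                for zj, zb in zip(z_groups, zbar_j)))
    if denom == 0.0:
        raise DegenerateGroupsError("zero within-group deviation spread")
    t2 = numer / denom
    p = float(stats.f.sf(t2, k - 1, n - k))
    return float(t2), k - 1, max(p, np.finfo(float).tiny)


def vgwas_scan(
    study: CohortStudy,
    residuals: pd.Series,
    group_min: int = 2,
    genome_wide: float = GENOME_WIDE,
    chip_wide: float = CHIP_WIDE,
    p_additive: pd.Series | None = None,
) -> VGwasResult:
    """Apply the Brown-Forsythe test to every variant.

    ``residuals`` must be indexed by sample iid and cover a subset of the
    study's samples; unknown ids raise an alignment error. Variants whose
    statistic is undefined carry a ``skip_reason`` instead of a p-value.
    """
    res_ids = pd.Index(residuals.index.astype(str))
    unknown = res_ids.difference(study.sample_ids)
    if len(unknown):
        raise ValueError(
            f"residual sample ids absent from study: {list(unknown[:5])}")
    sub = study.select_samples_by_id(list(res_ids))
    y = residuals.to_numpy(dtype=float)

    rows = []
    for j in range(sub.n_variants):
        rec = {
            "snp": sub.variants["snp"].iloc[j],
            "chrom": str(sub.variants["chrom"].iloc[j]),
            "pos": int(sub.variants["pos"].iloc[j]),
            "k_observed": np.nan, "t2": np.nan, "df": np.nan,
            "p_vgwas": np.nan, "p_additive": np.nan, "skip_reason": "",
        }
        try:
            t2, df, p = brown_forsythe_stat(y, sub.genotypes[:, j], group_min)
            rec.update(k_observed=df + 1, t2=t2, df=df, p_vgwas=p)
        except MonomorphicVariantError:
            rec["skip_reason"] = "monomorphic"
        except DegenerateGroupsError:
            rec["skip_reason"] = "degenerate"
        rows.append(rec)
    table = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    if p_additive is not None:
        table["p_additive"] = table["snp"].map(p_additive).to_numpy()

    valid = table["p_vgwas"].dropna()
    lam = genomic_inflation(valid.to_numpy()) if len(valid) >= 100 else np.nan
    return VGwasResult(table=table, genome_wide=genome_wide,
                       chip_wide=chip_wide, lambda_gc=lam)


def additive_gwas_scan(
    study: CohortStudy,
    covariates: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-variant logistic regression of case status on allele dosage plus
    covariates (default: intercept, sex, cohort indicators); returns the
    Wald p-value of the dosage coefficient, NaN where the fit separates."""
    import statsmodels.api as sm

    from .partition import build_covariates

    if covariates is None:
        covariates = build_covariates(study)
    sub = study.select_samples_by_id(list(covariates.index.astype(str)))
    y = sub.phenotype
    if np.isnan(y).any():
        raise ValueError("phenotype must be non-missing")
    x0 = covariates.to_numpy(dtype=float)

    pvals = np.full(sub.n_variants, np.nan)
    for j in range(sub.n_variants):
        dose = sub.genotypes[:, j]
        ok = ~np.isnan(dose)
        if np.nanstd(dose) == 0:
            continue
        x = np.column_stack([dose[ok], x0[ok]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y[ok], x).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True):
                continue
            pvals[j] = fit.pvalues[0]
        except Exception:
            continue  # separation or singular fit: recorded as missing
    return pd.Series(pvals, index=sub.variants["snp"].to_numpy())


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median of the 1-df chi-square quantiles
    implied by the p-values, divided by the null median 0.4549. Multi-df
    statistics are converted through their p-values, i.e. to 1-df
    equivalents, before taking the median."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        raise ValueError("genomic inflation needs >= 100 p-values")
    chi = stats.chi2.isf(np.clip(p, np.finfo(float).tiny, 1.0), df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
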