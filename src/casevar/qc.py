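"""Genotype quality control and cohort merging.

Filters follow the usual chip-data protocol: per-cohort MAF, SNP and sample
call rates, and a Hardy-Weinberg exact test; cohorts are merged on the
common variant set with allele-orientation harmonization. QC is a single
deterministic pass: samples first (call rate), then variants, each variant
criterion evaluated on the sample-filtered matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    AUTOSOMES,
    CohortStudy,
    EmptyStudyError,
    QcReport,
    QcThresholds,
)
from .plinkio import read_plink, write_plink  # noqa: F401  (module surface)

__all__ = ["read_plink", "write_plink", "hwe_exact_test", "qc_filter",
           "merge_cohorts", "genotype_counts"]


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg exact test.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count (Wigginton-style). Returns P in (0, 1].
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # minor allele count
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic: a single possible outcome

    # Heterozygote counts share the parity of the minor-allele count.
    het_obs = n_Aa
    mid = n_rare  # maximum possible heterozygote count
    # Unnormalized conditional probabilities by the standard recurrence,
    # anchored at (approximately) the mode so values stay in [0, 1] and
    # cannot overflow; tails underflow to zero harmlessly.
    probs = np.zeros(mid + 1)
    start = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if (start % 2) != (n_rare % 2):
        start += 1
    start = min(start, mid)
    probs[start] = 1.0
    het = start
    while het >= 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het - 2] = probs[het] * het * (het - 1) / (
            4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    het = start
    while het <= mid - 2 and probs[het] > 0:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / (
            (het + 2) * (het + 1))
        het += 2
    total = probs.sum()
    p_obs = probs[het_obs] / total
    p = probs[probs / total <= p_obs * (1 + 1e-12)].sum() / total
    return float(min(1.0, p))


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """Counts of (hom A1, het, hom A2) over non-missing entries."""
    d = dosages[~np.isnan(dosages)]
    return int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())


def _variant_stats(study: CohortStudy, controls_only: bool = False):
    g = study.genotypes
    miss = np.isnan(g)
    call_rate = 1.0 - miss.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)

    if controls_only:
        mask = study.samples["phenotype"].to_numpy() == 0.0
        g_hwe = g[mask]
    else:
        g_hwe = g
    hwe_p = np.ones(study.n_variants)
    for i in range(study.n_variants):
        nAA, nAa, naa = genotype_counts(g_hwe[:, i])
        if nAA + nAa + naa >= 1:
            hwe_p[i] = hwe_exact_test(nAA, nAa, naa)
    return call_rate, maf, hwe_p


def qc_filter(study: CohortStudy,
              thresholds: QcThresholds | None = None) -> tuple[CohortStudy, QcReport]:
    """Apply call-rate, MAF, HWE and autosome filters.

    Samples with call rate <= ``sample_call_min`` are dropped first; variant
    criteria (MAF > maf_min, call rate > snp_call_min, HWE P >= hwe_p_min,
    autosomal chromosome) are then evaluated on the sample-filtered matrix
    and failing variants removed in one pass. Idempotent.
    """
    thr = thresholds or QcThresholds()
    report = QcReport()

    sample_call = 1.0 - np.isnan(study.genotypes).mean(axis=1)
    keep_samples = sample_call > thr.sample_call_min
    report.samples_low_call = int((~keep_samples).sum())
    if not keep_samples.any():
        raise EmptyStudyError("sample call-rate filter removed every sample")
    filtered = study.subset(sample_idx=np.where(keep_samples)[0])

    call_rate, maf, hwe_p = _variant_stats(filtered, thr.hwe_controls_only)
    autosomal = filtered.variants["chrom"].astype(str).isin(AUTOSOMES).to_numpy()
    fail_maf = maf <= thr.maf_min
    fail_call = call_rate <= thr.snp_call_min
    fail_hwe = hwe_p < thr.hwe_p_min
    report.variants_low_maf = int(fail_maf.sum())
    report.variants_low_call = int(fail_call.sum())
    report.variants_hwe_fail = int(fail_hwe.sum())
    report.variants_nonautosomal = int((~autosomal).sum())
    keep_variants = autosomal & ~(fail_maf | fail_call | fail_hwe)
    report.variants_removed_total = int((~keep_variants).sum())
    if not keep_variants.any():
        raise EmptyStudyError("variant filters removed every variant")
    out = filtered.subset(variant_idx=np.where(keep_variants)[0])
    return out, report


def merge_cohorts(studies: list[CohortStudy]) -> tuple[CohortStudy, QcReport]:
    """Merge cohorts on the intersection of variant ids.

    Allele orientation is harmonized against the first study: a variant
    whose alleles appear swapped has its dosages flipped (2 - d); variants
    whose alleles cannot be reconciled by a swap are dropped with a warning
    and counted in the report.
    """
    if len(studies) < 2:
        raise ValueError("merge_cohorts needs at least two studies")
    all_ids = pd.concat([s.samples["iid"].astype(str) for s in studies])
    if all_ids.duplicated().any():
        dupes = all_ids[all_ids.duplicated()].unique()[:5]
        raise ValueError(f"sample ids must be disjoint across cohorts: {list(dupes)}")

    common = studies[0].variant_ids
    for s in studies[1:]:
        common = common.intersection(s.variant_ids)
    # keep the first study's ordering
    common = [v for v in studies[0].variant_ids if v in set(common)]

    ref = studies[0]
    ref_pos = ref.variant_ids.get_indexer(common)
    ref_var = ref.variants.iloc[ref_pos].reset_index(drop=True)
    ref_alleles = list(zip(ref_var["a1"], ref_var["a2"]))

    blocks, sample_frames = [], []
    unresolved = np.zeros(len(common), dtype=bool)
    for s in studies:
        pos = s.variant_ids.get_indexer(common)
        g = s.genotypes[:, pos].copy()
        var = s.variants.iloc[pos]
        for j, ((a1, a2), (b1, b2)) in enumerate(
                zip(ref_alleles, zip(var["a1"], var["a2"]))):
            if (b1, b2) == (a1, a2):
                continue
            if (b1, b2) == (a2, a1):
                g[:, j] = 2.0 - g[:, j]
            else:
                unresolved[j] = True
        blocks.append(g)
        sample_frames.append(s.samples)

    if unresolved.any():
        warnings.warn(
            f"{int(unresolved.sum())} variant(s) dropped in merge: alleles "
            "not resolvable by swap", UserWarning)
    keep = ~unresolved
    genotypes = np.vstack([b[:, keep] for b in blocks])
    samples = pd.concat(sample_frames, ignore_index=True)
    variants = ref_var.loc[keep].reset_index(drop=True)
    report = QcReport(variants_unresolvable_alleles=int(unresolved.sum()))
    return CohortStudy(genotypes, samples, variants), report
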