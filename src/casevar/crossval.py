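"""Split-half cross-validation of variance-heterogeneity signals.

Each iteration stratifies by case/control status, splits the study into two
disjoint halves, reruns the complete two-stage pipeline (GRM, pruning, PCs,
REML, residuals, Brown-Forsythe test) independently within each half, and
records the candidate SNPs' p-values in both halves. A SNP counts as
*discovered* in an iteration when either half reaches the threshold, and as
*validated* when the other half (the complement of the smaller-p half)
gives P < 0.05. Both halves' p-values are retained so either bookkeeping
convention can be reconstructed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CohortStudy, CVReport
from .vgwas import CHIP_WIDE, GENOME_WIDE, brown_forsythe_stat
from .vgwas import DegenerateGroupsError, MonomorphicVariantError

__all__ = ["split_stratified", "cross_validate"]


def split_stratified(
    study: CohortStudy,
    fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Case/control-stratified split into two disjoint, exhaustive halves.

    Returns positional index arrays ``(set1, set2)``: set1 holds
    ``round(fraction * N)`` cases and ``round(fraction * M)`` controls drawn
    without replacement; set2 is the complement. Splitting is by status
    only; cohort stays a covariate within each half.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ph = study.phenotype
    cases = np.where(ph == 1.0)[0]
    ctrls = np.where(ph == 0.0)[0]
    if cases.size < 2 or ctrls.size < 2:
        raise ValueError("need at least 2 cases and 2 controls to split")
    n1_case = int(round(fraction * cases.size))
    n1_ctrl = int(round(fraction * ctrls.size))
    pick_case = rng.choice(cases, n1_case, replace=False)
    pick_ctrl = rng.choice(ctrls, n1_ctrl, replace=False)
    set1 = np.sort(np.concatenate([pick_case, pick_ctrl]))
    set2 = np.setdiff1d(np.arange(study.n_samples), set1)
    return set1, set2


def _half_pvalues(
    half: CohortStudy,
    snps: list[str],
    prevalence: float,
    grm_cutoff: float,
    n_pcs: int,
    group_min: int,
) -> tuple[dict[str, float], bool]:
    """Run stage one + targeted stage two within one half; returns per-SNP
    vGWAS p-values and the REML convergence flag."""
    from .partition import partition_study

    fit, pruned, _ = partition_study(half, prevalence=prevalence,
                                     grm_cutoff=grm_cutoff, n_pcs=n_pcs)
    y = fit.residuals.to_numpy()
    aligned = pruned.select_samples_by_id(list(fit.residuals.index))
    out: dict[str, float] = {}
    for snp in snps:
        j = aligned.variant_index(snp)
        try:
            _, _, p = brown_forsythe_stat(y, aligned.genotypes[:, j], group_min)
        except (MonomorphicVariantError, DegenerateGroupsError):
            p = np.nan
        out[snp] = p
    return out, fit.converged


def cross_validate(
    study: CohortStudy,
    lead_snps: list[str],
    iterations: int = 10,
    seed: int = 0,
    prevalence: float = 0.01,
    grm_cutoff: float = 0.15,
    n_pcs: int = 10,
    group_min: int = 2,
    genome_wide: float = GENOME_WIDE,
    chip_wide: float = CHIP_WIDE,
) -> CVReport:
    """Count discoveries and validations of candidate SNPs over
    ``iterations`` stratified 50/50 splits; per-iteration seeds descend from
    the master seed by iteration index."""
    for snp in lead_snps:
        study.variant_index(snp)  # raises on unknown ids

    root = np.random.SeedSequence(seed)
    iter_seeds = root.spawn(iterations)
    records = []
    failed: list[int] = []
    for it, ss in enumerate(iter_seeds):
        set1, set2 = split_stratified(study, 0.5, np.random.default_rng(ss))
        assert np.intersect1d(set1, set2).size == 0
        halves = [study.subset(sample_idx=set1), study.subset(sample_idx=set2)]
        ps, conv = [], []
        for half in halves:
            p_half, converged = _half_pvalues(
                half, lead_snps, prevalence, grm_cutoff, n_pcs, group_min)
            ps.append(p_half)
            conv.append(converged)
        if not all(conv):
            failed.append(it)
        for snp in lead_snps:
            p1, p2 = ps[0][snp], ps[1][snp]
            best, other = (p1, p2) if (np.isnan(p2) or p1 <= p2) else (p2, p1)
            both_nan = np.isnan(p1) and np.isnan(p2)
            disc_gw = bool(np.nanmin([p1, p2]) < genome_wide) if not both_nan else False
            disc_chip = bool(np.nanmin([p1, p2]) < chip_wide) if not both_nan else False
            validated = bool(other < 0.05) if not np.isnan(other) else False
            for half_no, p in ((1, p1), (2, p2)):
                records.append({
                    "snp": snp, "iter": it, "half": half_no, "p": p,
                    "discovered_gw": disc_gw, "discovered_chip": disc_chip,
                    "validated": validated,
                    "failed": it in failed,
                })
    rec = pd.DataFrame(records)
    per_iter = rec[rec["half"] == 1]
    summary = per_iter.groupby("snp", sort=False).agg(
        n_discovered_genomewide=("discovered_gw", "sum"),
        n_discovered_chipwide=("discovered_chip", "sum"),
        n_validated=("validated", "sum"),
    ).reset_index()
    return CVReport(records=rec, summary=summary, iterations=iterations,
                    seed=seed, failed_iterations=failed)
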