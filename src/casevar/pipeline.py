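"""End-to-end helper chaining the two stages on one study."""

from __future__ import annotations

from .datatypes import CohortStudy, LiabilityFit, QcThresholds, VGwasResult
from .partition import partition_study
from .qc import qc_filter
from .vgwas import CHIP_WIDE, GENOME_WIDE, vgwas_scan

__all__ = ["two_stage_scan"]


def two_stage_scan(
    study: CohortStudy,
    prevalence: float = 0.01,
    grm_cutoff: float = 0.15,
    n_pcs: int = 10,
    group_min: int = 2,
    qc: QcThresholds | None = None,
    genome_wide: float = GENOME_WIDE,
    chip_wide: float = CHIP_WIDE,
    with_additive: bool = False,
) -> tuple[LiabilityFit, VGwasResult, CohortStudy]:
    """QC (optional) -> liability partition -> Brown-Forsythe scan.

    Returns the stage-one fit, the scan result, and the pruned study the
    scan ran on.
    """
    if qc is not None:
        study, _ = qc_filter(study, qc)
    fit, pruned, _ = partition_study(study, prevalence=prevalence,
                                     grm_cutoff=grm_cutoff, n_pcs=n_pcs)
    p_add = None
    if with_additive:
        from .partition import build_covariates
        from .vgwas import additive_gwas_scan

        p_add = additive_gwas_scan(pruned, build_covariates(pruned))
    result = vgwas_scan(pruned, fit.residuals, group_min=group_min,
                        genome_wide=genome_wide, chip_wide=chip_wide,
                        p_additive=p_add)
    return fit, result, pruned
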