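"""Explicit GxE / GxG likelihood-ratio tests at candidate SNPs.

For a candidate SNP G and an interacting factor F (sex, cohort, or a second
SNP), the disease model is logistic:

    logit P(case) = mu + beta * X + beta_g * G + beta_f * F + beta_gf * G:F

with G entered as a categorical three-level genotype factor (that coding,
not a dosage, yields the block degrees of freedom: 2 for G x sex, 10 for
G x cohort with six cohorts, 8 with five, 4 for G x G). The beta_gf = 0
hypothesis is tested by a likelihood-ratio chi-square whose df equals the
number of estimable interaction columns; empty genotype-by-factor cells
drop their column with the df reduced and the count recorded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import CohortStudy, InteractionResult, interaction_results_to_frame

__all__ = ["fit_interaction", "gxg_test", "interaction_screen",
           "interaction_results_to_frame"]


def _genotype_factor(study: CohortStudy, snp: str) -> pd.Series:
    j = study.variant_index(snp)
    return pd.Series(study.genotypes[:, j], name=snp)


def _factor_series(study: CohortStudy, factor: str) -> pd.Series:
    if factor == "sex":
        s = study.samples["sex"].replace({1: "male", 2: "female", 0: np.nan})
        return pd.Series(s.to_numpy(), name="sex")
    if factor == "cohort":
        return pd.Series(study.samples["cohort"].astype(str).to_numpy(),
                         name="cohort")
    # otherwise: a second SNP, entered as a genotype factor
    return _genotype_factor(study, factor)


def _dummies(series: pd.Series, prefix: str,
             ref: object | None = None) -> pd.DataFrame:
    cat = pd.Categorical(series)
    levels = list(cat.categories)
    if ref is None:
        ref = levels[0]
    cols = {}
    for lv in levels:
        if lv == ref:
            continue
        cols[f"{prefix}[{lv}]"] = (cat == lv).astype(float)
    return pd.DataFrame(cols, index=series.index)


def _fit_logit(y: np.ndarray, x: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, x.to_numpy(dtype=float))
        fit = model.fit(disp=0, maxiter=200, method="newton", tol=1e-10)
    return fit


def fit_interaction(
    study: CohortStudy,
    snp_g: str,
    factor: str,
    covariates: list[str] | None = None,
    ref_g: object | None = None,
    ref_f: object | None = None,
) -> InteractionResult:
    """Likelihood-ratio test of the G-by-F interaction block.

    ``factor`` is ``"sex"``, ``"cohort"`` or a variant id (GxG).
    ``covariates`` names additional adjustment factors from
    {"sex", "cohort"}; by default both are included when present in the
    data and not themselves the tested factor.
    """
    g = _genotype_factor(study, snp_g)
    f = _factor_series(study, factor)
    y = study.phenotype

    if covariates is None:
        covariates = [c for c in ("sex", "cohort") if c != factor]
    cov_frames = []
    for name in covariates:
        s = _factor_series(study, name)
        if s.nunique(dropna=True) > 1:
            cov_frames.append(_dummies(s, name))

    frame = pd.DataFrame({"y": y, "g": g, "f": f.to_numpy()})
    keep = frame.notna().all(axis=1)
    for c in cov_frames:
        keep &= c.notna().all(axis=1)
    frame = frame[keep]
    gd = _dummies(frame["g"], "G", ref=ref_g)
    fd = _dummies(frame["f"], "F", ref=ref_f)

    x = pd.DataFrame({"intercept": 1.0}, index=frame.index)
    for c in cov_frames:
        x = x.join(c.loc[frame.index])
    x = x.join(gd).join(fd)

    inter = {}
    dropped = 0
    for gc in gd.columns:
        for fc in fd.columns:
            col = gd[gc] * fd[fc]
            if col.sum() == 0:  # empty genotype-by-factor cell
                dropped += 1
                continue
            inter[f"{gc}:{fc}"] = col
    inter = pd.DataFrame(inter, index=frame.index)
    df = inter.shape[1]

    yv = frame["y"].to_numpy(dtype=float)
    try:
        fit_reduced = _fit_logit(yv, x)
        fit_full = _fit_logit(yv, x.join(inter))
        estimable = bool(fit_full.mle_retvals.get("converged", False)
                         and fit_reduced.mle_retvals.get("converged", False)
                         and np.isfinite(fit_full.llf)
                         and np.isfinite(fit_reduced.llf))
    except Exception:
        fit_reduced = fit_full = None
        estimable = False

    if estimable:
        lrt = 2.0 * (fit_full.llf - fit_reduced.llf)
        lrt = max(lrt, 0.0)
        p = float(stats.chi2.sf(lrt, df)) if df > 0 else 1.0
        names = list(x.columns) + list(inter.columns)
        params = pd.Series(fit_full.params, index=names)
        cov = pd.DataFrame(fit_full.cov_params(), index=names, columns=names)
        b_gf = params[list(inter.columns)]
        wald_p = None
        if df > 0:
            try:
                vb = cov.loc[inter.columns, inter.columns].to_numpy()
                w = float(b_gf.to_numpy() @ np.linalg.solve(vb, b_gf.to_numpy()))
                wald_p = float(stats.chi2.sf(w, df))
            except np.linalg.LinAlgError:
                wald_p = None
        result = InteractionResult(
            snp_g=snp_g, factor=factor, df=df, lrt_stat=float(lrt), p=p,
            beta_g=params[list(gd.columns)], beta_f=params[list(fd.columns)],
            beta_gf=b_gf, wald_p=wald_p, estimable=True,
            dropped_cells=dropped,
            ll_full=float(fit_full.llf), ll_reduced=float(fit_reduced.llf))
    else:
        result = InteractionResult(
            snp_g=snp_g, factor=factor, df=df, lrt_stat=np.nan, p=np.nan,
            beta_g=pd.Series(dtype=float), beta_f=pd.Series(dtype=float),
            beta_gf=pd.Series(dtype=float), estimable=False,
            dropped_cells=dropped)
    return result


def gxg_test(
    study: CohortStudy,
    snp_g: str,
    snp_h: str,
    covariates: list[str] | None = None,
) -> InteractionResult:
    """Gene-by-gene interaction LRT: both SNPs enter as three-level genotype
    factors (df = 4 when all nine cells are populated)."""
    return fit_interaction(study, snp_g, snp_h, covariates=covariates)


def interaction_screen(
    study: CohortStudy,
    lead_snps: list[str],
    factors: list[str],
) -> list[InteractionResult]:
    """All SNP-by-factor LRTs with a Bonferroni threshold of
    0.05 / len(lead_snps) applied per factor."""
    alpha = 0.05 / len(lead_snps)
    results = []
    for factor in factors:
        for snp in lead_snps:
            if snp == factor:
                continue
            r = fit_interaction(study, snp, factor)
            r.bonferroni_alpha = alpha
            results.append(r)
    return results
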