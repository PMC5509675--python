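"""Stage one of the two-stage vGWAS: mixed-model partition of case-control
status into an additive polygenic component and non-additive residuals.

The pipeline is: genetic relationship matrix (GRM) from standardized
genotypes, greedy relatedness pruning, principal components from the pruned
GRM, average-information REML on the observed 0/1 phenotype with intercept,
sex, the leading PCs and cohort indicators as fixed effects, BLUP of each
sample's polygenic value, and residuals

    e_i = y_i - x_i' beta_hat - g_hat_i ,

which are the trait of the downstream variance-heterogeneity scan. The
heritability estimate is transformed from the observed 0/1 scale to the
liability scale with the prevalence-based correction that also accounts for
case-control ascertainment (multiplier K^2 (1-K)^2 / (z^2 P (1-P)) with z
the normal density at the liability threshold and P the sample case
fraction).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datatypes import GRM, CohortStudy, LiabilityFit

__all__ = ["compute_grm", "prune_relatedness", "pca_from_grm", "reml_fit",
           "build_covariates", "liability_multiplier", "partition_study"]


# --------------------------------------------------------------------------
# GRM
# --------------------------------------------------------------------------

def compute_grm(study: CohortStudy) -> GRM:
    """GCTA-style GRM: A_jk = (1/m_jk) sum_i (x_ij - 2p_i)(x_ik - 2p_i) /
    (2 p_i (1 - p_i)), with p_i the sample allele frequency and m_jk the
    per-pair count of SNPs non-missing in both samples. Monomorphic SNPs
    are skipped with a warning."""
    if study.n_samples < 2 or study.n_variants < 1:
        raise ValueError("GRM needs >= 2 samples and >= 1 variant")
    g = study.genotypes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(g, axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.all():
        warnings.warn(f"{int((~poly).sum())} monomorphic SNP(s) skipped in GRM",
                      UserWarning)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; GRM undefined")
    g = g[:, poly]
    p = p[poly]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    s = (g - 2.0 * p) / denom
    observed = ~np.isnan(s)
    s = np.where(observed, s, 0.0)
    pair_m = observed.astype(float) @ observed.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (s @ s.T) / pair_m
    a[pair_m == 0] = 0.0
    a = (a + a.T) / 2.0  # exact symmetry
    return GRM(a, study.sample_ids, int(poly.sum()))


def prune_relatedness(grm: GRM, cutoff: float = 0.15) -> list[str]:
    """Greedy relatedness pruning: while any off-diagonal exceeds the
    cutoff, drop the sample in the most violating pairs (ties broken by
    lower sample index). Returns the retained sample ids in original
    order."""
    if not 0.0 < cutoff <= 2.0:
        raise ValueError("cutoff must be in (0, 2]")
    a = grm.matrix.copy()
    np.fill_diagonal(a, -np.inf)
    active = np.ones(grm.n_samples, dtype=bool)
    viol = a > cutoff
    while True:
        counts = viol.sum(axis=1)
        counts[~active] = 0
        worst = int(np.argmax(counts))  # argmax takes the lowest index on ties
        if counts[worst] == 0:
            break
        active[worst] = False
        viol[worst, :] = False
        viol[:, worst] = False
    return [sid for sid, keep in zip(grm.sample_ids, active) if keep]


def pca_from_grm(grm: GRM, n_components: int = 10) -> pd.DataFrame:
    """Top eigenvectors of the GRM as principal-component scores
    (columns PC1..PCn, indexed by sample id, eigenvalues in ``attrs``)."""
    if n_components > grm.n_samples:
        raise ValueError("n_components exceeds number of samples")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1][:n_components]
    scores = pd.DataFrame(
        vecs[:, order], index=grm.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)])
    scores.attrs["eigenvalues"] = vals[order]
    return scores


# --------------------------------------------------------------------------
# covariates
# --------------------------------------------------------------------------

def build_covariates(study: CohortStudy, pcs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fixed-effect design: intercept, sex indicator (if both sexes are
    present), PC scores, and one indicator per non-reference cohort (if the
    study has more than one cohort)."""
    idx = study.sample_ids
    x = pd.DataFrame({"intercept": 1.0}, index=idx)
    sex = study.samples["sex"].to_numpy()
    if len(np.unique(sex[sex != 0])) > 1:
        x["sex_male"] = (sex == 1).astype(float)
    if pcs is not None:
        x = x.join(pcs.reindex(idx))
    cohorts = study.samples["cohort"].astype(str).to_numpy()
    levels = pd.unique(cohorts)
    for lv in levels[1:]:
        x[f"cohort_{lv}"] = (cohorts == lv).astype(float)
    return x


def liability_multiplier(prevalence: float, case_fraction: float) -> float:
    """Observed-scale-to-liability-scale heritability multiplier
    K^2 (1-K)^2 / (z^2 P (1-P)) for prevalence K, sample case fraction P
    and z the standard-normal density at the (1-K) quantile."""
    k = prevalence
    z = stats.norm.pdf(stats.norm.ppf(1.0 - k))
    p = case_fraction
    return (k ** 2 * (1.0 - k) ** 2) / (z ** 2 * p * (1.0 - p))


# --------------------------------------------------------------------------
# AI-REML
# --------------------------------------------------------------------------

class _RotatedModel:
    """REML working quantities after rotating by the GRM eigenbasis, where
    V = sg2 * diag(d) + se2 * I is diagonal."""

    def __init__(self, y: np.ndarray, x: np.ndarray, d: np.ndarray, u: np.ndarray):
        self.d = d
        self.u = u
        self.ystar = u.T @ y
        self.xstar = u.T @ x
        self.n, self.p = x.shape

    def evaluate(self, theta: np.ndarray) -> dict | None:
        sg2, se2 = theta
        dv = sg2 * self.d + se2
        if np.any(dv <= 0):
            return None
        inv = 1.0 / dv
        xw = self.xstar * inv[:, None]
        xtvx = self.xstar.T @ xw
        try:
            cho = linalg.cho_factor(xtvx)
        except linalg.LinAlgError:
            return None
        beta = linalg.cho_solve(cho, self.xstar.T @ (self.ystar * inv))
        r = self.ystar - self.xstar @ beta
        py = r * inv  # P y = V^-1 (y - X beta_gls)
        ld_v = float(np.sum(np.log(dv)))
        ld_x = float(2.0 * np.sum(np.log(np.diag(cho[0]))))
        ypy = float(r @ py)
        ll = -0.5 * (ld_v + ld_x + ypy)
        return dict(inv=inv, cho=cho, beta=beta, r=r, py=py, ll=ll)

    def apply_p(self, vec: np.ndarray, work: dict) -> np.ndarray:
        """P v for the projection matrix P = V^-1 - V^-1 X C^-1 X' V^-1."""
        inv = work["inv"]
        w = inv * vec
        return w - inv * (self.xstar @ linalg.cho_solve(
            work["cho"], self.xstar.T @ w))

    def trace_pm(self, m_diag: np.ndarray, work: dict) -> float:
        """tr(P M) for diagonal M (in the rotated basis)."""
        inv = work["inv"]
        t1 = float(np.sum(m_diag * inv))
        xw = self.xstar * (inv * m_diag * inv)[:, None]
        q = self.xstar.T @ xw
        t2 = float(np.trace(linalg.cho_solve(work["cho"], q)))
        return t1 - t2

    def score_and_ai(self, work: dict) -> tuple[np.ndarray, np.ndarray]:
        py = work["py"]
        u_g = self.d * py      # V_g P y  with V_g = diag(d)
        u_e = py               # V_e = I
        score = np.array([
            -0.5 * (self.trace_pm(self.d, work) - float(py @ u_g)),
            -0.5 * (self.trace_pm(np.ones(self.n), work) - float(py @ u_e)),
        ])
        p_ug = self.apply_p(u_g, work)
        p_ue = self.apply_p(u_e, work)
        ai = 0.5 * np.array([
            [float(u_g @ p_ug), float(u_g @ p_ue)],
            [float(u_e @ p_ug), float(u_e @ p_ue)],
        ])
        return score, ai


def _check_collinearity(x: pd.DataFrame) -> None:
    mat = x.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, r, piv = linalg.qr(mat, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(mat.shape) * np.finfo(float).eps
        bad = [x.columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        bad += [x.columns[j] for j in piv[len(diag):]]
        raise ValueError(f"singular covariate matrix; collinear columns: {bad}")


def reml_fit(
    study: CohortStudy,
    grm: GRM,
    covariates: pd.DataFrame,
    prevalence: float = 0.01,
    max_iter: int = 100,
    tol: float = 1e-8,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> LiabilityFit:
    """Average-information REML of the one-GRM linear mixed model on the
    observed 0/1 phenotype, with EM fallback whenever an AI step would
    decrease the restricted likelihood or leave the parameter space.

    Variance components are constrained non-negative by projection to a
    small positive floor. BLUP is g_hat = sg2 * A V^-1 (y - X beta_hat);
    residuals are y - X beta_hat - g_hat.

    ``eig`` may carry a precomputed eigendecomposition (d, U) of the GRM
    restricted to the covariate rows' sample order.
    """
    ids = list(covariates.index.astype(str))
    sub = study.select_samples_by_id(ids)
    y = sub.phenotype
    if np.isnan(y).any():
        raise ValueError("phenotype must be non-missing for all fitted samples")
    _check_collinearity(covariates)
    x = covariates.to_numpy(dtype=float)
    n, p = x.shape

    if eig is None:
        a = grm.subset_ids(ids).matrix
        d, u = np.linalg.eigh(a)
    else:
        d, u = eig
    model = _RotatedModel(y, x, d, u)

    vary = float(np.var(y, ddof=1))
    floor = 1e-8 * vary
    theta = np.array([vary / 2.0, vary / 2.0])
    work = model.evaluate(theta)
    if work is None:
        raise RuntimeError("REML could not evaluate the starting point")
    ll_path = [work["ll"]]

    def em_step(theta, work):
        py = work["py"]
        new = theta.copy()
        for i, m_diag in enumerate((model.d, np.ones(n))):
            tr = model.trace_pm(m_diag, work)
            quad = float(py @ (m_diag * py))
            new[i] = theta[i] + theta[i] ** 2 * (quad - tr) / n
        return np.maximum(new, floor)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if it == 1:
            cand = em_step(theta, work)  # one EM step first, for stability
        else:
            score, ai = model.score_and_ai(work)
            try:
                cand = theta + np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                cand = np.full(2, -1.0)  # force the constrained branch
            if (cand < floor).any():
                # a component wants past its bound: pin it at the floor and
                # take the Newton step in the free coordinate only, so the
                # boundary optimum is reached instead of crawled toward
                viol = cand < floor
                cand = theta.copy()
                cand[viol] = floor
                free = np.where(~viol)[0]
                if free.size:
                    sub = np.linalg.solve(ai[np.ix_(free, free)], score[free])
                    cand[free] = np.maximum(theta[free] + sub, floor)
        cand_work = model.evaluate(cand)
        if cand_work is None or cand_work["ll"] < work["ll"] - 1e-10:
            cand = em_step(theta, work)
            cand_work = model.evaluate(cand)
            if cand_work is None:
                break
        dll = cand_work["ll"] - work["ll"]
        theta, work = cand, cand_work
        ll_path.append(work["ll"])
        if abs(dll) < tol * max(1.0, abs(work["ll"])):
            converged = True
            break
    if not converged:
        warnings.warn("REML did not converge within max_iter", UserWarning)

    sg2, se2 = float(theta[0]), float(theta[1])
    beta = work["beta"]
    r = work["r"]
    inv = work["inv"]
    gstar = sg2 * model.d * (r * inv)
    estar = se2 * (r * inv)
    blup = model.u @ gstar
    resid = model.u @ estar

    h2_obs = sg2 / (sg2 + se2)
    case_frac = float(np.mean(y))
    h2_lia = h2_obs * liability_multiplier(prevalence, case_frac)
    return LiabilityFit(
        sigma2_g=sg2, sigma2_e=se2,
        h2_observed=h2_obs, h2_liability=h2_lia,
        fixed_effects=pd.Series(beta, index=covariates.columns),
        blup=blup,
        residuals=pd.Series(resid, index=pd.Index(ids, name="iid")),
        converged=converged, n_iterations=it, loglik_path=ll_path,
        prevalence=prevalence, sample_case_fraction=case_frac,
    )


# --------------------------------------------------------------------------
# one-call stage one
# --------------------------------------------------------------------------

def partition_study(
    study: CohortStudy,
    prevalence: float = 0.01,
    grm_cutoff: float = 0.15,
    n_pcs: int = 10,
) -> tuple[LiabilityFit, CohortStudy, GRM]:
    """GRM -> relatedness pruning -> PCA -> REML -> residuals, sharing one
    eigendecomposition between the PCs and the REML rotation. Returns the
    fit, the pruned study and the pruned GRM."""
    grm = compute_grm(study)
    retained = prune_relatedness(grm, grm_cutoff)
    pruned = study.select_samples_by_id(retained)
    grm_p = grm.subset_ids(retained)
    vals, vecs = np.linalg.eigh(grm_p.matrix)
    order = np.argsort(vals)[::-1][: min(n_pcs, len(retained))]
    pcs = pd.DataFrame(vecs[:, order], index=grm_p.sample_ids,
                       columns=[f"PC{i + 1}" for i in range(len(order))])
    covs = build_covariates(pruned, pcs)
    fit = reml_fit(pruned, grm_p, covs, prevalence=prevalence,
                   eig=(vals, vecs))
    return fit, pruned, grm_p


def residuals_to_tsv(fit: LiabilityFit, study: CohortStudy, path: str) -> None:
    fam = study.samples.set_index(study.samples["iid"].astype(str))
    out = pd.DataFrame({
        "FID": fam.loc[fit.residuals.index, "fid"].to_numpy(),
        "IID": fit.residuals.index,
        "RESIDUAL": fit.residuals.to_numpy(),
    })
    out.to_csv(path, sep="\t", index=False)
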