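"""Two-stage multi-locus mixed-model GWAS.

Stage 1 is a single-marker mixed-model scan, y = μ + xβ + g + e with
g ~ N(0, G σ²g): the null-model variance components are estimated once by
REML and reused for every marker (the P3D shortcut), and each marker gets
a generalized-least-squares Wald χ²(1) test.  Markers with P below a
liberal retention threshold (default 0.01) move to stage 2.

Stage 2 refits all retained markers *jointly* as random effects with
per-marker variances estimated by an empirical-Bayes shrinkage sweep
(variance_j ∝ β̂_j² + posterior variance_j, renormalized each sweep until
the relative change falls below 1e−6).  Each surviving marker is scored by
a LOD — the base-10 log likelihood ratio between the joint model with and
without that marker — and classified:

* **significant** QTN: stage-1 P < 0.05/m (Bonferroni) *and* LOD > 3;
* **suggested** QTN: LOD > 3 only.

Per-QTN phenotypic variance explained is PVE% = 100·2p(1−p)β²/Var(y), with
Var(y) the sample phenotypic variance before any model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from popgs.genotypes import GenotypeMatrix
from popgs.popstruct import GRM, compute_grm
from popgs.gs_models import DELTA_MAX, VarianceComponents, reml_fit

log = logging.getLogger(__name__)

LN10 = np.log(10.0)


# ----------------------------------------------------------------------
# stage 1: P3D mixed-model scan
# ----------------------------------------------------------------------

@dataclass
class ScanResult:
    table: pd.DataFrame  # chrom, pos, beta, se, p per marker
    varcomp: VarianceComponents
    retain_p: float
    n_collinear: int

    @property
    def retained(self) -> np.ndarray:
        """Marker indices with stage-1 P below the retention threshold."""
        p = self.table["p"].to_numpy()
        return np.where(np.nan_to_num(p, nan=1.0) < self.retain_p)[0]


def mlm_scan(
    g: GenotypeMatrix,
    y: np.ndarray,
    grm: GRM | None = None,
    covariates: np.ndarray | None = None,
    retain_p: float = 0.01,
) -> ScanResult:
    """Single-marker mixed-model scan with P3D variance components."""
    y = np.asarray(y, dtype=float)
    if len(y) != g.n_samples:
        raise ValueError("phenotype length must match the genotype matrix")
    if grm is None:
        grm = compute_grm(g)
    X0 = np.ones((len(y), 1))
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(y):
            covariates = covariates.T
        X0 = np.column_stack([X0, covariates])
        if np.linalg.matrix_rank(X0) < X0.shape[1]:
            raise ValueError("singular covariate design")

    vc = reml_fit(y, grm, X=X0)
    s, U = np.linalg.eigh(grm.matrix)
    s = np.clip(s, 0.0, None)
    if vc.sigma_g2 > 0:
        w = 1.0 / (s + min(vc.delta, DELTA_MAX))
        resid_var = vc.sigma_g2
    else:  # boundary: V = sigma_e2 * I
        w = np.ones_like(s)
        resid_var = vc.sigma_e2
    sw = np.sqrt(w)

    ystar = sw * (U.T @ y)
    X0star = sw[:, None] * (U.T @ X0)
    Q, _ = np.linalg.qr(X0star)
    ytil = ystar - Q @ (Q.T @ ystar)

    W = g.centered()
    Xstar = sw[:, None] * (U.T @ W)
    Xtil = Xstar - Q @ (Q.T @ Xstar)
    den = np.einsum("ij,ij->j", Xtil, Xtil)
    num = Xtil.T @ ytil
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / den
        se = np.sqrt(resid_var / den)
        chi2 = num ** 2 / (den * resid_var)
    collinear = den < 1e-10 * max(den.max(), 1.0)
    beta[collinear] = np.nan
    se[collinear] = np.nan
    chi2[collinear] = np.nan
    if collinear.any():
        log.warning(
            "%d markers with zero GLS variance (monomorphic or collinear "
            "with covariates), excluded", collinear.sum(),
        )
    p = stats.chi2.sf(chi2, df=1)
    table = pd.DataFrame(
        {
            "chrom": g.markers["chrom"],
            "pos": g.markers["pos"],
            "beta": beta,
            "se": se,
            "p": p,
        }
    )
    return ScanResult(table, vc, retain_p, int(collinear.sum()))


# ----------------------------------------------------------------------
# stage 2: joint empirical-Bayes refit
# ----------------------------------------------------------------------

@dataclass
class QTNRecord:
    chrom: str
    pos: int
    beta: float
    p_stage1: float
    lod: float
    pve_pct: float
    maf: float
    klass: str  # "significant" | "suggested"
    marker_index: int


def _lowrank_loglik(y0: np.ndarray, X: np.ndarray, var: np.ndarray,
                    sigma_e2: float) -> float:
    """Gaussian log-likelihood of centered y under N(0, X·diag(var)·X' + σ²eI).

    Woodbury/low-rank form: O(k³) for k random markers.
    """
    n = len(y0)
    k = X.shape[1]
    if k == 0:
        rss = y0 @ y0
        return -0.5 * (n * np.log(2 * np.pi * sigma_e2) + rss / sigma_e2)
    Dh = np.sqrt(var)
    B = X * Dh  # n×k
    M = np.eye(k) + B.T @ B / sigma_e2
    sign, logdet_M = np.linalg.slogdet(M)
    logdet = n * np.log(sigma_e2) + logdet_M
    Bty = B.T @ y0
    quad = (y0 @ y0 - Bty @ np.linalg.solve(M, Bty) / sigma_e2) / sigma_e2
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def _ml_variance_scale(y0: np.ndarray, X: np.ndarray, shape: np.ndarray,
                       s0: float, e0: float) -> tuple[float, float]:
    """ML estimate of (marker-variance scale, σ²e) for fixed variance shape.

    y0 ~ N(0, s·X·diag(shape)·X' + σ²e·I); the low-rank spectrum makes each
    likelihood evaluation O(k), so a Nelder–Mead search is cheap.
    """
    from scipy.optimize import minimize

    n = len(y0)
    B = X * np.sqrt(shape)
    BtB = B.T @ B
    lam, V = np.linalg.eigh(BtB)
    lam = np.clip(lam, 0.0, None)
    z = V.T @ (B.T @ y0)
    yy = y0 @ y0
    # z_i are coordinates of y0 on the eigenvectors of BB' scaled by sqrt(lam)
    z2_over_lam = np.where(lam > 1e-12, z ** 2 / np.where(lam > 0, lam, 1.0), 0.0)
    sum_proj = z2_over_lam.sum()

    def neg_ll(theta):
        s, e = np.exp(theta)
        denom = s * lam + e
        # projected coordinates c_i² = z_i²/λ_i
        q_proj = np.sum(np.where(lam > 1e-12, z2_over_lam / denom, 0.0))
        q_orth = (yy - sum_proj) / e
        logdet = np.sum(np.log(denom[lam > 1e-12])) + (n - np.sum(lam > 1e-12)) * np.log(e)
        return 0.5 * (logdet + q_proj + q_orth)

    res = minimize(
        neg_ll,
        x0=np.log([max(s0, 1e-10), max(e0, 1e-10)]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
    )
    s, e = np.exp(res.x)
    return float(s), float(e)


def _clump_retained(g: GenotypeMatrix, scan: ScanResult, retained: np.ndarray,
                    clump_r2: float) -> np.ndarray:
    """Greedy LD clumping of the retained set, best stage-1 P first."""
    W = g.centered()[:, retained]
    sd = W.std(axis=0)
    sd[sd == 0] = np.nan
    Z = (W - W.mean(axis=0)) / sd
    with np.errstate(invalid="ignore"):
        R2 = np.nan_to_num((Z.T @ Z / Z.shape[0]) ** 2)
    chrom = g.markers["chrom"].to_numpy()[retained]
    order = np.argsort(scan.table["p"].to_numpy()[retained], kind="stable")
    kept: list[int] = []
    for i in order:
        if all(chrom[i] != chrom[kk] or R2[i, kk] <= clump_r2 for kk in kept):
            kept.append(i)
    return retained[np.sort(kept)]


def multilocus_refit(
    g: GenotypeMatrix,
    y: np.ndarray,
    scan: ScanResult,
    lod_min: float = 3.0,
    bonferroni_alpha: float = 0.05,
    max_sweeps: int = 300,
    tol: float = 1e-6,
    clump_r2: float | None = 0.2,
) -> tuple[list[QTNRecord], pd.DataFrame]:
    """Joint shrinkage refit of the stage-1 retained markers.

    The retained set is first LD-clumped (markers with r² > ``clump_r2`` to
    a smaller-P retained marker are dropped) so one representative carries
    each association signal rather than splitting it.  Per-marker variances
    then follow the empirical-Bayes sweep
    variance_j ∝ β̂_j² + posterior variance_j, renormalized each sweep; the
    overall scale of the marker variances and σ²e are re-estimated by
    maximum likelihood on the joint marginal model every sweep, so nulls
    shrink toward zero while real signals keep their variance share.

    Returns the records with LOD above ``lod_min`` plus a table of all
    retained markers with their joint effects and LODs.
    """
    retained = scan.retained
    if len(retained) == 0:
        return [], pd.DataFrame(
            columns=["marker_index", "chrom", "pos", "beta", "lod", "pve_pct"]
        )
    y = np.asarray(y, dtype=float)
    var_y = y.var(ddof=1)
    y0 = y - y.mean()

    if clump_r2 is not None and len(retained) > 1:
        retained = _clump_retained(g, scan, retained, clump_r2)
    X = g.centered()[:, retained]
    n, k = X.shape

    t = scan.table.iloc[retained]
    beta_scan = np.nan_to_num(t["beta"].to_numpy())
    se_scan = np.nan_to_num(t["se"].to_numpy(), nan=np.nanmean(t["se"]))
    shape = np.clip(beta_scan ** 2 + se_scan ** 2, 1e-12, None)
    shape /= shape.sum()
    s_scale, sigma_e2 = var_y * 0.1, var_y * 0.9

    converged = False
    var = s_scale * shape
    for sweep in range(max_sweeps):
        s_scale, sigma_e2 = _ml_variance_scale(y0, X, shape, s_scale, sigma_e2)
        var_new = np.clip(s_scale * shape, 1e-14, None)
        Dinv = sigma_e2 / var_new
        Cinv = np.linalg.inv(X.T @ X + np.diag(Dinv))
        beta_hat = Cinv @ (X.T @ y0)
        post_var = sigma_e2 * np.diag(Cinv)
        shape = np.clip(beta_hat ** 2 + post_var, 1e-14, None)
        shape /= shape.sum()
        # relative change, floored so variances collapsed to ~0 don't keep
        # the sweep alive with jitter at the numerical floor
        floor = 1e-6 * max(var_new.sum(), 1e-12)
        rel = np.max(np.abs(var_new - var) / np.maximum(var, floor))
        var = var_new
        if rel < tol:
            converged = True
            break
    if not converged:
        log.warning("empirical-Bayes sweep did not converge in %d sweeps", max_sweeps)

    Dinv = sigma_e2 / var
    Cinv = np.linalg.inv(X.T @ X + np.diag(Dinv))
    beta_hat = Cinv @ (X.T @ y0)

    ll_full = _lowrank_loglik(y0, X, var, sigma_e2)
    lods = np.empty(k)
    for j in range(k):
        mask = np.ones(k, dtype=bool)
        mask[j] = False
        ll_drop = _lowrank_loglik(y0, X[:, mask], var[mask], sigma_e2)
        lods[j] = (ll_full - ll_drop) / LN10
    lods = np.clip(lods, 0.0, None)

    p = g.allele_freq()[retained]
    pve = 100.0 * 2.0 * p * (1.0 - p) * beta_hat ** 2 / var_y
    maf = np.minimum(p, 1.0 - p)
    bonf = bonferroni_alpha / g.n_markers

    full = pd.DataFrame(
        {
            "marker_index": retained,
            "chrom": t["chrom"].to_numpy(),
            "pos": t["pos"].to_numpy(),
            "beta": beta_hat,
            "p_stage1": t["p"].to_numpy(),
            "lod": lods,
            "pve_pct": pve,
            "maf": maf,
            "converged": converged,
        }
    )
    records = []
    for _, row in full.iterrows():
        if row["lod"] <= lod_min:
            continue
        klass = (
            "significant"
            if row["p_stage1"] < bonf and row["lod"] > lod_min
            else "suggested"
        )
        records.append(
            QTNRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                beta=float(row["beta"]),
                p_stage1=float(row["p_stage1"]),
                lod=float(row["lod"]),
                pve_pct=float(row["pve_pct"]),
                maf=float(row["maf"]),
                klass=klass,
                marker_index=int(row["marker_index"]),
            )
        )
    return records, full


# ----------------------------------------------------------------------
# the full two-stage procedure as a model object
# ----------------------------------------------------------------------

@dataclass
class GWASResult:
    qtns: list[QTNRecord]
    scan: ScanResult
    joint_table: pd.DataFrame
    trait: str = ""

    def qtn_table(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": q.chrom,
                "pos": q.pos,
                "beta": q.beta,
                "p_stage1": q.p_stage1,
                "lod": q.lod,
                "pve_pct": q.pve_pct,
                "class": q.klass,
                "maf": q.maf,
            }
            for q in self.qtns
        ]
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "beta", "p_stage1", "lod", "pve_pct", "class", "maf"],
        )

    def manhattan_frame(self) -> pd.DataFrame:
        """Per-marker −log₁₀P plus the stage-2 LOD where available."""
        df = self.scan.table[["chrom", "pos", "p"]].copy()
        with np.errstate(divide="ignore"):
            df["neglog10p"] = -np.log10(df["p"])
        df["lod"] = np.nan
        df.loc[self.joint_table["marker_index"], "lod"] = self.joint_table["lod"].to_numpy()
        return df

    def summary(self) -> str:
        sig = sum(q.klass == "significant" for q in self.qtns)
        sug = len(self.qtns) - sig
        lines = [
            f"Two-stage multi-locus GWAS{' — ' + self.trait if self.trait else ''}",
            "=" * 44,
            f"markers scanned:   {len(self.scan.table)}",
            f"stage-1 retained:  {len(self.scan.retained)} (P < {self.scan.retain_p})",
            f"QTNs (LOD > 3):    {len(self.qtns)}  [{sig} significant, {sug} suggested]",
            f"null-model h2:     {self.scan.varcomp.h2:.3f}",
        ]
        if self.qtns:
            pves = [q.pve_pct for q in self.qtns]
            lines.append(f"PVE range:         {min(pves):.3f}% – {max(pves):.3f}%")
        return "\n".join(lines)


class TwoStageGWAS:
    """Model object for the two-stage scan; ``fit()`` returns GWASResult."""

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        y: np.ndarray,
        grm: GRM | None = None,
        covariates: np.ndarray | None = None,
        trait: str = "",
        retain_p: float = 0.01,
        lod_min: float = 3.0,
        bonferroni_alpha: float = 0.05,
    ):
        self.g = genotypes
        self.y = np.asarray(y, dtype=float)
        self.grm = grm
        self.covariates = covariates
        self.trait = trait
        self.retain_p = retain_p
        self.lod_min = lod_min
        self.bonferroni_alpha = bonferroni_alpha

    def fit(self) -> GWASResult:
        scan = mlm_scan(self.g, self.y, grm=self.grm,
                        covariates=self.covariates, retain_p=self.retain_p)
        qtns, joint = multilocus_refit(
            self.g, self.y, scan,
            lod_min=self.lod_min, bonferroni_alpha=self.bonferroni_alpha,
        )
        return GWASResult(qtns, scan, joint, trait=self.trait)


# ----------------------------------------------------------------------
# haplotype (genotype-class) comparison at a QTN
# ----------------------------------------------------------------------

def haplotype_test(g: GenotypeMatrix, y: np.ndarray, marker_index: int,
                   min_class_n: int = 3) -> dict:
    """Compare trait means across the dosage classes {0, 1, 2} at a QTN.

    Returns per-class means and sizes, Welch t-test P for each class pair,
    and a heterozygote-advantage flag (class-1 mean above both homozygote
    means).
    """
    y = np.asarray(y, dtype=float)
    d = np.round(g.dosage_float(impute_mean=False)[:, marker_index])
    classes = {}
    for k in (0, 1, 2):
        vals = y[d == k]
        if len(vals) >= min_class_n:
            classes[k] = vals
    if len(classes) < 2:
        raise ValueError("need at least 2 genotype classes with enough members")
    means = {k: float(v.mean()) for k, v in classes.items()}
    ns = {k: int(len(v)) for k, v in classes.items()}
    pvals = {}
    keys = sorted(classes)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = keys[i], keys[j]
            if np.allclose(classes[a], classes[a][0]) and np.allclose(classes[b], classes[b][0]) \
               and classes[a][0] == classes[b][0]:
                pvals[(a, b)] = 1.0
            else:
                pvals[(a, b)] = float(
                    stats.ttest_ind(classes[a], classes[b], equal_var=False).pvalue
                )
    het_adv = (
        1 in means
        and all(means[1] > means[k] for k in means if k != 1)
    )
    return {
        "means": means,
        "n": ns,
        "welch_p": pvals,
        "heterozygote_advantage": bool(het_adv),
    }


# ----------------------------------------------------------------------
# candidate-gene windows
# ----------------------------------------------------------------------

@dataclass
class CandidateWindow:
    qtn: QTNRecord
    flank: int
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand


def candidate_genes(
    qtns: list[QTNRecord],
    genes: pd.DataFrame,
    flank: int = 16_000,
) -> list[CandidateWindow]:
    """Genes overlapping the closed interval [pos − flank, pos + flank].

    The default flank is the population LD decay distance (16 kb); overlap
    is closed-interval and strand-agnostic, so a gene ending exactly at
    ``pos − flank`` is included.
    """
    windows = []
    for q in qtns:
        lo, hi = q.pos - flank, q.pos + flank
        hit = genes[
            (genes["chrom"] == q.chrom)
            & (genes["end"] >= lo)
            & (genes["start"] <= hi)
        ].reset_index(drop=True)
        windows.append(CandidateWindow(q, flank, hit))
    return windows
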