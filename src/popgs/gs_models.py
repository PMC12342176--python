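"""Genomic prediction models behind a common model/results interface.

Every model is a class constructed from data whose :meth:`fit` returns a
:class:`PredictionResult` carrying genomic estimated breeding values
(GEBVs) for *all* individuals, the fitted intercept, marker effects where
the model has them, and variance components or posterior summaries.

The suite covers the standard whole-genome regression families:

* **GBLUP** — y = 1μ + g + e with g ~ N(0, G σ²g) on the VanRaden GRM;
  variance components by restricted maximum likelihood (REML) via the
  spectral decomposition of G, test-set GEBVs by conditional expectation.
* **RR-BLUP** — ridge regression of y on centered dosages with
  λ = c·δ taken from REML on the corresponding GRM; exactly equivalent to
  GBLUP when G = WW'/c (the module's master identity).
* **Bayesian alphabet** — BRR, BayesA, BayesB, BayesC single-site Gibbs
  samplers with scaled-inverse-χ² variance priors and, for B/C, a
  point-mass-at-zero mixture with prior inclusion probability 1−π.
* **Machine-learning regressors** — random forest, gradient-boosted trees,
  kernel ridge (RBF, median-heuristic bandwidth), ridge and elastic net
  from scikit-learn with fixed, documented hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from popgs.genotypes import GenotypeMatrix
from popgs.popstruct import GRM, compute_grm

DELTA_MAX = 1e8  # effective h2 -> 0 boundary for the REML search


# ----------------------------------------------------------------------
# results containers
# ----------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    mu: float
    loglik: float
    boundary: bool = False

    @property
    def delta(self) -> float:
        return self.sigma_e2 / self.sigma_g2 if self.sigma_g2 > 0 else np.inf

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class PredictionResult:
    """GEBVs plus the fitted quantities that produced them."""

    model: str
    gebv: np.ndarray  # centered breeding values, all individuals
    mu: float
    sample_ids: np.ndarray
    effects: np.ndarray | None = None  # per-marker effects (marker models)
    varcomp: VarianceComponents | None = None
    posterior: dict = field(default_factory=dict)
    covariate_beta: np.ndarray | None = None

    def predicted_values(self) -> np.ndarray:
        """Predicted trait values μ̂ + GEBV."""
        return self.mu + self.gebv

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.sample_ids, "gebv": self.gebv,
             "predicted_value": self.predicted_values()}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [
            f"Genomic prediction results — {self.model}",
            "=" * 44,
            f"individuals: {len(self.gebv)}",
            f"intercept:   {self.mu:.4f}",
        ]
        if self.varcomp is not None:
            vc = self.varcomp
            lines += [
                f"sigma^2_g:   {vc.sigma_g2:.4f}",
                f"sigma^2_e:   {vc.sigma_e2:.4f}",
                f"genomic h2:  {vc.h2:.3f}" + ("  (boundary)" if vc.boundary else ""),
                f"REML loglik: {vc.loglik:.3f}",
            ]
        if self.effects is not None:
            a = np.abs(self.effects)
            lines.append(f"marker effects: {len(a)} (max |a| = {a.max():.4g})")
        if "inclusion" in self.posterior:
            lines.append(
                f"mean posterior inclusion: {np.mean(self.posterior['inclusion']):.3f}"
            )
        gv = self.gebv
        lines.append(f"GEBV range:  [{gv.min():.4f}, {gv.max():.4f}]")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# REML (EMMA-style spectral form)
# ----------------------------------------------------------------------

def _reml_neg_loglik(log_delta: float, s: np.ndarray, Uy: np.ndarray,
                     UX: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    XtWX = (UX * w[:, None]).T @ UX
    XtWy = (UX * w[:, None]).T @ Uy
    beta = np.linalg.solve(XtWX, XtWy)
    resid = Uy - UX @ beta
    R = max(float(np.sum(w * resid ** 2)), 1e-300)  # constant y → R = 0
    nq = len(s) - UX.shape[1]
    sign, logdet_X = np.linalg.slogdet(XtWX)
    ll = 0.5 * (
        nq * np.log(nq / (2.0 * np.pi))
        - nq
        - nq * np.log(R)
        - np.sum(np.log(s + delta))
        - logdet_X
    )
    return -ll


def reml_fit(y: np.ndarray, grm: GRM | np.ndarray,
             X: np.ndarray | None = None) -> VarianceComponents:
    """REML variance components for y = Xβ + g + e, g ~ N(0, G σ²g).

    The restricted likelihood is profiled to a one-dimensional search over
    δ = σ²e/σ²g on the log scale (coarse grid, then bounded Brent
    refinement to 1e−8 in log δ).  A flat-likelihood fit that runs into the
    large-δ boundary is returned with σ²g = 0 and ``boundary=True``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("REML needs at least 10 observations")
    G = grm.matrix if isinstance(grm, GRM) else np.asarray(grm)
    if X is None:
        X = np.ones((n, 1))
    s, U = np.linalg.eigh(G)
    s = np.clip(s, 0.0, None)
    Uy = U.T @ y
    UX = U.T @ X

    grid = np.linspace(np.log(1e-6), np.log(DELTA_MAX), 121)
    vals = np.array([_reml_neg_loglik(g, s, Uy, UX) for g in grid])
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    opt = minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(s, Uy, UX),
        method="bounded", options={"xatol": 1e-8},
    )
    log_delta = float(opt.x)
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    XtWX = (UX * w[:, None]).T @ UX
    beta = np.linalg.solve(XtWX, (UX * w[:, None]).T @ Uy)
    resid = Uy - UX @ beta
    nq = n - X.shape[1]
    sigma_g2 = float(np.sum(w * resid ** 2) / nq)
    sigma_e2 = sigma_g2 * delta
    boundary = log_delta >= np.log(DELTA_MAX) - 0.5
    if boundary:
        sigma_e2 = sigma_g2 * delta
        sigma_g2 = 0.0
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        mu=float(beta[0]),
        loglik=-float(opt.fun),
        boundary=boundary,
    )


# ----------------------------------------------------------------------
# GBLUP
# ----------------------------------------------------------------------

class GBLUP:
    """Genomic BLUP on a (VanRaden) genomic relationship matrix.

    Parameters
    ----------
    y
        Phenotype vector for the *training* individuals.
    grm
        GRM over all individuals (training + prediction targets).
    train_idx
        Row indices of the training individuals within the GRM; default all.
    covariates
        Optional fixed-effect design for the training individuals
        (intercept added automatically).
    """

    tag = "GBLUP"

    def __init__(self, y, grm: GRM | GenotypeMatrix, train_idx=None,
                 covariates: np.ndarray | None = None):
        self.grm = grm if isinstance(grm, GRM) else compute_grm(grm)
        self.y = np.asarray(y, dtype=float)
        self.train_idx = (
            np.arange(self.grm.n) if train_idx is None else np.asarray(train_idx)
        )
        if len(self.y) != len(self.train_idx):
            raise ValueError("y length must match train_idx")
        self.covariates = covariates

    def fit(self, varcomp: VarianceComponents | None = None) -> PredictionResult:
        t = self.train_idx
        G_tt = self.grm.submatrix(t)
        X = np.ones((len(t), 1))
        if self.covariates is not None:
            X = np.column_stack([X, self.covariates])
        if varcomp is None:
            varcomp = reml_fit(self.y, G_tt, X=X)
        delta = min(varcomp.delta, DELTA_MAX)
        A = G_tt + delta * np.eye(len(t))
        # GLS fixed effects under V ∝ (G_tt + δI)
        Ainv_X = np.linalg.solve(A, X)
        Ainv_y = np.linalg.solve(A, self.y)
        beta = np.linalg.solve(X.T @ Ainv_X, X.T @ Ainv_y)
        resid = self.y - X @ beta
        alpha = np.linalg.solve(A, resid)
        gebv = self.grm.matrix[:, t] @ alpha
        return PredictionResult(
            model=self.tag,
            gebv=gebv,
            mu=float(beta[0]),
            sample_ids=self.grm.sample_ids,
            varcomp=VarianceComponents(
                varcomp.sigma_g2, varcomp.sigma_e2, float(beta[0]),
                varcomp.loglik, varcomp.boundary,
            ),
            covariate_beta=beta[1:] if len(beta) > 1 else None,
        )


# ----------------------------------------------------------------------
# RR-BLUP
# ----------------------------------------------------------------------

class RRBLUP:
    """Ridge-regression BLUP on centered dosages.

    Uses the dual (kernel) form ``â = W'(WW' + λI)⁻¹(y − μ̂)`` with
    λ = c·δ from REML on the matched GRM, so GEBV = W·â coincides with
    GBLUP to numerical precision.
    """

    tag = "RR-BLUP"

    def __init__(self, y, genotypes: GenotypeMatrix, train_idx=None):
        self.g = genotypes
        self.y = np.asarray(y, dtype=float)
        self.train_idx = (
            np.arange(genotypes.n_samples) if train_idx is None else np.asarray(train_idx)
        )
        if len(self.y) != len(self.train_idx):
            raise ValueError("y length must match train_idx")

    def fit(self, varcomp: VarianceComponents | None = None) -> PredictionResult:
        p = self.g.allele_freq()
        poly = (p > 0) & (p < 1)
        c = float(2.0 * np.sum(p[poly] * (1.0 - p[poly])))
        W = self.g.centered()[:, poly]
        t = self.train_idx
        Wt = W[t]
        K_tt = Wt @ Wt.T / c
        if varcomp is None:
            varcomp = reml_fit(self.y, K_tt, X=np.ones((len(t), 1)))
        lam = c * min(varcomp.delta, DELTA_MAX)
        A = Wt @ Wt.T + lam * np.eye(len(t))
        ones = np.ones((len(t), 1))
        Ainv_1 = np.linalg.solve(A, ones)
        Ainv_y = np.linalg.solve(A, self.y)
        mu = float((ones.T @ Ainv_y).item() / (ones.T @ Ainv_1).item())
        ahat = Wt.T @ np.linalg.solve(A, self.y - mu)
        effects = np.zeros(self.g.n_markers)
        effects[poly] = ahat
        gebv = W @ ahat
        return PredictionResult(
            model=self.tag,
            gebv=gebv,
            mu=mu,
            sample_ids=self.g.sample_ids,
            effects=effects,
            varcomp=VarianceComponents(
                varcomp.sigma_g2, varcomp.sigma_e2, mu, varcomp.loglik,
                varcomp.boundary,
            ),
        )


# ----------------------------------------------------------------------
# Bayesian alphabet
# ----------------------------------------------------------------------

@dataclass
class BayesConfig:
    """Gibbs chain settings (BGLR-like defaults)."""

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    pi: float = 0.95  # prior zero-effect mass for BayesB/C
    nu: float = 4.0  # prior df for marker-variance scaled-inv-chi2
    scale: float | None = None  # marker-variance prior scale; None = heuristic
    nu_e: float = 4.0
    r2_prior: float = 0.5  # prior fraction of variance assigned to markers
    seed: int = 0
    fixed_variances: tuple[float, float] | None = None  # (sigma_b2, sigma_e2)

    def __post_init__(self) -> None:
        if not 0 <= self.pi < 1:
            raise ValueError("pi must lie in [0, 1)")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


class BayesAlphabet:
    """Single-site Gibbs samplers for BRR / BayesA / BayesB / BayesC.

    All four share the same sweep; they differ only in how marker variances
    are modeled (common vs per-marker) and whether a point mass at zero
    with prior probability π is mixed in.
    """

    MODELS = ("BRR", "BayesA", "BayesB", "BayesC")

    def __init__(self, model: str, config: BayesConfig | None = None):
        if model not in self.MODELS:
            raise ValueError(f"unknown Bayesian model {model!r}")
        self.model = model
        self.cfg = config or BayesConfig()

    # The sampler works on centered marker codes; callers pass the full
    # matrix plus training indices so GEBVs cover everyone.
    def fit(self, y, genotypes: GenotypeMatrix | np.ndarray,
            train_idx=None) -> PredictionResult:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        if isinstance(genotypes, GenotypeMatrix):
            W_all = genotypes.centered()
            sample_ids = genotypes.sample_ids
        else:
            W_all = np.asarray(genotypes, dtype=float)
            sample_ids = np.arange(W_all.shape[0])
        y = np.asarray(y, dtype=float)
        t = np.arange(W_all.shape[0]) if train_idx is None else np.asarray(train_idx)
        W = np.ascontiguousarray(W_all[t])
        n, m = W.shape
        xtx = np.einsum("ij,ij->j", W, W)
        xtx = np.where(xtx <= 0, np.nan, xtx)

        vy = y.var(ddof=1)
        msx = np.nansum(xtx) / n
        fixed = cfg.fixed_variances is not None
        if fixed:
            sigma_b2_common, sigma_e2 = cfg.fixed_variances
            S_b = sigma_b2_common
        else:
            sigma_e2 = vy * (1.0 - cfg.r2_prior)
            # prior scale so the prior mode of total marker variance ≈ R2·Var(y)
            frac = (1.0 - cfg.pi) if self.model in ("BayesB", "BayesC") else 1.0
            S_b = cfg.scale if cfg.scale is not None else (
                vy * cfg.r2_prior * (cfg.nu + 2.0) / cfg.nu / max(msx * frac, 1e-12)
            )
            sigma_b2_common = S_b * cfg.nu / (cfg.nu + 2.0)
        S_e = vy * (1.0 - cfg.r2_prior) * (cfg.nu_e + 2.0) / cfg.nu_e

        per_marker_var = self.model in ("BayesA", "BayesB")
        has_indicator = self.model in ("BayesB", "BayesC")
        sigma_b2 = (
            np.full(m, sigma_b2_common) if per_marker_var else sigma_b2_common
        )

        mu = float(y.mean())
        beta = np.zeros(m)
        included = np.ones(m, dtype=bool)
        r = y - mu

        n_kept = 0
        beta_sum = np.zeros(m)
        beta_sq_sum = np.zeros(m)
        mu_sum = 0.0
        incl_sum = np.zeros(m)
        sigma_sum = np.zeros(2)

        log_prior_odds = (
            np.log((1.0 - cfg.pi) / cfg.pi) if has_indicator and cfg.pi > 0 else np.inf
        )

        for it in range(cfg.n_iter):
            # intercept
            r += mu
            mu = rng.normal(r.mean(), np.sqrt(sigma_e2 / n))
            r -= mu

            var_j = sigma_b2 if per_marker_var else np.full(m, sigma_b2)
            for j in range(m):
                if np.isnan(xtx[j]):
                    beta[j] = 0.0
                    included[j] = False
                    continue
                x = W[:, j]
                rhs = x @ r + xtx[j] * beta[j]
                lam = sigma_e2 / var_j[j]
                C = xtx[j] + lam
                if has_indicator and np.isfinite(log_prior_odds):
                    log_bf = 0.5 * np.log(lam / C) + rhs ** 2 / (2.0 * sigma_e2 * C)
                    p_incl = 1.0 / (1.0 + np.exp(-(log_prior_odds + log_bf)))
                    inc = rng.random() < p_incl
                else:
                    inc = True
                old = beta[j]
                if inc:
                    new = rng.normal(rhs / C, np.sqrt(sigma_e2 / C))
                else:
                    new = 0.0
                if new != old:
                    r += x * (old - new)
                    beta[j] = new
                included[j] = inc

            if not fixed:
                if self.model == "BayesA":
                    sigma_b2 = (beta ** 2 + cfg.nu * S_b) / rng.chisquare(
                        cfg.nu + 1.0, size=m
                    )
                elif self.model == "BayesB":
                    df = cfg.nu + included.astype(float)
                    sigma_b2 = (beta ** 2 + cfg.nu * S_b) / rng.chisquare(df)
                elif self.model == "BayesC":
                    k = int(included.sum())
                    sigma_b2 = float(
                        (np.sum(beta[included] ** 2) + cfg.nu * S_b)
                        / rng.chisquare(cfg.nu + k)
                    )
                else:  # BRR
                    sigma_b2 = float(
                        (np.sum(beta ** 2) + cfg.nu * S_b)
                        / rng.chisquare(cfg.nu + m)
                    )
                sigma_e2 = float(
                    (r @ r + cfg.nu_e * S_e) / rng.chisquare(n + cfg.nu_e)
                )

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                n_kept += 1
                beta_sum += beta
                beta_sq_sum += beta ** 2
                mu_sum += mu
                incl_sum += included
                sb = float(np.mean(sigma_b2)) if per_marker_var else float(sigma_b2)
                sigma_sum += (sb, sigma_e2)

        beta_mean = beta_sum / n_kept
        beta_sd = np.sqrt(np.clip(beta_sq_sum / n_kept - beta_mean ** 2, 0.0, None))
        mu_mean = mu_sum / n_kept
        gebv = W_all @ beta_mean
        return PredictionResult(
            model=self.model,
            gebv=gebv,
            mu=mu_mean,
            sample_ids=sample_ids,
            effects=beta_mean,
            posterior={
                "effect_sd": beta_sd,
                "inclusion": incl_sum / n_kept,
                "sigma_b2": sigma_sum[0] / n_kept,
                "sigma_e2": sigma_sum[1] / n_kept,
                "n_samples": n_kept,
            },
        )


# ----------------------------------------------------------------------
# scikit-learn regressors
# ----------------------------------------------------------------------

class SklearnGS:
    """Generic regressor contract: fit on training rows, predict everyone.

    Fixed hyperparameters (no nested tuning): RF 500 trees; GBDT depth 3,
    500 rounds, learning rate 0.1; KRR with RBF kernel at the median-
    heuristic bandwidth; ridge/elastic-net α from the REML ridge parameter
    of the matched GRM (elastic net l1_ratio 0.5).
    """

    TAGS = ("RF", "GBDT", "KRR", "RR", "EN")

    def __init__(self, tag: str, seed: int = 0, alpha: float | None = None):
        if tag not in self.TAGS:
            raise ValueError(f"unknown ML regressor tag {tag!r}")
        self.tag = tag
        self.seed = seed
        self.alpha = alpha

    def _make(self, X: np.ndarray, y: np.ndarray):
        from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
        from sklearn.kernel_ridge import KernelRidge
        from sklearn.linear_model import ElasticNet, Ridge

        if self.tag == "RF":
            return RandomForestRegressor(n_estimators=500, random_state=self.seed, n_jobs=1)
        if self.tag == "GBDT":
            return GradientBoostingRegressor(
                max_depth=3, n_estimators=500, learning_rate=0.1, random_state=self.seed
            )
        if self.tag == "KRR":
            sub = X[np.random.default_rng(self.seed).choice(len(X), min(len(X), 200), replace=False)]
            d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
            med = np.median(d2[np.triu_indices_from(d2, k=1)])
            gamma = 1.0 / max(med, 1e-12)
            return KernelRidge(kernel="rbf", gamma=gamma, alpha=1.0)
        alpha = self.alpha
        if alpha is None:
            # REML-derived ridge penalty on the matched kernel
            K = X @ X.T / max(np.trace(X @ X.T) / len(X), 1e-12)
            vc = reml_fit(y, K)
            alpha = min(vc.delta, 1e6) * max(np.trace(X @ X.T) / len(X), 1e-12)
        if self.tag == "RR":
            return Ridge(alpha=alpha)
        return ElasticNet(alpha=alpha / (2.0 * len(X)), l1_ratio=0.5, max_iter=5000)

    def fit(self, y, genotypes: GenotypeMatrix | np.ndarray,
            train_idx=None) -> PredictionResult:
        if isinstance(genotypes, GenotypeMatrix):
            X_all = genotypes.centered()
            ids = genotypes.sample_ids
        else:
            X_all = np.asarray(genotypes, dtype=float)
            ids = np.arange(X_all.shape[0])
        y = np.asarray(y, dtype=float)
        t = np.arange(X_all.shape[0]) if train_idx is None else np.asarray(train_idx)
        ybar = float(y.mean())  # center the target: KRR has no intercept term
        est = self._make(X_all[t], y - ybar)
        est.fit(X_all[t], y - ybar)
        pred = est.predict(X_all) + ybar
        mu = float(np.mean(pred[t]))
        return PredictionResult(
            model=self.tag, gebv=pred - mu, mu=mu, sample_ids=ids,
        )


# ----------------------------------------------------------------------
# registry
# ----------------------------------------------------------------------

def fit_model(tag: str, y, genotypes: GenotypeMatrix, train_idx=None,
              seed: int = 0, bayes_config: BayesConfig | None = None) -> PredictionResult:
    """Uniform entry point used by the cross-validation engine.

    ``tag`` is one of GBLUP, RR-BLUP, BayesA, BayesB, BayesC, BRR,
    RF, GBDT, KRR, RR, EN.
    """
    if tag == "GBLUP":
        return GBLUP(y, genotypes, train_idx).fit()
    if tag == "RR-BLUP":
        return RRBLUP(y, genotypes, train_idx).fit()
    if tag in BayesAlphabet.MODELS:
        cfg = bayes_config or BayesConfig(seed=seed)
        return BayesAlphabet(tag, cfg).fit(y, genotypes, train_idx)
    if tag in SklearnGS.TAGS:
        return SklearnGS(tag, seed=seed).fit(y, genotypes, train_idx)
    raise KeyError(f"unknown model tag {tag!r}")


MODEL_TAGS = ("GBLUP", "RR-BLUP", "BayesA", "BayesB", "BayesC", "BRR",
              "RF", "GBDT", "KRR", "RR", "EN")
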