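"""Repeated cross-validation over models, marker densities and selection strategies.

Predictive ability (PA) of a (model, marker subset) cell is the Pearson
correlation between validation-set phenotypes and the GEBVs predicted for
them; five-fold CV repeated 10 times and averaged over all repetition ×
fold cells is the headline evaluation.

Marker-selection strategies:

* ``random`` — uniform draws at six densities (1, 0.5, 0.2, 0.1, 0.05,
  0.01 of the panel);
* ``ld_prune`` — the PLINK ``--indep-pairwise 50 50 0.2`` analogue;
* ``gwas_p`` — markers whose stage-1 mixed-model P on the *training
  individuals of the current fold only* falls below a threshold.  The scan
  is recomputed inside every fold of every repetition, never on the full
  data, so no validation phenotype leaks into marker choice.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from popgs.genotypes import GenotypeMatrix
from popgs.gs_models import BayesConfig, fit_model
from popgs.gwas import mlm_scan
from popgs.popstruct import compute_grm, ld_prune

log = logging.getLogger(__name__)

DENSITY_FRACTIONS = (1.0, 0.5, 0.2, 0.1, 0.05, 0.01)
GWAS_P_THRESHOLDS = (1.0, 0.5, 0.1, 0.01, 0.001, 0.0001)


# ----------------------------------------------------------------------
# fold plans
# ----------------------------------------------------------------------

@dataclass
class FoldPlan:
    n: int
    k: int
    assignments: list[np.ndarray]  # one length-n fold-label vector per repetition
    seed: int

    @property
    def repetitions(self) -> int:
        return len(self.assignments)

    def folds(self, rep: int):
        """Yield (fold, train_idx, val_idx) for one repetition."""
        lab = self.assignments[rep]
        for f in range(self.k):
            val = np.where(lab == f)[0]
            train = np.where(lab != f)[0]
            yield f, train, val


def kfold_plan(n: int, k: int = 5, repetitions: int = 10, seed: int = 0) -> FoldPlan:
    """Seeded repeated k-fold partition; ``k = n`` gives LOOCV (1 repetition)."""
    if k > n:
        raise ValueError("k cannot exceed n")
    if k == n:
        repetitions = 1
    rng = np.random.default_rng(seed)
    assignments = []
    base = np.arange(n) % k
    for _ in range(repetitions):
        perm = rng.permutation(n)
        lab = np.empty(n, dtype=int)
        lab[perm] = base
        assignments.append(lab)
    return FoldPlan(n, k, assignments, seed)


# ----------------------------------------------------------------------
# marker subsets
# ----------------------------------------------------------------------

@dataclass
class MarkerSubset:
    strategy: str  # random | ld_prune | gwas_p
    parameter: float
    indices: np.ndarray | None  # None for fold-local (gwas_p) subsets
    provenance: str = "global"

    @property
    def label(self) -> str:
        return f"{self.strategy}:{self.parameter:g}"


def density_grid(
    n_markers: int,
    fractions=DENSITY_FRACTIONS,
    seed: int = 0,
) -> list[MarkerSubset]:
    """Random marker subsets at the six standard densities."""
    rng = np.random.default_rng(seed)
    subsets = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        size = max(1, int(round(frac * n_markers)))
        if frac == 1.0:
            idx = np.arange(n_markers)
        else:
            idx = np.sort(rng.choice(n_markers, size=size, replace=False))
        subsets.append(MarkerSubset("random", frac, idx))
    return subsets


def ld_prune_subset(g: GenotypeMatrix, window: int = 50, step: int = 50,
                    r2_max: float = 0.2) -> MarkerSubset:
    idx = ld_prune(g, window=window, step=step, r2_max=r2_max)
    return MarkerSubset("ld_prune", r2_max, idx)


def gwas_p_subsets(
    g: GenotypeMatrix,
    y: np.ndarray,
    train_idx: np.ndarray,
    thresholds=GWAS_P_THRESHOLDS,
    fallback_top: int = 10,
) -> dict[float, tuple[np.ndarray, bool]]:
    """Fold-local GWAS-P marker subsets.

    The stage-1 scan runs on the training individuals only.  Returns
    threshold → (marker indices, fallback flag); an empty subset at a
    strict threshold falls back to the ``fallback_top`` smallest-P markers.
    """
    g_train = g.take_samples(train_idx)
    y_train = np.asarray(y, dtype=float)[train_idx]
    scan = mlm_scan(g_train, y_train, grm=compute_grm(g_train))
    p = np.nan_to_num(scan.table["p"].to_numpy(), nan=1.0)
    out = {}
    for thr in thresholds:
        idx = np.where(p <= thr)[0]
        fallback = False
        if len(idx) < 2:  # empty (or degenerate single-marker) subset
            idx = np.argsort(p, kind="stable")[:fallback_top]
            fallback = True
            log.warning("empty gwas_p subset at P<=%g; top-%d fallback", thr, fallback_top)
        out[thr] = (np.sort(idx), fallback)
    return out


# ----------------------------------------------------------------------
# the factorial run
# ----------------------------------------------------------------------

def predictive_ability(y_val: np.ndarray, gebv_val: np.ndarray) -> float:
    """Pearson r between validation phenotypes and their GEBVs."""
    if len(y_val) < 2 or np.std(y_val) == 0 or np.std(gebv_val) == 0:
        return np.nan
    return float(stats.pearsonr(y_val, gebv_val).statistic)


def run_cv(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    traits: list[str],
    models: list[str],
    subsets: list[MarkerSubset],
    plan: FoldPlan,
    seed: int = 0,
    bayes_config: BayesConfig | None = None,
) -> pd.DataFrame:
    """Full factorial (model × subset × trait × repetition × fold).

    Returns a tidy table with one row per cell; a failed fit leaves the
    cell's ``pa`` missing with the error recorded, and the run continues.
    """
    ids = phenotypes["id"].to_numpy()
    row_idx = genotypes.sample_index(ids)
    g = genotypes.take_samples(row_idx)
    rows = []
    for trait in traits:
        y = phenotypes[trait].to_numpy(dtype=float)
        for subset in subsets:
            for rep in range(plan.repetitions):
                for fold, train, val in plan.folds(rep):
                    if subset.strategy == "gwas_p" and subset.indices is None:
                        local = gwas_p_subsets(g, y, train, thresholds=(subset.parameter,))
                        idx, fallback = local[subset.parameter]
                        provenance = f"fold-local rep{rep} fold{fold}"
                    else:
                        idx, fallback = subset.indices, False
                        provenance = subset.provenance
                    g_sub = g.take_markers(idx)
                    for model in models:
                        t0 = time.perf_counter()
                        try:
                            res = fit_model(
                                model, y[train], g_sub, train_idx=train,
                                seed=seed + rep, bayes_config=bayes_config,
                            )
                            pa = predictive_ability(y[val], res.gebv[val])
                            err = ""
                        except Exception as exc:  # noqa: BLE001 - cell-level policy
                            pa, err = np.nan, f"{type(exc).__name__}: {exc}"
                            log.warning("cell failed (%s %s): %s", model, subset.label, err)
                        rows.append(
                            {
                                "model": model,
                                "trait": trait,
                                "strategy": subset.strategy,
                                "parameter": subset.parameter,
                                "repetition": rep,
                                "fold": fold,
                                "pa": pa,
                                "seconds": time.perf_counter() - t0,
                                "n_markers": len(idx),
                                "fallback": fallback,
                                "provenance": provenance,
                                "error": err,
                            }
                        )
    return pd.DataFrame(rows)


def summarize_cv(cv: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD predictive ability per (trait, model, strategy, parameter)."""
    grp = cv.groupby(["trait", "model", "strategy", "parameter"], as_index=False)
    out = grp.agg(
        pa_mean=("pa", "mean"),
        pa_sd=("pa", "std"),
        n_cells=("pa", "size"),
        n_complete=("pa", "count"),
        mean_markers=("n_markers", "mean"),
        mean_seconds=("seconds", "mean"),
    )
    out["completeness"] = out["n_complete"] / out["n_cells"]
    return out


# ----------------------------------------------------------------------
# optimal model / strategy selection
# ----------------------------------------------------------------------

@dataclass
class OptimalChoice:
    trait: str
    best_model: str
    model_pa: float
    best_strategy: str
    best_parameter: float
    strategy_pa: float
    improvement_pct: float | None = None  # vs the full-panel PA of the model


def select_optimal(summary: pd.DataFrame) -> list[OptimalChoice]:
    """Two-phase selection per trait.

    Phase 1: the model with the best mean PA across the random marker
    densities.  Phase 2: given that model, the marker-selection strategy
    and parameter with the best mean PA.  Ties break toward the smaller
    subset, then the faster mean fit.
    """
    choices = []
    for trait, sub in summary.groupby("trait"):
        dens = sub[sub["strategy"] == "random"]
        if dens.empty:
            dens = sub
        by_model = dens.groupby("model").agg(
            pa=("pa_mean", "mean"), markers=("mean_markers", "mean"),
            secs=("mean_seconds", "mean"),
        ).reset_index()
        by_model = by_model.sort_values(
            ["pa", "markers", "secs"], ascending=[False, True, True], kind="stable"
        )
        best_model = by_model.iloc[0]["model"]
        model_pa = float(by_model.iloc[0]["pa"])

        cand = sub[sub["model"] == best_model].sort_values(
            ["pa_mean", "mean_markers", "mean_seconds"],
            ascending=[False, True, True], kind="stable",
        )
        top = cand.iloc[0]
        full = sub[
            (sub["model"] == best_model)
            & (sub["strategy"] == "random")
            & (sub["parameter"] == 1.0)
        ]
        improvement = None
        if not full.empty and full["pa_mean"].iloc[0] > 0:
            improvement = float(
                100.0 * (top["pa_mean"] - full["pa_mean"].iloc[0]) / full["pa_mean"].iloc[0]
            )
        choices.append(
            OptimalChoice(
                trait=trait,
                best_model=str(best_model),
                model_pa=model_pa,
                best_strategy=str(top["strategy"]),
                best_parameter=float(top["parameter"]),
                strategy_pa=float(top["pa_mean"]),
                improvement_pct=improvement,
            )
        )
    return choices
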