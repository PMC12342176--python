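"""Breeding-population deployment of a chosen genomic-prediction model.

The reference (phenotyped) population trains the selected model on the
selected marker subset, with GWAS-significant QTNs entering as fixed
covariates; the breeding candidates receive GEBVs, the top fraction
(default 20%) are selected per trait or on a composite value, genetic gain
is reported on the predicted-value scale, and parental kinship networks
identify core parents by counting selected progeny per parent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from popgs.genotypes import GenotypeMatrix
from popgs.gs_models import GBLUP, PredictionResult, fit_model
from popgs.pedigree import Pedigree
from popgs.popstruct import compute_grm


class PanelMismatchError(ValueError):
    pass


# ----------------------------------------------------------------------
# prediction for the breeding population
# ----------------------------------------------------------------------

def harmonize_panels(ref: GenotypeMatrix, breeding: GenotypeMatrix,
                     min_overlap: float = 0.5) -> tuple[GenotypeMatrix, GenotypeMatrix, int]:
    """Restrict both panels to shared (chrom, pos) markers.

    Raises :class:`PanelMismatchError` when fewer than ``min_overlap`` of
    the reference panel's markers are shared (the trained model needs its
    own markers genotyped in the candidates).
    """
    key_ref = pd.MultiIndex.from_frame(ref.markers[["chrom", "pos"]])
    key_brd = pd.MultiIndex.from_frame(breeding.markers[["chrom", "pos"]])
    shared = key_ref.intersection(key_brd)
    frac = len(shared) / len(key_ref)
    if frac < min_overlap:
        raise PanelMismatchError(
            f"only {frac:.0%} of markers shared between panels (<{min_overlap:.0%})"
        )
    ref_idx = np.where(key_ref.isin(shared))[0]
    brd_idx = np.where(key_brd.isin(shared))[0]
    return ref.take_markers(ref_idx), breeding.take_markers(brd_idx), len(shared)


def predict_breeding(
    ref_genotypes: GenotypeMatrix,
    y_ref: np.ndarray,
    breeding_genotypes: GenotypeMatrix,
    model: str = "GBLUP",
    subset_marker_ids: np.ndarray | None = None,
    qtn_marker_ids: np.ndarray | None = None,
    seed: int = 0,
) -> PredictionResult:
    """Train on the full reference population, predict all breeding candidates.

    ``subset_marker_ids`` (``Chr_pos`` strings) restricts the panel;
    ``qtn_marker_ids`` are GWAS-significant QTNs whose dosages enter as
    fixed covariates.  Returns a :class:`PredictionResult` over the stacked
    reference + breeding individuals (breeding GEBVs in the tail rows).
    """
    ref_h, brd_h, _ = harmonize_panels(ref_genotypes, breeding_genotypes)
    dos = np.vstack([
        ref_h.dosage_float(impute_mean=True),
        brd_h.dosage_float(impute_mean=True),
    ])
    ids = np.concatenate([ref_h.sample_ids, brd_h.sample_ids])
    if len(set(ids)) < len(ids):  # disambiguate duplicated ids across panels
        ids = np.array(
            [f"{s}#ref" for s in ref_h.sample_ids]
            + [f"{s}#brd" for s in brd_h.sample_ids],
            dtype=object,
        )
    combined = GenotypeMatrix(dos, ids, ref_h.markers)

    mids = combined.marker_ids()
    if subset_marker_ids is not None:
        keep = np.where(np.isin(mids, np.asarray(subset_marker_ids)))[0]
        if len(keep) == 0:
            raise PanelMismatchError("marker subset has no overlap with shared panel")
    else:
        keep = np.arange(combined.n_markers)

    covariates = None
    if qtn_marker_ids is not None and len(qtn_marker_ids) > 0:
        qidx = np.where(np.isin(mids, np.asarray(qtn_marker_ids)))[0]
        if len(qidx):
            covariates = combined.centered()[:, qidx]

    g_model = combined.take_markers(keep)
    train = np.arange(ref_h.n_samples)
    y_ref = np.asarray(y_ref, dtype=float)

    if model == "GBLUP":
        grm = compute_grm(g_model).with_jitter()
        cov_train = covariates[train] if covariates is not None else None
        res = GBLUP(y_ref, grm, train_idx=train, covariates=cov_train).fit()
        if covariates is not None and res.covariate_beta is not None:
            res.gebv = res.gebv + covariates @ res.covariate_beta
        return res

    # other model tags: pre-adjust y for the QTN covariates, add back on top
    if covariates is not None:
        X = np.column_stack([np.ones(len(train)), covariates[train]])
        beta = np.linalg.lstsq(X, y_ref, rcond=None)[0]
        y_adj = y_ref - covariates[train] @ beta[1:]
        res = fit_model(model, y_adj, g_model, train_idx=train, seed=seed)
        res.gebv = res.gebv + covariates @ beta[1:]
        return res
    return fit_model(model, y_ref, g_model, train_idx=train, seed=seed)


def breeding_slice(res: PredictionResult, breeding_ids) -> pd.DataFrame:
    """GEBV table restricted to the breeding candidates."""
    frame = res.to_frame()
    wanted = {str(s) for s in breeding_ids}
    mask = frame["id"].astype(str).str.replace("#brd", "", regex=False).isin(wanted) & \
        ~frame["id"].astype(str).str.endswith("#ref")
    out = frame[mask].copy()
    out["id"] = out["id"].astype(str).str.replace("#brd", "", regex=False)
    return out.reset_index(drop=True)


# ----------------------------------------------------------------------
# selection
# ----------------------------------------------------------------------

@dataclass
class SelectionReport:
    trait: str
    table: pd.DataFrame  # id, gebv, predicted_value, rank, selected
    rate: float
    gain_pct: float
    direction: str = "max"

    @property
    def selected_ids(self) -> np.ndarray:
        return self.table.loc[self.table["selected"], "id"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def select_top(
    predictions: pd.DataFrame,
    rate: float = 0.20,
    trait: str = "",
    direction: str = "max",
) -> SelectionReport:
    """Rank by GEBV and select the top ``rate`` fraction (⌈rate·n⌉ clones).

    ``direction="min"`` selects the smallest values (for traits where
    lower is better, e.g. basic density for pulp breeding).  Ties break by
    id for determinism.  Genetic gain is reported on the predicted-value
    scale: 100·(mean_selected − mean_all)/|mean_all|.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must lie in (0, 1]")
    df = predictions.copy()
    if "predicted_value" not in df.columns:
        df["predicted_value"] = df["gebv"]
    if not np.isfinite(df["gebv"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite GEBVs")
    ascending = direction == "min"
    df = df.sort_values(["gebv", "id"], ascending=[ascending, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    n_sel = math.ceil(rate * len(df))
    df["selected"] = df["rank"] <= n_sel
    mean_all = df["predicted_value"].mean()
    mean_sel = df.loc[df["selected"], "predicted_value"].mean()
    gain = 0.0 if mean_all == 0 else 100.0 * (mean_sel - mean_all) / abs(mean_all)
    return SelectionReport(trait, df, rate, float(gain), direction)


@dataclass
class CompositeConfig:
    """Traits and weights of a composite breeding value (weights sum to 1)."""

    weights: dict[str, float]
    standardize: bool = True

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"composite weights must sum to 1, got {total}")


def composite_gcbv(
    predictions: dict[str, pd.DataFrame],
    cfg: CompositeConfig | None = None,
) -> pd.DataFrame:
    """Genomic composite breeding value: GCBV = Σ w_t·z(GEBV_t).

    GEBVs are z-standardized per trait before weighting (otherwise equal
    weights would be scale-dependent across trait units); disable with
    ``cfg.standardize=False``.  Default weights: H and DBH at 0.5 each.
    """
    if cfg is None:
        cfg = CompositeConfig({"H": 0.5, "DBH": 0.5})
    base = None
    for trait, w in cfg.weights.items():
        if trait not in predictions:
            raise KeyError(f"no predictions for composite trait {trait!r}")
        df = predictions[trait][["id", "gebv"]].copy()
        v = df["gebv"].to_numpy(dtype=float)
        if cfg.standardize:
            sd = v.std(ddof=1)
            v = (v - v.mean()) / sd if sd > 0 else v - v.mean()
        df[trait] = w * v
        df = df.drop(columns="gebv")
        base = df if base is None else base.merge(df, on="id", validate="1:1")
    base["gcbv"] = base[list(cfg.weights)].sum(axis=1)
    return base[["id", "gcbv"]]


# ----------------------------------------------------------------------
# kinship networks
# ----------------------------------------------------------------------

@dataclass
class KinshipNetwork:
    graph: nx.Graph  # bipartite parents <-> selected progeny
    parent_weights: pd.DataFrame  # parent, role, weight
    trait: str = "pooled"

    def core_parents(self, top: int = 3) -> pd.DataFrame:
        return (
            self.parent_weights.sort_values(["weight", "parent"],
                                            ascending=[False, True])
            .head(top)
            .reset_index(drop=True)
        )

    def to_edge_tsv(self, path) -> None:
        rows = [
            {"parent": u, "progeny": v, **d}
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def kinship_network(
    selected_ids: np.ndarray,
    pedigree: Pedigree,
    trait: str = "pooled",
) -> KinshipNetwork:
    """Bipartite parents ↔ selected progeny graph with parent node weights.

    Each selected progeny contributes one count to its dam and one to its
    sire, so parent weights always sum to twice the selected count.
    """
    table = pedigree.table.set_index(pedigree.table["id"].astype(str))
    G = nx.Graph()
    weights: dict[tuple[str, str], int] = {}
    for pid in map(str, selected_ids):
        if pid not in table.index:
            raise KeyError(f"selected progeny {pid!r} not in pedigree")
        row = table.loc[pid]
        fam = str(row["family"])
        for parent, role in ((str(row["dam"]), "dam"), (str(row["sire"]), "sire")):
            G.add_node(parent, kind="parent", role=role)
            G.add_node(pid, kind="progeny")
            G.add_edge(parent, pid, family=fam)
            weights[(parent, role)] = weights.get((parent, role), 0) + 1
    pw = pd.DataFrame(
        [{"parent": p, "role": r, "weight": w} for (p, r), w in weights.items()]
    ).sort_values(["weight", "parent"], ascending=[False, True]).reset_index(drop=True)
    for parent, grp in pw.groupby("parent"):
        G.nodes[parent]["weight"] = int(grp["weight"].sum())
    return KinshipNetwork(G, pw, trait)


# ----------------------------------------------------------------------
# validation against field observations
# ----------------------------------------------------------------------

def validate_against_observations(
    predictions: pd.DataFrame,
    observations: pd.DataFrame,
    value_col: str = "observed",
    extreme_rate: float = 0.2,
) -> dict:
    """Pearson r between GEBVs and observed values, plus a top/bottom contrast.

    ``observations`` needs columns ``id`` and ``value_col``.  The contrast
    compares observed means of the top vs bottom ``extreme_rate`` GEBV
    groups with a Welch t-test.
    """
    merged = predictions[["id", "gebv"]].merge(observations, on="id", validate="1:1")
    if len(merged) < 3:
        raise ValueError("need at least 3 matched individuals")
    x = merged["gebv"].to_numpy(dtype=float)
    o = merged[value_col].to_numpy(dtype=float)
    if np.allclose(x, o):
        r, p = 1.0, 0.0
    else:
        r, p = stats.pearsonr(x, o)
    k = max(2, math.ceil(extreme_rate * len(merged)))
    order = np.argsort(x)
    bottom, top = o[order[:k]], o[order[-k:]]
    welch = stats.ttest_ind(top, bottom, equal_var=False)
    return {
        "n": len(merged),
        "pearson_r": float(r),
        "pearson_p": float(p),
        "top_mean": float(top.mean()),
        "bottom_mean": float(bottom.mean()),
        "top_bottom_ratio": float(top.mean() / bottom.mean()) if bottom.mean() != 0 else np.inf,
        "welch_p": float(welch.pvalue),
    }


def network_summary_json(networks: list[KinshipNetwork], path) -> None:
    payload = {
        net.trait: {
            "core_parents": net.core_parents().to_dict(orient="records"),
            "n_selected": sum(
                1 for _, d in net.graph.nodes(data=True) if d.get("kind") == "progeny"
            ),
        }
        for net in networks
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
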