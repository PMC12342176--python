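"""Population structure: genomic relationships, PCA, NJ trees and LD.

The genomic relationship matrix (GRM) follows VanRaden's first method,
``G = WW'/c`` with ``W`` the column-centered dosage matrix and
``c = 2Σ p_j(1−p_j)`` — the additive kinship kernel GBLUP runs on, and the
scaling under which GBLUP and RR-BLUP give identical breeding values.

LD is summarized as the squared Pearson correlation of dosage vectors
(unphased composite LD, the convention of PLINK's ``--indep-pairwise``),
binned by physical distance to give a decay curve; the decay distance is
where the curve falls to half its maximum bin mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from popgs.genotypes import GenotypeMatrix

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# GRM
# ----------------------------------------------------------------------

@dataclass
class GRM:
    """VanRaden method-1 genomic relationship matrix."""

    matrix: np.ndarray
    sample_ids: np.ndarray
    scale_c: float
    method: str = "VanRaden-1"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def eigendecompose(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (descending) and eigenvectors of G."""
        vals, vecs = np.linalg.eigh(self.matrix)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    def with_jitter(self, rel_tol: float = 1e-8, eps: float = 1e-6) -> "GRM":
        """Add ``eps·I`` if the smallest eigenvalue is below tolerance.

        Keeps downstream solvers on a positive-definite kernel; logged.
        """
        vals = np.linalg.eigvalsh(self.matrix)
        if vals.min() < rel_tol * np.trace(self.matrix) / self.n:
            log.info("GRM jitter applied: min eigenvalue %.3e", vals.min())
            return GRM(self.matrix + eps * np.eye(self.n), self.sample_ids,
                       self.scale_c, self.method)
        return self

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        return self.matrix[np.ix_(idx, idx)]


def compute_grm(g: GenotypeMatrix) -> GRM:
    """``G = WW'/c`` with mean-imputed, column-centered dosages."""
    p = g.allele_freq()
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic markers for a GRM")
    c = float(2.0 * np.sum(p[poly] * (1.0 - p[poly])))
    W = g.centered()[:, poly]
    G = W @ W.T / c
    return GRM(G, g.sample_ids, c)


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    coordinates: np.ndarray  # n × k, eigenvectors scaled by sqrt(eigenvalue)
    variance_explained_pct: np.ndarray
    sample_ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(self.coordinates, columns=[f"PC{i+1}" for i in range(k)])
        df.insert(0, "id", self.sample_ids)
        return df


def pca(g_or_grm: GenotypeMatrix | GRM, n_components: int = 10) -> PCAResult:
    """Principal components from the eigendecomposition of the GRM."""
    grm = g_or_grm if isinstance(g_or_grm, GRM) else compute_grm(g_or_grm)
    vals, vecs = grm.eigendecompose()
    k = min(n_components, grm.n)
    vals_k = np.clip(vals[:k], 0.0, None)
    coords = vecs[:, :k] * np.sqrt(vals_k)
    total = np.clip(vals, 0.0, None).sum()
    var_pct = 100.0 * vals_k / total if total > 0 else np.full(k, np.nan)
    return PCAResult(vals_k, coords, var_pct, grm.sample_ids)


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------

def allele_sharing_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """``1 − allele-sharing proportion`` between all sample pairs.

    Allele sharing between dosages a and b at one marker is
    ``(2 − |a−b|)/2``; the distance averages over markers.
    """
    D = g.dosage_float(impute_mean=True)
    n = g.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(D[i] - D[i + 1:])
        dist[i, i + 1:] = dist[i + 1:, i] = diff.mean(axis=1) / 2.0
    return DistanceMatrix(dist, ids=[str(s) for s in g.sample_ids])


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Canonical non-trivial bipartitions of an unrooted tree."""
    tips = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            other = tips - side
            parts.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return parts


def nj_tree(
    source: GenotypeMatrix | DistanceMatrix,
    bootstrap: int = 0,
    seed: int = 0,
) -> TreeNode:
    """Saitou–Nei neighbor-joining tree, optionally with bootstrap support.

    For genotype input the distance is 1 − allele sharing; bootstrap
    replicates resample markers with replacement and internal nodes of the
    returned tree carry percent support in their ``name``.
    """
    if isinstance(source, DistanceMatrix):
        if bootstrap:
            raise ValueError("bootstrap requires genotype input (marker resampling)")
        dm = source
    else:
        dm = allele_sharing_distance(source)
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = nj(dm)
    if bootstrap and isinstance(source, GenotypeMatrix):
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {}
        D = source.dosage_float(impute_mean=True)
        ids = [str(s) for s in source.sample_ids]
        for _ in range(bootstrap):
            cols = rng.integers(0, source.n_markers, size=source.n_markers)
            Drep = D[:, cols]
            n = len(ids)
            dist = np.zeros((n, n))
            for i in range(n):
                diff = np.abs(Drep[i] - Drep[i + 1:])
                dist[i, i + 1:] = dist[i + 1:, i] = diff.mean(axis=1) / 2.0
            rep_tree = nj(DistanceMatrix(dist, ids=ids))
            for part in _bipartitions(rep_tree):
                counts[part] = counts.get(part, 0) + 1
        tips = frozenset(t.name for t in tree.tips())
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(tips) - 1:
                key = min(side, tips - side, key=lambda s: tuple(sorted(s)))
                node.name = f"{100.0 * counts.get(key, 0) / bootstrap:.0f}"
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ----------------------------------------------------------------------
# LD
# ----------------------------------------------------------------------

@dataclass
class LDResult:
    """Pairwise r² records with a binned decay curve."""

    pairs: pd.DataFrame  # chrom, pos_i, pos_j, distance, r2
    curve: pd.DataFrame  # bin_mid, mean_r2, n_pairs
    decay_distance: float
    bin_width: float = 1000.0

    def curve_to_tsv(self, path) -> None:
        self.curve.to_csv(path, sep="\t", index=False)


def _standardize(D: np.ndarray) -> np.ndarray:
    Z = D - D.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = np.nan
    return Z / sd


def ld_r2(g: GenotypeMatrix, max_dist: int = 100_000, bin_width: int = 1000) -> LDResult:
    """All intra-chromosome dosage-r² pairs within ``max_dist`` bp.

    The decay distance is the smallest bin midpoint at which the binned
    mean r² has fallen to half the maximum bin mean (half-maximum rule; an
    absolute-threshold alternative is ``decay_below``).
    """
    records = []
    D = g.dosage_float(impute_mean=True)
    for chrom in g.markers["chrom"].unique():
        cols = np.where((g.markers["chrom"] == chrom).to_numpy())[0]
        pos = g.markers["pos"].to_numpy()[cols]
        Z = _standardize(D[:, cols])
        n = Z.shape[0]
        for a in range(len(cols)):
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            if hi <= a + 1:
                continue
            with np.errstate(invalid="ignore"):
                r = Z[:, a] @ Z[:, a + 1: hi] / n
            dist = pos[a + 1: hi] - pos[a]
            r2 = r ** 2
            ok = ~np.isnan(r2)
            for d, v, pj in zip(dist[ok], r2[ok], pos[a + 1: hi][ok]):
                records.append((chrom, pos[a], pj, int(d), float(v)))
    pairs = pd.DataFrame(records, columns=["chrom", "pos_i", "pos_j", "distance", "r2"])
    if pairs.empty:
        raise ValueError("no marker pairs within max_dist")
    edges = np.arange(0, max_dist + bin_width, bin_width)
    mids = edges[:-1] + bin_width / 2.0
    which = np.clip(np.digitize(pairs["distance"], edges) - 1, 0, len(mids) - 1)
    grouped = pairs.groupby(which)["r2"]
    curve = pd.DataFrame(
        {
            "bin_mid": mids[grouped.mean().index],
            "mean_r2": grouped.mean().to_numpy(),
            "n_pairs": grouped.size().to_numpy(),
        }
    )
    half = curve["mean_r2"].max() / 2.0
    below = curve.loc[curve["mean_r2"] <= half, "bin_mid"]
    decay = float(below.min()) if not below.empty else float("inf")
    return LDResult(pairs, curve, decay, bin_width)


def decay_below(ld: LDResult, threshold: float = 0.1) -> float:
    """Alternative decay definition: first bin with mean r² below ``threshold``."""
    below = ld.curve.loc[ld.curve["mean_r2"] < threshold, "bin_mid"]
    return float(below.min()) if not below.empty else float("inf")


# ----------------------------------------------------------------------
# LD pruning
# ----------------------------------------------------------------------

def ld_prune(
    g: GenotypeMatrix,
    window: int = 50,
    step: int = 50,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy sliding-window LD pruning (``--indep-pairwise`` analogue).

    Within each window of ``window`` surviving SNPs, every pair with
    r² > ``r2_max`` loses its lower-MAF member (ties: the later marker is
    removed); windows slide by ``step`` and passes repeat until no within-
    window pair exceeds the ceiling.  Returns the surviving marker indices.
    """
    maf = g.maf()
    D = g.dosage_float(impute_mean=True)
    chrom = g.markers["chrom"].to_numpy()
    keep = np.ones(g.n_markers, dtype=bool)

    changed = True
    while changed:
        changed = False
        for c in pd.unique(chrom):
            idx = np.where(keep & (chrom == c))[0]
            for start in range(0, len(idx), step):
                widx = idx[start: start + window]
                if len(widx) < 2:
                    continue
                alive = list(widx)
                Z = _standardize(D[:, alive])
                with np.errstate(invalid="ignore"):
                    R2 = np.nan_to_num((Z.T @ Z / Z.shape[0]) ** 2)
                np.fill_diagonal(R2, 0.0)
                active = np.ones(len(alive), dtype=bool)
                while True:
                    sub = np.where(active)[0]
                    viol = None
                    for ai in range(len(sub)):
                        for bi in range(ai + 1, len(sub)):
                            if R2[sub[ai], sub[bi]] > r2_max:
                                viol = (sub[ai], sub[bi])
                                break
                        if viol:
                            break
                    if viol is None:
                        break
                    a, b = viol
                    drop = b if maf[alive[a]] >= maf[alive[b]] else a
                    active[drop] = False
                    keep[alive[drop]] = False
                    changed = True
    return np.where(keep)[0]


def write_marker_list(g: GenotypeMatrix, indices: np.ndarray, path) -> None:
    """One marker id per line (``.prune.in`` analogue)."""
    ids = g.marker_ids()[indices]
    with open(path, "w") as fh:
        fh.write("\n".join(ids) + "\n")
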