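"""Synthetic breeding-population generator.

Three stages, each independently seeded from one root seed:

1. **Founders** — phased haplotypes drawn from a first-order Markov chain
   along each chromosome.  Adjacent markers have haplotype allele
   correlation ``ld_rho``, so LD decays geometrically with marker distance:
   ``r²(d) ≈ ld_rho ** (2 d / spacing)`` and the half-decay distance has the
   closed form ``-log(2) · spacing / log(ld_rho²)``.  This gives tunable,
   analytically checkable LD without a coalescent simulator.
2. **Gene dropping** — gametes are recombinant copies of parental
   haplotypes with crossover counts Poisson-distributed at the chromosome's
   genetic length (Haldane map, no interference), transmitted down the
   full-sib pedigree.
3. **Traits** — a sparse additive architecture: ``n_qtn`` markers receive
   effects, the genetic values are scaled so that the phenotypic variance
   and heritability match the requested preset, and Gaussian noise is added.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from popgs.config import ConfigError, SimulationConfig, TraitPreset
from popgs.genotypes import GenotypeMatrix
from popgs.pedigree import UNKNOWN, Pedigree


# ----------------------------------------------------------------------
# founders
# ----------------------------------------------------------------------

def _marker_table(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced marker positions per chromosome (strictly increasing)."""
    rows = []
    for c, (length, m) in enumerate(config.chromosomes):
        if m > length:
            raise ConfigError("more markers than base pairs on a chromosome")
        spacing = length / m
        pos = np.round((np.arange(m) + 0.5) * spacing).astype(int)
        pos = np.maximum(pos, 1)
        if np.any(np.diff(pos) <= 0):
            raise ConfigError("marker positions are not strictly increasing")
        chrom = f"Chr{c + 1:02d}"
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    table = pd.concat(rows, ignore_index=True)
    table["ref"] = "A"
    table["alt"] = "G"
    return table


def _markov_haplotypes(rng, n_hap: int, p: np.ndarray, rho: float) -> np.ndarray:
    """Copy-or-refresh binary Markov chains with lag-1 correlation ``rho``.

    Each haplotype allele copies its left neighbour with probability ``rho``
    and is otherwise redrawn as Bernoulli(p_j), so the allele correlation
    between markers k steps apart is ``rho**k`` exactly (geometric decay —
    the property the LD half-decay closed form rests on).  The marginal
    frequency at marker j is the geometrically smoothed sequence
    ``(1−rho)·Σ rho^i p_{j−i}``: at rho=0 exactly the per-marker draw, at
    high rho a locally smoothed version of it — mimicking the empirical
    fact that tightly linked markers have similar allele frequencies.
    """
    m = len(p)
    H = np.empty((n_hap, m), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < p[0]
    for j in range(1, m):
        copy = rng.random(n_hap) < rho
        fresh = rng.random(n_hap) < p[j]
        H[:, j] = np.where(copy, H[:, j - 1], fresh)
    return H


def simulate_founders(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw phased founder haplotypes with Markov-chain LD.

    Returns a :class:`GenotypeMatrix` whose ``haplotypes`` attribute holds
    the phased 0/1 array (two rows per founder).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    markers = _marker_table(config)
    n_hap = 2 * config.n_founders
    lo, hi = config.maf_range
    hap_blocks = []
    for (length, m), rho in zip(config.chromosomes, config.ld_rho):
        p = rng.uniform(lo, hi, size=m)
        hap_blocks.append(_markov_haplotypes(rng, n_hap, p, rho))
    H = np.concatenate(hap_blocks, axis=1)
    dosages = H[0::2] + H[1::2]
    ids = np.array([f"F{i + 1:03d}" for i in range(config.n_founders)], dtype=object)
    return GenotypeMatrix(dosages, ids, markers, haplotypes=H)


# ----------------------------------------------------------------------
# pedigree construction and gene dropping
# ----------------------------------------------------------------------

def build_pedigree(config: SimulationConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Random multi-generation full-sib mating design.

    Generation-1 crosses draw distinct parent pairs from the founders;
    later generations may also recruit earlier progeny as parents, as in a
    recurrent-selection program.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = [
        {"id": f"F{i + 1:03d}", "dam": UNKNOWN, "sire": UNKNOWN, "generation": 0, "family": "founder"}
        for i in range(config.n_founders)
    ]
    available: dict[int, list[str]] = {0: [r["id"] for r in rows]}
    fam_gens = config.family_generations()
    counter = 0
    for fam_idx, gen in enumerate(fam_gens):
        pool = [i for g, members in available.items() if g < gen for i in members]
        dam, sire = rng.choice(pool, size=2, replace=False)
        fam = f"FAM{fam_idx + 1:02d}"
        for _ in range(config.progeny_per_family[fam_idx]):
            counter += 1
            pid = f"P{counter:04d}"
            rows.append({"id": pid, "dam": dam, "sire": sire, "generation": gen, "family": fam})
            available.setdefault(gen, []).append(pid)
    return Pedigree(pd.DataFrame(rows))


def _meiosis(rng, hap_pair: np.ndarray, pos: np.ndarray, morgans: float) -> np.ndarray:
    """One recombinant gamete from a pair of parental haplotypes.

    Crossover count ~ Poisson(map length in Morgans); crossover points
    uniform in physical coordinates (uniform cM/Mb within a chromosome).
    """
    n_cross = rng.poisson(morgans)
    phase = rng.integers(0, 2)
    if n_cross == 0:
        return hap_pair[phase].copy()
    cuts = np.sort(rng.uniform(pos[0], pos[-1], size=n_cross))
    segment = phase + np.searchsorted(cuts, pos, side="right")
    return np.where(segment % 2 == 0, hap_pair[0], hap_pair[1])


def gene_drop(
    pedigree: Pedigree,
    founders: GenotypeMatrix,
    recomb_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    chromosome_lengths: dict[str, int] | None = None,
) -> GenotypeMatrix:
    """Transmit founder haplotypes down the pedigree with recombination.

    Parameters
    ----------
    recomb_rate
        cM/Mb; the genetic length of a chromosome is
        ``recomb_rate × length_bp / 1e6 / 100`` Morgans.
    chromosome_lengths
        Physical length per chromosome in bp; defaults to the last marker
        position (slightly shortens the map, negligible at the default
        marker densities).

    Returns a :class:`GenotypeMatrix` covering every pedigree member, with
    phased haplotypes retained.
    """
    if founders.haplotypes is None:
        raise ValueError("founder GenotypeMatrix must carry phased haplotypes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    markers = founders.markers
    chrom_order = markers["chrom"].unique()
    blocks = {
        chrom: np.where((markers["chrom"] == chrom).to_numpy())[0] for chrom in chrom_order
    }
    founder_index = {s: i for i, s in enumerate(founders.sample_ids)}
    missing = set(pedigree.founders) - set(founder_index)
    if missing:
        raise ValueError(f"pedigree founders without genotypes: {sorted(missing)[:5]}")

    m = founders.n_markers
    all_ids = pedigree.ids
    hap = np.zeros((2 * len(all_ids), m), dtype=np.int8)
    index = {s: i for i, s in enumerate(all_ids)}

    # founders: copy haplotypes through unchanged
    for fid in pedigree.founders:
        i = index[fid]
        hap[2 * i: 2 * i + 2] = founders.haplotypes[2 * founder_index[fid]: 2 * founder_index[fid] + 2]

    # progeny, in generation order (guaranteed acyclic by Pedigree)
    nonfounders = pedigree.nonfounders.sort_values("generation", kind="stable")
    for _, row in nonfounders.iterrows():
        i = index[str(row["id"])]
        for parent_col, h_slot in (("dam", 0), ("sire", 1)):
            parent = str(row[parent_col])
            if parent not in index:
                raise ValueError(f"parent {parent!r} missing from pedigree")
            pi = index[parent]
            for chrom in chrom_order:
                cols = blocks[chrom]
                pos = markers["pos"].to_numpy()[cols]
                length = (
                    chromosome_lengths[chrom]
                    if chromosome_lengths is not None
                    else pos[-1]
                )
                morgans = recomb_rate * length / 1e6 / 100.0
                hap[2 * i + h_slot, cols] = _meiosis(
                    rng, hap[2 * pi: 2 * pi + 2][:, cols], pos, morgans
                )

    dosages = hap[0::2] + hap[1::2]
    return GenotypeMatrix(dosages, np.asarray(all_ids, dtype=object), markers, haplotypes=hap)


# ----------------------------------------------------------------------
# traits
# ----------------------------------------------------------------------

@dataclass
class TruthSet:
    """Ground truth of a simulated multi-trait architecture."""

    qtn_indices: dict[str, np.ndarray]  # trait -> marker column indices
    qtn_effects: dict[str, np.ndarray]  # trait -> additive effect per ALT copy
    true_breeding_values: pd.DataFrame  # id + one column per trait
    realized_h2: dict[str, float]
    pve_pct: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "qtn_indices": {t: v.tolist() for t, v in self.qtn_indices.items()},
            "qtn_effects": {t: v.tolist() for t, v in self.qtn_effects.items()},
            "realized_h2": self.realized_h2,
            "pve_pct": {t: v.tolist() for t, v in self.pve_pct.items()},
            "true_breeding_values": self.true_breeding_values.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def tbv(self, trait: str) -> np.ndarray:
        return self.true_breeding_values[trait].to_numpy()


def qtn_pve(p: np.ndarray, beta: np.ndarray, var_y: float) -> np.ndarray:
    """Per-QTN percentage of phenotypic variance explained: 100·2p(1−p)β²/Var(y)."""
    return 100.0 * 2.0 * p * (1.0 - p) * beta ** 2 / var_y


def simulate_traits(
    genotypes: GenotypeMatrix,
    presets: list[TraitPreset],
    n_qtn: int = 20,
    effect_dist: str = "gaussian",
    seed: int | np.random.Generator = 0,
    min_qtn_maf: float = 0.05,
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate phenotypes with a sparse additive QTN architecture.

    For each trait, ``n_qtn`` markers (MAF ≥ ``min_qtn_maf``) receive raw
    effects from the chosen distribution; effects are rescaled so that
    Var(TBV) = h²·sd² and Gaussian noise with variance (1−h²)·sd² is added,
    so the sample phenotypic variance is close to the preset ``sd²`` and the
    realized heritability close to the preset ``h2``.
    """
    if n_qtn > genotypes.n_markers:
        raise ConfigError("n_qtn exceeds the number of markers")
    if effect_dist not in ("gaussian", "gamma"):
        raise ConfigError("effect_dist must be 'gaussian' or 'gamma'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    maf = genotypes.maf()
    eligible = np.where(maf >= min_qtn_maf)[0]
    if len(eligible) < n_qtn:
        eligible = np.argsort(maf)[::-1][:n_qtn]
    p = genotypes.allele_freq()
    W = genotypes.centered()

    pheno = pd.DataFrame({"id": genotypes.sample_ids})
    tbv_table = pd.DataFrame({"id": genotypes.sample_ids})
    qtn_idx: dict[str, np.ndarray] = {}
    qtn_eff: dict[str, np.ndarray] = {}
    realized: dict[str, float] = {}
    pves: dict[str, np.ndarray] = {}

    for preset in presets:
        idx = np.sort(rng.choice(eligible, size=n_qtn, replace=False))
        if effect_dist == "gaussian":
            beta_raw = rng.normal(0.0, 1.0, size=n_qtn)
        else:  # L-shaped gamma magnitudes with random sign
            beta_raw = rng.gamma(0.4, 1.0, size=n_qtn) * rng.choice([-1.0, 1.0], size=n_qtn)
        g_raw = W[:, idx] @ beta_raw
        var_g = g_raw.var()
        if var_g <= 0:
            raise ConfigError("degenerate QTN draw: no genetic variance")
        scale = np.sqrt(preset.h2 * preset.sd ** 2 / var_g)
        tbv = scale * g_raw
        noise = rng.normal(0.0, np.sqrt((1.0 - preset.h2) * preset.sd ** 2), size=len(tbv))
        y = preset.mean + tbv + noise
        beta = scale * beta_raw

        pheno[preset.name] = y
        tbv_table[preset.name] = tbv
        qtn_idx[preset.name] = idx
        qtn_eff[preset.name] = beta
        realized[preset.name] = float(tbv.var() / y.var())
        pves[preset.name] = qtn_pve(p[idx], beta, y.var(ddof=1))

    truth = TruthSet(qtn_idx, qtn_eff, tbv_table, realized, pves)
    return pheno, truth


# ----------------------------------------------------------------------
# one-call population
# ----------------------------------------------------------------------

@dataclass
class SimulatedPopulation:
    config: SimulationConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # all pedigree members
    phenotypes: pd.DataFrame  # progeny only
    truth: TruthSet

    @property
    def progeny(self) -> GenotypeMatrix:
        ids = self.phenotypes["id"].to_numpy()
        return self.genotypes.take_samples(self.genotypes.sample_index(ids))


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Founders → pedigree → gene drop → traits, all from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    founders = simulate_founders(config, rng=rngs[0])
    pedigree = build_pedigree(config, rng=rngs[1])
    genotypes = gene_drop(
        pedigree,
        founders,
        recomb_rate=config.recomb_rate,
        seed=rngs[2],
        chromosome_lengths={
            f"Chr{c + 1:02d}": length for c, (length, _) in enumerate(config.chromosomes)
        },
    )
    progeny_ids = pedigree.nonfounders["id"].astype(str).to_numpy()
    progeny = genotypes.take_samples(genotypes.sample_index(progeny_ids))
    phenotypes, truth = simulate_traits(
        progeny,
        config.trait_presets,
        n_qtn=config.n_qtn_per_trait,
        effect_dist=config.qtn_effect_dist,
        seed=rngs[3],
    )
    return SimulatedPopulation(config, pedigree, genotypes, phenotypes, truth)
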