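"""Simulation configuration: trait presets and population design.

The default trait presets reproduce the phenotypic summary of the poplar
reference population the package emulates: six growth and wood-quality
traits (tree height H, diameter at breast height DBH, basic density BD,
microfibril angle MA, fiber length FL, fiber width FW) with their observed
means, standard deviations and narrow-sense heritabilities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TraitPreset:
    """Target moments for one simulated trait.

    ``mean`` and ``sd`` are in trait units; ``h2`` is the narrow-sense
    heritability, the fraction of phenotypic variance that is additive
    genetic.
    """

    name: str
    mean: float
    sd: float
    h2: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigError(f"trait {self.name!r}: sd must be > 0, got {self.sd}")
        if not 0.0 < self.h2 < 1.0:
            raise ConfigError(f"trait {self.name!r}: h2 must lie in (0,1), got {self.h2}")

    @property
    def cv_pct(self) -> float:
        """Coefficient of variation, 100·sd/mean."""
        return 100.0 * self.sd / self.mean


#: Default presets: the six traits of the reference poplar population.
#: Units: H in m, DBH in cm, BD in g/cm^3, MA in degrees, FL and FW in um.
TABLE_PRESETS: tuple[TraitPreset, ...] = (
    TraitPreset("H", mean=14.37, sd=1.38, h2=0.42),
    TraitPreset("DBH", mean=22.24, sd=4.21, h2=0.87),
    TraitPreset("BD", mean=0.41, sd=0.03, h2=0.80),
    TraitPreset("MA", mean=14.21, sd=0.91, h2=0.13),
    TraitPreset("FL", mean=1147.45, sd=78.07, h2=0.14),
    TraitPreset("FW", mean=24.60, sd=2.28, h2=0.24),
)


def get_preset(name: str) -> TraitPreset:
    for p in TABLE_PRESETS:
        if p.name == name:
            return p
    raise KeyError(f"no default preset for trait {name!r}")


def rho_for_decay(spacing_bp: float, target_decay_bp: float) -> float:
    """Adjacent-marker haplotype correlation giving a target LD half-decay.

    Under the first-order Markov founder model, r² between markers ``d`` bp
    apart is ``rho**(2 d / spacing)``; the half-decay distance is
    ``-log(2) * spacing / log(rho²)``.  Inverting for ``rho``:
    """
    if target_decay_bp <= 0 or spacing_bp <= 0:
        raise ConfigError("spacing and target decay must be positive")
    return math.exp(-math.log(2.0) * spacing_bp / (2.0 * target_decay_bp))


@dataclass
class SimulationConfig:
    """Design of a synthetic multi-generation full-sib breeding population.

    Parameters
    ----------
    n_founders
        Number of founder individuals (the elite-parent pool).
    n_families
        Number of full-sib crosses; default 32, the design of the breeding
        program the package emulates.
    progeny_per_family
        Progeny count per cross, either one integer applied to every family
        or a per-family list.  The default 24 yields 768 progeny from 32
        crosses, matching the 765-progeny program at desk scale (exact
        per-family sizes were never published; see the methods note).
    n_generations
        Number of progeny generations.  Families are spread as evenly as
        possible over generations; crosses in generation g>1 may draw
        parents from earlier progeny, creating a multi-generation pedigree.
    chromosomes
        List of ``(length_bp, n_markers)`` tuples, one per chromosome.
    ld_rho
        Adjacent-marker haplotype allele correlation in [0,1) of the founder
        Markov chain; scalar or one value per chromosome.
    recomb_rate
        Recombination rate in cM/Mb (Haldane map, no interference).
    """

    n_founders: int = 40
    n_families: int = 32
    progeny_per_family: int | list[int] = 24
    n_generations: int = 2
    chromosomes: list[tuple[int, int]] = field(default_factory=lambda: [(20_000_000, 1000)])
    ld_rho: float | list[float] = 0.9
    recomb_rate: float = 1.0
    n_qtn_per_trait: int = 20
    qtn_effect_dist: str = "gaussian"
    trait_presets: list[TraitPreset] = field(default_factory=lambda: list(TABLE_PRESETS))
    maf_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_families", "n_generations"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if isinstance(self.progeny_per_family, int):
            self.progeny_per_family = [self.progeny_per_family] * self.n_families
        if len(self.progeny_per_family) != self.n_families:
            raise ConfigError("progeny_per_family length must equal n_families")
        if any(c < 1 for c in self.progeny_per_family):
            raise ConfigError("progeny counts must be positive")
        if isinstance(self.ld_rho, (int, float)):
            self.ld_rho = [float(self.ld_rho)] * len(self.chromosomes)
        if len(self.ld_rho) != len(self.chromosomes):
            raise ConfigError("ld_rho must be scalar or one value per chromosome")
        if any(not 0.0 <= r < 1.0 for r in self.ld_rho):
            raise ConfigError("ld_rho values must lie in [0, 1)")
        if self.qtn_effect_dist not in ("gaussian", "gamma"):
            raise ConfigError("qtn_effect_dist must be 'gaussian' or 'gamma'")
        for length, m in self.chromosomes:
            if length < 1 or m < 1:
                raise ConfigError("chromosome lengths and marker counts must be positive")
        lo, hi = self.maf_range
        if not 0.0 < lo < hi < 1.0:
            raise ConfigError("maf_range must satisfy 0 < lo < hi < 1")

    @property
    def n_markers(self) -> int:
        return sum(m for _, m in self.chromosomes)

    @property
    def n_progeny(self) -> int:
        return sum(self.progeny_per_family)

    def family_generations(self) -> list[int]:
        """Generation (1-based) of each family, spread evenly in order."""
        if self.n_generations > self.n_families:
            raise ConfigError("more generations than families")
        per_gen = self.n_families // self.n_generations
        extra = self.n_families % self.n_generations
        gens: list[int] = []
        for g in range(1, self.n_generations + 1):
            gens.extend([g] * (per_gen + (1 if g <= extra else 0)))
        return gens

    # ------------------------------------------------------------------
    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "trait_presets" in d:
            d["trait_presets"] = [TraitPreset(**p) for p in d["trait_presets"]]
        if "chromosomes" in d:
            d["chromosomes"] = [tuple(c) for c in d["chromosomes"]]
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


def study_config(seed: int = 0, markers_per_chrom: int = 1000,
                 n_chromosomes: int = 2, chrom_length: int = 20_000_000) -> SimulationConfig:
    """A desk-scale configuration emulating the poplar breeding program.

    32 full-sib families over two generations, 24 progeny each, founder LD
    tuned so the population half-decay distance lands near 16 kb (the
    observed decay of the reference population) given the marker spacing.
    """
    spacing = chrom_length / markers_per_chrom
    rho = rho_for_decay(spacing, 16_000.0)
    return SimulationConfig(
        n_founders=12,
        n_families=32,
        progeny_per_family=24,
        n_generations=2,
        chromosomes=[(chrom_length, markers_per_chrom)] * n_chromosomes,
        ld_rho=rho,
        recomb_rate=1.0,
        n_qtn_per_trait=20,
        seed=seed,
    )
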