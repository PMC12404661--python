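"""Synthetic assay generator.

Emulates the statistical structure of the study design end to end so every
downstream stage (estimation, simulation, classification, testing) can be
exercised without any external data:

* co-culture plate growth sampled at 0/24/72/168 h, where the 72 h
  proportion of species A equals the planted free-living fitness
  ``true_w_P_A`` and totals saturate at the plate carrying capacity;
* worm assays — early colonization, established colonization, short-term
  persistence and release — where the persistence (and release) proportion
  equals the planted within-host fitness ``true_w_W_A`` and colonization
  proportions are a configurable mixture of the plate proportion (uptake
  from the lawn) and the within-host fitness (host filtering);
* mono-culture counterparts in which each species alone reaches the full
  plate capacity (plate competition released) but matches its co-culture
  abundance in the worm (no detectable within-host competition);
* a genome-trait table with planted CSR strategies that the classifier
  recovers exactly.

Noise is multiplicative lognormal on CFU: counts are strictly positive and
span orders of magnitude, and replicate proportions then follow a
logit-normal-like law whose median is the planted value.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .datamodel import (
    Assay,
    CFUObservation,
    CFUTable,
    Culture,
    Habitat,
    TraitTable,
    Unit,
)
from .life_history import STRATEGY_TRAITS, Strategy

__all__ = ["GeneratorConfig", "ConfigError", "generate_co_culture_assays",
           "generate_mono_culture_assays", "generate_trait_table",
           "WORM_ASSAY_TIMES_H"]


class ConfigError(ValueError):
    """Generator configuration is incomplete or inconsistent."""


#: nominal hours of host association used as record keys per worm assay
#: (early colonization is a 1.5 h exposure; persistence and release are
#: measured 1 h after collection from an established culture)
WORM_ASSAY_TIMES_H = {
    Assay.early_colonization: 1.5,
    Assay.established_colonization: 48.0,
    Assay.persistence: 49.0,
    Assay.release: 49.0,
}

#: worm totals before noise, as fractions of K_W per assay
WORM_TOTAL_FRACTIONS = {
    Assay.early_colonization: 0.1,
    Assay.established_colonization: 1.0,
    Assay.persistence: 1.0,
    Assay.release: 0.2,
}


class GeneratorConfig(BaseModel):
    """Planted truth and noise model for the synthetic assays.

    Defaults mirror the focal community: species A is the fast-growing plate
    competitor (``true_w_P_A`` high), species B the within-host persister
    (``true_w_W_A`` below one half); 4–6 replicates per assay; plate growth
    sampled at 0/24/72/168 h.
    """

    species_a: str = "MYb11"
    species_b: str = "MYb71"
    true_w_W_A: float = 0.3
    true_w_P_A: float = 0.9
    K_P: float = Field(default=1e9, gt=0)
    K_W: float = Field(default=1e4, gt=0)
    prop_A_initial: float = Field(default=0.5, ge=0.0, le=1.0)
    inoculum_total_cfu: float = Field(default=1e7, gt=0)
    colonization_mixing: float = Field(default=0.5, ge=0.0, le=1.0)
    mono_means: Optional[Dict[str, float]] = None  # keys "<species>:<habitat>"
    noise_sigma_log: float = Field(default=0.3, ge=0.0)
    n_replicates: int = 6
    timepoints_h: Tuple[float, ...] = (0.0, 24.0, 72.0, 168.0)
    seed: int = 0

    @field_validator("true_w_W_A", "true_w_P_A")
    @classmethod
    def _open_unit_interval(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError(f"planted fitness must lie in (0, 1), got {v}")
        return v

    @field_validator("n_replicates")
    @classmethod
    def _at_least_one(cls, v: int) -> int:
        if v < 1:
            raise ConfigError("n_replicates must be >= 1")
        return v

    @model_validator(mode="after")
    def _sorted_times(self) -> "GeneratorConfig":
        object.__setattr__(self, "timepoints_h", tuple(sorted(self.timepoints_h)))
        return self


def _co_plate_means(cfg: GeneratorConfig) -> Dict[float, Tuple[float, float]]:
    """time -> (total CFU, proportion of A) before noise for co-culture growth."""
    out = {}
    for t in cfg.timepoints_h:
        if t == 0:
            out[t] = (cfg.inoculum_total_cfu, cfg.prop_A_initial)
        elif t < 72:
            # lawn mid-expansion: composition halfway to the 3-day equilibrium
            out[t] = (0.5 * cfg.K_P, 0.5 * (cfg.prop_A_initial + cfg.true_w_P_A))
        else:
            out[t] = (cfg.K_P, cfg.true_w_P_A)
    return out


def _co_worm_means(cfg: GeneratorConfig) -> Dict[Assay, Tuple[float, float]]:
    """assay -> (total CFU/worm, proportion of A) before noise."""
    m = cfg.colonization_mixing
    uptake = cfg.true_w_P_A  # worms feed on the 3-day co-culture lawn
    colonization_prop = m * uptake + (1 - m) * cfg.true_w_W_A
    return {
        Assay.early_colonization: (
            WORM_TOTAL_FRACTIONS[Assay.early_colonization] * cfg.K_W,
            colonization_prop,
        ),
        Assay.established_colonization: (
            WORM_TOTAL_FRACTIONS[Assay.established_colonization] * cfg.K_W,
            colonization_prop,
        ),
        Assay.persistence: (cfg.K_W, cfg.true_w_W_A),
        Assay.release: (
            WORM_TOTAL_FRACTIONS[Assay.release] * cfg.K_W,
            cfg.true_w_W_A,
        ),
    }


def _noisy(mean: float, sigma: float, rng: np.random.Generator) -> float:
    if sigma == 0.0:
        return mean
    return float(mean * np.exp(rng.normal(0.0, sigma)))


def _obs(species, habitat, assay, culture, t, rep, cfu) -> CFUObservation:
    return CFUObservation(
        species_id=species,
        habitat=habitat,
        assay=assay,
        culture=culture,
        time_h=t,
        replicate=rep,
        cfu=cfu,
        unit=Unit.per_plate if habitat is Habitat.plate else Unit.per_worm,
    )


def generate_co_culture_assays(config: GeneratorConfig) -> CFUTable:
    """Co-culture plate growth plus the four worm assays, per replicate.

    Before noise, the persistence proportion of A equals ``true_w_W_A`` and
    the 72 h plate proportion equals ``true_w_P_A``; lognormal noise of
    standard deviation ``noise_sigma_log`` (natural-log scale) is applied
    independently per species count.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    sigma = config.noise_sigma_log
    obs = []
    plate = _co_plate_means(config)
    worm = _co_worm_means(config)
    for rep in range(1, config.n_replicates + 1):
        for t, (total, prop) in plate.items():
            for sp, share in ((config.species_a, prop), (config.species_b, 1 - prop)):
                obs.append(
                    _obs(sp, Habitat.plate, Assay.growth, Culture.co, t, rep,
                         _noisy(total * share, sigma, rng))
                )
        for assay, (total, prop) in worm.items():
            t = WORM_ASSAY_TIMES_H[assay]
            for sp, share in ((config.species_a, prop), (config.species_b, 1 - prop)):
                obs.append(
                    _obs(sp, Habitat.worm, assay, Culture.co, t, rep,
                         _noisy(total * share, sigma, rng))
                )
    return CFUTable(observations=obs, experiment_id="synthetic-co")


def _mono_mean(cfg: GeneratorConfig, species: str, habitat: Habitat) -> float:
    if cfg.mono_means is not None:
        key = f"{species}:{habitat.value}"
        if habitat is Habitat.plate:
            if key not in cfg.mono_means:
                raise ConfigError(f"mono_means missing entry {key!r}")
            return cfg.mono_means[key]
        if key in cfg.mono_means:
            return cfg.mono_means[key]
    if habitat is Habitat.plate:
        # competition released: each species alone fills the plate
        return cfg.K_P
    raise AssertionError("worm mono means derive from co-culture means")


def generate_mono_culture_assays(config: GeneratorConfig) -> CFUTable:
    """Mono-culture growth and colonization records per species.

    Plate mono-culture means exceed the co-culture per-species means (each
    species alone reaches the full plate capacity, emulating release from
    competition); worm mono-culture means equal the co-culture per-species
    means (within-host abundances indistinguishable between mono- and
    co-colonization).
    """
    rng = np.random.default_rng([config.seed, 1])
    sigma = config.noise_sigma_log
    worm_co = _co_worm_means(config)
    obs = []
    for rep in range(1, config.n_replicates + 1):
        for sp in (config.species_a, config.species_b):
            cap = _mono_mean(config, sp, Habitat.plate)
            for t in config.timepoints_h:
                if t == 0:
                    mean = config.inoculum_total_cfu
                elif t < 72:
                    mean = 0.5 * cap
                else:
                    mean = cap
                obs.append(
                    _obs(sp, Habitat.plate, Assay.growth, Culture.mono, t, rep,
                         _noisy(mean, sigma, rng))
                )
            for assay in (Assay.established_colonization, Assay.persistence):
                total, prop = worm_co[assay]
                share = prop if sp == config.species_a else 1 - prop
                obs.append(
                    _obs(sp, Habitat.worm, assay, Culture.mono,
                         WORM_ASSAY_TIMES_H[assay], rep,
                         _noisy(total * share, sigma, rng))
                )
    return CFUTable(observations=obs, experiment_id="synthetic-mono")


# community-typical trait values (background members all sit here) and the
# extreme values planted species take on their strategy-congruent traits
_BACKGROUND = {
    "genome_size_mb": 4.5,
    "n_antibiotic_pathways": 4,
    "n_siderophore_pathways": 3,
    "n_catabolic_pathways": 50,
    "max_growth_rate": 0.25,
    "n_rrna_copies": 5,
    "n_biofilm_genes": 15,
    "n_auxotrophies": 4,
    "codon_usage_bias": 0.6,
}
_HIGH = {
    "genome_size_mb": 8.0,
    "n_antibiotic_pathways": 12,
    "n_siderophore_pathways": 10,
    "n_catabolic_pathways": 110,
    "max_growth_rate": 0.8,
    "n_rrna_copies": 12,
    "n_biofilm_genes": 40,
    "n_auxotrophies": 14,
    "codon_usage_bias": 0.9,
}
_LOW = {
    "genome_size_mb": 2.0,
    "n_antibiotic_pathways": 0,
    "n_siderophore_pathways": 0,
    "n_catabolic_pathways": 5,
    "max_growth_rate": 0.05,
    "n_rrna_copies": 1,
    "n_biofilm_genes": 2,
    "n_auxotrophies": 0,
    "codon_usage_bias": 0.3,
}
_INT_TRAITS = {
    "n_antibiotic_pathways",
    "n_siderophore_pathways",
    "n_catabolic_pathways",
    "n_rrna_copies",
    "n_biofilm_genes",
    "n_auxotrophies",
}


def generate_trait_table(
    n_species: int,
    planted: Optional[Mapping[str, Strategy | str]] = None,
    seed: int = 0,
) -> TraitTable:
    """Community trait table with planted CSR strategies.

    Background members share the community-typical trait vector; each
    planted species takes extreme values (with seeded, pairwise-distinct
    jitter) on its strategy-congruent traits and the typical value
    elsewhere.  Under the strict extreme-quartile scoring rule this makes
    zero-noise recovery of the planted labels structural as long as planted
    species remain a minority per strategy: background species score zero
    on every strategy (intermediate), planted species score the full
    congruent count and nothing else.
    """
    if n_species < 4:
        raise ValueError("need at least 4 species for quartile thresholds")
    planted = {k: Strategy(v) for k, v in (planted or {}).items()}
    if len(planted) > n_species:
        raise ValueError("more planted species than n_species")
    rng = np.random.default_rng([seed, 2])
    names = list(planted)
    i = 1
    while len(names) < n_species:
        candidate = f"sp{i:02d}"
        if candidate not in planted:
            names.append(candidate)
        i += 1
    rows = {}
    # distinct jitter ranks per (trait, direction) keep quantile comparisons strict
    jitter_pool = {key: rng.permutation(len(planted)) for key in
                   [(t, d) for traits in STRATEGY_TRAITS.values() for t, d in traits]}
    planted_idx = {sp: j for j, sp in enumerate(planted)}
    for sp in names:
        row = dict(_BACKGROUND)
        if sp in planted:
            strategy = planted[sp]
            for trait, direction in STRATEGY_TRAITS[strategy]:
                rank = int(jitter_pool[(trait, direction)][planted_idx[sp]])
                if direction == "high":
                    if trait == "codon_usage_bias":
                        # bounded in [0, 1]: jitter toward 1, never past it
                        value = 1.0 - (1.0 - _HIGH[trait]) / (1.0 + 0.05 * rank)
                    else:
                        value = _HIGH[trait] * (1.0 + 0.05 * rank)
                else:
                    value = _LOW[trait] / (1.0 + 0.05 * rank)
                if trait in _INT_TRAITS:
                    value = float(round(value)) + (rank if direction == "high" else 0)
                row[trait] = value
        rows[sp] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "species_id"
    return TraitTable(frame)
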