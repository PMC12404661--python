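"""Estimation of life-cycle model parameters from CFU assay tables.

Relative within-host fitness is estimated from co-culture species proportions
during short-term persistence (bacteria retained in the worm after 1 h in
bacteria-free buffer: the community that would be transferred in a
serial-passage design).  Relative free-living fitness is estimated from
co-culture proportions on agar after 3 days (the length of the plate phase).
Carrying capacities are the experimentally observed maximum population sizes.
Inoculum composition comes from the equal-OD co-inoculation protocol,
optionally converted to a CFU basis through the OD calibration.
"""

from __future__ import annotations

import dataclasses
import logging
from statistics import median
from typing import List, Literal, Optional, Sequence

import numpy as np

from .datamodel import Assay, CFUTable, Culture, Habitat, ODCalibration
from .lifecycle import FitnessParameters

__all__ = [
    "ProportionResult",
    "cfu_to_proportions",
    "proportion_from_selective_plating",
    "estimate_relative_fitness",
    "estimate_carrying_capacity",
    "od_to_cfu",
    "inoculum_proportion",
    "estimate_parameters",
]

logger = logging.getLogger(__name__)

#: plate growth timepoint used for free-living fitness ("agar after 3 days")
DEFAULT_PLATE_FITNESS_TIME_H = 72.0


class EmptySelectionError(ValueError):
    """No observations match the requested assay/time selection."""


@dataclasses.dataclass
class ProportionResult:
    """Per-replicate proportions of species A, plus bookkeeping on replicates
    excluded because both species counts were zero."""

    proportions: List[float]
    replicates: List[int]
    n_excluded: int = 0

    def __iter__(self):
        return iter(self.proportions)


def cfu_to_proportions(
    table: CFUTable,
    assay: Assay | str,
    species_a: str,
    species_b: str,
    time_h: Optional[float] = None,
) -> ProportionResult:
    """Per-replicate proportion of species A in co-culture records.

    ``proportion_A = cfu_A / (cfu_A + cfu_B)`` per replicate; replicates
    whose species total is zero carry no compositional information and are
    excluded (counted in ``n_excluded``).
    """
    sel = table.select(assay=Assay(assay), culture=Culture.co, time_h=time_h)
    by_rep: dict[int, dict[str, float]] = {}
    for obs in sel.observations:
        if obs.species_id in (species_a, species_b):
            by_rep.setdefault(obs.replicate, {})[obs.species_id] = obs.cfu
    pairs = {
        r: d for r, d in by_rep.items() if species_a in d and species_b in d
    }
    if not pairs:
        raise EmptySelectionError(
            f"no co-culture records with both species for assay={Assay(assay).value}, "
            f"time_h={time_h}"
        )
    proportions, replicates, n_excluded = [], [], 0
    for r in sorted(pairs):
        a, b = pairs[r][species_a], pairs[r][species_b]
        total = a + b
        if total == 0:
            n_excluded += 1
            logger.warning(
                "replicate %d excluded from proportions: zero total CFU", r
            )
            continue
        proportions.append(a / total)
        replicates.append(r)
    return ProportionResult(proportions, replicates, n_excluded)


def proportion_from_selective_plating(total_cfu: float, resistant_cfu: float) -> float:
    """Proportion of the sensitive species A from a selective-plating pair.

    The total count comes from permissive plates; the resistant count (the
    kanamycin-resistant species B in the focal community) comes from
    selective plates, so A = total − resistant.
    """
    if total_cfu <= 0:
        raise ValueError("total CFU must be > 0")
    if resistant_cfu < 0 or resistant_cfu > total_cfu:
        raise ValueError("resistant CFU must lie in [0, total]")
    return (total_cfu - resistant_cfu) / total_cfu


def estimate_relative_fitness(
    proportions: Sequence[float], summary: Literal["median", "mean"] = "median"
) -> float:
    """Summarize per-replicate proportions into a relative-fitness estimate.

    The median (default) is robust to the multiplicative (lognormal) noise of
    CFU counts, under which the replicate median — not the mean — targets the
    underlying proportion.
    """
    props = list(proportions)
    if not props:
        raise ValueError("no proportions supplied")
    if any(p < 0 or p > 1 for p in props):
        raise ValueError("proportions must lie in [0, 1]")
    if summary == "median":
        return float(median(props))
    if summary == "mean":
        return float(np.mean(props))
    raise ValueError(f"unknown summary {summary!r}")


def estimate_carrying_capacity(
    table: CFUTable,
    habitat: Habitat | str,
    co_only: bool = True,
    plate_time_h: Optional[float] = None,
) -> float:
    """Observed maximum population size in a habitat.

    Plate: species-summed totals per replicate at the final growth timepoint
    (or ``plate_time_h`` when given); worm: totals over established
    colonization and persistence.  Returns the maximum across replicates.
    Co-culture records only by default (``co_only``), mirroring the
    community experiments the model is parameterized from.
    """
    habitat = Habitat(habitat)
    sel = table.select(habitat=habitat)
    if co_only:
        sel = sel.select(culture=Culture.co)
    if habitat is Habitat.plate:
        sel = sel.select(assay=Assay.growth)
        times = sorted({o.time_h for o in sel.observations})
        if not times:
            raise EmptySelectionError("no plate growth records")
        t = plate_time_h if plate_time_h is not None else times[-1]
        sel = sel.select(time_h=t)
        obs = sel.observations
    else:
        obs = [
            o
            for o in sel.observations
            if o.assay in (Assay.established_colonization, Assay.persistence)
        ]
    if not obs:
        raise EmptySelectionError(f"no records for habitat={habitat.value}")
    totals: dict[tuple, float] = {}
    for o in obs:
        totals.setdefault((o.assay, o.time_h, o.replicate), 0.0)
        totals[(o.assay, o.time_h, o.replicate)] += o.cfu
    return max(totals.values())


def od_to_cfu(od: float, species_id: str, calibration: ODCalibration) -> float:
    """Convert optical density to CFU assuming linearity of the calibration."""
    if od < 0:
        raise ValueError("OD must be >= 0")
    if species_id not in calibration.cfu_per_od:
        raise KeyError(f"no OD calibration for species {species_id!r}")
    return od * calibration.cfu_per_od[species_id]


def inoculum_proportion(
    od_a: float,
    od_b: float,
    calibration: Optional[ODCalibration] = None,
    species_a: str = "MYb11",
    species_b: str = "MYb71",
    basis: Literal["od", "cfu"] = "od",
) -> float:
    """Proportion of species A in a co-inoculum mixed by optical density.

    ``basis="od"`` returns the OD share (0.5 under the equal-OD protocol);
    ``basis="cfu"`` converts both ODs through the calibration first, which
    for the published constants turns a 1:1 OD mix into ≈0.70 species A.
    """
    if od_a < 0 or od_b < 0:
        raise ValueError("ODs must be >= 0")
    if od_a + od_b == 0:
        raise ValueError("at least one OD must be positive")
    if basis == "od":
        return od_a / (od_a + od_b)
    if basis == "cfu":
        if calibration is None:
            calibration = ODCalibration()
        cfu_a = od_to_cfu(od_a, species_a, calibration)
        cfu_b = od_to_cfu(od_b, species_b, calibration)
        return cfu_a / (cfu_a + cfu_b)
    raise ValueError(f"unknown basis {basis!r}")


def estimate_parameters(
    table: CFUTable,
    species_a: str,
    species_b: str,
    summary: Literal["median", "mean"] = "median",
    plate_fitness_time_h: float = DEFAULT_PLATE_FITNESS_TIME_H,
    prop_A_initial: float = 0.5,
) -> FitnessParameters:
    """Full model parameterization from one co-culture CFU table.

    w_W_A from persistence proportions, w_P_A from plate proportions at
    ``plate_fitness_time_h``, carrying capacities from observed maxima.
    """
    w_w = estimate_relative_fitness(
        cfu_to_proportions(table, Assay.persistence, species_a, species_b),
        summary=summary,
    )
    w_p = estimate_relative_fitness(
        cfu_to_proportions(
            table, Assay.growth, species_a, species_b, time_h=plate_fitness_time_h
        ),
        summary=summary,
    )
    k_w = estimate_carrying_capacity(table, Habitat.worm)
    k_p = estimate_carrying_capacity(table, Habitat.plate)
    return FitnessParameters(
        w_W_A=w_w, w_P_A=w_p, K_W=k_w, K_P=k_p, prop_A_initial=prop_A_initial
    )
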