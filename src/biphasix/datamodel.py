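"""Shared domain types for CFU assay tables and genome-trait tables.

The package models a two-member bacterial community that alternates between a
host-associated phase (the *Caenorhabditis elegans* gut, "worm") and a
free-living phase (growth on nematode growth medium agar, "plate").  Every
measurement in the experimental design is a colony-forming-unit (CFU) count
keyed by species, habitat, assay, culture mode, time and replicate; those
records are the universal currency that the estimation, simulation and
statistics layers consume.

Species labels are free strings.  The two ecological roles — "A", the
fast-growing plate competitor (MYb11-like), and "B", the slow-growing
host persister (MYb71-like) — are bound in configuration, never hard-coded.
"""

from __future__ import annotations

import enum
import math
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "Habitat",
    "Assay",
    "Culture",
    "Unit",
    "CFUObservation",
    "CFUTable",
    "ODCalibration",
    "TraitTable",
    "TRAIT_COLUMNS",
    "TableValidationError",
    "TableSchemaError",
]


class TableSchemaError(ValueError):
    """A table file is missing a required column or has an unusable header."""


class TableValidationError(Exception):
    """A table row violates a domain invariant (negative CFU, duplicate key...).

    Deliberately not a ValueError subclass: pydantic would re-wrap it during
    model construction and hide the row-level message.
    """


class Habitat(str, enum.Enum):
    plate = "plate"
    worm = "worm"


class Assay(str, enum.Enum):
    growth = "growth"
    early_colonization = "early_colonization"
    established_colonization = "established_colonization"
    persistence = "persistence"
    release = "release"


#: assays measured inside the host
WORM_ASSAYS = frozenset(
    {
        Assay.early_colonization,
        Assay.established_colonization,
        Assay.persistence,
        Assay.release,
    }
)


class Culture(str, enum.Enum):
    mono = "mono"
    co = "co"


class Unit(str, enum.Enum):
    per_plate = "per_plate"
    per_worm = "per_worm"


class CFUObservation(BaseModel):
    """One colony-count measurement.

    CFU values are stored as reals, not integers: plated colony counts are
    back-multiplied by dilution factors before they reach this record.
    """

    model_config = ConfigDict(frozen=True)

    species_id: str
    habitat: Habitat
    assay: Assay
    culture: Culture
    time_h: float = Field(ge=0)
    replicate: int = Field(ge=1)
    cfu: float = Field(ge=0)
    unit: Unit

    @model_validator(mode="after")
    def _check_consistency(self) -> "CFUObservation":
        if self.habitat is Habitat.plate and self.unit is not Unit.per_plate:
            raise ValueError("habitat=plate requires unit=per_plate")
        if self.habitat is Habitat.worm and self.unit is not Unit.per_worm:
            raise ValueError("habitat=worm requires unit=per_worm")
        if self.assay is Assay.growth and self.habitat is not Habitat.plate:
            raise ValueError("assay=growth requires habitat=plate")
        if self.assay in WORM_ASSAYS and self.habitat is not Habitat.worm:
            raise ValueError(f"assay={self.assay.value} requires habitat=worm")
        return self

    def key(self) -> Tuple:
        return (
            self.species_id,
            self.habitat.value,
            self.assay.value,
            self.culture.value,
            self.time_h,
            self.replicate,
        )


CFU_COLUMNS = [
    "species_id",
    "habitat",
    "assay",
    "culture",
    "time_h",
    "replicate",
    "cfu",
    "unit",
]


class CFUTable(BaseModel):
    """An ordered collection of :class:`CFUObservation` records.

    The key (species, habitat, assay, culture, time, replicate) must be
    unique.  Co-culture records are expected in species pairs per
    (assay, time, replicate); :meth:`incomplete_co_groups` flags groups
    where one member is missing.
    """

    observations: List[CFUObservation] = Field(default_factory=list)
    experiment_id: str = "experiment"

    def model_post_init(self, __context) -> None:
        # raised here (not in a validator) so the domain error surfaces
        # unwrapped by pydantic
        seen: Dict[Tuple, int] = {}
        for i, obs in enumerate(self.observations):
            k = obs.key()
            if k in seen:
                raise TableValidationError(
                    f"duplicate observation key {k} at rows {seen[k]} and {i}"
                )
            seen[k] = i

    def __len__(self) -> int:
        return len(self.observations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CFUTable):
            return NotImplemented
        return (
            self.experiment_id == other.experiment_id
            and self.observations == other.observations
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species_id": o.species_id,
                "habitat": o.habitat.value,
                "assay": o.assay.value,
                "culture": o.culture.value,
                "time_h": o.time_h,
                "replicate": o.replicate,
                "cfu": o.cfu,
                "unit": o.unit.value,
            }
            for o in self.observations
        ]
        return pd.DataFrame(rows, columns=CFU_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, experiment_id: str = "experiment") -> "CFUTable":
        missing = [c for c in CFU_COLUMNS if c not in frame.columns]
        if missing:
            raise TableSchemaError(f"missing column(s): {', '.join(missing)}")
        observations = []
        for i, row in enumerate(frame.itertuples(index=False)):
            try:
                observations.append(
                    CFUObservation(
                        species_id=str(row.species_id),
                        habitat=row.habitat,
                        assay=row.assay,
                        culture=row.culture,
                        time_h=float(row.time_h),
                        replicate=int(row.replicate),
                        cfu=float(row.cfu),
                        unit=row.unit,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise TableValidationError(f"row {i}: {exc}") from exc
        return cls(observations=observations, experiment_id=experiment_id)

    def incomplete_co_groups(self) -> List[Tuple]:
        """Return (habitat, assay, time, replicate) co-culture groups with a
        single species record (pairs are expected)."""
        groups: Dict[Tuple, set] = {}
        for o in self.observations:
            if o.culture is Culture.co:
                g = (o.habitat.value, o.assay.value, o.time_h, o.replicate)
                groups.setdefault(g, set()).add(o.species_id)
        return [g for g, species in groups.items() if len(species) < 2]

    def select(
        self,
        species_id: Optional[str] = None,
        habitat: Optional[Habitat] = None,
        assay: Optional[Assay] = None,
        culture: Optional[Culture] = None,
        time_h: Optional[float] = None,
    ) -> "CFUTable":
        obs: Iterable[CFUObservation] = self.observations
        if species_id is not None:
            obs = [o for o in obs if o.species_id == species_id]
        if habitat is not None:
            obs = [o for o in obs if o.habitat is Habitat(habitat)]
        if assay is not None:
            obs = [o for o in obs if o.assay is Assay(assay)]
        if culture is not None:
            obs = [o for o in obs if o.culture is Culture(culture)]
        if time_h is not None:
            obs = [o for o in obs if o.time_h == time_h]
        return CFUTable(observations=list(obs), experiment_id=self.experiment_id)


class ODCalibration(BaseModel):
    """Optical-density to CFU conversion: CFU count at OD 600nm = 1 per species.

    The default carries the published calibration for the two focal isolates:
    OD = 1 corresponds to ~1.86e9 MYb11 CFUs and ~8.0e8 MYb71 CFUs.
    """

    cfu_per_od: Dict[str, float] = Field(
        default_factory=lambda: {"MYb11": 1.86e9, "MYb71": 8.0e8}
    )

    @field_validator("cfu_per_od")
    @classmethod
    def _positive(cls, v: Dict[str, float]) -> Dict[str, float]:
        for sp, val in v.items():
            if not val > 0:
                raise ValueError(f"cfu_per_od[{sp!r}] must be > 0, got {val}")
        return v


#: trait columns of a genome-trait table, one row per species
TRAIT_COLUMNS = [
    "genome_size_mb",
    "n_antibiotic_pathways",
    "n_siderophore_pathways",
    "n_catabolic_pathways",
    "max_growth_rate",
    "doubling_time_h",
    "n_rrna_copies",
    "n_biofilm_genes",
    "n_auxotrophies",
    "codon_usage_bias",
]

#: columns that must be non-negative counts
COUNT_TRAITS = [
    "n_antibiotic_pathways",
    "n_siderophore_pathways",
    "n_catabolic_pathways",
    "n_rrna_copies",
    "n_biofilm_genes",
    "n_auxotrophies",
]


class TraitTable:
    """Community genome-trait matrix: one row per species.

    Traits are inputs here (genome size in Mb, gapseq-style pathway counts,
    rRNA copies, biofilm genes, auxotrophies, codon usage bias of highly
    expressed genes in [0, 1], and the codon-usage-predicted maximum growth
    rate r_max per hour).  ``doubling_time_h`` is derivable as ln(2)/r_max and
    is auto-filled when absent; when both are present they must agree within
    5% (rounding slack for published values).
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = self._validate(frame.copy())

    @staticmethod
    def _validate(frame: pd.DataFrame) -> pd.DataFrame:
        if "species_id" in frame.columns:
            frame = frame.set_index("species_id")
        required = [c for c in TRAIT_COLUMNS if c != "doubling_time_h"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise TableSchemaError(f"missing trait column(s): {', '.join(missing)}")
        for col in required:
            try:
                frame[col] = frame[col].astype(float)
            except (ValueError, TypeError) as exc:
                raise TableValidationError(f"non-numeric value in {col!r}: {exc}") from exc
        for col in COUNT_TRAITS:
            if (frame[col] < 0).any():
                raise TableValidationError(f"negative count in {col!r}")
        if (frame["max_growth_rate"] <= 0).any():
            raise TableValidationError("max_growth_rate must be > 0")
        cub = frame["codon_usage_bias"]
        if ((cub < 0) | (cub > 1)).any():
            bad = frame.index[(cub < 0) | (cub > 1)].tolist()
            raise TableValidationError(
                f"codon_usage_bias outside [0, 1] for species {bad}"
            )
        if "doubling_time_h" not in frame.columns:
            frame["doubling_time_h"] = math.log(2) / frame["max_growth_rate"]
        else:
            frame["doubling_time_h"] = frame["doubling_time_h"].astype(float)
            absent = frame["doubling_time_h"].isna()
            frame.loc[absent, "doubling_time_h"] = (
                math.log(2) / frame.loc[absent, "max_growth_rate"]
            )
            implied = math.log(2) / frame["max_growth_rate"]
            rel = (frame["doubling_time_h"] - implied).abs() / implied
            if (rel > 0.05).any():
                bad = frame.index[rel > 0.05].tolist()
                raise TableValidationError(
                    "doubling_time_h inconsistent with ln(2)/max_growth_rate "
                    f"(>5% off) for species {bad}"
                )
        return frame[TRAIT_COLUMNS]

    @property
    def species(self) -> List[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitTable):
            return NotImplemented
        if list(self.frame.index) != list(other.frame.index):
            return False
        import numpy as np

        return bool(
            np.allclose(self.frame.to_numpy(), other.frame.to_numpy(), rtol=0, atol=0)
        )
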