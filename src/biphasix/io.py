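"""Readers and writers for the tabular assay formats.

All tables are UTF-8 TSV with a mandatory header row; numeric fields may use
plain or scientific notation.  Round-tripping a validated table through
``write_* ∘ read_*`` is the identity.
"""

from __future__ import annotations

import os
from typing import Union

import pandas as pd

from .datamodel import (
    CFU_COLUMNS,
    CFUTable,
    TableSchemaError,
    TableValidationError,
    TraitTable,
    TRAIT_COLUMNS,
)

__all__ = [
    "read_cfu_table",
    "write_cfu_table",
    "read_trait_table",
    "write_trait_table",
]

PathLike = Union[str, os.PathLike]


def read_cfu_table(path: PathLike, sep: str = "\t") -> CFUTable:
    """Read a CFU assay table from a delimited text file.

    Raises :class:`TableSchemaError` when a required column is absent and
    :class:`TableValidationError` (citing the offending row) when a record
    violates a domain invariant.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in CFU_COLUMNS if c not in frame.columns]
    if missing:
        raise TableSchemaError(
            f"{path}: missing column(s): {', '.join(missing)}"
        )
    experiment_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return CFUTable.from_frame(frame, experiment_id=experiment_id)


def write_cfu_table(table: CFUTable, path: PathLike, sep: str = "\t") -> PathLike:
    """Write a CFU table as TSV; ``read_cfu_table`` parses it back identically.

    Uses repr-precision floats so values like 1.86e9 survive the round trip
    exactly.
    """
    frame = table.to_frame()
    frame.to_csv(path, sep=sep, index=False, float_format=None)
    return path


def read_trait_table(path: PathLike, sep: str = "\t") -> TraitTable:
    """Read a genome-trait table (one row per species).

    ``doubling_time_h`` is optional and auto-filled as ln(2)/max_growth_rate.
    """
    frame = pd.read_csv(path, sep=sep)
    if "species_id" not in frame.columns:
        raise TableSchemaError(f"{path}: missing column(s): species_id")
    try:
        return TraitTable(frame)
    except (TableSchemaError, TableValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_trait_table(table: TraitTable, path: PathLike, sep: str = "\t") -> PathLike:
    frame = table.frame.reset_index(names="species_id")
    frame = frame[["species_id"] + TRAIT_COLUMNS]
    frame.to_csv(path, sep=sep, index=False)
    return path
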