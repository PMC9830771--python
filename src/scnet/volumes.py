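"""Regional grey-matter volume tables.

The pipeline's universal input is a *volume table*: one row per subject
(and per timepoint in longitudinal designs), with metadata columns
followed by one column per named brain region holding that subject's
regional grey-matter volume.  A plain :class:`pandas.DataFrame` is used
as the in-memory container; the functions here validate its structure
and read/write the on-disk TSV representation.

Column layout (fixed header order)::

    subject_id  group  timepoint  age  sex  <region 1> ... <region N>

``timepoint`` is ``"baseline"``/``"followup"`` for longitudinal tables
and ``"baseline"`` throughout for cross-sectional ones.  ``sex`` is a
0/1 indicator (1 = male by the generator's convention).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import DataError

METADATA_COLUMNS = ["subject_id", "group", "timepoint", "age", "sex"]

BASELINE = "baseline"
FOLLOWUP = "followup"


def aal116_labels() -> list[str]:
    """Return the 116 region names of the AAL anatomical parcellation."""
    text = resources.files("scnet").joinpath("data/aal116_labels.txt").read_text()
    labels = [line.strip() for line in text.splitlines() if line.strip()]
    if len(labels) != 116:
        raise RuntimeError("packaged AAL label list is corrupt")
    return labels


def region_columns(table: pd.DataFrame) -> list[str]:
    """Names of the region (volume) columns, in table order."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def validate_volume_table(table: pd.DataFrame) -> None:
    """Check the structural invariants of a volume table.

    Raises
    ------
    DataError
        If metadata columns are missing, any volume is missing, or a
        (subject_id, timepoint) pair occurs more than once.
    """
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"volume table lacks metadata columns: {missing}")
    regions = region_columns(table)
    if not regions:
        raise DataError("volume table has no region columns")
    vols = table[regions]
    if vols.isna().any().any():
        bad = [c for c in regions if vols[c].isna().any()]
        raise DataError(f"missing volumes in regions: {bad[:5]}")
    dup = table.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        pairs = table.loc[dup, ["subject_id", "timepoint"]].values.tolist()
        raise DataError(f"duplicate (subject_id, timepoint) rows: {pairs[:5]}")


def volume_matrix(table: pd.DataFrame) -> np.ndarray:
    """Region volumes as a float (n_rows, n_regions) array."""
    return table[region_columns(table)].to_numpy(dtype=float)


def write_volume_table(table: pd.DataFrame, path) -> None:
    """Write a volume table as TSV with the fixed header order."""
    validate_volume_table(table)
    cols = METADATA_COLUMNS + region_columns(table)
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_volume_table(path) -> pd.DataFrame:
    """Read a volume table from delimited text (TSV or CSV, autodetected)."""
    table = pd.read_csv(path, sep=None, engine="python")
    validate_volume_table(table)
    return table
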