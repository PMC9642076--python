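"""Shared data model and I/O for all tabular and image inputs.

Every downstream stage consumes one of the containers defined here. Tables
are thin dataclass wrappers around :class:`pandas.DataFrame` with validation
on construction; images are plain ``numpy`` arrays checked for 8-bit range.

Missing-value convention: a measurement that was not made is an explicit
``NA`` (``NaN`` in floating columns, the string ``"NA"`` on disk), distinct
from a measured zero. Loaders never materialize absent
(protein, condition, fraction) combinations; downstream operations state
their own NA policy.

Identifier matching is case-sensitive and exact — no symbol aliasing is
attempted between quantification tables, DE tables and gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("solshift")

# Canonical labels used throughout the package.
SOLUBLE = "soluble"
INSOLUBLE = "insoluble"
WHOLE = "whole"
TWO_FRACTION = "two-fraction"
WHOLE_LYSATE = "whole-lysate"

#: Serialized precision for floating-point output (significant digits).
FLOAT_SIG_DIGITS = 6
#: On-disk token for missing values.
NA_TOKEN = "NA"


class SchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class TableValidationError(ValueError):
    """Well-formed file whose contents violate a table invariant."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

QUANT_COLUMNS = [
    "protein_id",
    "condition",
    "fraction",
    "replicate",
    "spectral_index",
    "psm_count",
]


@dataclass
class QuantTable:
    """Per-protein spectral-index records from a fractionated co-IP.

    Parameters
    ----------
    records
        One row per (protein, condition, fraction, replicate) with columns
        ``protein_id, condition, fraction, replicate, spectral_index,
        psm_count``.
    bait_id
        The affinity-tagged protein the co-IP was performed against
        (e.g. ``ACT-5`` or ``RAB-11.1``); must be measured in every
        condition present.
    condition_labels
        Ordered (control, treatment) pair.
    fraction_mode
        ``"two-fraction"`` (soluble/insoluble split) or ``"whole-lysate"``.
    """

    records: pd.DataFrame
    bait_id: str
    condition_labels: tuple[str, str] = ("control", "treatment")
    fraction_mode: str = TWO_FRACTION

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in QUANT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        df["spectral_index"] = pd.to_numeric(df["spectral_index"])
        df["psm_count"] = pd.to_numeric(df["psm_count"])
        df["replicate"] = pd.to_numeric(df["replicate"])
        if (df["spectral_index"].dropna() < 0).any():
            raise TableValidationError("spectral_index must be non-negative")
        psm = df["psm_count"].dropna()
        if (psm < 0).any() or (psm != psm.astype(int)).any():
            raise TableValidationError("psm_count must be a non-negative integer")
        if (df["replicate"] <= 0).any():
            raise TableValidationError("replicate must be a positive integer")
        key = ["protein_id", "condition", "fraction", "replicate"]
        dup = df.duplicated(subset=key, keep=False)
        if dup.any():
            rows = df.loc[dup, key].to_string(index=False)
            raise TableValidationError(
                f"duplicate (protein, condition, fraction, replicate) rows:\n{rows}"
            )
        if self.fraction_mode == TWO_FRACTION:
            allowed = {SOLUBLE, INSOLUBLE}
        elif self.fraction_mode == WHOLE_LYSATE:
            allowed = {WHOLE}
        else:
            raise TableValidationError(
                f"unknown fraction_mode {self.fraction_mode!r}"
            )
        bad = set(df["fraction"].unique()) - allowed
        if bad:
            raise TableValidationError(
                f"fractions {sorted(bad)} not allowed in {self.fraction_mode} mode"
            )
        for cond in df["condition"].unique():
            sub = df[df["condition"] == cond]
            if self.bait_id not in set(sub["protein_id"]):
                raise TableValidationError(
                    f"bait {self.bait_id!r} absent in condition {cond!r}"
                )
        self.records = df.reset_index(drop=True)

    @property
    def control(self) -> str:
        return self.condition_labels[0]

    @property
    def treatment(self) -> str:
        return self.condition_labels[1]

    def protein_ids(self) -> list[str]:
        return sorted(self.records["protein_id"].unique())

    def swap_conditions(self) -> "QuantTable":
        """Return a copy with control and treatment labels exchanged."""
        return QuantTable(
            self.records.copy(),
            bait_id=self.bait_id,
            condition_labels=(self.condition_labels[1], self.condition_labels[0]),
            fraction_mode=self.fraction_mode,
        )


@dataclass
class DETable:
    """Gene-level differential-expression table (gene_id, log2fc, p_value)."""

    rows: pd.DataFrame
    dataset_label: str = ""

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in ("gene_id", "log2fc", "p_value") if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        df["log2fc"] = pd.to_numeric(df["log2fc"])
        df["p_value"] = pd.to_numeric(df["p_value"])
        p = df["p_value"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise TableValidationError("p_value must lie in [0, 1]")
        if df["gene_id"].duplicated().any():
            dups = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
            raise TableValidationError(f"duplicate gene_id(s): {dups}")
        self.rows = df.reset_index(drop=True)


@dataclass
class GeneSetCollection:
    """Named annotation sets over an explicit identifier universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)
    descriptions: dict[str, str] = field(default_factory=dict)

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with *universe* (harmonization step)."""
        uni = frozenset(universe)
        return GeneSetCollection(
            sets={name: s & uni for name, s in self.sets.items()},
            universe=uni,
            descriptions=dict(self.descriptions),
        )


@dataclass
class EventTable:
    """Per-event large-particle flow cytometry table (TOF, fluorescence)."""

    rows: pd.DataFrame
    group_label: str = "sample"

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in ("event_id", "tof", "fluor_integral") if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        df["tof"] = pd.to_numeric(df["tof"])
        df["fluor_integral"] = pd.to_numeric(df["fluor_integral"])
        if (df["tof"] <= 0).any():
            raise TableValidationError("tof must be strictly positive")
        if (df["fluor_integral"] < 0).any():
            raise TableValidationError("fluor_integral must be non-negative")
        self.rows = df.reset_index(drop=True)


@dataclass
class CellTable:
    """Per-cell nuclear and proximal-cytosol fluorescence intensities."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        need = ("animal_id", "cell_id", "nucleus_intensity", "cytosol_intensity")
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        df["nucleus_intensity"] = pd.to_numeric(df["nucleus_intensity"])
        df["cytosol_intensity"] = pd.to_numeric(df["cytosol_intensity"])
        if (df["nucleus_intensity"] < 0).any() or (df["cytosol_intensity"] < 0).any():
            raise TableValidationError("intensities must be non-negative")
        counts = df.groupby("animal_id").size()
        if (counts > 20).any():
            bad = counts[counts > 20].index.tolist()
            raise TableValidationError(
                f"more than 20 cells for animal(s) {bad}; C. elegans intestines "
                "are scored over 20 cells"
            )
        self.rows = df.reset_index(drop=True)


@dataclass
class CtTable:
    """qPCR Ct table with at least one housekeeping gene per sample."""

    rows: pd.DataFrame
    housekeeping_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.rows
        need = ("sample_label", "gene_id", "ct", "replicate")
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if not self.housekeeping_ids:
            raise TableValidationError("at least one housekeeping gene is required")
        df = df.copy()
        df["ct"] = pd.to_numeric(df["ct"])
        if (df["ct"] <= 0).any():
            raise TableValidationError("ct must be strictly positive")
        for sample in df["sample_label"].unique():
            present = set(df.loc[df["sample_label"] == sample, "gene_id"])
            absent = [h for h in self.housekeeping_ids if h not in present]
            if absent:
                raise TableValidationError(
                    f"sample {sample!r} lacks housekeeping gene(s) {absent}"
                )
        self.rows = df.reset_index(drop=True)


def validate_gray_image(image: np.ndarray) -> np.ndarray:
    """Check an array is a rectangular 8-bit grayscale image; return it as uint8."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise TableValidationError(
            f"expected a 2-D grayscale image, got shape {arr.shape}"
        )
    if arr.size == 0:
        raise TableValidationError("empty image")
    if arr.min() < 0 or arr.max() > 255:
        raise TableValidationError("intensities must lie in [0, 255]")
    return arr.astype(np.uint8)


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, csv: bool = False) -> pd.DataFrame:
    sep = "," if csv else "\t"
    return pd.read_csv(path, sep=sep, na_values=[NA_TOKEN], keep_default_na=False)


def load_quant_table(
    path: str | Path,
    bait_id: str,
    condition_labels: tuple[str, str] | None = None,
    fraction_mode: str | None = None,
    csv: bool = False,
) -> QuantTable:
    """Read a spectral-index table from TSV (or CSV with ``csv=True``).

    Condition labels default to the order of first appearance in the file;
    fraction mode is inferred from the fraction labels present.
    """
    df = _read_table(path, csv=csv)
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    if condition_labels is None:
        conds = list(dict.fromkeys(df["condition"]))
        if len(conds) == 1:
            condition_labels = (conds[0], conds[0])
        elif len(conds) == 2:
            condition_labels = (conds[0], conds[1])
        else:
            raise TableValidationError(
                f"{path}: expected at most 2 conditions, found {conds}"
            )
    if fraction_mode is None:
        fraction_mode = (
            WHOLE_LYSATE if set(df["fraction"].unique()) == {WHOLE} else TWO_FRACTION
        )
    return QuantTable(df, bait_id=bait_id, condition_labels=condition_labels,
                      fraction_mode=fraction_mode)


def load_de_table(path: str | Path, dataset_label: str = "", csv: bool = False) -> DETable:
    """Read a gene-level DE table (gene_id, log2fc, p_value)."""
    return DETable(_read_table(path, csv=csv), dataset_label=dataset_label or str(path))


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Read GMT gene sets: one set per line, ``name<TAB>description<TAB>members…``.

    Duplicate members within a set are silently de-duplicated; a line with
    fewer than three fields is a parse error reported with its line number.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    members_all: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line needs name, description and at "
                    f"least one member (got {len(fields)} field(s))"
                )
            name, desc, *members = fields
            member_set = frozenset(m for m in members if m)
            sets[name] = member_set
            descriptions[name] = desc
            members_all |= member_set
    return GeneSetCollection(sets=sets, universe=frozenset(members_all),
                             descriptions=descriptions)


def load_event_table(path: str | Path, group_label: str = "sample", csv: bool = False) -> EventTable:
    """Read a per-event flow table (event_id, tof, fluor_integral)."""
    return EventTable(_read_table(path, csv=csv), group_label=group_label)


def load_cell_table(path: str | Path, csv: bool = False) -> CellTable:
    """Read a per-cell intensity table."""
    return CellTable(_read_table(path, csv=csv))


def load_ct_table(path: str | Path, housekeeping_ids: Sequence[str], csv: bool = False) -> CtTable:
    """Read a qPCR Ct table and attach the housekeeping gene list."""
    return CtTable(_read_table(path, csv=csv), housekeeping_ids=tuple(housekeeping_ids))


def load_gray_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF into a uint8 array."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse an explicit single plane / luminance-only stack
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise TableValidationError(
                f"{path}: expected single-plane grayscale, got shape {arr.shape}"
            )
    return validate_gray_image(arr)


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------


def _format_value(v: object) -> str:
    if v is None:
        return NA_TOKEN
    if isinstance(v, float):
        if np.isnan(v):
            return NA_TOKEN
        return f"{v:.{FLOAT_SIG_DIGITS}g}"
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    return str(v)


def write_results(table: pd.DataFrame, path: str | Path, csv: bool = False) -> None:
    """Write a result table as TSV with fixed 6-significant-digit floats.

    Missing values are serialized as ``NA``; booleans as ``true``/``false``.
    Column order is the DataFrame's order and is preserved on round-trip.
    An empty table yields a header-only file.
    """
    sep = "," if csv else "\t"
    out = table.copy()
    for col in out.columns:
        out[col] = out[col].map(_format_value)
    out.to_csv(path, sep=sep, index=False)


def read_results(path: str | Path, csv: bool = False) -> pd.DataFrame:
    """Load a table written by :func:`write_results`, restoring NA and bools."""
    df = _read_table(path, csv=csv)
    for col in df.columns:
        if df[col].dtype == object:
            vals = set(df[col].dropna().unique())
            if vals and vals <= {"true", "false"}:
                df[col] = df[col].map({"true": True, "false": False})
    return df
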