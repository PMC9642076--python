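"""Solubility-shift indexing of co-IP interactors.

Upon a perturbation that destabilizes a protein network (here, *hsf-1*
knockdown destabilizing the enteric actin interactome), interacting
proteins can partition from the soluble supernatant into the insoluble
pellet of an ultracentrifuged lysate. Two statistics summarize this:

* solubility ratio ``SR = soluble / (soluble + insoluble)`` per condition,
  in [0, 1];
* destabilization index ``DI = SR(control) − SR(treatment)``, in [−1, 1],
  where 1 is a complete soluble→insoluble shift under treatment.

Proteins are ranked by DI (descending) and the top decile is the default
selection handed to over-representation analysis.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .tables_io import (
    INSOLUBLE,
    SOLUBLE,
    TWO_FRACTION,
    QuantTable,
    TableValidationError,
    logger,
)

#: Replicate aggregation strategies for :func:`index_table`.
AGG_MEAN_THEN_RATIO = "mean-then-ratio"
AGG_RATIO_THEN_MEAN = "ratio-then-mean"

RESULT_COLUMNS = [
    "protein_id",
    "sr_control",
    "sr_treatment",
    "destab_index",
    "rank",
    "in_top_fraction",
]


def solubility_ratio(soluble_si: float, insoluble_si: float) -> float:
    """Fraction of a protein's spectral index found in the soluble fraction.

    Returns ``soluble / (soluble + insoluble)``. When both fractions are
    zero the ratio is undefined and NaN is returned (with a warning); NaN
    in either argument propagates. Negative input is a domain error.
    """
    if np.isnan(soluble_si) or np.isnan(insoluble_si):
        return float("nan")
    if soluble_si < 0 or insoluble_si < 0:
        raise ValueError("spectral indices must be non-negative")
    total = soluble_si + insoluble_si
    if total == 0:
        logger.warning("solubility ratio undefined: 0 in both fractions")
        return float("nan")
    return soluble_si / total


def destabilization_index(sr_control: float, sr_treatment: float) -> float:
    """``SR(control) − SR(treatment)``; 1 means a complete soluble→insoluble shift."""
    for v in (sr_control, sr_treatment):
        if not np.isnan(v) and not (0.0 <= v <= 1.0):
            raise ValueError(f"solubility ratio {v} outside [0, 1]")
    return sr_control - sr_treatment


def _sr_from_fraction_table(table: pd.DataFrame) -> pd.Series:
    """SR per row of a soluble/insoluble column table; 0/0 rows give NaN."""
    for frac in (SOLUBLE, INSOLUBLE):
        if frac not in table.columns:
            table[frac] = np.nan
    # detected in the condition but no record for one fraction: below
    # detection in that fraction, counted as 0 (distinct from a fully
    # absent protein, which never reaches this table and stays NA)
    table = table.fillna(0.0)
    total = table[SOLUBLE] + table[INSOLUBLE]
    n_undef = int((total == 0).sum())
    if n_undef:
        logger.warning("solubility ratio undefined for %d protein(s): 0 in both "
                       "fractions", n_undef)
    with np.errstate(invalid="ignore", divide="ignore"):
        return table[SOLUBLE] / total


def _condition_sr(
    df: pd.DataFrame, condition: str, proteins: Iterable[str], aggregate: str
) -> pd.Series:
    """Per-protein SR for one condition, NaN where the protein is unmeasured."""
    sub = df[df["condition"] == condition]
    out = pd.Series(np.nan, index=pd.Index(list(proteins)), dtype=float)
    if sub.empty:
        return out
    if aggregate == AGG_MEAN_THEN_RATIO:
        means = (
            sub.groupby(["protein_id", "fraction"])["spectral_index"]
            .mean()
            .unstack("fraction")
        )
        sr = _sr_from_fraction_table(means)
    elif aggregate == AGG_RATIO_THEN_MEAN:
        sums = (
            sub.groupby(["protein_id", "replicate", "fraction"])["spectral_index"]
            .sum()
            .unstack("fraction")
        )
        per_rep = _sr_from_fraction_table(sums)
        sr = per_rep.groupby(level="protein_id").mean()
    else:
        raise ValueError(f"unknown aggregation {aggregate!r}")
    out.loc[sr.index] = sr.values
    return out


def index_table(
    quant: QuantTable,
    aggregate: str = AGG_MEAN_THEN_RATIO,
    top_frac: float = 0.10,
) -> pd.DataFrame:
    """Compute SR per condition, DI and the top-fraction ranking for a co-IP.

    Replicate spectral indices are aggregated by mean per
    (protein, condition, fraction) before ratioing (default); a
    ratio-per-replicate-then-mean variant is available via ``aggregate``.
    Proteins unmeasured in either condition carry NA DI and are excluded
    from ranking; ranking is descending by DI with ties broken by
    protein_id so the ordering is deterministic.

    Returns a DataFrame with columns ``protein_id, sr_control,
    sr_treatment, destab_index, rank, in_top_fraction``.
    """
    if quant.fraction_mode != TWO_FRACTION:
        raise TableValidationError(
            "solubility indexing requires a two-fraction (soluble/insoluble) table"
        )
    df = quant.records
    proteins = quant.protein_ids()
    sr_c = _condition_sr(df, quant.control, proteins, aggregate)
    sr_t = _condition_sr(df, quant.treatment, proteins, aggregate)
    di = sr_c - sr_t

    result = pd.DataFrame(
        {
            "protein_id": proteins,
            "sr_control": sr_c.values,
            "sr_treatment": sr_t.values,
            "destab_index": di.values,
        }
    )
    defined = result.dropna(subset=["destab_index"]).copy()
    # descending DI, protein_id lexicographic as the deterministic tie-break
    defined = defined.sort_values(
        ["destab_index", "protein_id"], ascending=[False, True]
    )
    rank = pd.Series(
        np.arange(1, len(defined) + 1), index=defined["protein_id"].values
    )
    result["rank"] = result["protein_id"].map(rank)
    top = top_fraction(result, fraction=top_frac) if len(defined) else set()
    result["in_top_fraction"] = result["protein_id"].isin(top)
    return result[RESULT_COLUMNS]


def top_fraction(results: pd.DataFrame, fraction: float = 0.10) -> set[str]:
    """The ``ceil(fraction × k)`` proteins with highest DI among the k defined.

    Ties at the cutoff are broken by protein_id lexicographic order. The
    denominator k is the number of proteins with a defined DI, not the full
    detected proteome.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    defined = results.dropna(subset=["destab_index"])
    k = len(defined)
    if k == 0:
        raise ValueError("no protein has a defined destabilization index")
    n_top = math.ceil(fraction * k)
    ordered = defined.sort_values(
        ["destab_index", "protein_id"], ascending=[False, True]
    )
    return set(ordered["protein_id"].head(n_top))
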