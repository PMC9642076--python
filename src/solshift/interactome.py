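"""Bait-normalized relative-binding analysis of co-IP interactors.

In an affinity-purification experiment the amount of captured bait can
differ between conditions for purely technical reasons; interactor
abundances in the treatment condition are therefore rescaled so that the
bait's mean spectral index matches its control level. Relative binding
(RB) of each interactor is then the ratio of its bait-adjusted mean
treatment spectral index over its mean control spectral index. Proteins
are flagged by the detection-confidence filter PSM ≥ 2 (maximum PSM count
over all runs), and a category subset (e.g. a KEGG endocytosis list) can
restrict the output for condition comparisons.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .tables_io import QuantTable, TableValidationError, logger

BINDING_COLUMNS = [
    "protein_id",
    "mean_si_control",
    "mean_si_treatment_adj",
    "relative_binding",
    "max_psm",
    "passes_psm_filter",
    "treatment_only",
]


class NormalizationError(ValueError):
    """Bait not quantified (spectral index 0) in a condition."""


def _bait_means(quant: QuantTable) -> tuple[float, float]:
    df = quant.records
    bait = df[df["protein_id"] == quant.bait_id]
    means = []
    for cond in quant.condition_labels:
        si = bait.loc[bait["condition"] == cond, "spectral_index"]
        m = float(si.mean()) if len(si) else 0.0
        if not m > 0:
            raise NormalizationError(
                f"bait {quant.bait_id!r} has zero mean spectral index in "
                f"condition {cond!r}; cannot normalize"
            )
        means.append(m)
    return means[0], means[1]


def bait_normalize(quant: QuantTable) -> QuantTable:
    """Rescale treatment spectral indices to the control bait level.

    Every treatment-condition spectral index is multiplied by
    ``mean bait SI (control) / mean bait SI (treatment)``; control records
    are untouched, so control-relative quantities keep their raw scale.
    After normalization the bait's adjusted treatment mean equals its
    control mean exactly.
    """
    bait_c, bait_t = _bait_means(quant)
    scale = bait_c / bait_t
    df = quant.records.copy()
    mask = df["condition"] == quant.treatment
    df.loc[mask, "spectral_index"] = df.loc[mask, "spectral_index"] * scale
    return QuantTable(
        df,
        bait_id=quant.bait_id,
        condition_labels=quant.condition_labels,
        fraction_mode=quant.fraction_mode,
    )


def relative_binding_table(
    quant: QuantTable, psm_threshold: int = 2, normalized: bool = False
) -> pd.DataFrame:
    """Per-interactor relative binding (treatment/control) after bait normalization.

    Replicate spectral indices are averaged within condition (fractions, if
    present, are pooled by the same mean). RB is NA with a
    ``treatment_only`` flag when the control mean is zero — no infinite
    ratio is fabricated. Proteins failing the PSM filter are kept but
    flagged. ``normalized=True`` skips the bait normalization step for a
    table already adjusted.
    """
    if not normalized:
        quant = bait_normalize(quant)
    df = quant.records
    rows = []
    for pid in quant.protein_ids():
        sub = df[df["protein_id"] == pid]
        si_c = sub.loc[sub["condition"] == quant.control, "spectral_index"]
        si_t = sub.loc[sub["condition"] == quant.treatment, "spectral_index"]
        mean_c = float(si_c.mean()) if len(si_c) else 0.0
        mean_t = float(si_t.mean()) if len(si_t) else 0.0
        if mean_c > 0:
            rb = mean_t / mean_c
            treatment_only = False
        else:
            rb = float("nan")
            treatment_only = True
        max_psm = int(sub["psm_count"].max()) if len(sub) else 0
        rows.append(
            {
                "protein_id": pid,
                "mean_si_control": mean_c,
                "mean_si_treatment_adj": mean_t,
                "relative_binding": rb,
                "max_psm": max_psm,
                "passes_psm_filter": max_psm >= psm_threshold,
                "treatment_only": treatment_only,
            }
        )
    return pd.DataFrame(rows, columns=BINDING_COLUMNS)


def subset_by_category(results: pd.DataFrame, category: Iterable[str]) -> pd.DataFrame:
    """Restrict binding results to a category of identifiers, preserving order.

    Used to compare category-restricted RB distributions (e.g. KEGG
    endocytosis, cel04144) between conditions. An empty intersection yields
    an empty result with a warning.
    """
    cat = set(category)
    out = results[results["protein_id"].isin(cat)].reset_index(drop=True)
    if out.empty:
        logger.warning("category does not intersect the binding results")
    return out
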