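"""Reporter, cytometry, staining, image and qPCR quantification rules.

Each operation encodes one of the study-style scoring rules:

* nuclear reporter scoring — a cell is positive when nuclear fluorescence
  is at least ``fold`` (default 2) times the proximal cytosolic signal;
  per-animal percentages use the fixed denominator of 20 intestinal cells,
  so percentages are always multiples of 5;
* large-particle flow cytometry — whole-animal integral fluorescence is
  divided by time-of-flight (TOF, a size proxy) per event, averaged per
  group, and standardized relative to control;
* oil red O density — staining density is the inverse of measured image
  brightness, relative to the mean control inverse brightness;
* TEM lipid density — micrographs are inverted, thresholded to black &
  white, and the black-pixel fraction is the readout;
* ΔΔCt — qPCR relative abundance 2^(−ΔΔCt) with housekeeping-gene
  normalization (geometric mean on the linear scale == arithmetic mean of
  Cts on the log2 scale);
* absorption scoring — an animal is impaired when it absorbed strictly
  less than 50% of the supplemented tracer.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables_io import CellTable, CtTable, EventTable, validate_gray_image, logger

NUCLEAR_DENOMINATOR = 20  # intestinal cells scored per C. elegans


# ---------------------------------------------------------------------------
# Nuclear reporter scoring
# ---------------------------------------------------------------------------


def score_nuclear(cells: CellTable, fold: float = 2.0) -> pd.DataFrame:
    """Per-animal count and percentage of nuclei with nuclear-enriched signal.

    A cell is positive when ``nucleus_intensity / cytosol_intensity >= fold``.
    Cells with zero cytosolic intensity are unscorable: they are excluded
    from the numerator but the denominator stays at 20, so percentages
    remain multiples of 5.
    """
    rows = []
    for animal, sub in cells.rows.groupby("animal_id", sort=True):
        scorable = sub[sub["cytosol_intensity"] > 0]
        n_unscorable = len(sub) - len(scorable)
        if n_unscorable:
            logger.warning(
                "animal %s: %d cell(s) with zero cytosolic intensity excluded",
                animal, n_unscorable,
            )
        ratio = scorable["nucleus_intensity"] / scorable["cytosol_intensity"]
        positive = int((ratio >= fold).sum())
        rows.append(
            {
                "animal_id": animal,
                "positive_nuclei": positive,
                "percent_nuclear": 100.0 * positive / NUCLEAR_DENOMINATOR,
            }
        )
    return pd.DataFrame(rows, columns=["animal_id", "positive_nuclei", "percent_nuclear"])


# ---------------------------------------------------------------------------
# Large-particle flow cytometry
# ---------------------------------------------------------------------------


def tof_normalize(events: EventTable, control: EventTable) -> pd.DataFrame:
    """Size-normalized group fluorescence relative to the control group.

    Each event's fluorescence integral is divided by its TOF; the group
    value is the mean of these per-event ratios, and ``relative_to_control``
    is the group value over the control-group value. Evaluating the control
    against itself yields exactly 1.
    """
    if control.rows.empty:
        raise ValueError("control event table is empty")
    if events.rows.empty:
        raise ValueError("sample event table is empty")

    def group_value(t: EventTable) -> float:
        return float((t.rows["fluor_integral"] / t.rows["tof"]).mean())

    ctrl_val = group_value(control)
    rows = []
    for t in (control, events):
        v = group_value(t)
        rows.append(
            {"group_label": t.group_label, "value": v,
             "relative_to_control": v / ctrl_val}
        )
    return pd.DataFrame(rows, columns=["group_label", "value", "relative_to_control"])


# ---------------------------------------------------------------------------
# oil red O staining density
# ---------------------------------------------------------------------------


def oro_density(
    sample_brightness: Sequence[float],
    control_brightness: Sequence[float],
    inverse_of_mean: bool = False,
) -> pd.DataFrame:
    """Relative staining density from per-worm mean brightness values.

    Brighter signal means less dye, so density is inverse brightness. Each
    sample's density is ``(1/brightness)`` divided by the mean control
    inverse brightness (default), or — with ``inverse_of_mean=True`` — by
    the inverse of the mean control brightness. The control's own mean
    relative density is 1 under the default reading.
    """
    s = np.asarray(sample_brightness, dtype=float)
    c = np.asarray(control_brightness, dtype=float)
    if s.size == 0 or c.size == 0:
        raise ValueError("brightness collections must be non-empty")
    if np.any(s <= 0) or np.any(c <= 0):
        raise ValueError("brightness values must be strictly positive")
    denom = (1.0 / c.mean()) if inverse_of_mean else (1.0 / c).mean()
    rows = [
        {"group_label": "control", "value": float((1.0 / c).mean()),
         "relative_to_control": float((1.0 / c).mean() / denom)},
        {"group_label": "sample", "value": float((1.0 / s).mean()),
         "relative_to_control": float((1.0 / s).mean() / denom)},
    ]
    return pd.DataFrame(rows, columns=["group_label", "value", "relative_to_control"])


def oro_density_per_sample(
    sample_brightness: Sequence[float], control_brightness: Sequence[float]
) -> np.ndarray:
    """Per-sample relative densities: (1/brightness) / mean control (1/brightness)."""
    s = np.asarray(sample_brightness, dtype=float)
    c = np.asarray(control_brightness, dtype=float)
    if np.any(s <= 0) or np.any(c <= 0):
        raise ValueError("brightness values must be strictly positive")
    return (1.0 / s) / (1.0 / c).mean()


# ---------------------------------------------------------------------------
# TEM lipid density
# ---------------------------------------------------------------------------


def tem_black_fraction(image: np.ndarray, threshold: int = 128) -> float:
    """Black-pixel fraction of an inverted, thresholded TEM micrograph.

    The 8-bit image is inverted (v → 255 − v) and binarized: inverted
    pixels ≥ ``threshold`` count as black. Lipid droplets image dark, so
    after inversion they are bright and the black fraction tracks droplet
    coverage.
    """
    arr = validate_gray_image(image)
    if not (0 <= threshold <= 255):
        raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    inverted = 255 - arr.astype(np.int16)
    return float(np.mean(inverted >= threshold))


def tem_relative_density(
    sample_images: Iterable[np.ndarray],
    control_images: Iterable[np.ndarray],
    threshold: int = 128,
) -> pd.DataFrame:
    """Per-image black fractions normalized to the mean control fraction."""
    ctrl = [tem_black_fraction(im, threshold) for im in control_images]
    samp = [tem_black_fraction(im, threshold) for im in sample_images]
    if not ctrl or not samp:
        raise ValueError("need at least one control and one sample image")
    ctrl_mean = float(np.mean(ctrl))
    if ctrl_mean == 0:
        raise ValueError("mean control black fraction is zero; cannot normalize")
    rows = [
        {"group_label": "control", "image_index": i, "black_fraction": f,
         "relative_to_control": f / ctrl_mean}
        for i, f in enumerate(ctrl)
    ] + [
        {"group_label": "sample", "image_index": i, "black_fraction": f,
         "relative_to_control": f / ctrl_mean}
        for i, f in enumerate(samp)
    ]
    return pd.DataFrame(
        rows, columns=["group_label", "image_index", "black_fraction",
                       "relative_to_control"]
    )


# ---------------------------------------------------------------------------
# qPCR ΔΔCt
# ---------------------------------------------------------------------------


def delta_delta_ct(ct: CtTable, control_label: str) -> pd.DataFrame:
    """Relative transcript abundance 2^(−ΔΔCt) per (sample, gene).

    Technical Ct replicates are averaged first. ΔCt = mean target Ct −
    mean housekeeping Ct (the arithmetic mean of housekeeping Cts equals
    geometric-mean normalization on the linear scale); ΔΔCt subtracts the
    control sample's ΔCt gene-wise; relative abundance is 2^(−ΔΔCt).
    """
    df = ct.rows
    samples = list(dict.fromkeys(df["sample_label"]))
    if control_label not in samples:
        raise ValueError(f"control sample {control_label!r} not in table")
    hk = set(ct.housekeeping_ids)
    # mean Ct per (sample, gene) across replicates
    mean_ct = df.groupby(["sample_label", "gene_id"])["ct"].mean()

    def hk_mean(sample: str) -> float:
        vals = [mean_ct[(sample, h)] for h in ct.housekeeping_ids]
        return float(np.mean(vals))

    targets = [g for g in dict.fromkeys(df["gene_id"]) if g not in hk]
    rows = []
    for gene in targets:
        if (control_label, gene) not in mean_ct.index:
            raise ValueError(
                f"target {gene!r} not measured in control sample {control_label!r}"
            )
        dct_control = mean_ct[(control_label, gene)] - hk_mean(control_label)
        for sample in samples:
            if (sample, gene) not in mean_ct.index:
                continue
            dct = mean_ct[(sample, gene)] - hk_mean(sample)
            ddct = dct - dct_control
            rows.append(
                {"sample_label": sample, "gene_id": gene,
                 "delta_ct": float(dct), "delta_delta_ct": float(ddct),
                 "relative_abundance": float(2.0 ** (-ddct))}
            )
    return pd.DataFrame(
        rows, columns=["sample_label", "gene_id", "delta_ct", "delta_delta_ct",
                       "relative_abundance"]
    )


# ---------------------------------------------------------------------------
# Absorption scoring
# ---------------------------------------------------------------------------


def absorption_impairment(
    per_animal_fraction_absorbed: Sequence[float], cutoff: float = 0.5
) -> float:
    """Percent of animals absorbing strictly less than ``cutoff`` of the tracer."""
    fr = np.asarray(per_animal_fraction_absorbed, dtype=float)
    if fr.size == 0:
        raise ValueError("no animals to score")
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("fractions absorbed must lie in [0, 1]")
    return float(100.0 * np.mean(fr < cutoff))
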