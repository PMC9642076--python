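"""Threshold significance calls on DE tables and cross-dataset classification.

Genes are called significant when |log2FC| > 0.5 and p < 0.05 (both strict,
per the thresholds used throughout the study). Significant genes from a
reference dataset A are classified against a second dataset B as:

* ``unchanged``   — measured in B but not significant there;
* ``inverse``     — significant in B with the opposite log2FC sign;
* ``concordant``  — significant in B with the same sign;
* ``absent_in_B`` — not measured in B at all.

The summary reports each class as a percentage of |sig A| rounded to whole
percent, the granularity at which such compositions are usually quoted
(e.g. 68% unchanged, 19% inverse for a 25 + 7 of 37 split).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .tables_io import DETable

DEFAULT_LFC_MIN = 0.5
DEFAULT_P_MAX = 0.05

CLASSES = ("unchanged", "inverse", "concordant", "absent_in_B")

CROSS_COLUMNS = ["gene_id", "sig_A", "lfc_A", "sig_B", "lfc_B", "cls"]


def call_significant(
    table: DETable, lfc_min: float = DEFAULT_LFC_MIN, p_max: float = DEFAULT_P_MAX
) -> dict[str, int]:
    """Genes with |log2FC| strictly > lfc_min and p strictly < p_max.

    Returns a mapping gene_id → sign of log2FC (+1 or −1). With
    ``lfc_min=0, p_max=1`` this degenerates to every gene with a non-zero
    fold change.
    """
    df = table.rows
    mask = (df["log2fc"].abs() > lfc_min) & (df["p_value"] < p_max)
    sub = df[mask]
    return {
        g: int(np.sign(l)) for g, l in zip(sub["gene_id"], sub["log2fc"]) if l != 0
    }


def overlap(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[int, int, int]:
    """Two-set Venn partition counts: (only A, shared, only B)."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(a & b), len(b - a)


def cross_classify(
    sig_a: dict[str, int],
    table_b: DETable,
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
    b_p_only: bool = False,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify dataset-A significant genes against dataset B.

    Parameters
    ----------
    sig_a
        Mapping gene_id → sign from :func:`call_significant` on dataset A.
        The sign may also be a signed log2FC; only its sign is used.
    table_b
        The second dataset's DE table.
    lfc_min, p_max
        Significance thresholds applied in B.
    b_p_only
        If true, significance in B requires only p < p_max (no fold-change
        cutoff) — the looser reading of a p-value-only cross-comparison.

    Returns the per-gene record table and a summary of percentages
    (``percent_unchanged`` etc., rounded to whole percent) plus raw counts.
    """
    if not sig_a:
        raise ValueError("no significant genes in dataset A")
    b = table_b.rows.set_index("gene_id")
    rows = []
    for gene in sorted(sig_a):
        sign_a = int(np.sign(sig_a[gene]))
        if gene not in b.index:
            rows.append(
                {"gene_id": gene, "sig_A": True, "lfc_A": float(sign_a),
                 "sig_B": False, "lfc_B": float("nan"), "cls": "absent_in_B"}
            )
            continue
        lfc_b = float(b.at[gene, "log2fc"])
        p_b = float(b.at[gene, "p_value"])
        sig_b = (p_b < p_max) and (b_p_only or abs(lfc_b) > lfc_min)
        if not sig_b:
            cls = "unchanged"
        elif int(np.sign(lfc_b)) == -sign_a:
            cls = "inverse"
        else:
            cls = "concordant"
        rows.append(
            {"gene_id": gene, "sig_A": True, "lfc_A": float(sign_a),
             "sig_B": sig_b, "lfc_B": lfc_b, "cls": cls}
        )
    records = pd.DataFrame(rows, columns=CROSS_COLUMNS)
    n = len(records)
    summary: dict[str, float] = {"n_sig_A": n}
    for cls in CLASSES:
        count = int((records["cls"] == cls).sum())
        summary[f"n_{cls}"] = count
        summary[f"percent_{cls}"] = round(100.0 * count / n)
    return records, summary
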