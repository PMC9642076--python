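"""Over-representation analysis of a selected set against annotation sets.

Given a universe of N identifiers, an annotation set covering K of them, and
a selection of n identifiers of which x fall in the set, the upper-tail
hypergeometric probability P(X ≥ x) measures over-representation. P-values
across annotation sets are adjusted by Benjamini–Hochberg step-up FDR.

The universe is explicit and caller-supplied (e.g. all proteins with a
defined destabilization index, or all detected interactors), because the
background choice dominates over-representation results.
"""

from __future__ import annotations

from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables_io import GeneSetCollection

ENRICHMENT_COLUMNS = [
    "set_name",
    "universe_size",
    "annotated",
    "selected",
    "overlap",
    "expected",
    "p_value",
    "q_value",
]


def hypergeom_p(N: int, K: int, n: int, x: int) -> float:
    """Exact upper-tail hypergeometric probability P(X ≥ x).

    Computed by summing exact integer-binomial PMF terms
    ``C(K, i) C(N−K, n−i) / C(N, n)`` for i = x … min(K, n); no normal
    approximation is used anywhere.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("x", x)):
        if v != int(v) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N:
        raise ValueError(f"K ({K}) and n ({n}) must not exceed N ({N})")
    if x > min(K, n):
        raise ValueError(f"x ({x}) exceeds min(K, n) = {min(K, n)}")
    total = comb(N, n)
    numer = sum(comb(K, i) * comb(N - K, n - i) for i in range(x, min(K, n) + 1))
    return numer / total


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1.

    The adjustment is computed on the sorted values and mapped back, so the
    output is invariant to input order and monotone in the p-value ordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards, then cap
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def enrich(
    selected: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str] | None = None,
    min_set_size: int = 2,
    include_zero_overlap: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of *selected* against annotation sets.

    Every annotation set is intersected with the universe before counting;
    sets with fewer than ``min_set_size`` members after intersection are
    dropped as uninformative. By default only sets overlapping the
    selection (x ≥ 1) are reported; results are sorted by p ascending and
    q-values come from BH adjustment over the reported sets.
    """
    uni = frozenset(universe) if universe is not None else sets.universe
    if not uni:
        raise ValueError("empty universe")
    sel = frozenset(selected)
    if not sel:
        raise ValueError("empty selection")
    if not sel <= uni:
        extra = sorted(sel - uni)[:5]
        raise ValueError(f"selection not contained in universe (e.g. {extra})")
    harmonized = sets.restricted_to(uni)
    N, n = len(uni), len(sel)
    rows = []
    for name in sorted(harmonized.sets):
        members = harmonized.sets[name]
        K = len(members)
        if K < min_set_size:
            continue
        x = len(sel & members)
        if x == 0 and not include_zero_overlap:
            continue
        rows.append(
            {
                "set_name": name,
                "universe_size": N,
                "annotated": K,
                "selected": n,
                "overlap": x,
                "expected": n * K / N,
                "p_value": hypergeom_p(N, K, n, x),
            }
        )
    result = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if len(result):
        result["q_value"] = bh_adjust(result["p_value"].to_numpy())
        result = result.sort_values(
            ["p_value", "set_name"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        result["q_value"] = pd.Series(dtype=float)
    return result[ENRICHMENT_COLUMNS]
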