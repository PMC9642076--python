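import numpy as np
import pandas as pd
import pytest

from solshift import QuantTable

QUANT_COLS = ["protein_id", "condition", "fraction", "replicate",
              "spectral_index", "psm_count"]


def make_quant(rows, bait_id="BAIT", **kwargs) -> QuantTable:
    """Build a QuantTable from (protein, condition, fraction, replicate, si, psm) tuples."""
    return QuantTable(pd.DataFrame(rows, columns=QUANT_COLS), bait_id=bait_id, **kwargs)


def two_fraction_rows(per_protein, replicate=1):
    """Expand {protein: {(condition, fraction): si}} into record tuples.

    PSM counts default to ceil(si) so detected proteins pass the PSM filter.
    """
    rows = []
    for pid, cells in per_protein.items():
        for (cond, frac), si in cells.items():
            rows.append((pid, cond, frac, replicate, float(si),
                         int(np.ceil(si))))
    return rows


@pytest.fixture
def simple_quant():
    """Bait plus one fully shifting protein: control all-soluble, treatment all-insoluble."""
    rows = two_fraction_rows({
        "BAIT": {("control", "soluble"): 50, ("control", "insoluble"): 50,
                 ("treatment", "soluble"): 50, ("treatment", "insoluble"): 50},
        "SHIFTER": {("control", "soluble"): 4, ("control", "insoluble"): 0,
                    ("treatment", "soluble"): 0, ("treatment", "insoluble"): 4},
    })
    return make_quant(rows)


def random_quant(rng, n_proteins=6, n_replicates=1, max_si=30):
    """Random well-formed two-fraction table with an always-detected bait."""
    rows = []
    for cond in ("control", "treatment"):
        for frac in ("soluble", "insoluble"):
            for rep in range(1, n_replicates + 1):
                rows.append(("BAIT", cond, frac, rep,
                             float(rng.integers(10, max_si + 10)), 5))
    for i in range(n_proteins):
        pid = f"P{i:03d}"
        for cond in ("control", "treatment"):
            for frac in ("soluble", "insoluble"):
                for rep in range(1, n_replicates + 1):
                    rows.append((pid, cond, frac, rep,
                                 float(rng.integers(0, max_si)),
                                 int(rng.integers(0, 6))))
    return make_quant(rows)
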