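import logging

import numpy as np
import pandas as pd
import pytest

from heritagescan import GenotypePanel

logging.getLogger("heritagescan").setLevel(logging.ERROR)


def make_panel(doses, chroms=None, positions=None, freqs=None, sample_ids=None):
    """Build a small panel from a dose matrix (rows = samples)."""
    doses = np.asarray(doses, dtype=float)
    n, m = doses.shape
    chroms = [1] * m if chroms is None else chroms
    positions = list(range(1, m + 1)) if positions is None else positions
    variants = pd.DataFrame(
        {
            "id": [f"m{i}" for i in range(m)],
            "chrom": chroms,
            "pos": positions,
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    ids = sample_ids or [f"s{j}" for j in range(n)]
    samples = pd.DataFrame({"id": ids})
    return GenotypePanel(variants=variants, samples=samples, doses=doses)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def grm_brute_force(doses, p):
    """Independent double-loop evaluation of the frequency-weighted
    relationship estimator, pairwise-complete over missing data."""
    n, m = doses.shape
    G = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            terms = []
            for i in range(m):
                xj, xk, pi = doses[j, i], doses[k, i], p[i]
                if np.isnan(xj) or np.isnan(xk) or not (0 < pi < 1):
                    continue
                if j == k:
                    terms.append(
                        1 + (xj**2 - (1 + 2 * pi) * xj + 2 * pi**2) / (2 * pi * (1 - pi))
                    )
                else:
                    terms.append((xj - 2 * pi) * (xk - 2 * pi) / (2 * pi * (1 - pi)))
            G[j, k] = np.mean(terms) if terms else 0.0
    return G


def hudson_fst(p1, n1, p2, n2):
    """Hudson's FST estimator (ratio of averages) from sample frequencies."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return np.nanmean(num) / np.nanmean(den)
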