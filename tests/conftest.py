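import numpy as np
import pandas as pd
import pytest

from barrisk.genotypes import GenotypeMatrix, RiskLocus


@pytest.fixture
def panel():
    """A three-SNP risk panel with one protective allele."""
    return [
        RiskLocus("rs1", "T", "C", 2.0),
        RiskLocus("rs2", "A", "G", 0.5),
        RiskLocus("rs3", "G", "A", 3.0),
    ]


@pytest.fixture
def cohort(panel):
    """Six samples in two groups with one missing genotype."""
    dosage = pd.DataFrame(
        {
            "rs1": [2.0, 1.0, 0.0, 1.0, 0.0, 2.0],
            "rs2": [1.0, 0.0, 2.0, np.nan, 1.0, 0.0],
            "rs3": [0.0, 0.0, 1.0, 2.0, 1.0, 1.0],
        },
        index=[f"s{i}" for i in range(6)],
    )
    groups = {f"s{i}": ("case" if i < 3 else "control") for i in range(6)}
    return GenotypeMatrix(dosage, panel, groups)


def brute_force_mannwhitney_p(x, y):
    """Exact two-sided Mann-Whitney p by enumeration of all label assignments."""
    from itertools import combinations

    pooled = list(x) + list(y)
    n = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    observed = u_stat(x, y)
    mid = len(x) * len(y) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mid) >= abs(observed - mid) - 1e-12:
            count += 1
    return count / total


def brute_force_bh(p):
    """Benjamini-Hochberg q-values: sort, p*m/rank, cummin from largest rank."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def brute_force_hypergeom_upper(k, universe_size, set_size, draw_size):
    """P(overlap >= k) by exhaustive enumeration over all draws."""
    from itertools import combinations
    from math import comb

    hits = sum(
        1
        for draw in combinations(range(universe_size), draw_size)
        if sum(1 for g in draw if g < set_size) >= k
    )
    return hits / comb(universe_size, draw_size)
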