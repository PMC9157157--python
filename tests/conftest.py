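"""Shared fixtures: tiny in-memory experiments and exact-test oracles."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from stressase.types import CountMatrix


def make_samples(spec: list[tuple[str, str, str, int]]) -> pd.DataFrame:
    """Build a sample sheet from (genotype, tissue, condition, replicate) tuples."""
    rows = []
    for geno, tissue, cond, rep in spec:
        rows.append(
            {
                "sample_id": f"{geno}_{tissue}_{cond}_{rep}",
                "genotype": geno,
                "tissue": tissue,
                "condition": cond,
                "replicate": rep,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def make_cm(counts: dict[str, list[int]], samples: pd.DataFrame, genes=None) -> CountMatrix:
    n = len(next(iter(counts.values())))
    genes = genes or [f"g{i}" for i in range(n)]
    table = pd.DataFrame(counts, index=genes)[list(samples.index)]
    return CountMatrix(table, samples)


@pytest.fixture
def b6_liver_sheet() -> pd.DataFrame:
    return make_samples(
        [("B6", "liver", "control", r) for r in (1, 2, 3)]
        + [("B6", "liver", "TM", r) for r in (1, 2, 3)]
    )


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher p by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with a tiny
    relative tolerance for ties).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    probs = {x: comb(r1, x) * comb(r2, c1 - x) / denom for x in support}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


def bh_oracle(pvalues: np.ndarray) -> np.ndarray:
    """Brute-force BH: sort, scale by m/rank, cumulative min from the top."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def hypergeom_overlap_oracle(universe_n: int, na: int, nb: int, k: int) -> float:
    """P(overlap >= k) by direct enumeration over all possible overlaps."""
    denom = comb(universe_n, nb)
    total = 0
    for x in range(k, min(na, nb) + 1):
        if universe_n - na >= nb - x:
            total += comb(na, x) * comb(universe_n - na, nb - x)
    return total / denom
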