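"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately naive (explicit loops,
closed-form summation) and independent of the code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from zdat import ContrastSpec, ExpressionMatrix, SimConfig, ZMatrix, simulate


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up.

    For the i-th smallest p (rank r = i+1), the adjusted value is
    min over ranks j ≥ r of p_(j)·m/j, capped at 1 — evaluated literally.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        candidates = [sorted_p[j] * m / (j + 1) for j in range(i, m)]
        adj_sorted[i] = min(1.0, min(candidates))
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P[X ≥ k] for X ~ Hypergeom(N, K, n) by explicit summation of
    exact binomial-coefficient terms."""
    from math import comb

    if k <= 0:
        return 1.0
    total = 0
    denom = comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += comb(K, i) * comb(N - K, n - i)
    return total / denom


def two_sample_z_oracle(x1, x2) -> float:
    """Textbook unequal-variance two-sample z computed step by step."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    m1, m2 = x1.mean(), x2.mean()
    v1 = ((x1 - m1) ** 2).sum() / (len(x1) - 1)
    v2 = ((x2 - m2) ** 2).sum() / (len(x2) - 1)
    return (m1 - m2) / np.sqrt(v1 / len(x1) + v2 / len(x2))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale generator settings for fast unit tests."""
    return SimConfig(n_probes=400, n_per_group=(10, 10), n_sets=12,
                     set_size=8, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One small simulated dataset shared across read-only tests."""
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_contrast_spec(small_dataset) -> ContrastSpec:
    _, meta, _, _, _ = small_dataset
    return ContrastSpec(meta.samples_in_group("acute"),
                        meta.samples_in_group("convalescent"))


def make_zmatrix(z_values, probe_ids=None, sample_ids=None) -> ZMatrix:
    """Wrap a raw array as a ZMatrix (log_intensities mirrors z)."""
    z_values = np.asarray(z_values, dtype=float)
    probes = probe_ids or [f"p{i}" for i in range(z_values.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(z_values.shape[1])]
    frame = pd.DataFrame(z_values, index=probes, columns=samples)
    return ZMatrix(z=frame, log_intensities=frame.copy())


def make_expression(values, probe_ids=None, sample_ids=None,
                    detected=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probes = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    intens = pd.DataFrame(values, index=probes, columns=samples)
    if detected is None:
        det = intens > 0
    else:
        det = pd.DataFrame(np.asarray(detected, dtype=bool), index=probes,
                           columns=samples)
    return ExpressionMatrix(intens, det)
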