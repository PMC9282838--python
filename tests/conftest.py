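"""Shared fixtures: small synthetic clocks, references, zero-noise cohorts,
and an independent simplex-grid oracle for the deconvolution solver."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import dsclocks as d


@pytest.fixture(scope="session")
def small_clock():
    return d.generate_synthetic_clock(12, "calibrated-adult", seed=11, name="sb")


@pytest.fixture(scope="session")
def gest_clock():
    return d.generate_synthetic_clock(10, "linear-days", seed=12, name="ga")


@pytest.fixture(scope="session")
def reference30():
    return d.generate_cell_reference(30, seed=7)


def make_cohort(seed=5, n_ds=60, n_non_ds=80, clocks=None, reference=None, **overrides):
    """Small cohort with both noise sources off unless overridden."""
    overrides.setdefault("noise_sd_beta", 0.0)
    overrides.setdefault("noise_sd_clock_years", 0.0)
    overrides.setdefault("noise_sd_log2", 0.0)
    overrides.setdefault("mosaic_fraction_values", (0.3, 0.4))
    cfg = d.SimulationConfig(n_ds=n_ds, n_non_ds=n_non_ds, seed=seed, **overrides)
    clocks = clocks or [d.generate_synthetic_clock(12, "calibrated-adult", 11, name="sb"),
                        d.generate_synthetic_clock(10, "linear-days", 12, name="ga")]
    reference = reference or d.generate_cell_reference(30, seed=7)
    betas, sheet, bins, truth = d.generate_cohort(cfg, clocks, reference)
    return cfg, clocks, reference, betas, sheet, bins, truth


@pytest.fixture(scope="session")
def zero_noise_cohort():
    return make_cohort()


def simplex_grid_best(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Grid-search oracle on the 7-simplex at 0.01 resolution.

    Enumerates the full simplex at step 0.05, then refines at 0.01 in a
    +/-0.05 box around the coarse optimum.  Independent of the NNLS path.
    A is cell-by-CpG, y the sample's beta vector; returns the best weight
    vector (summing to 1).
    """
    k = A.shape[0]

    def best_of(points: np.ndarray) -> np.ndarray:
        resid = points @ A - y[None, :]
        return points[np.argmin(np.einsum("ij,ij->i", resid, resid))]

    # coarse: compositions of 20 into k parts (step 0.05)
    total = 20
    combos = itertools.combinations(range(total + k - 1), k - 1)
    dividers = np.array(list(combos))
    bounds = np.hstack([
        np.full((len(dividers), 1), -1), dividers,
        np.full((len(dividers), 1), total + k - 1),
    ])
    coarse = (np.diff(bounds, axis=1) - 1) / total
    w0 = best_of(coarse)

    # refine: step 0.01 within +/-0.05 of the coarse optimum
    lo = np.maximum(0, np.round(w0 * 100).astype(int) - 5)
    hi = np.minimum(100, np.round(w0 * 100).astype(int) + 5)
    axes = [np.arange(l, h + 1, dtype=np.int16) for l, h in zip(lo[:-1], hi[:-1])]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, k - 1)
    last = 100 - mesh.sum(axis=1)
    ok = (last >= lo[-1]) & (last <= hi[-1])
    fine = np.hstack([mesh[ok], last[ok, None]]).astype(float) / 100.0
    if not len(fine):
        return w0
    return best_of(fine)
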