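"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results by brute force (explicit
double loops, local-extremum bracketing, literal re-analysis) so that the
vectorized implementations are checked against an independent path.
"""
from __future__ import annotations

import numpy as np
import pytest

from hetscan.io import HET, HOM, MISSING, GenotypeMatrix
from hetscan.simulate import SimConfig, simulate_cohort
from hetscan.stage1 import WindowConfig, compute_htrack


# --------------------------------------------------------------------------
# oracle implementations (independent of the package's vectorized paths)
# --------------------------------------------------------------------------

def brute_force_window_counts(calls: np.ndarray, i: int, m: int) -> tuple[int, int]:
    """Explicit double loop over the (2m+1) x n_samples window cells."""
    g = h = 0
    for row in calls[i - m : i + m + 1]:
        for v in row:
            if v == HOM:
                g += 1
            elif v == HET:
                h += 1
    return g, h


def collapse_runs(H) -> list[tuple[float, int, int]]:
    """(value, first_index, last_index) for maximal runs of equal H."""
    runs = []
    start = 0
    for i in range(1, len(H)):
        if H[i] != H[start]:
            runs.append((H[start], start, i - 1))
            start = i
    runs.append((H[start], start, len(H) - 1))
    return runs


def bracket_segments(H) -> list[tuple[int, int]]:
    """Independent rise-then-fall segmentation by local-extremum bracketing.

    Collapses plateaus into single points, finds every interior local
    maximum, and extends it to the flanking local minima.  A valley shared
    by two segments belongs to the earlier one (the later segment starts one
    variant further right), keeping raw index ranges disjoint.
    """
    runs = collapse_runs(H)
    M = len(runs)
    segs: list[tuple[int, int]] = []
    prev_end = -1
    for j in range(1, M - 1):
        if runs[j - 1][0] < runs[j][0] > runs[j + 1][0]:
            a = j - 1
            while a > 0 and runs[a - 1][0] < runs[a][0]:
                a -= 1
            b = j + 1
            while b < M - 1 and runs[b + 1][0] < runs[b][0]:
                b += 1
            start = runs[a][2]  # last variant of the valley run
            end = runs[b][1]  # first variant of the closing valley run
            if start == prev_end:
                start += 1
            segs.append((start, end))
            prev_end = end
    return segs


# --------------------------------------------------------------------------
# matrix / cohort fixtures
# --------------------------------------------------------------------------

def make_matrix(classes: np.ndarray, chrom: str = "chr1", start: int = 1000,
                step: int = 100, samples: list[str] | None = None) -> GenotypeMatrix:
    """GenotypeMatrix from a (n_sites, n_samples) class array on one chromosome."""
    classes = np.asarray(classes, dtype=np.int8)
    if classes.ndim == 1:
        classes = classes[:, None]
    n, k = classes.shape
    return GenotypeMatrix(
        chrom=np.full(n, chrom, dtype=object),
        pos=start + step * np.arange(n, dtype=np.int64),
        ids=np.full(n, ".", dtype=object),
        samples=samples or [f"s{j}" for j in range(k)],
        calls=classes,
    )


def random_class_matrix(rng: np.random.Generator, n: int, k: int,
                        p=(0.55, 0.4, 0.05)) -> np.ndarray:
    return rng.choice([int(HOM), int(HET), int(MISSING)], size=(n, k), p=p).astype(np.int8)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (3 carriers + 3 noncarriers), with truth."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def carrier_scan(default_cohort):
    """Pooled-carrier Stage-1 track of the default cohort."""
    matrix, truth = default_cohort
    carriers = [s for s, c in truth.carrier_status.items() if c]
    track = compute_htrack(matrix.subset_samples(carriers), WindowConfig(m=50))
    return track, truth


@pytest.fixture(scope="session")
def null_track():
    """Stage-1 track of a no-carrier (pure Hardy-Weinberg) cohort."""
    matrix, _ = simulate_cohort(
        SimConfig(n_carriers=0, n_noncarriers=4, n_chromosomes=2, seed=7)
    )
    return compute_htrack(matrix, WindowConfig(m=50))
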