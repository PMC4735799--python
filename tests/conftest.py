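"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the library code paths they check:
cluster merging is decided from ground-truth pixel coordinates by brute-force
Chebyshev distances, and re-activation onset by a literal scan of its
definition on the mean curve.
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ligandswitch import default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture
def minute_grid():
    return np.arange(0.0, 61.0, 1.0)


# --------------------------------------------------------------------------
# brute-force clustering oracle
# --------------------------------------------------------------------------

def _shifted(mask, dr, dc, fill):
    out = np.full_like(mask, fill)
    rows = slice(max(dr, 0), mask.shape[0] + min(dr, 0))
    cols = slice(max(dc, 0), mask.shape[1] + min(dc, 0))
    src_rows = slice(max(-dr, 0), mask.shape[0] + min(-dr, 0))
    src_cols = slice(max(-dc, 0), mask.shape[1] + min(-dc, 0))
    out[rows, cols] = mask[src_rows, src_cols]
    return out


def naive_open(mask):
    """3x3 opening written from the definition: erosion keeps a pixel iff all
    nine neighbors are foreground, dilation is the union of nine shifts."""
    shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
    eroded = np.logical_and.reduce(
        [_shifted(mask, dr, dc, False) for dr, dc in shifts])
    return np.logical_or.reduce(
        [_shifted(eroded, dr, dc, False) for dr, dc in shifts])


def opened_disk_pixels(center, radius, shape):
    """Pixel coordinates of a rasterized disk after 3x3 opening (the
    footprint the segmentation pipeline sees for an isolated nucleus)."""
    r0, c0 = center
    pad = radius + 2
    rr, cc = np.mgrid[-pad:pad + 1, -pad:pad + 1]
    local = naive_open(rr**2 + cc**2 <= radius**2)
    coords = np.column_stack(np.nonzero(local)) - pad + np.array([r0, c0])
    keep = ((coords[:, 0] >= 0) & (coords[:, 0] < shape[0])
            & (coords[:, 1] >= 0) & (coords[:, 1] < shape[1]))
    return coords[keep]


def oracle_counts(centers, radius, shape, dilate_px):
    """Ground-truth N0 and N5 from nucleus geometry alone (valid when nuclei
    do not overlap, so per-nucleus opening equals opening of the union).

    Two pixel sets A, B become one 8-connected object after each is dilated
    by d (Chebyshev balls) iff min Chebyshev distance between them is at most
    2d + 1.  N0 uses d = 0 (overlap/touch), N5 uses d = dilate_px.  Component
    counting is done by union-find over the merge graph.
    """
    pix = [opened_disk_pixels(c, radius, shape) for c in centers]
    n = len(pix)

    def components(max_dist):
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if cdist(pix[i], pix[j], metric="chebyshev").min() <= max_dist:
                    parent[find(i)] = find(j)
        return len({find(i) for i in range(n)})

    return components(1), components(2 * dilate_px + 1)


# --------------------------------------------------------------------------
# brute-force onset oracle
# --------------------------------------------------------------------------

def oracle_onset(times, mean_signal, rise_fraction=0.2):
    """Literal scan of the onset definition: global peak, post-peak trough,
    first post-trough time strictly above trough + f*(peak - trough) that
    stays above it at the next sample (last sample counts as sustained)."""
    y = np.asarray(mean_signal, float)
    peak = int(np.argmax(y))
    if peak == len(y) - 1:
        return None
    trough = peak + int(np.argmin(y[peak:]))
    if trough == len(y) - 1:
        return None
    thresh = y[trough] + rise_fraction * (y[peak] - y[trough])
    for i in range(trough + 1, len(y)):
        if y[i] > thresh and (i == len(y) - 1 or y[i + 1] > thresh):
            return float(times[i])
    return None
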