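"""Shared fixtures and independent oracle helpers.

The oracles here deliberately re-derive results by the most direct route
possible (per-pixel line tests, all-pairs distances, exhaustive sign
enumeration) so they stay independent of the vectorized implementation
paths they check.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from scipy.stats import rankdata

from iansegmap import PhantomParams, ReferenceSlice, generate_subject_side
from iansegmap.geometry import SegmentPartition


@pytest.fixture(scope="session")
def noiseless_subject():
    """Default phantom, zero noise: every stage has an exact reference."""
    params = PhantomParams(noise_sd=0.0, seed=11)
    return generate_subject_side(params)


@pytest.fixture(scope="session")
def default_subject():
    params = PhantomParams(seed=5)
    return generate_subject_side(params)


def random_ellipse_slice(rng: np.random.Generator, spacing: float = 0.15) -> ReferenceSlice:
    """A random elliptical canal mask with valid interior landmarks."""
    a = rng.uniform(1.2, 3.0)
    b = rng.uniform(1.2, 3.0)
    angle = rng.uniform(0, np.pi)
    margin = 1.0
    W = H0 = 2 * (max(a, b) + margin)
    crest_gap = rng.uniform(3.0, 6.0)
    H = H0 + crest_gap
    cx, cy = W / 2, crest_gap + H0 / 2
    ny, nx = int(np.ceil(H / spacing)), int(np.ceil(W / spacing))
    x = (np.arange(nx) + 0.5) * spacing
    y = (np.arange(ny) + 0.5) * spacing
    X, Y = np.meshgrid(x, y)
    ca, sa = np.cos(angle), np.sin(angle)
    u = (X - cx) * ca + (Y - cy) * sa
    v = -(X - cx) * sa + (Y - cy) * ca
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    # nerve midpoint strictly inside, crest above the mask
    ox = rng.uniform(-0.4, 0.4) * min(a, b)
    oy = rng.uniform(-0.4, 0.4) * min(a, b)
    return ReferenceSlice(
        image=np.zeros_like(mask, dtype=float),
        spacing=(spacing, spacing),
        side=str(rng.choice(["left", "right"])),
        site=str(rng.choice(["M3", "M2"])),
        crest_mm=(cx + rng.uniform(-1, 1), rng.uniform(0.2, 0.8)),
        nerve_midpoint_mm=(cx + ox, cy + oy),
        iac_mask=mask,
        baseline_angle_deg=float(rng.uniform(-10, 10)),
    )


def brute_force_labels(slc: ReferenceSlice, part: SegmentPartition) -> np.ndarray:
    """Per-pixel three-line classification applied directly, pixel by pixel.

    Uses only the construction lines the partition reports: the side of the
    midline containing the crest is superior; the buccal/lingual thirds are
    delimited by the two perpendicular foot points along the buccal
    direction.  Ties go inferior-ward / middle-ward.
    """
    hy, hx = slc.spacing
    mx, my = part.midline.point
    dx, dy = part.midline.direction
    bx, by = part.buccal_direction
    p1x, p1y = part.perpendicular_1.point  # lingual cut
    p2x, p2y = part.perpendicular_2.point  # buccal cut
    crest_cross = dx * (slc.crest_mm[1] - my) - dy * (slc.crest_mm[0] - mx)
    sup_sign = 1.0 if crest_cross > 0 else -1.0
    eps = 1e-6  # shared on-line tie convention, mm

    labels = np.zeros(slc.iac_mask.shape, dtype=np.int8)
    for r, c in np.argwhere(slc.iac_mask):
        x, y = (c + 0.5) * hx, (r + 0.5) * hy
        cross = dx * (y - my) - dy * (x - mx)
        superior = sup_sign * cross > eps
        buccal = (x - p2x) * bx + (y - p2y) * by > eps
        lingual = (x - p1x) * bx + (y - p1y) * by < -eps
        col = 0 if buccal else (2 if lingual else 1)
        labels[r, c] = (1 if superior else 4) + col
    return labels


def feret_oracle(mask2d: np.ndarray, spacing: tuple[float, float]) -> float:
    """All-pairs maximum distance between boundary-pixel centers, plus 1 px."""
    from scipy import ndimage
    from scipy.spatial.distance import cdist

    boundary = mask2d & ~ndimage.binary_erosion(mask2d)
    pts = np.argwhere(boundary).astype(float) * np.asarray(spacing)
    if len(pts) == 1:
        return float(np.mean(spacing))
    return float(cdist(pts, pts).max()) + float(np.mean(spacing))


def wilcoxon_enumeration_p(diffs) -> float:
    """Two-sided signed-rank p by exhaustive 2^n sign enumeration (no ties)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    n = len(d)
    total = n * (n + 1) / 2
    t_plus = ranks[d > 0].sum()
    t_min = min(t_plus, total - t_plus)
    count = 0
    for signs in product((0, 1), repeat=n):
        T = sum(r for r, s in zip(ranks, signs) if s)
        if T <= t_min or T >= total - t_min:
            count += 1
    return count / 2**n
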