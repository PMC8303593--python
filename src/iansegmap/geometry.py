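"""Six-segment partition of the inferior alveolar canal cross-section.

On the coronal reference slice, a "horizontal" baseline is placed through the
alveolar crest of the buccal cortical plate and a parallel midline through the
midpoint of the inferior alveolar nerve (IAN).  The chord that the midline
cuts through the canal mask — the intraosseous diameter of the canal — is
divided into three equal thirds by two perpendiculars, yielding six segments:

    1 upper buccal   2 upper middle   3 upper lingual
    4 lower buccal   5 lower middle   6 lower lingual

Coordinate conventions (documented for cross-language ports):

* slice arrays are indexed ``[row, col]`` with rows running superior→inferior
  and columns along the buccolingual axis;
* physical coordinates are ``(x, y)`` in mm with ``x = (col + 0.5) * spacing``
  and ``y = (row + 0.5) * spacing`` — origin at the slice corner, pixel
  positions at pixel centers;
* for a ``left`` side the buccal direction is +x, for ``right`` it is -x
  (slices are stored un-mirrored; :func:`mirror_partition` maps between them).

Tie-break conventions (deterministic tiling): a pixel exactly on the midline
belongs to the inferior band; a pixel exactly on a perpendicular belongs to
the middle column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, LandmarkError, ShapeError

SEGMENT_NAMES = {
    1: "upper buccal",
    2: "upper middle",
    3: "upper lingual",
    4: "lower buccal",
    5: "lower middle",
    6: "lower lingual",
}

#: supported rules for placing the two perpendiculars along the midline
PARTITION_RULES = ("chord-thirds", "bbox-thirds")

#: tie tolerance for the half-open line conventions, in mm.  A point within
#: this distance of a dividing line counts as *on* it (midline ties go
#: inferior-ward, perpendicular ties middle-ward); 1e-6 mm is a million times
#: below any pixel size used here, so only exact geometric ties are affected.
TIE_EPS_MM = 1e-6


@dataclass(frozen=True)
class Line:
    """An infinite 2D line given by a point (mm) and a unit direction."""

    point: tuple[float, float]
    direction: tuple[float, float]


@dataclass
class ReferenceSlice:
    """A single coronal slice with the landmarks needed for partitioning.

    Parameters
    ----------
    image:
        2D intensity array, rows superior→inferior, columns buccolingual.
    spacing:
        (row_mm, col_mm) pixel spacing.
    side, site:
        ``"left"``/``"right"`` and ``"M3"``/``"M2"``.
    crest_mm, nerve_midpoint_mm:
        Landmark positions ``(x, y)`` in mm (alveolar crest of the buccal
        cortical plate; midpoint of the IAN).
    iac_mask:
        Boolean canal mask on the same grid.
    baseline_angle_deg:
        Orientation of the "horizontal" baseline relative to the image row
        direction (0 = image rows).
    """

    image: np.ndarray
    spacing: tuple[float, float]
    side: str
    site: str
    crest_mm: tuple[float, float]
    nerve_midpoint_mm: tuple[float, float]
    iac_mask: np.ndarray
    baseline_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.iac_mask = np.asarray(self.iac_mask, dtype=bool)
        if self.image.shape != self.iac_mask.shape:
            raise ShapeError(
                f"image {self.image.shape} and iac_mask {self.iac_mask.shape} differ"
            )
        if self.side not in ("left", "right"):
            raise LandmarkError(f"side must be left/right, got {self.side!r}")
        if not self.iac_mask.any():
            raise LandmarkError("iac_mask is empty")
        hy, hx = self.spacing
        if hy <= 0 or hx <= 0:
            raise ShapeError("spacing must be strictly positive")
        r, c = self._point_to_pixel(self.nerve_midpoint_mm)
        inside = (
            0 <= r < self.iac_mask.shape[0]
            and 0 <= c < self.iac_mask.shape[1]
            and self.iac_mask[r, c]
        )
        if not inside:
            raise LandmarkError("nerve midpoint does not lie inside the IAC mask")
        rows = np.nonzero(self.iac_mask)[0]
        crest_y = self.crest_mm[1]
        if crest_y >= (rows.min() + 0.5) * hy:
            raise LandmarkError("crest point must be superior to the IAC mask")

    def _point_to_pixel(self, point_mm: tuple[float, float]) -> tuple[int, int]:
        hy, hx = self.spacing
        return int(np.floor(point_mm[1] / hy)), int(np.floor(point_mm[0] / hx))

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate grids in mm."""
        hy, hx = self.spacing
        ny, nx = self.iac_mask.shape
        x = (np.arange(nx) + 0.5) * hx
        y = (np.arange(ny) + 0.5) * hy
        return np.meshgrid(x, y)

    @property
    def width_mm(self) -> float:
        return self.iac_mask.shape[1] * self.spacing[1]


@dataclass
class SegmentPartition:
    """The six disjoint segment masks plus the construction lines."""

    label_map: np.ndarray  # int8, 0 outside the canal, 1..6 inside
    spacing: tuple[float, float]
    side: str
    baseline: Line
    midline: Line
    perpendicular_1: Line  # lingual-third cut
    perpendicular_2: Line  # buccal-third cut
    buccal_direction: tuple[float, float]
    chord_mm: tuple[float, float]  # chord interval in buccal coordinates
    rule: str = "chord-thirds"

    @property
    def segment_masks(self) -> dict[int, np.ndarray]:
        return {s: self.label_map == s for s in range(1, 7)}

    @property
    def iac_mask(self) -> np.ndarray:
        return self.label_map > 0

    def areas_mm2(self) -> dict[int, float]:
        px = self.spacing[0] * self.spacing[1]
        return {s: float(np.count_nonzero(self.label_map == s)) * px for s in range(1, 7)}

    def pixel_counts(self) -> dict[int, int]:
        return {s: int(np.count_nonzero(self.label_map == s)) for s in range(1, 7)}


def _axes(baseline_angle_deg: float, side: str) -> tuple[np.ndarray, np.ndarray]:
    """Unit buccal direction and superior normal for the given baseline angle."""
    th = np.deg2rad(baseline_angle_deg)
    u = np.array([np.cos(th), np.sin(th)])  # along-baseline, image x at angle 0
    superior = np.array([np.sin(th), -np.cos(th)])  # -y is superior at angle 0
    buccal = u if side == "left" else -u
    return buccal, superior


def classify_segments(
    x: np.ndarray,
    y: np.ndarray,
    nerve_midpoint_mm: tuple[float, float],
    buccal: np.ndarray,
    superior: np.ndarray,
    cut_lingual: float,
    cut_buccal: float,
) -> np.ndarray:
    """Vectorized 6-way classification of points given the constructed lines.

    ``cut_lingual < cut_buccal`` are the two perpendicular positions in the
    buccal along-midline coordinate ``t``.  Ties: ``s == 0`` goes inferior,
    ``t == cut`` goes middle.
    """
    dx = np.asarray(x) - nerve_midpoint_mm[0]
    dy = np.asarray(y) - nerve_midpoint_mm[1]
    s = dx * superior[0] + dy * superior[1]
    t = dx * buccal[0] + dy * buccal[1]
    base = np.where(s > TIE_EPS_MM, 1, 4)
    lateral = np.full(np.shape(t), 1, dtype=np.int8)  # middle column offset
    lateral[t > cut_buccal + TIE_EPS_MM] = 0
    lateral[t < cut_lingual - TIE_EPS_MM] = 2
    return (base + lateral).astype(np.int8)


def build_partition(slc: ReferenceSlice, rule: str = "chord-thirds") -> SegmentPartition:
    """Construct the six-segment partition of ``slc.iac_mask``.

    The midline chord — the canal's intraosseous diameter along the line
    through the nerve midpoint — is split into three equal thirds by the two
    perpendiculars (``rule="chord-thirds"``, default).  ``rule="bbox-thirds"``
    instead splits the full extent of the mask projected onto the baseline
    direction.

    Raises
    ------
    LandmarkError
        If the slice landmarks violate their invariants (checked on
        construction of :class:`ReferenceSlice`).
    GeometryError
        If the midline chord through the mask is empty.
    """
    if rule not in PARTITION_RULES:
        raise GeometryError(f"unknown partition rule {rule!r}")
    buccal, superior = _axes(slc.baseline_angle_deg, slc.side)
    nm = np.asarray(slc.nerve_midpoint_mm, dtype=float)

    X, Y = slc.pixel_centers_mm()
    mask = slc.iac_mask
    dx = X[mask] - nm[0]
    dy = Y[mask] - nm[1]
    s = dx * superior[0] + dy * superior[1]
    t = dx * buccal[0] + dy * buccal[1]

    if rule == "chord-thirds":
        # tiny slack so centers exactly half a pixel off the line still count
        half = 0.5 * max(slc.spacing) * (1.0 + 1e-9)
        on_chord = np.abs(s) <= half
        if not on_chord.any():
            raise GeometryError("midline chord through the IAC mask is empty")
        t_min, t_max = float(t[on_chord].min()), float(t[on_chord].max())
    else:  # bbox-thirds
        t_min, t_max = float(t.min()), float(t.max())
    if t_max <= t_min:
        raise GeometryError("degenerate midline chord (zero length)")
    span = t_max - t_min
    cut_lingual = t_min + span / 3.0
    cut_buccal = t_min + 2.0 * span / 3.0

    labels_in = classify_segments(
        X[mask], Y[mask], tuple(nm), buccal, superior, cut_lingual, cut_buccal
    )
    label_map = np.zeros(mask.shape, dtype=np.int8)
    label_map[mask] = labels_in

    along = tuple(buccal)  # baseline/midline direction (sign irrelevant for a line)
    perp = tuple(superior)
    crest = tuple(np.asarray(slc.crest_mm, dtype=float))
    p1 = tuple(nm + cut_lingual * buccal)
    p2 = tuple(nm + cut_buccal * buccal)
    return SegmentPartition(
        label_map=label_map,
        spacing=slc.spacing,
        side=slc.side,
        baseline=Line(crest, along),
        midline=Line(tuple(nm), along),
        perpendicular_1=Line(p1, perp),
        perpendicular_2=Line(p2, perp),
        buccal_direction=tuple(buccal),
        chord_mm=(t_min, t_max),
        rule=rule,
    )


def mirror_partition(p: SegmentPartition, width_mm: float | None = None) -> SegmentPartition:
    """Mirror a partition across the buccolingual axis, swapping the side.

    Segment labels keep their anatomical meaning (1/4 buccal, 3/6 lingual);
    only the raster and the construction lines are reflected.  Applying the
    operation twice restores the input exactly (involution).
    """
    if width_mm is None:
        width_mm = p.label_map.shape[1] * p.spacing[1]

    def mirror_point(pt: tuple[float, float]) -> tuple[float, float]:
        return (width_mm - pt[0], pt[1])

    def mirror_dir(d: tuple[float, float]) -> tuple[float, float]:
        return (-d[0], d[1])

    def mirror_line(ln: Line) -> Line:
        return Line(mirror_point(ln.point), mirror_dir(ln.direction))

    return replace(
        p,
        label_map=p.label_map[:, ::-1].copy(),
        side="right" if p.side == "left" else "left",
        baseline=mirror_line(p.baseline),
        midline=mirror_line(p.midline),
        perpendicular_1=mirror_line(p.perpendicular_1),
        perpendicular_2=mirror_line(p.perpendicular_2),
        buccal_direction=mirror_dir(p.buccal_direction),
    )
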