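"""Per-segment nerve occupancy scoring and co-occurrence tables.

A segment counts as *visible* (nerve-occupied) when at least half of its area
contains hyperintense nerve signal — the threshold is inclusive at exactly
one half.  Scoring is performed on the single coronal reference slice;
"segment volume" is therefore a 2D area.

The marginal table gives, per segment, the percentage of evaluated nerves in
which the segment was visible ("Generally Yes"); the conditional table gives,
for each ordered pair (i, j), the percentage of nerves with segment *j*
visible among those with segment *i* visible ("If Segment i Yes").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError, SegmentationError, ShapeError
from .geometry import ReferenceSlice, SegmentPartition

N_SEGMENTS = 6


@dataclass
class OccupancyRecord:
    """Fill fractions and visibility flags for one nerve at one site."""

    subject_id: str
    side: str
    site: str
    fractions: np.ndarray  # six values in [0, 1]
    visible: np.ndarray  # six booleans
    threshold: float = 0.5
    retention_label: str = "unknown"
    empty_segments: np.ndarray = field(
        default_factory=lambda: np.zeros(N_SEGMENTS, dtype=bool)
    )

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.fractions.shape != (N_SEGMENTS,) or self.visible.shape != (N_SEGMENTS,):
            raise ShapeError("fractions and visible must have six entries")
        if not np.all(np.isfinite(self.fractions)):
            raise ShapeError("fractions must be finite")


@dataclass
class CooccurrenceTable:
    """Marginal and conditional visibility percentages for one site."""

    site: str
    n_records: int
    marginal: np.ndarray  # six percentages
    conditional: np.ndarray  # 6x6, row i = "If Segment i Yes"; diagonal NaN
    counts: np.ndarray  # 6x6 joint visibility counts; diagonal = marginal counts
    stratum: str = "pooled"

    def to_frame(self, decimals: int | None = 1) -> pd.DataFrame:
        """Tabular layout: 'Generally Yes' row plus six 'If Segment i Yes' rows."""
        cols = [f"Segment {j}" for j in range(1, 7)]
        rows = {"Generally Yes": self.marginal}
        for i in range(N_SEGMENTS):
            rows[f"If Segment {i + 1} Yes"] = self.conditional[i]
        df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        if decimals is not None:
            df = df.round(decimals)
        df.insert(0, "n", self.n_records)
        return df


def score_occupancy(
    partition: SegmentPartition,
    nerve_mask: np.ndarray,
    threshold: float = 0.5,
    *,
    subject_id: str = "",
    side: str | None = None,
    site: str = "M3",
    retention_label: str = "unknown",
) -> OccupancyRecord:
    """Score the fraction of each segment covered by ``nerve_mask``.

    ``fraction_s = |nerve ∧ segment_s| / |segment_s|``; a segment is visible
    when its fraction is at least ``threshold`` (inclusive).  Empty segments
    score 0 and are flagged in ``empty_segments``.
    """
    nerve_mask = np.asarray(nerve_mask, dtype=bool)
    if nerve_mask.shape != partition.label_map.shape:
        raise ShapeError(
            f"nerve mask {nerve_mask.shape} does not match partition grid "
            f"{partition.label_map.shape}"
        )
    if not (0.0 < threshold <= 1.0):
        raise InputError("threshold must lie in (0, 1]")
    seg_area = np.bincount(partition.label_map.ravel(), minlength=7)[1:7]
    overlap = np.bincount(
        partition.label_map.ravel(), weights=nerve_mask.ravel(), minlength=7
    )[1:7]
    empty = seg_area == 0
    fractions = np.zeros(N_SEGMENTS)
    np.divide(overlap, seg_area, out=fractions, where=~empty)
    visible = fractions >= threshold
    visible[empty] = False
    return OccupancyRecord(
        subject_id=subject_id,
        side=side if side is not None else partition.side,
        site=site,
        fractions=fractions,
        visible=visible,
        threshold=threshold,
        retention_label=retention_label,
        empty_segments=empty,
    )


def extract_nerve_mask(
    slc: ReferenceSlice,
    *,
    background_percentile: float = 20.0,
    peak_percentile: float = 98.0,
    min_contrast_frac: float = 0.15,
) -> np.ndarray:
    """Extract the hyperintense IAN mask on an MRI reference slice.

    The threshold is the midpoint between the canal-interior background level
    (``background_percentile`` of intensities inside the canal mask) and the
    nerve peak (``peak_percentile``).  Of the resulting supra-threshold
    pixels the connected component containing the nerve midpoint is returned.

    Raises
    ------
    SegmentationError
        If the canal interior shows no usable nerve contrast, or no
        supra-threshold component contains the nerve midpoint.  Callers are
        expected to exclude (and log) such records rather than impute them.
    """
    vals = slc.image[slc.iac_mask].astype(float)
    bg = np.percentile(vals, background_percentile)
    peak = np.percentile(vals, peak_percentile)
    lo, hi = np.percentile(slc.image.astype(float), [1.0, 99.0])
    global_range = max(hi - lo, np.finfo(float).tiny)
    if (peak - bg) < min_contrast_frac * global_range:
        raise SegmentationError(
            "no nerve contrast inside the canal "
            f"(in-mask spread {peak - bg:.4g} vs slice range {global_range:.4g})"
        )
    thr = 0.5 * (bg + peak)
    hyper = (slc.image >= thr) & slc.iac_mask
    labels, _ = ndimage.label(hyper)
    r, c = slc._point_to_pixel(slc.nerve_midpoint_mm)
    lab = labels[r, c]
    if lab == 0:
        raise SegmentationError("no hyperintense component contains the nerve midpoint")
    return labels == lab


def build_cooccurrence(
    records: list[OccupancyRecord], site: str, stratum: str = "pooled"
) -> CooccurrenceTable:
    """Build marginal and conditional visibility percentages for one site.

    ``conditional[i, j] = 100 * count(i ∧ j) / count(i)``; rows with
    ``count(i) = 0`` are reported as NaN (undefined).  The joint count matrix
    is returned alongside so that identities like
    ``n_i * P(j|i) = n_j * P(i|j)`` can be asserted exactly.
    """
    if not records:
        raise InputError("empty record list")
    mismatched = [r for r in records if r.site != site]
    if mismatched:
        raise InputError(f"{len(mismatched)} records are not at site {site!r}")
    V = np.stack([r.visible for r in records]).astype(int)  # (n, 6)
    n = V.shape[0]
    counts = V.T @ V  # joint visibility counts; diagonal = per-segment counts
    diag = np.diag(counts).astype(float)
    marginal = 100.0 * diag / n
    with np.errstate(divide="ignore", invalid="ignore"):
        conditional = 100.0 * counts / diag[:, None]
    conditional[diag == 0, :] = np.nan
    np.fill_diagonal(conditional, np.nan)
    return CooccurrenceTable(
        site=site,
        n_records=n,
        marginal=marginal,
        conditional=conditional,
        counts=counts,
        stratum=stratum,
    )


def stratify(
    records: list[OccupancyRecord], site: str, by: str = "retention_label"
) -> dict[str, CooccurrenceTable]:
    """One co-occurrence table per stratum plus the pooled table.

    With ``by="none"`` only the pooled table is returned.  Pooled joint
    counts equal the elementwise sum of the stratum counts by construction.
    """
    at_site = [r for r in records if r.site == site]
    tables = {"pooled": build_cooccurrence(at_site, site)}
    if by == "none":
        return tables
    if by != "retention_label":
        raise InputError(f"cannot stratify by {by!r}")
    for label in sorted({r.retention_label for r in at_site}):
        group = [r for r in at_site if r.retention_label == label]
        tables[label] = build_cooccurrence(group, site, stratum=label)
    return tables


def records_to_frame(records: list[OccupancyRecord]) -> pd.DataFrame:
    """Tidy one-row-per-nerve/site table (subject, side, site, f1..f6, v1..v6)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subject_id": r.subject_id,
            "side": r.side,
            "site": r.site,
        }
        for s in range(N_SEGMENTS):
            row[f"f{s + 1}"] = r.fractions[s]
        for s in range(N_SEGMENTS):
            row[f"v{s + 1}"] = bool(r.visible[s])
        row["threshold"] = r.threshold
        row["retention_label"] = r.retention_label
        rows.append(row)
    return pd.DataFrame(rows)
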