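"""Structure segmentation and maximum plane-diameter morphometry.

The canal (IAC, both modalities) and the nerve (IAN, MRI only — CBCT carries
no nerve contrast) are segmented by seeded region growing with an intensity
criterion derived from local statistics, then measured as the maximum Feret
diameter (maximum caliper width over all in-plane directions) of the 2D
cross-section through the reference site in each of the three anatomical
planes.

Diameter convention: the Feret value is the maximum pairwise distance between
boundary-pixel centers plus one in-plane pixel width, so a single-pixel
region has diameter equal to the pixel size.  Diameters are measured on the
binary mask at pixel resolution; no sub-pixel contour fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import (
    LeakageError,
    ModalityError,
    ParameterError,
    SegmentationError,
    SiteError,
)
from .phantom import ImageVolume

STRUCTURES = ("IAC", "IAN")
PLANES = ("axial", "sagittal", "coronal")

#: which anatomical axis each plane's cross-section is taken across
PLANE_FIXED_AXIS = {
    "axial": "superoinferior",
    "sagittal": "buccolingual",
    "coronal": "mesiodistal",
}


@dataclass
class SegmentationConfig:
    """Region-growing parameters (all lengths in mm).

    The growth criterion keeps voxels on the non-bone side of the midpoint
    between two local intensity references:

    * IAC — the cortical-bone level is the extreme percentile of a ball of
      ``context_radius_mm`` around the seed on the bone side of the modality
      (cortical bone is dark on water-excited MRI, bright on CBCT:
      ``bone_polarity``); the non-bone level is the ball median.  Growth
      proceeds away from the cortical extreme and is stopped by the ring.
    * IAN — the hyperintense level (mean over ``neighborhood_radius_mm``
      around the seed) versus the median of a surrounding shell of canal
      interior (``ian_shell_mm``).
    """

    neighborhood_radius_mm: float = 0.6
    context_radius_mm: float = 6.0
    bone_percentile: float = 2.0  # distance from the extreme, per polarity
    ian_shell_mm: tuple[float, float] = (1.4, 2.8)
    bone_polarity: dict = field(
        default_factory=lambda: {"MRI": "dark", "CBCT": "bright"}
    )
    closing_radius_mm: float = 0.3
    max_volume_fraction: float = 0.25
    min_contrast: float = 0.10  # in robustly normalized intensity units


@dataclass
class StructureMask:
    """A connected binary mask of one structure with its provenance."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    structure: str
    modality: str
    seed_voxel: tuple[int, int, int]
    axes: dict[str, int]
    site: str = ""
    params: dict = field(default_factory=dict)


@dataclass
class DiameterSet:
    """Maximum plane diameters (mm) of one structure in one modality."""

    structure: str
    modality: str
    site: str
    d_axial: float
    d_sagittal: float
    d_coronal: float
    subject_id: str = ""
    side: str = ""

    def __post_init__(self) -> None:
        for plane in PLANES:
            if self[plane] <= 0:
                raise ParameterError(f"{plane} diameter must be > 0")

    def __getitem__(self, plane: str) -> float:
        return getattr(self, f"d_{plane}")


@dataclass
class SiteMeasurement:
    """Per-site morphometry with per-structure failures kept explicit."""

    site: str
    diameters: list[DiameterSet]
    failures: dict[str, str]
    provenance: dict


def _normalize(data: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(data, [1.0, 99.0])
    if hi <= lo:
        raise SegmentationError("volume has no intensity range")
    return (data.astype(float) - lo) / (hi - lo)


def _ball_values(
    v: np.ndarray, seed: tuple[int, int, int], spacing, r_out: float, r_in: float = 0.0
) -> np.ndarray:
    """Intensities in the (shell of the) physical ball around the seed."""
    hw = [int(np.ceil(r_out / h)) for h in spacing]
    sl = tuple(
        slice(max(0, s - w), min(n, s + w + 1))
        for s, w, n in zip(seed, hw, v.shape)
    )
    sub = v[sl]
    grids = np.meshgrid(
        *[
            (np.arange(s.start, s.stop) - c) * h
            for s, c, h in zip(sl, seed, spacing)
        ],
        indexing="ij",
    )
    d2 = sum(g**2 for g in grids)
    sel = (d2 <= r_out**2) & (d2 >= r_in**2)
    return sub[sel]


def _ellipsoid_element(
    radius_mm: float, spacing, skip_axis: int | None = None
) -> np.ndarray | None:
    """Ellipsoidal structuring element; flat along ``skip_axis`` if given.

    Closing is applied in-plane only (``skip_axis`` = mesiodistal) so that a
    tube spanning the full volume is not eroded at the end slices, where the
    out-of-volume border counts as background.
    """
    r = [int(round(radius_mm / h)) for h in spacing]
    if skip_axis is not None:
        r[skip_axis] = 0
    if max(r) < 1:
        return None
    grids = np.meshgrid(*[np.arange(-k, k + 1) for k in r], indexing="ij")
    d2 = sum((g / max(k, 1)) ** 2 for g, k in zip(grids, r))
    return d2 <= 1.0


def segment_structure(
    volume: ImageVolume,
    seed_voxel: tuple[int, int, int],
    structure: str,
    config: SegmentationConfig | None = None,
) -> StructureMask:
    """Seeded region growing of the IAC or IAN.

    Raises
    ------
    ModalityError
        If the IAN is requested on CBCT (it carries no nerve contrast).
    SegmentationError
        If the local contrast at the seed is insufficient or the seed fails
        its own criterion (e.g. seed placed in homogeneous background).
    LeakageError
        If growth floods more than ``config.max_volume_fraction`` of the
        volume.
    """
    config = config or SegmentationConfig()
    if structure not in STRUCTURES:
        raise ParameterError(f"unknown structure {structure!r}")
    if structure == "IAN" and volume.modality != "MRI":
        raise ModalityError("the IAN can only be segmented on MRI")
    seed = tuple(int(i) for i in seed_voxel)
    if not all(0 <= s < n for s, n in zip(seed, volume.data.shape)):
        raise ParameterError(f"seed voxel {seed} outside the volume")

    v = _normalize(volume.data)
    spacing = volume.spacing
    if structure == "IAC":
        polarity = config.bone_polarity.get(volume.modality, "bright")
        ball = _ball_values(v, seed, spacing, config.context_radius_mm)
        target = float(np.median(ball))  # non-bone level (interior/marrow)
        pct = (
            config.bone_percentile
            if polarity == "dark"
            else 100.0 - config.bone_percentile
        )
        ref = float(np.percentile(ball, pct))  # cortical ring level
    else:
        target = float(np.mean(_ball_values(v, seed, spacing, config.neighborhood_radius_mm)))
        # the background shell widens until it clears the nerve itself
        # (a large nerve can fill the innermost shell entirely).  Detection
        # compares the seed against the shell's upper quartile — with no
        # nerve that quartile *is* the interior level and detection fails;
        # the boundary reference is then the median of the sub-quartile
        # shell, which excludes nerve spill-over and the dark cortical ring
        # pulls it only mildly.
        r_in, r_out = config.ian_shell_mm
        width = r_out - r_in
        detected = False
        ref = target
        for _ in range(3):
            shell = _ball_values(v, seed, spacing, r_out, r_in)
            q75 = float(np.percentile(shell, 75.0))
            if target - q75 >= config.min_contrast:
                ref = float(np.median(shell[shell <= q75]))
                detected = True
                break
            r_in, r_out = r_out, r_out + width
        if not detected:
            # the IAN is hyperintense by definition; a seed that is not
            # brighter than its surroundings marks an absent/invisible nerve
            raise SegmentationError(
                f"no hyperintense structure at the IAN seed "
                f"(seed level {target:.3f} vs local background {ref:.3f})"
            )
    if abs(target - ref) < config.min_contrast:
        raise SegmentationError(
            f"insufficient contrast at seed for {structure} "
            f"(target {target:.3f} vs reference {ref:.3f})"
        )

    def grow(thr: float) -> np.ndarray:
        # inclusive on the target side: a voxel exactly at half coverage of
        # the structure sits exactly on the midpoint threshold and belongs in
        crit = v >= thr if target > ref else v <= thr
        labels, _ = ndimage.label(crit)  # 6-connectivity: no diagonal leaks
        lab = labels[seed]
        if lab == 0:
            raise SegmentationError("seed voxel does not satisfy the growth criterion")
        comp = labels == lab
        if comp.sum() > config.max_volume_fraction * comp.size:
            raise LeakageError(
                f"region growing flooded {comp.mean():.1%} of the volume "
                f"(limit {config.max_volume_fraction:.0%})"
            )
        return comp

    thr = 0.5 * (target + ref)
    comp = grow(thr)
    if structure == "IAC":
        # refine: the first pass may anchor on the marrow level rather than
        # the canal interior; re-estimate the interior from the grown region
        # (quartile nearest the cortical side, so the hyperintense nerve
        # inside the canal cannot skew it) and regrow with the threshold
        # midway between interior and cortex — the half-coverage boundary.
        q = 25.0 if target > ref else 75.0
        interior = float(np.percentile(v[comp], q))
        if abs(interior - ref) >= config.min_contrast:
            try:
                refined = grow(0.5 * (interior + ref))
            except LeakageError:
                # the sharper threshold breached the cortical ring (thin ring
                # or noise); keep the conservative first pass instead
                refined = None
            if refined is not None:
                target, thr, comp = interior, 0.5 * (interior + ref), refined
    elem = _ellipsoid_element(
        config.closing_radius_mm, spacing, skip_axis=volume.axes["mesiodistal"]
    )
    if elem is not None:
        comp = ndimage.binary_closing(comp, structure=elem)
        labels, _ = ndimage.label(comp)
        comp = labels == labels[seed]
    return StructureMask(
        mask=comp,
        spacing=spacing,
        structure=structure,
        modality=volume.modality,
        seed_voxel=seed,
        axes=dict(volume.axes),
        params={
            "threshold": thr,
            "target": target,
            "reference": ref,
            "grow_above": bool(target > ref),
            "closing_radius_mm": config.closing_radius_mm,
        },
    )


def feret_diameter(mask2d: np.ndarray, spacing: tuple[float, float]) -> float:
    """Maximum Feret (caliper) diameter of a 2D binary region, in mm.

    Computed as the maximum pairwise distance between boundary-pixel centers
    (convex-hull accelerated) plus one in-plane pixel width.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if not mask2d.any():
        raise SiteError("empty cross-section")
    boundary = mask2d & ~ndimage.binary_erosion(mask2d)
    pts = np.argwhere(boundary).astype(float) * np.asarray(spacing)
    px = float(np.mean(spacing))
    if len(pts) == 1:
        return px
    try:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except QhullError:
        pass  # collinear points: brute force on the (few) boundary pixels
    return float(pdist(pts).max()) + px


def max_plane_diameters(
    smask: StructureMask,
    site_slice: int,
    site: str = "",
    center_voxel: tuple[int, int, int] | None = None,
) -> DiameterSet:
    """Maximum Feret diameter of the mask's cross-section in each plane.

    The coronal cross-section is taken at ``site_slice`` (the reference-layer
    index along the mesiodistal axis); the axial and sagittal cross-sections
    pass through the centroid of that coronal section unless an explicit
    ``center_voxel`` is given.
    """
    md = smask.axes["mesiodistal"]
    coronal_sec = np.take(smask.mask, site_slice, axis=md)
    if not coronal_sec.any():
        raise SiteError(f"empty coronal cross-section at slice {site_slice}")
    if center_voxel is None:
        com = ndimage.center_of_mass(coronal_sec)
        rem = [ax for ax in range(3) if ax != md]
        center = [0, 0, 0]
        center[md] = site_slice
        center[rem[0]], center[rem[1]] = int(round(com[0])), int(round(com[1]))
        center_voxel = tuple(center)

    values = {}
    for plane in PLANES:
        ax = smask.axes[PLANE_FIXED_AXIS[plane]]
        sec = np.take(smask.mask, center_voxel[ax], axis=ax)
        if not sec.any():
            raise SiteError(f"empty {plane} cross-section at the site center")
        sp = tuple(h for i, h in enumerate(smask.spacing) if i != ax)
        values[plane] = feret_diameter(sec, sp)
    return DiameterSet(
        structure=smask.structure,
        modality=smask.modality,
        site=site,
        d_axial=values["axial"],
        d_sagittal=values["sagittal"],
        d_coronal=values["coronal"],
    )


def _mm_to_voxel(
    volume: ImageVolume, nerve_midpoint_mm: tuple[float, float], z_index: int
) -> tuple[int, int, int]:
    """In-plane landmark (x buccolingual, y superoinferior) to a voxel index."""
    si, bl = volume.axes["superoinferior"], volume.axes["buccolingual"]
    idx = [0, 0, 0]
    idx[volume.axes["mesiodistal"]] = z_index
    idx[si] = int(nerve_midpoint_mm[1] / volume.spacing[si])
    idx[bl] = int(nerve_midpoint_mm[0] / volume.spacing[bl])
    return tuple(idx)


def measure_site(
    mri: ImageVolume,
    cbct: ImageVolume | None,
    nerve_midpoint_mm: tuple[float, float],
    site: str,
    config: SegmentationConfig | None = None,
    reference_slices: dict[str, int] | None = None,
    cached_masks: dict[tuple[str, str], StructureMask] | None = None,
) -> SiteMeasurement:
    """Measure IAC (CBCT and MRI) and IAN (MRI) diameters at one site.

    The nerve midpoint landmark seeds all three segmentations (it lies inside
    the canal by definition).  Per-structure failures are recorded in
    ``failures`` instead of aborting the remaining measurements.  3D masks
    can be shared between sites via ``cached_masks`` (keyed by
    (structure, modality)); segmentation does not depend on the site, only
    the measurement slice does.
    """
    config = config or SegmentationConfig()
    jobs: list[tuple[str, ImageVolume]] = []
    if cbct is not None:
        jobs.append(("IAC", cbct))
    jobs.extend([("IAC", mri), ("IAN", mri)])

    diameters: list[DiameterSet] = []
    failures: dict[str, str] = {}
    provenance: dict = {"site": site, "seeds": {}, "segmentation": {}}
    for structure, volume in jobs:
        key = f"{structure}-{volume.modality}"
        try:
            z_ref = (
                reference_slices[volume.modality]
                if reference_slices is not None
                else volume.reference_slices[site]
            )
            cache_key = (structure, volume.modality)
            smask = cached_masks.get(cache_key) if cached_masks is not None else None
            if smask is None:
                seed = _mm_to_voxel(volume, nerve_midpoint_mm, z_ref)
                smask = segment_structure(volume, seed, structure, config)
                if cached_masks is not None:
                    cached_masks[cache_key] = smask
            ds = max_plane_diameters(smask, z_ref, site=site)
            diameters.append(ds)
            provenance["seeds"][key] = list(smask.seed_voxel)
            provenance["segmentation"][key] = {
                k: v for k, v in smask.params.items()
            }
            provenance.setdefault("slice_index", {})[key] = z_ref
        except (SegmentationError, ModalityError, SiteError, ParameterError) as exc:
            failures[key] = str(exc)
    return SiteMeasurement(site=site, diameters=diameters, failures=failures,
                           provenance=provenance)


def diameters_to_frame(
    entries: list[tuple[str, str, DiameterSet]]
) -> pd.DataFrame:
    """Tidy (subject, side, site, structure, modality, plane, diameter_mm) table."""
    rows = []
    for subject_id, side, ds in entries:
        for plane in PLANES:
            rows.append(
                {
                    "subject_id": subject_id,
                    "side": side,
                    "site": ds.site,
                    "structure": ds.structure,
                    "modality": ds.modality,
                    "plane": plane,
                    "diameter_mm": ds[plane],
                }
            )
    return pd.DataFrame(rows)
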