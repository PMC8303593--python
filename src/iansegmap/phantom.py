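"""Synthetic paired CBCT/MRI phantoms of the inferior alveolar canal.

Every phantom subject side is a small 3D slab of mandibular bone crossed by a
straight elliptical canal (the IAC) running along the mesiodistal axis, with
an elliptical nerve tube (the IAN) inside it.  Two volumes are rendered from
the same anatomy:

* an MRI-like volume (0.75 mm isotropic by default) with a *dark* cortical
  ring around the canal and a *hyperintense* nerve blob inside it, and
* a CBCT-like volume (0.16 mm by default) with a *bright* cortical ring and
  no nerve contrast at all.

The canal drawn in the MRI volume may be scaled relative to the CBCT one
(``modality_scale``) to emulate the small systematic size difference between
the modalities.  Default sizes are calibrated to published normative values:
canal semiaxes (1.95, 2.65) mm so the CBCT canal measures 3.9 mm
buccolingually and 5.3 mm coronally, nerve semiaxes (1.3, 2.05) mm.

Because every region is analytic (ellipses and tubes), each downstream stage
has an exact oracle: segment fill fractions by quadrature
(:func:`truth_occupancy`), plane diameters in closed form
(``PhantomTruth.true_diameters``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .geometry import ReferenceSlice
from .occupancy import OccupancyRecord

MODALITIES = ("MRI", "CBCT")
SITES = ("M3", "M2")

#: nominal tissue intensities (arbitrary units in [0, 1])
INTENSITIES = {
    "MRI": {"bone": 0.50, "cortical": 0.10, "interior": 0.35, "nerve": 0.90},
    "CBCT": {"bone": 0.30, "cortical": 0.90, "interior": 0.25},
}


@dataclass
class PhantomParams:
    """Ground-truth geometry and acquisition parameters for one subject side.

    Lengths in mm; ``canal_semiaxes``/``nerve_semiaxes`` are (buccolingual,
    superoinferior) pairs; ``nerve_offset`` is the nerve-center displacement
    from the canal center along (buccal+, inferior+).  ``modality_scale``
    multiplies the canal semiaxes in the MRI rendering only.
    """

    canal_semiaxes: tuple[float, float] = (1.95, 2.65)
    nerve_semiaxes: tuple[float, float] = (1.3, 2.05)
    nerve_offset: tuple[float, float] = (0.0, 0.2)
    crest_height: float = 15.0
    cortical_thickness: float = 1.0
    mri_spacing: float = 0.75
    cbct_spacing: float = 0.16
    modality_scale: tuple[float, float] = (4.18 / 3.9, 5.49 / 5.3)
    noise_sd: float = 0.02
    n_slices: int = 8
    seed: int = 0
    allow_protruding: bool = False
    margin: float = 2.5
    crest_buccal_offset: float = 1.0
    blur_sigma_mm: float = 0.0  # PSF blur beyond the partial-volume averaging
    undulation_amp_mm: float = 0.0
    undulation_period_mm: float = 20.0
    baseline_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        a, b = self.canal_semiaxes
        na, nb = self.nerve_semiaxes
        if a <= 0 or b <= 0:
            raise ParameterError("canal semiaxes must be > 0")
        if na < 0 or nb < 0:
            raise ParameterError("nerve semiaxes must be >= 0")
        if self.mri_spacing <= 0 or self.cbct_spacing <= 0:
            raise ParameterError("spacings must be > 0")
        if self.cortical_thickness < 0:
            raise ParameterError("cortical_thickness must be >= 0")
        if self.n_slices < 1:
            raise ParameterError("n_slices must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.crest_height <= max(self.canal_semiaxes) * max(self.modality_scale):
            raise ParameterError("crest_height must clear the canal")
        if not self.allow_protruding:
            ea, eb = self.canal_semiaxes_for("min")
            ox, oy = self.nerve_offset
            if abs(ox) + na > ea + 1e-9 or abs(oy) + nb > eb + 1e-9:
                raise ParameterError(
                    "nerve does not fit inside the canal "
                    f"(|offset|+semiaxis = ({abs(ox) + na:.3g}, {abs(oy) + nb:.3g}) "
                    f"vs canal semiaxes ({ea:.3g}, {eb:.3g})); "
                    "set allow_protruding=True to override"
                )

    def canal_semiaxes_for(self, modality: str) -> tuple[float, float]:
        """Effective canal semiaxes per modality ('min' = tightest of both)."""
        a, b = self.canal_semiaxes
        sa, sb = self.modality_scale
        if modality == "CBCT":
            return (a, b)
        if modality == "MRI":
            return (a * sa, b * sb)
        if modality == "min":
            return (min(a, a * sa), min(b, b * sb))
        raise ParameterError(f"unknown modality {modality!r}")

    @property
    def slab_length(self) -> float:
        return self.n_slices * self.mri_spacing


@dataclass
class ImageVolume:
    """A 3D scalar volume with spacing and anatomical axis labels."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str
    axes: dict[str, int] = field(
        default_factory=lambda: {"mesiodistal": 0, "superoinferior": 1, "buccolingual": 2}
    )
    reference_slices: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError("volume must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be strictly positive")
        if sorted(self.axes.values()) != [0, 1, 2]:
            raise ParameterError("axes must be a bijection onto the three grid axes")


@dataclass
class PhantomTruth:
    """Analytic ground truth of one subject side (both imaging modalities)."""

    params: PhantomParams
    subject_id: str
    side: str
    retention_label: str
    canal_center_mm: tuple[float, float]
    canal_semiaxes_mm: dict[str, tuple[float, float]]  # per modality
    nerve_center_mm: tuple[float, float]
    nerve_semiaxes_mm: tuple[float, float]
    crest_mm: tuple[float, float]
    slab_length_mm: dict[str, float]
    true_diameters: dict[tuple[str, str, str], float]  # (structure, modality, plane)
    diameters_exact: bool
    reference_slices: dict[str, dict[str, int]]  # modality -> site -> z index

    @property
    def landmark_nerve_midpoint(self) -> tuple[float, float]:
        return self.nerve_center_mm

    @property
    def landmark_crest(self) -> tuple[float, float]:
        return self.crest_mm


@dataclass
class TruthOccupancy:
    """Quadrature-based segment fill fractions with an error estimate."""

    fractions: np.ndarray
    visible: np.ndarray
    threshold: float
    quadrature_step_mm: float
    tolerance_estimate: float
    rule: str
    segment_areas_mm2: np.ndarray


@dataclass
class SubjectSide:
    subject_id: str
    side: str
    mri: ImageVolume
    cbct: ImageVolume
    truth: PhantomTruth


# ---------------------------------------------------------------------------
# geometry helpers


def _fov(params: PhantomParams) -> tuple[float, float, float, float]:
    """Field of view (W, H) and canal center (xc, yc) in mm.

    W is snapped up to a multiple of the MRI spacing so the MRI pixel grid is
    exactly reflection-symmetric about the canal center — left/right sides
    are then bit-exact mirrors of each other.
    """
    ct, m = params.cortical_thickness, params.margin
    a_mri, b_mri = params.canal_semiaxes_for("MRI")
    a_cb, b_cb = params.canal_semiaxes_for("CBCT")
    a_max, b_max = max(a_mri, a_cb), max(b_mri, b_cb)
    h = params.mri_spacing
    W = math.ceil(2.0 * (a_max + ct + m) / h) * h
    yc = m + params.crest_height
    H = math.ceil((yc + b_max + ct + m) / h) * h
    return W, H, W / 2.0, yc


def _side_sign(side: str) -> float:
    """Buccal direction along +x for the left side, -x for the right."""
    return 1.0 if side == "left" else -1.0


def _geometry(params: PhantomParams, side: str) -> dict:
    W, H, xc, yc = _fov(params)
    s = _side_sign(side)
    ox, oy = params.nerve_offset
    nerve_center = (xc + s * ox, yc + oy)
    crest = (xc + s * params.crest_buccal_offset, yc - params.crest_height)
    return {
        "W": W,
        "H": H,
        "canal_center": (xc, yc),
        "nerve_center": nerve_center,
        "crest": crest,
        "sign": s,
    }


def _ellipse(X: np.ndarray, Y: np.ndarray, center, semiaxes) -> np.ndarray:
    a, b = semiaxes
    if a <= 0 or b <= 0:
        return np.zeros(X.shape, dtype=bool)
    return ((X - center[0]) / a) ** 2 + ((Y - center[1]) / b) ** 2 <= 1.0


def _render_plane(
    params: PhantomParams,
    geo: dict,
    modality: str,
    spacing: float,
    nerve_center: tuple[float, float] | None = None,
    subsample: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one coronal plane; returns (intensity, canal_mask, nerve_mask).

    Intensities are area-weighted over ``subsample``² sub-pixels so partial
    boundary pixels take intermediate values; masks use the >= 50 % coverage
    convention.
    """
    W, H = geo["W"], geo["H"]
    ny, nx = int(math.ceil(H / spacing)), int(math.ceil(W / spacing))
    k = subsample
    xs = (np.arange(nx * k) + 0.5) * (spacing / k)
    ys = (np.arange(ny * k) + 0.5) * (spacing / k)
    X, Y = np.meshgrid(xs, ys)

    tones = INTENSITIES[modality]
    a, b = params.canal_semiaxes_for(modality)
    ct = params.cortical_thickness
    cc = geo["canal_center"]
    in_outer = _ellipse(X, Y, cc, (a + ct, b + ct))
    in_inner = _ellipse(X, Y, cc, (a, b))
    img = np.full(X.shape, tones["bone"])
    img[in_outer] = tones["cortical"]
    img[in_inner] = tones["interior"]
    in_nerve = np.zeros(X.shape, dtype=bool)
    if modality == "MRI" and min(params.nerve_semiaxes) > 0:
        nc = nerve_center if nerve_center is not None else geo["nerve_center"]
        in_nerve = _ellipse(X, Y, nc, params.nerve_semiaxes)
        img[in_nerve] = tones["nerve"]

    def pool(arr: np.ndarray) -> np.ndarray:
        return arr.reshape(ny, k, nx, k).mean(axis=(1, 3))

    intensity = pool(img)
    if params.blur_sigma_mm > 0:
        intensity = ndimage.gaussian_filter(intensity, params.blur_sigma_mm / spacing)
    canal_mask = pool(in_inner.astype(float)) >= 0.5
    nerve_mask = pool(in_nerve.astype(float)) >= 0.5
    return intensity, canal_mask, nerve_mask


def _reference_indices(n_z: int) -> dict[str, int]:
    return {"M3": n_z // 3, "M2": (2 * n_z) // 3}


def _true_diameters(params: PhantomParams, n_z: dict[str, int]) -> dict:
    """Closed-form plane Feret diameters of the canal and nerve tubes.

    For a straight axis-aligned elliptical tube of length L and in-plane
    semiaxes (a, b): coronal Feret = 2 max(a, b); the axial cut through the
    tube center is a 2a × L strip whose Feret is the diagonal hypot(L, 2a);
    sagittally hypot(L, 2b).
    """
    out = {}
    for modality, spacing in (("CBCT", params.cbct_spacing), ("MRI", params.mri_spacing)):
        L = n_z[modality] * spacing
        a, b = params.canal_semiaxes_for(modality)
        out[("IAC", modality, "axial")] = math.hypot(L, 2 * a)
        out[("IAC", modality, "sagittal")] = math.hypot(L, 2 * b)
        out[("IAC", modality, "coronal")] = 2 * max(a, b)
    na, nb = params.nerve_semiaxes
    L = n_z["MRI"] * params.mri_spacing
    out[("IAN", "MRI", "axial")] = math.hypot(L, 2 * na)
    out[("IAN", "MRI", "sagittal")] = math.hypot(L, 2 * nb)
    out[("IAN", "MRI", "coronal")] = 2 * max(na, nb)
    return out


# ---------------------------------------------------------------------------
# generation


def generate_subject_side(
    params: PhantomParams,
    side: str = "left",
    subject_id: str = "S000",
    retention_label: str = "unknown",
) -> tuple[ImageVolume, ImageVolume, PhantomTruth]:
    """Generate the paired MRI/CBCT volumes and their analytic ground truth.

    Deterministic given ``params.seed``: the same parameters always yield
    bit-identical volumes and truth.
    """
    params.validate()
    if side not in ("left", "right"):
        raise ParameterError(f"side must be left/right, got {side!r}")
    geo = _geometry(params, side)
    rng = np.random.default_rng(params.seed)

    n_z = {
        "MRI": params.n_slices,
        "CBCT": max(1, round(params.slab_length / params.cbct_spacing)),
    }
    volumes: dict[str, ImageVolume] = {}
    for modality, spacing in (("MRI", params.mri_spacing), ("CBCT", params.cbct_spacing)):
        nz = n_z[modality]
        if modality == "MRI" and params.undulation_amp_mm != 0:
            planes = []
            for iz in range(nz):
                z = (iz + 0.5) * spacing
                wob = params.undulation_amp_mm * math.sin(
                    2 * math.pi * z / params.undulation_period_mm
                )
                nc = (geo["nerve_center"][0] + geo["sign"] * wob, geo["nerve_center"][1])
                planes.append(_render_plane(params, geo, modality, spacing, nerve_center=nc)[0])
            vol = np.stack(planes)
        else:
            plane, _, _ = _render_plane(params, geo, modality, spacing)
            vol = np.broadcast_to(plane, (nz,) + plane.shape).copy()
        if params.noise_sd > 0:
            vol = vol + rng.normal(0.0, params.noise_sd, vol.shape)
        volumes[modality] = ImageVolume(
            data=vol.astype(np.float32),
            spacing=(spacing, spacing, spacing),
            modality=modality,
            reference_slices=_reference_indices(nz),
        )

    truth = PhantomTruth(
        params=params,
        subject_id=subject_id,
        side=side,
        retention_label=retention_label,
        canal_center_mm=geo["canal_center"],
        canal_semiaxes_mm={m: params.canal_semiaxes_for(m) for m in MODALITIES},
        nerve_center_mm=geo["nerve_center"],
        nerve_semiaxes_mm=params.nerve_semiaxes,
        crest_mm=geo["crest"],
        slab_length_mm={m: n_z[m] * s for m, s in
                        (("MRI", params.mri_spacing), ("CBCT", params.cbct_spacing))},
        true_diameters=_true_diameters(params, n_z),
        diameters_exact=params.undulation_amp_mm == 0,
        reference_slices={m: volumes[m].reference_slices for m in MODALITIES},
    )
    return volumes["MRI"], volumes["CBCT"], truth


def rasterize_truth_masks(
    truth: PhantomTruth, modality: str = "MRI", spacing: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the true canal and nerve regions at the given pixel size."""
    if spacing is None:
        spacing = truth.params.mri_spacing if modality == "MRI" else truth.params.cbct_spacing
    geo = _geometry(truth.params, truth.side)
    _, canal, nerve = _render_plane(truth.params, geo, modality, spacing)
    return canal, nerve


def truth_reference_slice(
    truth: PhantomTruth,
    site: str = "M3",
    spacing: float | None = None,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> ReferenceSlice:
    """Render an MRI reference slice (any pixel size) with the true canal mask.

    Used wherever a slice with a known-good canal mask is needed — e.g. to
    study occupancy scoring in isolation from 3D segmentation.
    """
    params = truth.params
    if spacing is None:
        spacing = params.mri_spacing
    geo = _geometry(params, truth.side)
    img, canal, _ = _render_plane(params, geo, "MRI", spacing)
    sd = params.noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        img = img + rng.normal(0.0, sd, img.shape)
    return ReferenceSlice(
        image=img,
        spacing=(spacing, spacing),
        side=truth.side,
        site=site,
        crest_mm=truth.crest_mm,
        nerve_midpoint_mm=truth.nerve_center_mm,
        iac_mask=canal,
        baseline_angle_deg=params.baseline_angle_deg,
    )


# ---------------------------------------------------------------------------
# analytic occupancy oracle


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan approximation, ample for a tolerance estimate
    return math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))


def truth_occupancy(
    truth: PhantomTruth,
    rule: str = "chord-thirds",
    n_grid: int = 1500,
    threshold: float = 0.5,
) -> TruthOccupancy:
    """Segment fill fractions by fine-grid quadrature over the analytic regions.

    The construction mirrors the reference-slice readout — baseline through
    the crest, parallel midline through the nerve midpoint, perpendiculars at
    thirds of the midline chord — but the chord ends come from intersecting
    the midline with the canal *ellipse* in closed form, and membership is
    counted on an ``n_grid`` × ``n_grid`` sample lattice, independently of the
    raster pipeline.
    """
    params = truth.params
    A, B = truth.canal_semiaxes_mm["MRI"]
    xc, yc = truth.canal_center_mm
    nx0, ny0 = truth.nerve_center_mm
    na, nb = truth.nerve_semiaxes_mm
    th = math.radians(params.baseline_angle_deg)
    u = np.array([math.cos(th), math.sin(th)]) * _side_sign(truth.side)  # buccal
    sup = np.array([math.sin(th), -math.cos(th)])

    # midline ∩ canal ellipse, in the buccal along-line coordinate t
    px, py = nx0 - xc, ny0 - yc
    qa = (u[0] / A) ** 2 + (u[1] / B) ** 2
    qb = 2 * (px * u[0] / A**2 + py * u[1] / B**2)
    qc = (px / A) ** 2 + (py / B) ** 2 - 1.0
    disc = qb * qb - 4 * qa * qc
    if disc <= 0:
        raise ParameterError("nerve midpoint lies outside the canal ellipse")
    if rule == "chord-thirds":
        t_lo = (-qb - math.sqrt(disc)) / (2 * qa)
        t_hi = (-qb + math.sqrt(disc)) / (2 * qa)
    elif rule == "bbox-thirds":
        # extent of the canal ellipse projected on the baseline direction
        half = math.hypot(A * u[0], B * u[1])
        t_c = (np.array([xc, yc]) - np.array([nx0, ny0])) @ u
        t_lo, t_hi = t_c - half, t_c + half
    else:
        raise ParameterError(f"unknown partition rule {rule!r}")
    span = t_hi - t_lo
    cut_l, cut_b = t_lo + span / 3.0, t_lo + 2 * span / 3.0

    step = 2 * max(A, B) / n_grid
    gx = xc - A + (np.arange(n_grid) + 0.5) * (2 * A / n_grid)
    gy = yc - B + (np.arange(n_grid) + 0.5) * (2 * B / n_grid)
    X, Y = np.meshgrid(gx, gy)
    in_canal = ((X - xc) / A) ** 2 + ((Y - yc) / B) ** 2 <= 1.0
    in_nerve = (
        _ellipse(X, Y, (nx0, ny0), (na, nb)) if min(na, nb) > 0 else np.zeros_like(in_canal)
    )

    dx, dy = X - nx0, Y - ny0
    s = dx * sup[0] + dy * sup[1]
    t = dx * u[0] + dy * u[1]
    eps = 1e-6  # same on-line tie convention as the raster path, in mm
    seg = np.where(s > eps, 1, 4).astype(np.int8)
    lateral = np.ones(X.shape, dtype=np.int8)
    lateral[t > cut_b + eps] = 0
    lateral[t < cut_l - eps] = 2
    seg = seg + lateral
    seg[~in_canal] = 0

    cell = (2 * A / n_grid) * (2 * B / n_grid)
    counts = np.bincount(seg.ravel(), minlength=7)[1:7].astype(float)
    hits = np.bincount(seg.ravel(), weights=(in_nerve & in_canal).ravel(), minlength=7)[1:7]
    fractions = np.zeros(6)
    np.divide(hits, counts, out=fractions, where=counts > 0)
    areas = counts * cell

    per = _ellipse_perimeter(A, B) + (_ellipse_perimeter(na, nb) if min(na, nb) > 0 else 0)
    with np.errstate(divide="ignore"):
        tol = float(np.max(np.where(areas > 0, step * per / (2 * areas), 0.0)))
    return TruthOccupancy(
        fractions=fractions,
        visible=fractions >= threshold,
        threshold=threshold,
        quadrature_step_mm=step,
        tolerance_estimate=tol,
        rule=rule,
        segment_areas_mm2=areas,
    )


def truth_occupancy_record(
    truth: PhantomTruth, site: str = "M3", rule: str = "chord-thirds", n_grid: int = 1500
) -> OccupancyRecord:
    """Package the quadrature oracle as an :class:`OccupancyRecord`."""
    occ = truth_occupancy(truth, rule=rule, n_grid=n_grid)
    return OccupancyRecord(
        subject_id=truth.subject_id,
        side=truth.side,
        site=site,
        fractions=occ.fractions,
        visible=occ.visible,
        threshold=occ.threshold,
        retention_label=truth.retention_label,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortDistributions:
    """Per-parameter (mean, sd) sampling spec for a synthetic cohort.

    Defaults emulate the scale of published normative canal and nerve
    diameters; ``asymmetry_sd`` jitters the right side relative to the left,
    ``missing_side_prob`` drops a side entirely (an absent third molar: the
    nerve on that side is simply not evaluated).  With 19 subjects and the
    default 1/19 missing probability the expected number of evaluated nerves
    is 36.
    """

    canal_bl: tuple[float, float] = (1.95, 0.42)
    canal_si: tuple[float, float] = (2.65, 0.50)
    nerve_bl: tuple[float, float] = (1.30, 0.40)
    nerve_si: tuple[float, float] = (2.05, 0.45)
    offset_bl: tuple[float, float] = (0.0, 0.45)
    offset_si: tuple[float, float] = (0.2, 0.45)
    crest_height: tuple[float, float] = (15.0, 1.5)
    noise_sd: float = 0.02
    asymmetry_sd: float = 0.10
    missing_side_prob: float = 1.0 / 19.0
    retention_labels: tuple[str, ...] = ("type3", "type4", "type5", "none")
    retention_weights: tuple[float, ...] = (11.0, 19.0, 2.0, 4.0)

    def validate(self) -> None:
        for name in ("canal_bl", "canal_si", "nerve_bl", "nerve_si",
                     "offset_bl", "offset_si", "crest_height"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ParameterError(f"{name}: sd must be >= 0 (got {sd})")
        if not (0.0 <= self.missing_side_prob < 1.0):
            raise ParameterError("missing_side_prob must be in [0, 1)")
        if self.asymmetry_sd < 0 or self.noise_sd < 0:
            raise ParameterError("sd parameters must be >= 0")


def _fit_nerve(
    canal: tuple[float, float],
    nerve: tuple[float, float],
    offset: tuple[float, float],
    scale: tuple[float, float],
    margin: float = 0.08,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Shrink nerve semiaxes/offset deterministically so the nerve fits."""
    ea = min(canal[0], canal[0] * scale[0]) - margin
    eb = min(canal[1], canal[1] * scale[1]) - margin
    na = min(nerve[0], 0.95 * ea)
    nb = min(nerve[1], 0.95 * eb)
    ox = math.copysign(min(abs(offset[0]), ea - na), offset[0])
    oy = math.copysign(min(abs(offset[1]), eb - nb), offset[1])
    return (na, nb), (ox, oy)


def generate_cohort(
    n_subjects: int,
    dists: CohortDistributions | None = None,
    seed: int = 0,
    base_params: PhantomParams | None = None,
) -> list[SubjectSide]:
    """Generate a reproducible cohort of subject sides with shared anatomy.

    Each subject's left and right sides share the sampled anatomy up to a
    mirroring of the buccolingual axis and a small ``asymmetry_sd`` jitter.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    dists = dists or CohortDistributions()
    dists.validate()
    base = base_params or PhantomParams()
    rng = np.random.default_rng(seed)

    def draw(spec: tuple[float, float], lo: float | None = None) -> float:
        v = rng.normal(*spec)
        return v if lo is None else max(v, lo)

    cohort: list[SubjectSide] = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        canal = (draw(dists.canal_bl, 1.0), draw(dists.canal_si, 1.4))
        nerve = (draw(dists.nerve_bl, 0.3), draw(dists.nerve_si, 0.3))
        offset = (rng.normal(*dists.offset_bl), rng.normal(*dists.offset_si))
        crest = draw(dists.crest_height, 8.0)
        label = str(
            rng.choice(
                np.array(dists.retention_labels),
                p=np.asarray(dists.retention_weights) / np.sum(dists.retention_weights),
            )
        )
        for side in ("left", "right"):
            j = dists.asymmetry_sd
            s_canal = (draw((canal[0], j), 1.0), draw((canal[1], j), 1.4))
            s_nerve = (draw((nerve[0], j), 0.3), draw((nerve[1], j), 0.3))
            s_offset = (offset[0] + rng.normal(0, j), offset[1] + rng.normal(0, j))
            side_seed = int(rng.integers(2**31))
            missing = rng.random() < dists.missing_side_prob
            if missing:
                continue
            fit_nerve, fit_offset = _fit_nerve(
                s_canal, s_nerve, s_offset, base.modality_scale
            )
            params = replace(
                base,
                canal_semiaxes=s_canal,
                nerve_semiaxes=fit_nerve,
                nerve_offset=fit_offset,
                crest_height=crest,
                noise_sd=dists.noise_sd,
                seed=side_seed,
            )
            mri, cbct, truth = generate_subject_side(
                params, side=side, subject_id=sid, retention_label=label
            )
            cohort.append(SubjectSide(sid, side, mri, cbct, truth))
    return cohort
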