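"""End-to-end study pipeline: phantoms or files → occupancy, morphometry, stats.

The pipeline mirrors the study design: for every evaluated nerve (subject
side) a coronal reference slice per site is scored for six-segment occupancy,
the canal and nerve are segmented in 3D and measured in the three planes, and
the per-observation conversion factors are summarized and compared between
modalities with a per-subject Wilcoxon signed-rank test.

Per-record failures (no nerve contrast, segmentation leakage, ...) are
logged and excluded — never silently imputed.  In synthetic mode a rerun
with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conversion import (
    FACTOR_TYPES,
    WilcoxonResult,
    compare_factors,
    compute_observations,
    side_average,
    summaries_frame,
)
from .errors import (
    GeometryError,
    InputError,
    LandmarkError,
    ParameterError,
    PipelineError,
    SegmentationError,
)
from .geometry import PARTITION_RULES, ReferenceSlice, build_partition
from .io import read_landmarks, read_manifest, read_volume
from .morphometry import (
    PLANES,
    SegmentationConfig,
    diameters_to_frame,
    measure_site,
    segment_structure,
)
from .occupancy import (
    CooccurrenceTable,
    build_cooccurrence,
    extract_nerve_mask,
    records_to_frame,
    score_occupancy,
    stratify,
)
from .phantom import (
    CohortDistributions,
    ImageVolume,
    SubjectSide,
    generate_cohort,
)

log = logging.getLogger("iansegmap")

SITES = ("M3", "M2")


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    mode: str = "synthetic"  # 'synthetic' | 'files'
    seed: int = 0
    n_subjects: int = 19
    cohort: CohortDistributions = field(default_factory=CohortDistributions)
    sites: tuple[str, ...] = SITES
    partition_rule: str = "chord-thirds"
    occupancy_threshold: float = 0.5
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    stratify_by: str = "retention_label"  # or 'none'
    alpha: float = 0.05
    zero_handling: str = "drop"
    out_dir: str | None = None
    manifest_path: str | None = None
    landmarks_path: str | None = None
    include_timestamp: bool = False

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ParameterError(f"mode must be synthetic/files, got {self.mode!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError("alpha must lie in (0, 1)")
        if self.partition_rule not in PARTITION_RULES:
            raise ParameterError(f"unknown partition rule {self.partition_rule!r}")
        if self.mode == "files":
            if not self.manifest_path or not self.landmarks_path:
                raise ParameterError("files mode needs manifest_path and landmarks_path")
        if self.mode == "synthetic" and self.seed is None:
            raise ParameterError("synthetic mode requires a seed")

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = _jsonable(asdict(self))
        for key in ("out_dir", "manifest_path", "landmarks_path"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """All study outputs plus provenance; every table carries its n."""

    occupancy_records: pd.DataFrame
    occupancy_tables: dict[str, dict[str, CooccurrenceTable]]  # site -> stratum
    diameters: pd.DataFrame
    diameter_summary: pd.DataFrame
    observations: pd.DataFrame
    conversion_summary: pd.DataFrame
    per_subject: pd.DataFrame
    wilcoxon: list[WilcoxonResult]
    exclusions: list[dict]
    provenance: dict


@dataclass
class _Bundle:
    subject_id: str
    side: str
    mri: ImageVolume
    cbct: ImageVolume | None
    crest_mm: tuple[float, float]
    nerve_midpoint_mm: tuple[float, float]
    baseline_angle_deg: float
    retention_label: str


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _canonical(volume: ImageVolume) -> ImageVolume:
    """Reorder axes to (mesiodistal, superoinferior, buccolingual)."""
    order = [volume.axes["mesiodistal"], volume.axes["superoinferior"],
             volume.axes["buccolingual"]]
    if order == [0, 1, 2]:
        return volume
    return ImageVolume(
        data=np.moveaxis(volume.data, order, [0, 1, 2]),
        spacing=tuple(volume.spacing[a] for a in order),  # type: ignore[arg-type]
        modality=volume.modality,
        reference_slices=dict(volume.reference_slices),
    )


def _bundles_synthetic(config: PipelineConfig) -> list[_Bundle]:
    cohort = generate_cohort(config.n_subjects, config.cohort, seed=config.seed)
    return [
        _Bundle(
            subject_id=ss.subject_id,
            side=ss.side,
            mri=ss.mri,
            cbct=ss.cbct,
            crest_mm=ss.truth.crest_mm,
            nerve_midpoint_mm=ss.truth.nerve_center_mm,
            baseline_angle_deg=ss.truth.params.baseline_angle_deg,
            retention_label=ss.truth.retention_label,
        )
        for ss in cohort
    ]


def _bundles_files(config: PipelineConfig) -> list[_Bundle]:
    manifest = read_manifest(config.manifest_path)
    landmarks = {(r["subject"], r["side"]): r for r in read_landmarks(config.landmarks_path)}
    root = Path(config.manifest_path).parent
    bundles = []
    for _, row in manifest.iterrows():
        key = (row["subject_id"], row["side"])
        if key not in landmarks:
            raise InputError(f"no landmarks for subject/side {key}")
        lm = landmarks[key]
        refs = lm.get("reference_slices", {})
        mri = read_volume(root / row["mri_path"], modality="MRI",
                          reference_slices=refs.get("MRI"))
        cbct = None
        if "cbct_path" in row and isinstance(row["cbct_path"], str):
            cbct = read_volume(root / row["cbct_path"], modality="CBCT",
                               reference_slices=refs.get("CBCT"))
        bundles.append(
            _Bundle(
                subject_id=str(row["subject_id"]),
                side=str(row["side"]),
                mri=mri,
                cbct=cbct,
                crest_mm=tuple(lm["crest_xy_mm"]),
                nerve_midpoint_mm=tuple(lm["nerve_midpoint_xy_mm"]),
                baseline_angle_deg=float(lm.get("baseline_angle_deg", 0.0)),
                retention_label=str(lm.get("retention_label",
                                           row.get("retention_label", "unknown"))),
            )
        )
    return bundles


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute all stages and return (and optionally write) the study report."""
    config.validate()
    bundles = _bundles_synthetic(config) if config.mode == "synthetic" else _bundles_files(config)
    if not bundles:
        raise PipelineError("no usable subject sides")

    records, diam_entries, exclusions = [], [], []
    for b in bundles:
        mri = _canonical(b.mri)
        cbct = _canonical(b.cbct) if b.cbct is not None else None
        cached_masks: dict = {}
        # 3D canal segmentation on MRI provides the reference-slice canal mask
        try:
            z0 = mri.reference_slices[config.sites[0]]
            seed = _seed_voxel(mri, b.nerve_midpoint_mm, z0)
            iac_mri = segment_structure(mri, seed, "IAC", config.segmentation)
            cached_masks[("IAC", "MRI")] = iac_mri
        except (SegmentationError, ParameterError, KeyError) as exc:
            exclusions.append(_excl(b, "IAC-MRI", exc))
            continue
        for site in config.sites:
            z = mri.reference_slices.get(site)
            if z is None:
                continue  # site not evaluated for this side
            try:
                slc = ReferenceSlice(
                    image=mri.data[z],
                    spacing=(mri.spacing[1], mri.spacing[2]),
                    side=b.side,
                    site=site,
                    crest_mm=b.crest_mm,
                    nerve_midpoint_mm=b.nerve_midpoint_mm,
                    iac_mask=iac_mri.mask[z],
                    baseline_angle_deg=b.baseline_angle_deg,
                )
                partition = build_partition(slc, rule=config.partition_rule)
                nerve_mask = extract_nerve_mask(slc)
                rec = score_occupancy(
                    partition,
                    nerve_mask,
                    threshold=config.occupancy_threshold,
                    subject_id=b.subject_id,
                    side=b.side,
                    site=site,
                    retention_label=b.retention_label,
                )
                records.append(rec)
            except (LandmarkError, GeometryError, SegmentationError) as exc:
                exclusions.append(_excl(b, f"occupancy@{site}", exc))
            sm = measure_site(
                mri, cbct, b.nerve_midpoint_mm, site,
                config=config.segmentation, cached_masks=cached_masks,
            )
            for key, msg in sm.failures.items():
                exclusions.append(_excl(b, f"{key}@{site}", msg))
            for ds in sm.diameters:
                diam_entries.append((b.subject_id, b.side, ds))

    if not records and not diam_entries:
        raise PipelineError("all records failed; nothing to report")

    occupancy_tables: dict[str, dict[str, CooccurrenceTable]] = {}
    for site in config.sites:
        at_site = [r for r in records if r.site == site]
        if not at_site:
            continue
        if config.stratify_by == "none":
            occupancy_tables[site] = {"pooled": build_cooccurrence(at_site, site)}
        else:
            occupancy_tables[site] = stratify(at_site, site, by=config.stratify_by)

    diameters = diameters_to_frame(diam_entries)
    diameter_summary = (
        diameters.groupby(["site", "structure", "modality", "plane"], as_index=False)
        .agg(n=("diameter_mm", "size"), mean_mm=("diameter_mm", "mean"),
             sd_mm=("diameter_mm", lambda x: x.std(ddof=1)))
        if not diameters.empty
        else pd.DataFrame(columns=["site", "structure", "modality", "plane",
                                   "n", "mean_mm", "sd_mm"])
    )
    observations = compute_observations(diameters) if not diameters.empty else pd.DataFrame()
    conversion_summary = (
        summaries_frame(observations) if not observations.empty else pd.DataFrame()
    )
    per_subject = side_average(observations)
    wilcoxon: list[WilcoxonResult] = []
    for site in config.sites:
        for plane in PLANES:
            try:
                wilcoxon.append(
                    compare_factors(per_subject, site, plane,
                                    zero_handling=config.zero_handling,
                                    alpha=config.alpha)
                )
            except InputError as exc:
                exclusions.append({"subject_id": "", "side": "", "stage":
                                   f"wilcoxon@{site}/{plane}", "reason": str(exc)})

    provenance = {
        "config": _jsonable(asdict(config)),
        "config_hash": config.digest(),
        "versions": _versions(),
        "n_subject_sides": len(bundles),
        "n_occupancy_records": len(records),
        "n_exclusions": len(exclusions),
    }
    if config.include_timestamp:
        provenance["timestamp"] = datetime.now(timezone.utc).isoformat()

    report = StudyReport(
        occupancy_records=records_to_frame(records),
        occupancy_tables=occupancy_tables,
        diameters=diameters,
        diameter_summary=diameter_summary,
        observations=observations,
        conversion_summary=conversion_summary,
        per_subject=per_subject,
        wilcoxon=wilcoxon,
        exclusions=exclusions,
        provenance=provenance,
    )
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def _seed_voxel(volume: ImageVolume, nerve_mm: tuple[float, float], z: int):
    return (z, int(nerve_mm[1] / volume.spacing[1]), int(nerve_mm[0] / volume.spacing[2]))


def _excl(b: _Bundle, stage: str, exc) -> dict:
    log.warning("excluded %s/%s at %s: %s", b.subject_id, b.side, stage, exc)
    return {"subject_id": b.subject_id, "side": b.side, "stage": stage, "reason": str(exc)}


def _versions() -> dict:
    import nibabel
    import scipy

    return {
        "iansegmap": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
    }


def write_report(report: StudyReport, out_dir: str | Path) -> Path:
    """Write the report as a CSV set plus JSON.

    Percentages in the CSV tables are rounded to one decimal (matching the
    usual table style); full precision is retained in the JSON report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.occupancy_records.to_csv(out / "occupancy_records.csv", index=False)
    for site, tables in report.occupancy_tables.items():
        frames = []
        for stratum, table in tables.items():
            df = table.to_frame(decimals=1)
            df.insert(0, "stratum", stratum)
            df.insert(0, "row", df.index)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            out / f"occupancy_{site}.csv", index=False
        )
    report.diameters.to_csv(out / "diameters.csv", index=False)
    report.diameter_summary.round(3).to_csv(out / "diameter_summary.csv", index=False)
    if not report.observations.empty:
        report.observations.to_csv(out / "conversion_observations.csv", index=False)
        report.conversion_summary.round(3).to_csv(
            out / "conversion_summary.csv", index=False
        )
    wilcoxon_json = [
        _jsonable(asdict(w)) | {"reject_null": w.reject_null} for w in report.wilcoxon
    ]
    (out / "wilcoxon.json").write_text(json.dumps(wilcoxon_json, indent=2, sort_keys=True))
    full = {
        "provenance": report.provenance,
        "wilcoxon": wilcoxon_json,
        "conversion_summary": report.conversion_summary.to_dict(orient="records"),
        "diameter_summary": report.diameter_summary.to_dict(orient="records"),
        "occupancy_marginals": {
            site: {stratum: t.marginal.tolist() for stratum, t in tables.items()}
            for site, tables in report.occupancy_tables.items()
        },
        "exclusions": report.exclusions,
    }
    (out / "report.json").write_text(json.dumps(_jsonable(full), indent=2, sort_keys=True))
    return out
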