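"""Per-patient measurement chain and cohort analysis.

``run_patient`` executes the full measurement sequence on one pre/post case:

    volume QC -> masked ICP superimposition -> cranial frame -> region crops
    -> condylar rigid fits -> condyle displacement metrics -> symphysis
    centre-point deviation -> airway segment volumes -> CSA profiles ->
    percentage change

Any stage error aborts the patient with a structured reason; ``run_cohort``
continues, tallies exclusions (accounting closure: patients in = records out
+ exclusions), summarises each metric (median, IQR), and runs the configured
grid of one-tailed Spearman tests between sagittal deviation sources (L_dX,
R_dX, S_dX) and airway outcomes.  No multiple-testing correction is applied
by default; an optional Benjamini-Hochberg switch is provided.

``simulate_cohort_study`` is the synthetic power-study path: it generates a
phantom cohort, measures the symphysis shift and the hypopharyngeal minCSA
change through the same sectioning operations, and tests the coupling
hypothesis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .airway_metrics import (
    AirwayChange,
    AirwayPlanes,
    AirwayProfile,
    AirwaySegmentVolumes,
    airway_change,
    airway_volumes,
    csa_profile,
)
from .errors import (
    InsufficientDataError,
    MandairError,
    UndefinedStatisticError,
    ValidationError,
)
from .mandible_metrics import (
    CondyleDisplacement,
    SymphysisDeviation,
    condyle_displacement,
    crop_region,
    fit_region_transform,
    symphysis_deviation,
)
from .mesh_core import RegionSpec, SurfaceMesh, VolumeQCReport, read_stl, volume_qc, write_stl
from .registration import (
    LandmarkSet,
    build_frame,
    midsagittal_plane,
    register_icp,
    to_frame,
)
from .stats import (
    CorrelationResult,
    benjamini_hochberg,
    describe,
    icc_a1,
    spearman_one_tailed,
)

log = logging.getLogger(__name__)

DEFAULT_HYPOTHESES = {
    "sources": ["L_dX", "R_dX", "S_dX"],
    "outcomes": [
        "vol_total_pct",
        "vol_naso_pct",
        "vol_oro_pct",
        "vol_hypo_pct",
        "mincsa_oro_pct",
        "mincsa_hypo_pct",
    ],
    "direction": "positive",
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Shared landmark / region / plane configuration (JSON or YAML)."""

    landmarks: dict
    mask_region: dict
    region_specs: dict
    airway_plane_z: dict
    qc_tolerance: float = 0.02
    icp_samples: int = 2000
    icp_seed: int = 0
    profile_spacing: float = 1.0
    area_mode: str = "sum"
    shape_change_rms: float = 0.5

    def landmark_set(self) -> LandmarkSet:
        return LandmarkSet({k: np.asarray(v, float) for k, v in self.landmarks.items()})

    def mask(self) -> RegionSpec:
        return RegionSpec.from_dict(self.mask_region)

    def region(self, name: str) -> RegionSpec:
        return RegionSpec.from_dict(self.region_specs[name])

    def airway_planes(self) -> AirwayPlanes:
        z = self.airway_plane_z
        return AirwayPlanes.from_z_offsets(z["top"], z["naso_oro"], z["e_plane"], z["bottom"])

    def to_dict(self) -> dict:
        return {
            "landmarks": {k: list(map(float, v)) for k, v in self.landmarks.items()},
            "mask_region": self.mask_region,
            "region_specs": self.region_specs,
            "airway_plane_z": {k: float(v) for k, v in self.airway_plane_z.items()},
            "qc_tolerance": self.qc_tolerance,
            "icp_samples": self.icp_samples,
            "icp_seed": self.icp_seed,
            "profile_spacing": self.profile_spacing,
            "area_mode": self.area_mode,
            "shape_change_rms": self.shape_change_rms,
        }

    def save(self, path) -> None:
        path = Path(path)
        text = json.dumps(self.to_dict(), indent=2)
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


@dataclass
class PatientCase:
    """File references for one patient's pre/post meshes + configuration."""

    id: str
    pre_bone: Path
    post_bone: Path
    pre_airway: Path
    post_airway: Path
    config: Path
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for attr in ("pre_bone", "post_bone", "pre_airway", "post_airway", "config"):
            p = Path(getattr(self, attr))
            setattr(self, attr, p)
            if not p.exists():
                raise ValidationError(f"case {self.id}: missing file {p}")


# ---------------------------------------------------------------------------
# per-patient record
# ---------------------------------------------------------------------------


@dataclass
class PatientRecord:
    id: str
    qc: VolumeQCReport
    registration_rms: float
    condyle_left: CondyleDisplacement
    condyle_right: CondyleDisplacement
    symphysis: SymphysisDeviation
    volumes_pre: AirwaySegmentVolumes
    volumes_post: AirwaySegmentVolumes
    profile_pre: AirwayProfile
    profile_post: AirwayProfile
    change: AirwayChange
    warnings: list = field(default_factory=list)

    def to_row(self) -> dict:
        row: dict = {"patient": self.id, "qc_ratio": self.qc.ratio, "reg_rms_mm": self.registration_rms}
        for side, disp in (("L", self.condyle_left), ("R", self.condyle_right)):
            for key, value in disp.as_dict().items():
                if key == "side":
                    continue
                row[f"{side}_{key}"] = value
        row.update(self.symphysis.as_dict())
        for tag, vols in (("pre", self.volumes_pre), ("post", self.volumes_post)):
            for key, value in vols.as_dict().items():
                row[f"vol_{key}_{tag}_mm3"] = value
        for tag, prof in (("pre", self.profile_pre), ("post", self.profile_post)):
            row[f"mincsa_oro_{tag}_mm2"] = prof.min_csa_oro
            row[f"mincsa_hypo_{tag}_mm2"] = prof.min_csa_hypo
        row.update(self.change.as_dict())
        return row


@dataclass
class PatientFailure:
    id: str
    stage: str
    reason: str


@dataclass
class CohortResults:
    records: pd.DataFrame
    exclusions: list
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    icc_table: pd.DataFrame | None = None

    def summary_text(self) -> str:
        lines = [
            f"cohort: {len(self.records)} records, {len(self.exclusions)} exclusions",
        ]
        for f in self.exclusions:
            lines.append(f"  excluded {f.id} at {f.stage}: {f.reason}")
        lines.append("")
        lines.append("descriptives (median (Q1;Q3)):")
        for _, r in self.descriptives.iterrows():
            lines.append(
                f"  {r['variable']}: {r['median']:.2f} ({r['q1']:.2f};{r['q3']:.2f})"
            )
        lines.append("")
        lines.append("one-tailed Spearman tests:")
        for _, r in self.correlations.iterrows():
            if np.isnan(r["p_one_tailed"]):
                lines.append(f"  {r['source']} vs {r['outcome']}: {r['method']}")
                continue
            star = " *" if r["p_one_tailed"] < 0.05 else ""
            lines.append(
                f"  {r['source']} vs {r['outcome']}: rho={r['rho']:.3f}, "
                f"p={r['p_one_tailed']:.4f}{star}"
            )
        if self.icc_table is not None:
            lines.append("")
            lines.append("intra-rater reliability, ICC(A,1):")
            for _, r in self.icc_table.iterrows():
                lines.append(
                    f"  {r['variable']}: {r['icc']:.3f} "
                    f"({r['ci_low']:.3f};{r['ci_high']:.3f})"
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# per-patient pipeline
# ---------------------------------------------------------------------------


def run_patient(case: PatientCase, seed: int | None = None) -> PatientRecord:
    """Execute the full measurement chain for one patient case."""
    config = PipelineConfig.load(case.config)
    icp_seed = config.icp_seed if seed is None else seed
    warnings: list[str] = []

    pre_bone = read_stl(case.pre_bone, name=f"{case.id}_bone_pre")
    post_bone = read_stl(case.post_bone, name=f"{case.id}_bone_post")
    pre_air = read_stl(case.pre_airway, name=f"{case.id}_air_pre")
    post_air = read_stl(case.post_airway, name=f"{case.id}_air_post")

    qc = volume_qc(pre_bone, post_bone, tolerance=config.qc_tolerance)
    if not qc.passed:
        raise ValidationError(
            f"segmentation volume mismatch: ratio {qc.ratio:.4f} outside "
            f"±{config.qc_tolerance:.2%}"
        )

    reg = register_icp(
        post_bone,
        pre_bone,
        mask_region=config.mask(),
        samples=config.icp_samples,
        seed=icp_seed,
    )
    post_bone_aligned = reg.transform.apply_mesh(post_bone)
    post_air_aligned = reg.transform.apply_mesh(post_air)

    frame = build_frame(config.landmark_set())
    pre_bone_f = to_frame(pre_bone, frame)
    post_bone_f = to_frame(post_bone_aligned, frame)
    pre_air_f = to_frame(pre_air, frame)
    post_air_f = to_frame(post_air_aligned, frame)

    condyles = {}
    for side, region_name in (("left", "condyle_left"), ("right", "condyle_right")):
        spec = config.region(region_name)
        crop_pre = crop_region(pre_bone_f, spec, name=f"{region_name}_pre")
        crop_post = crop_region(post_bone_f, spec, name=f"{region_name}_post")
        fit = fit_region_transform(
            crop_pre,
            crop_post,
            shape_change_rms=config.shape_change_rms,
            seed=icp_seed,
            samples=config.icp_samples,
        )
        condyles[side] = condyle_displacement(
            fit.transform, crop_pre.surface_centroid(), side
        )

    sym_spec = config.region("symphysis")
    sym_pre = crop_region(pre_bone_f, sym_spec, name="symphysis_pre")
    sym_post = crop_region(post_bone_f, sym_spec, name="symphysis_post")
    # meshes are already in frame coordinates: the midsagittal plane is the
    # canonical XZ plane
    sym = symphysis_deviation(sym_pre, sym_post, midsagittal_plane_canonical())

    planes = config.airway_planes()
    vols_pre = airway_volumes(pre_air_f, planes, "pre")
    vols_post = airway_volumes(post_air_f, planes, "post")
    prof_pre = csa_profile(pre_air_f, planes, spacing=config.profile_spacing, area_mode=config.area_mode)
    prof_post = csa_profile(post_air_f, planes, spacing=config.profile_spacing, area_mode=config.area_mode)
    warnings.extend(prof_pre.warnings)
    warnings.extend(prof_post.warnings)
    change = airway_change(vols_pre, vols_post, prof_pre, prof_post)

    return PatientRecord(
        id=case.id,
        qc=qc,
        registration_rms=reg.rms,
        condyle_left=condyles["left"],
        condyle_right=condyles["right"],
        symphysis=sym,
        volumes_pre=vols_pre,
        volumes_post=vols_post,
        profile_pre=prof_pre,
        profile_post=prof_post,
        change=change,
        warnings=warnings,
    )


def midsagittal_plane_canonical():
    from .registration import CranialFrame

    return midsagittal_plane(CranialFrame.canonical())


# ---------------------------------------------------------------------------
# cohort analysis
# ---------------------------------------------------------------------------


def run_cohort(
    cases: list[PatientCase],
    hypotheses: dict | None = None,
    repeated_measures: dict | None = None,
    bh_correction: bool = False,
    seed: int | None = None,
) -> CohortResults:
    """Measure all cases, summarise, and test the configured hypotheses.

    ``repeated_measures`` maps variable name -> (n, 2) rating matrix for the
    optional intra-rater reliability table.  Exclusions never drop silently:
    every failed case appears with its stage and reason.
    """
    ids = [c.id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate patient ids in cohort")
    hypo = dict(DEFAULT_HYPOTHESES, **(hypotheses or {}))

    rows = []
    exclusions: list[PatientFailure] = []
    for case in cases:
        try:
            rows.append(run_patient(case, seed=seed).to_row())
        except MandairError as exc:
            stage = type(exc).__name__
            exclusions.append(PatientFailure(case.id, stage, str(exc)))
            log.warning("excluded %s (%s): %s", case.id, stage, exc)
    assert len(rows) + len(exclusions) == len(cases)
    if len(rows) < 4:
        raise InsufficientDataError(
            f"cohort analysis needs >= 4 successful records, got {len(rows)}"
        )
    records = pd.DataFrame(rows)

    numeric = records.select_dtypes(include=[np.number])
    desc_rows = [
        {"variable": col, **vars(describe(numeric[col].dropna()))}
        for col in numeric.columns
    ]
    descriptives = pd.DataFrame(desc_rows)

    corr_rows = []
    for source in hypo["sources"]:
        for outcome in hypo["outcomes"]:
            if source not in records or outcome not in records:
                continue
            try:
                res = spearman_one_tailed(
                    records[source], records[outcome], direction=hypo["direction"]
                )
                row = {
                    "source": source,
                    "outcome": outcome,
                    "rho": res.rho,
                    "p_one_tailed": res.p_one_tailed,
                    "n": res.n,
                    "method": res.method,
                }
            except UndefinedStatisticError as exc:
                row = {
                    "source": source,
                    "outcome": outcome,
                    "rho": np.nan,
                    "p_one_tailed": np.nan,
                    "n": len(records),
                    "method": f"undefined ({exc})",
                }
            corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)
    if bh_correction and len(correlations):
        correlations["p_bh"] = benjamini_hochberg(correlations["p_one_tailed"])

    icc_table = None
    if repeated_measures:
        icc_rows = []
        for var, matrix in repeated_measures.items():
            res = icc_a1(np.asarray(matrix, float))
            icc_rows.append(
                {
                    "variable": var,
                    "icc": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n": res.n,
                }
            )
        icc_table = pd.DataFrame(icc_rows)
        icc_table.loc[len(icc_table)] = {
            "variable": "average (arithmetic mean of estimates)",
            "icc": icc_table["icc"].mean(),
            "ci_low": icc_table["ci_low"].mean(),
            "ci_high": icc_table["ci_high"].mean(),
            "n": icc_table["n"].iloc[0] if len(icc_table) else 0,
        }

    return CohortResults(
        records=records,
        exclusions=exclusions,
        descriptives=descriptives,
        correlations=correlations,
        icc_table=icc_table,
    )


# ---------------------------------------------------------------------------
# phantom case I/O and the synthetic cohort study
# ---------------------------------------------------------------------------


def write_phantom_case(
    truth: ph.PhantomTruth, directory, case_id: str | None = None
) -> PatientCase:
    """Materialise a phantom as STL files + config + truth table on disk, so
    it is indistinguishable from a real case to the pipeline."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    case_id = case_id or truth.label
    bone = ph.make_bone_phantom(truth)
    air = ph.make_airway_phantom(truth)
    paths = {}
    for tag, mesh in (
        ("pre_bone", bone.pre),
        ("post_bone", bone.post),
        ("pre_airway", air.pre),
        ("post_airway", air.post),
    ):
        paths[tag] = directory / f"{case_id}_{tag}.stl"
        write_stl(mesh, paths[tag])
    config = PipelineConfig(
        landmarks={k: list(v) for k, v in bone.landmarks.to_dict().items()},
        mask_region=bone.mask_region.to_dict(),
        region_specs={k: v.to_dict() for k, v in bone.region_specs.items()},
        airway_plane_z=dict(ph.AIRWAY_PLANE_Z),
    )
    config_path = directory / f"{case_id}_config.json"
    config.save(config_path)
    truth_path = directory / f"{case_id}_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "condyle_left_rot": list(truth.condyle_left_rot),
                "condyle_left_trans": list(truth.condyle_left_trans),
                "condyle_right_rot": list(truth.condyle_right_rot),
                "condyle_right_trans": list(truth.condyle_right_trans),
                "symphysis_shift": list(truth.symphysis_shift),
                "noise_sd": truth.noise_sd,
                "seed": truth.seed,
            },
            indent=2,
        )
    )
    return PatientCase(
        id=case_id,
        pre_bone=paths["pre_bone"],
        post_bone=paths["post_bone"],
        pre_airway=paths["pre_airway"],
        post_airway=paths["post_airway"],
        config=config_path,
    )


def measure_subject_light(truth: ph.PhantomTruth, pre_cache: dict | None = None) -> dict:
    """Fast measurement of the coupling-study quantities for one subject:
    symphysis s_dX (midsagittal centre point) and hypopharyngeal minCSA
    percentage change, via the same sectioning operations as the full chain.

    ``pre_cache`` may carry the shared pre-operative template measurements
    (centroid and minCSA) to avoid re-measuring an identical template.
    """
    from .mesh_core import contour_centroid, section_with_plane

    plane = midsagittal_plane_canonical()
    planes = ph.airway_planes()
    if pre_cache is None:
        pre_cache = {}
    if "centre_pre" not in pre_cache:
        arch_pre = ph.symphysis_arch()
        pre_cache["arch_pre"] = arch_pre
        pre_cache["centre_pre"] = contour_centroid(section_with_plane(arch_pre, plane))
        # tube template spanning the profiled (hypopharyngeal) range only;
        # per-subject lumens are radial rescalings of this fixed topology
        pre_cache["template"] = _truth_tube(truth, truth.pre_profile, "pre")
        prof = csa_profile(pre_cache["template"], planes, segments=("hypo",))
        pre_cache["mincsa_hypo_pre"] = prof.min_csa_hypo

    s_dx, s_dz = truth.symphysis_shift
    arch_post = pre_cache["arch_pre"].transformed(np.eye(3), np.array([s_dx, 0.0, s_dz]))
    centre_post = contour_centroid(section_with_plane(arch_post, plane))
    diff = centre_post - pre_cache["centre_pre"]

    tube_post = _rescale_tube(pre_cache["template"], truth.pre_profile, truth.post_profile)
    prof_post = csa_profile(tube_post, planes, segments=("hypo",))
    return {
        "subject": truth.label,
        "S_dX": float(diff[0]),
        "S_dZ": float(diff[2]),
        "mincsa_hypo_pre_mm2": pre_cache["mincsa_hypo_pre"],
        "mincsa_hypo_post_mm2": prof_post.min_csa_hypo,
        "mincsa_hypo_pct": 100.0 * prof_post.min_csa_hypo / pre_cache["mincsa_hypo_pre"],
    }


def _truth_tube(truth: ph.PhantomTruth, profile, tag: str) -> SurfaceMesh:
    # only the hypopharyngeal span (plus margin) is profiled in the light path
    z_lo = ph.AIRWAY_PLANE_Z["bottom"] - 1.5
    z_hi = ph.AIRWAY_PLANE_Z["e_plane"] + 1.5
    n = int(round((z_hi - z_lo) / truth.ring_spacing)) + 1
    z = z_lo + truth.ring_spacing * np.arange(n)
    radii = profile(z - ph.AIRWAY_PLANE_Z["e_plane"])
    return ph.tube_mesh(z, radii, segments=truth.segments, name=f"airway_{tag}")


def _rescale_tube(template: SurfaceMesh, old_profile, new_profile) -> SurfaceMesh:
    """Radially rescale a tube-of-revolution mesh to a new radius profile.

    Exact because tube vertices (and the cap centroids, which sit on the
    axis) scale linearly with the ring radius at their Z."""
    offsets = template.vertices[:, 2] - ph.AIRWAY_PLANE_Z["e_plane"]
    scale = new_profile(offsets) / old_profile(offsets)
    verts = template.vertices.copy()
    verts[:, 0] *= scale
    verts[:, 1] *= scale
    return SurfaceMesh(verts, template.faces.copy(), "airway_post")


def simulate_cohort_study(
    spec: ph.CohortSpec, direction: str = "positive"
) -> tuple[pd.DataFrame, CorrelationResult]:
    """Generate a phantom cohort, measure it, and test S_dX vs the
    hypopharyngeal minCSA percentage change (one-tailed Spearman)."""
    truths, truth_table = ph.make_cohort(spec)
    pre_cache: dict = {}
    rows = [measure_subject_light(t, pre_cache) for t in truths]
    measured = pd.DataFrame(rows)
    measured = measured.merge(truth_table, on="subject")
    result = spearman_one_tailed(
        measured["S_dX"], measured["mincsa_hypo_pct"], direction=direction
    )
    return measured, result


def rejection_rate(
    coupling: float,
    n_subjects: int = 35,
    n_seeds: int = 50,
    alpha: float = 0.05,
    base_seed: int = 0,
    **spec_kwargs,
) -> float:
    """Fraction of seeds in which the cohort coupling test rejects at
    ``alpha`` (power for coupling > 0, type-I rate at coupling = 0)."""
    hits = 0
    for i in range(n_seeds):
        spec = ph.CohortSpec(
            n=n_subjects, coupling=coupling, seed=base_seed + 1000 + i, **spec_kwargs
        )
        _, res = simulate_cohort_study(spec)
        hits += res.p_one_tailed < alpha
    return hits / n_seeds
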