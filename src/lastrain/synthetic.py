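"""Synthetic 4D left-atrial anatomies, images, and two-group cohorts.

Real 4D retrospective-gated CT of the atrium is not publicly shareable,
so every downstream stage is exercised on synthetic data with known
ground truth.  The generator emulates:

* a closed LA-like endocardial surface (superellipsoid-deformed sphere
  with the five-wall region labelling plus an excluded superior cap as
  the pulmonary-vein/appendage analogue);
* a reservoir-expansion / conduit-recoil / active-contraction cycle,
  prescribed as a global area-strain transient ``S(t)`` with amplitude
  ``reservoir_amplitude`` at ``t_peak``, a decline to
  ``contractile_fraction * reservoir_amplitude`` at the
  conduit--contractile boundary ``t_cc``, and return to 0 at cycle end;
* per-region amplitude modifiers, per-vertex tracking jitter (Gaussian
  displacement noise), and 10- or 20-frame sampling (10% or 5% R-R
  increments);
* CT-like voxelized frames (bright blood pool on dark background);
* two-group cohorts with configurable group effects on the phasic
  parameters and volumetrics, with clinical covariates.

Motion law: each vertex is scaled radially about the centroid by
``s_v(t) = sqrt(1 + m_v * S(t) / 100)`` where ``m_v`` is the vertex's
regional modifier.  A face whose vertices share modifier ``m`` then has
area strain exactly ``m * S(t)`` (uniform scaling multiplies triangle
areas by ``s^2``), which is the closed-form oracle used by the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
import trimesh
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.ndimage import gaussian_filter

from .image import Image3D
from .mesh import (EXCLUDED, REGIONS, MeshFrameSequence, VolumeCurve,
                   assign_regions, enclosed_volume, spherical_region_chart)
from .strain import PhasicStrainModel

__all__ = [
    "MotionModelParams",
    "CohortSpec",
    "BaseShape",
    "make_base_shape",
    "strain_transient",
    "generate_mesh_sequence",
    "voxelize_sequence",
    "generate_cohort",
    "SyntheticMeshSequence",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# motion model
# ---------------------------------------------------------------------------

@dataclass
class MotionModelParams:
    """Prescribed phasic motion for one synthetic subject.

    reservoir_amplitude : peak global area strain (%), > 0 (0 allowed for
        the static/identity case).
    contractile_fraction : share of total emptying due to active
        contraction, in [0, 1]; the prescribed contractile strain is
        ``contractile_fraction * reservoir_amplitude``.
    t_peak, t_cc : normalized R-R times of peak reservoir strain and of
        the conduit--contractile boundary, ``0 < t_peak < t_cc < 1``.
    regional_modifiers : multiplicative amplitude factor per wall region
        (all > 0).
    noise_sd : per-vertex Gaussian displacement noise (mm), applied to
        all frames except the reference.
    n_frames : 10 (10% increments) or 20 (5% increments).
    transient_mode : "plateau" (piecewise monotone cubic with an exact
        plateau after t_cc -- an easy, well-defined detector target) or
        "smooth" (C2 periodic spline that stresses the detector).
    """

    reservoir_amplitude: float = 21.0
    contractile_fraction: float = 0.5
    t_peak: float = 0.40
    t_cc: float = 0.70
    regional_modifiers: dict[str, float] = dataclass_field(
        default_factory=lambda: {r: 1.0 for r in REGIONS})
    noise_sd: float = 0.0
    n_frames: int = 10
    seed: int = 0
    transient_mode: str = "plateau"

    def __post_init__(self) -> None:
        if not (0 < self.t_peak < self.t_cc < 1):
            raise ValueError("need 0 < t_peak < t_cc < 1")
        if self.reservoir_amplitude < 0:
            raise ValueError("reservoir_amplitude must be >= 0")
        if not 0 <= self.contractile_fraction <= 1:
            raise ValueError("contractile_fraction must be in [0, 1]")
        if set(self.regional_modifiers) != set(REGIONS):
            raise ValueError(f"regional_modifiers must cover {REGIONS}")
        if any(m <= 0 for m in self.regional_modifiers.values()):
            raise ValueError("regional_modifiers must be positive")
        if self.n_frames not in (10, 20):
            raise ValueError("n_frames must be 10 or 20")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.transient_mode not in ("plateau", "smooth"):
            raise ValueError("transient_mode must be 'plateau' or 'smooth'")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.n_frames

    @property
    def conduit_strain(self) -> float:
        return self.reservoir_amplitude * (1 - self.contractile_fraction)

    @property
    def contractile_strain(self) -> float:
        return self.reservoir_amplitude * self.contractile_fraction


def strain_transient(t: np.ndarray, params: MotionModelParams) -> np.ndarray:
    """Prescribed global area-strain transient S(t) in percent.

    Rises 0 -> A on [0, t_peak], declines to A*cf at t_cc (the conduit
    phase sheds (1-cf)*A), and returns to 0 at the cycle end.  In
    "plateau" mode a short exact plateau follows t_cc; in "smooth" mode
    the transient is a C2 periodic cubic spline through the same phase
    landmarks.  By construction reservoir = conduit + contractile.
    """
    t = np.asarray(t, dtype=float)
    A = params.reservoir_amplitude
    if A == 0:
        return np.zeros_like(t)
    cf = params.contractile_fraction
    tp, tc = params.t_peak, params.t_cc
    if params.transient_mode == "plateau":
        dt = min(0.08, (1.0 - tc) / 3.0)
        knots_x = np.array([0.0, tp, tc, tc + dt, 1.0])
        knots_y = np.array([0.0, A, A * cf, A * cf, 0.0])
        f = PchipInterpolator(knots_x, knots_y)
    else:
        # C2 periodic spline; a gently-sloped diastasis knot after t_cc
        # separates the sharp conduit recoil from the atrial kick
        mid_conduit = 0.5 * (tp + tc)
        diastasis = tc + 0.35 * (1.0 - tc)
        knots_x = np.array([0.0, 0.5 * tp, tp, mid_conduit, tc,
                            diastasis, 1.0])
        knots_y = np.array([0.0, 0.55 * A, A, A * (cf + 0.5 * (1 - cf)),
                            A * cf, 0.93 * A * cf, 0.0])
        f = CubicSpline(knots_x, knots_y, bc_type="periodic")
    return f(np.mod(t, 1.0))


# ---------------------------------------------------------------------------
# base anatomy
# ---------------------------------------------------------------------------

@dataclass
class BaseShape:
    """Closed triangulated LA-like reference surface with region labelling."""

    vertices: np.ndarray          # (n, 3) mm, centered at the origin
    faces: np.ndarray             # (m, 3)
    unit_directions: np.ndarray   # (n, 3) parametric-sphere chart positions
    region_labels: np.ndarray     # per-face labels
    vertex_regions: np.ndarray    # per-vertex chart labels (modifier lookup)

    def validate(self) -> None:
        tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        if not (tm.is_watertight and tm.is_winding_consistent):
            raise ValueError("base shape must be a closed orientable surface")


def make_base_shape(
    subdivisions: int = 3,
    radius_mm: float = 30.0,
    axes: tuple[float, float, float] = (1.0, 0.85, 1.15),
    superellipse_p: float = 2.5,
    sphere: bool = False,
) -> BaseShape:
    """Superellipsoid-deformed icosphere with the five-wall labelling.

    ``sphere=True`` gives the plain sphere (axes 1, exponent 2), for
    which uniform radial motion is an exact similarity.
    """
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(ico.vertices, float)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    if sphere:
        axes, superellipse_p = (1.0, 1.0, 1.0), 2.0
    a = np.asarray(axes, float)
    rho = np.sum(np.abs(u / a) ** superellipse_p, axis=1) ** (-1.0 / superellipse_p)
    vertices = radius_mm * rho[:, None] * u
    faces = np.asarray(ico.faces, int)
    labels = assign_regions(vertices, faces, chart_directions=u)
    vertex_regions = spherical_region_chart(u)
    shape = BaseShape(vertices=vertices, faces=faces, unit_directions=u,
                      region_labels=labels, vertex_regions=vertex_regions)
    shape.validate()
    return shape


# ---------------------------------------------------------------------------
# mesh sequence generation
# ---------------------------------------------------------------------------

class SyntheticMeshSequence(MeshFrameSequence):
    """Mesh sequence plus generator ground truth (prescribed transient,
    per-vertex modifiers, and noise-free geometry)."""

    def __init__(self, *args, params: MotionModelParams,
                 base_shape: BaseShape, vertex_modifiers: np.ndarray,
                 noise_free_vertices: list[np.ndarray], **kwargs) -> None:
        super().__init__(*args, **kwargs)
        self.params = params
        self.base_shape = base_shape
        self.vertex_modifiers = vertex_modifiers
        self.noise_free_vertices = noise_free_vertices

    def prescribed_global_strain(self, t: np.ndarray | None = None) -> np.ndarray:
        if t is None:
            t = self.frame_times
        return strain_transient(t, self.params)

    def ground_truth_element_strain(self) -> np.ndarray:
        """Elemental area strain of the noise-free motion, (n_frames, n_faces)."""
        from .strain import area_strain  # local import to avoid cycle at module load

        clean = MeshFrameSequence(
            vertices_per_frame=self.noise_free_vertices,
            faces=self.faces, frame_times=self.frame_times,
            region_labels=self.region_labels)
        return area_strain(clean)


def generate_mesh_sequence(
    params: MotionModelParams,
    base_shape: BaseShape | None = None,
) -> SyntheticMeshSequence:
    """Deform the base anatomy through the prescribed phasic cycle.

    Frame 0 is the end-diastolic reference.  Vertices are scaled radially
    about the origin by ``sqrt(1 + m_v * S(t)/100)`` (``m_v`` = modifier
    of the vertex's wall region; 1 for the excluded cap), so the
    elementwise area strain of a face with uniform modifier ``m`` is
    exactly ``m * S(t)``.  Gaussian displacement noise (tracking jitter)
    is added to every frame except the reference.
    """
    if base_shape is None:
        base_shape = make_base_shape()
    base_shape.validate()
    times = params.frame_times
    s_curve = strain_transient(times, params)
    modifiers = np.array([
        params.regional_modifiers.get(r, 1.0) if r != EXCLUDED else 1.0
        for r in base_shape.vertex_regions])
    scales = np.sqrt(1.0 + modifiers[None, :] * s_curve[:, None] / 100.0)
    clean = [scales[k][:, None] * base_shape.vertices
             for k in range(params.n_frames)]
    rng = np.random.default_rng(params.seed)
    noisy = [clean[0].copy()]
    for k in range(1, params.n_frames):
        v = clean[k]
        if params.noise_sd > 0:
            v = v + rng.normal(0.0, params.noise_sd, size=v.shape)
        noisy.append(v)
    return SyntheticMeshSequence(
        vertices_per_frame=noisy,
        faces=base_shape.faces.copy(),
        frame_times=times,
        region_labels=base_shape.region_labels.copy(),
        params=params,
        base_shape=base_shape,
        vertex_modifiers=modifiers,
        noise_free_vertices=clean,
    )


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def _rasterize_closed_mesh(vertices: np.ndarray, faces: np.ndarray,
                           xs: np.ndarray, ys: np.ndarray,
                           zs: np.ndarray) -> np.ndarray:
    """Boolean inside/outside on a voxel grid by z-ray parity counting.

    Vertical rays through each (x, y) grid column are intersected with
    every triangle (2D barycentric test on the projection); each crossing
    flips the parity of all voxels above it.
    """
    inside = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
    tri = vertices[faces]  # (F, 3, 3)
    for t in tri:
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = t
        denom = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
        if abs(denom) < 1e-14:       # projection degenerate (vertical face)
            continue
        i0 = np.searchsorted(xs, min(x0, x1, x2))
        i1 = np.searchsorted(xs, max(x0, x1, x2), side="right")
        j0 = np.searchsorted(ys, min(y0, y1, y2))
        j1 = np.searchsorted(ys, max(y0, y1, y2), side="right")
        if i0 >= i1 or j0 >= j1:
            continue
        px = xs[i0:i1][:, None]
        py = ys[j0:j1][None, :]
        l0 = ((y1 - y2) * (px - x2) + (x2 - x1) * (py - y2)) / denom
        l1 = ((y2 - y0) * (px - x2) + (x0 - x2) * (py - y2)) / denom
        l2 = 1.0 - l0 - l1
        hit = (l0 >= 0) & (l1 >= 0) & (l2 >= 0)
        if not hit.any():
            continue
        zc = l0 * z0 + l1 * z1 + l2 * z2
        ii, jj = np.nonzero(hit)
        flips = zs[None, :] > zc[ii, jj][:, None]
        np.logical_xor.at(inside, (ii + i0, jj + j0), flips)
    return inside


def voxelize_sequence(
    seq: MeshFrameSequence,
    voxel_size: float | tuple[float, float, float] = 2.0,
    margin_mm: float = 6.0,
    smooth_sigma_vox: float = 0.7,
    noise_sd: float = 0.0,
    seed: int = 0,
    fov_mm: float | None = None,
) -> list[Image3D]:
    """CT-like scalar volumes (blood pool bright, background dark).

    All frames share one world grid sized from the union of the frame
    bounding boxes plus ``margin_mm``.  Intensities are 1 inside the
    endocardial surface and 0 outside, optionally Gaussian-smoothed (in
    voxels) and corrupted with additive Gaussian noise.
    """
    spacing = (voxel_size,) * 3 if np.isscalar(voxel_size) else tuple(voxel_size)
    all_v = np.vstack(seq.vertices_per_frame)
    lo = all_v.min(axis=0) - margin_mm
    hi = all_v.max(axis=0) + margin_mm
    if fov_mm is not None and np.any(hi - lo > fov_mm):
        raise ValueError("mesh exceeds the requested field of view")
    extent = all_v.max(axis=0) - all_v.min(axis=0)
    if np.any(extent < 3 * np.asarray(spacing)):
        raise ValueError("voxel size too coarse: need >= 3 voxels across "
                         "the smallest feature")
    # offset the grid by half a voxel so rays avoid mesh vertices/edges
    grids = [lo[a] + spacing[a] * (0.5 + np.arange(
        int(np.ceil((hi[a] - lo[a]) / spacing[a])))) for a in range(3)]
    rng = np.random.default_rng(seed)
    frames = []
    for verts in seq.vertices_per_frame:
        inside = _rasterize_closed_mesh(verts, seq.faces, *grids)
        data = inside.astype(np.float32)
        if smooth_sigma_vox > 0:
            data = gaussian_filter(data, smooth_sigma_vox)
        if noise_sd > 0:
            data = data + rng.normal(0, noise_sd, data.shape).astype(np.float32)
        frames.append(Image3D(data, spacing, tuple(g[0] for g in grids)))
    return frames


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: Baseline (group-0) sampling distributions; means/SDs chosen to emulate
#: an AF pre-ablation population (ages ~61 +- 12, 39% female, reservoir
#: strain ~24%, contractile fraction ~0.55, LA EDV ~82 mL).
DEFAULT_COVARIATES: dict[str, tuple] = {
    "age_y": (61.0, 12.0, 25.0, 90.0),
    "female_prevalence": 0.39,
    "height_cm_male": (180.0, 8.0),
    "height_cm_female": (165.0, 8.0),
    "weight_kg": (90.0, 20.0, 45.0, 160.0),
    "chf_prevalence": 0.145,
    "hypertension_prevalence": 0.58,
    "diabetes_prevalence": 0.16,
    "stroke_tia_prevalence": 0.05,
    "vascular_disease_prevalence": 0.14,
}

DEFAULT_MOTION_PRIORS: dict[str, tuple] = {
    "reservoir_amplitude": (24.0, 9.0, 6.0, 60.0),
    "contractile_fraction": (0.55, 0.12, 0.15, 0.85),
    "t_peak": (0.40, 0.03, 0.32, 0.48),
    "t_cc": (0.70, 0.035, 0.60, 0.82),
    "regional_modifier_sd": 0.12,
    "la_edv_ml": (82.0, 30.0, 35.0, 220.0),
    "lv_edv_ml": (184.0, 35.0, 100.0, 320.0),
    "lvef_pct": (50.0, 6.8, 30.0, 70.0),
}

#: Default group-1 ("recurrence"-like) effects: reduced contractile strain
#: and reservoir amplitude, enlarged LA.
DEFAULT_GROUP_EFFECTS: dict[str, float] = {
    "contractile_strain": -6.6,
    "reservoir_amplitude": -4.0,
    "la_edv_ml": 28.0,
}


@dataclass
class CohortSpec:
    """Specification of a synthetic two-group cohort.

    ``group_effects`` are additive mean shifts applied to group 1:
    recognised keys are the MotionModelParams fields plus the derived
    ``contractile_strain`` (implemented by adjusting the contractile
    fraction at fixed reservoir amplitude + shift) and the volumetrics
    ``la_edv_ml`` / ``lvef_pct``.  ``mode="mesh"`` runs the full mesh
    pipeline per subject; ``mode="analytic"`` evaluates the prescribed
    transient directly (same extraction code, no mesh, fast -- used for
    large-n statistical checks).
    """

    n_per_group: int = 10
    group_effects: dict[str, float] = dataclass_field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    covariate_distributions: dict = dataclass_field(
        default_factory=lambda: dict(DEFAULT_COVARIATES))
    seed: int = 0
    n_frames: int = 20
    transient_mode: str = "smooth"
    noise_sd: float = 0.05
    mode: str = "mesh"
    subdivisions: int = 3
    group_labels: tuple[str, str] = ("no_recurrence", "recurrence")

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for key in ("female_prevalence", "chf_prevalence",
                    "hypertension_prevalence", "diabetes_prevalence",
                    "stroke_tia_prevalence", "vascular_disease_prevalence"):
            p = self.covariate_distributions.get(key, 0.0)
            if not 0 <= p <= 1:
                raise ValueError(f"{key} must be in [0, 1]")
        if self.mode not in ("mesh", "analytic"):
            raise ValueError("mode must be 'mesh' or 'analytic'")


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _sample_subject_params(rng: np.random.Generator, spec: CohortSpec,
                           group: int, subject_seed: int) -> dict:
    pri = DEFAULT_MOTION_PRIORS
    eff = spec.group_effects if group == 1 else {}
    A = _truncated_normal(rng, *pri["reservoir_amplitude"])
    cf = _truncated_normal(rng, *pri["contractile_fraction"])
    tp = _truncated_normal(rng, *pri["t_peak"])
    tc = _truncated_normal(rng, *pri["t_cc"])
    tc = max(tc, tp + 0.12)
    # effects target the derived strains jointly: contractile_strain shifts
    # the prescribed contractile strain by exactly its delta even when the
    # reservoir amplitude is shifted too
    contractile_target = A * cf + eff.get("contractile_strain", 0.0)
    A = A + eff.get("reservoir_amplitude", 0.0)
    if A <= 0:
        raise ValueError("degenerate group effect: non-positive reservoir "
                         "amplitude after shift")
    if "contractile_strain" in eff:
        cf = float(np.clip(contractile_target / A, 0.05, 0.95))
    tp = float(np.clip(tp + eff.get("t_peak", 0.0), 0.25, 0.55))
    tc = float(np.clip(tc + eff.get("t_cc", 0.0), tp + 0.1, 0.9))
    sd_mod = pri["regional_modifier_sd"]
    modifiers = {r: _truncated_normal(rng, 1.0, sd_mod, 0.6, 1.6)
                 for r in REGIONS}
    la_edv = _truncated_normal(rng, *pri["la_edv_ml"]) + eff.get("la_edv_ml", 0.0)
    if la_edv <= 0:
        raise ValueError("degenerate group effect: non-positive LA EDV")
    lv_edv = _truncated_normal(rng, *pri["lv_edv_ml"])
    lvef = float(np.clip(_truncated_normal(rng, *pri["lvef_pct"])
                         + eff.get("lvef_pct", 0.0), 5.0, 85.0))
    params = MotionModelParams(
        reservoir_amplitude=A, contractile_fraction=cf, t_peak=tp, t_cc=tc,
        regional_modifiers=modifiers, noise_sd=spec.noise_sd,
        n_frames=spec.n_frames, seed=subject_seed,
        transient_mode=spec.transient_mode)
    return {"params": params, "la_edv_ml": la_edv, "lv_edv_ml": lv_edv,
            "lvef_pct": lvef}


def _sample_covariates(rng: np.random.Generator, spec: CohortSpec) -> dict:
    cov = spec.covariate_distributions
    female = bool(rng.random() < cov["female_prevalence"])
    h_mean, h_sd = cov["height_cm_female" if female else "height_cm_male"]
    height = _truncated_normal(rng, h_mean, h_sd, 140, 210)
    weight = _truncated_normal(rng, *cov["weight_kg"])
    age = _truncated_normal(rng, *cov["age_y"])
    flags = {name: bool(rng.random() < cov[f"{name}_prevalence"])
             for name in ("chf", "hypertension", "diabetes", "stroke_tia",
                          "vascular_disease")}
    return {"age_y": age, "female": female, "height_cm": height,
            "weight_kg": weight, "bmi": weight / (height / 100.0) ** 2,
            **flags}


def _lv_volume_curve(times: np.ndarray, edv: float, ef_pct: float,
                     t_es: float = 0.40) -> VolumeCurve:
    """Parametric LV volume transient: ejection to ESV at end-systole,
    refill to EDV by cycle end (smoothstep in both directions)."""
    sv = edv * ef_pct / 100.0
    tau = np.clip(times / t_es, 0, 1)
    eject = 3 * tau**2 - 2 * tau**3
    tau2 = np.clip((times - t_es) / (1.0 - t_es), 0, 1)
    refill = 3 * tau2**2 - 2 * tau2**3
    v = edv - sv * eject + sv * refill * (times >= t_es)
    return VolumeCurve(chamber="LV", volumes=v, frame_times=times)


def _analytic_curveset(params: MotionModelParams):
    from .strain import StrainCurveSet

    t = params.frame_times
    s = strain_transient(t, params)
    regional = {r: params.regional_modifiers[r] * s for r in REGIONS}
    return StrainCurveSet(frame_times=t, global_strain=s,
                          regional_strain=regional)


def generate_cohort(
    spec: CohortSpec,
    return_sequences: bool = False,
    curves_out: list | None = None,
) -> tuple[pd.DataFrame, dict[str, SyntheticMeshSequence] | None]:
    """Generate a two-group cohort table (and optionally the meshes).

    Returns one row per subject with covariates, CHA2DS2-VASc,
    volumetrics, the 36 phasic features extracted by the measurement
    pipeline, the prescribed (true) motion parameters under ``true_*``
    columns, and a ``phase_corrected`` flag (subjects for which automatic
    phase detection required the manual-correction hook, which falls back
    to the prescribed boundary time -- mirroring the manual review step
    of the measurement protocol).

    ``curves_out``, if given a list, receives one tidy per-subject curve
    DataFrame per subject (for writing the measured curves alongside the
    metrics table).

    Fully reproducible: a fixed ``spec.seed`` yields an identical table.
    """
    from .stats import chads_vasc

    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.generate_state(2 * spec.n_per_group * 4)
    rows = []
    sequences: dict[str, SyntheticMeshSequence] = {}
    unit_volume_ml = None
    if spec.mode == "mesh":
        base_unit = make_base_shape(subdivisions=spec.subdivisions,
                                    radius_mm=1.0)
        unit_volume_ml = enclosed_volume(base_unit.vertices, base_unit.faces)
    idx = 0
    for group in (0, 1):
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(subject_seeds[4 * idx: 4 * idx + 2])
            subject_seed = int(subject_seeds[4 * idx + 2] % (2**31))
            sid = f"{spec.group_labels[group][:4]}_{i:03d}"
            cov = _sample_covariates(rng, spec)
            draw = _sample_subject_params(rng, spec, group, subject_seed)
            params: MotionModelParams = draw["params"]
            times = params.frame_times
            lv_curve = _lv_volume_curve(times, draw["lv_edv_ml"],
                                        draw["lvef_pct"])
            if spec.mode == "mesh":
                radius = (draw["la_edv_ml"] / unit_volume_ml) ** (1.0 / 3.0)
                shape = make_base_shape(subdivisions=spec.subdivisions,
                                        radius_mm=radius)
                seq = generate_mesh_sequence(params, shape)
                model = PhasicStrainModel(seq, lv_volumes=lv_curve,
                                          height_cm=cov["height_cm"],
                                          weight_kg=cov["weight_kg"])
                if return_sequences:
                    sequences[sid] = seq
            else:
                curves = _analytic_curveset(params)
                s = curves.global_strain
                la_curve = VolumeCurve(
                    chamber="LA",
                    volumes=draw["la_edv_ml"] * (1 + s / 100.0) ** 1.5,
                    frame_times=times)
                model = PhasicStrainModel(curves, lv_volumes=lv_curve,
                                          la_volumes=la_curve,
                                          height_cm=cov["height_cm"],
                                          weight_kg=cov["weight_kg"])
            res = model.fit()
            corrected = False
            if not res.phases.ok:
                res = model.fit(t_cc_override=params.t_cc)
                corrected = True
            row = {
                "subject_id": sid,
                "group": group,
                "group_label": spec.group_labels[group],
                **cov,
                "chads_vasc": chads_vasc(
                    chf=cov["chf"], hypertension=cov["hypertension"],
                    diabetes=cov["diabetes"], stroke_tia=cov["stroke_tia"],
                    vascular_disease=cov["vascular_disease"],
                    age_y=cov["age_y"], female=cov["female"]),
                "phase_corrected": corrected,
                **(res.metrics.volumetric or {}),
                **res.feature_vector().to_dict(),
                "true_reservoir_strain": params.reservoir_amplitude,
                "true_conduit_strain": params.conduit_strain,
                "true_contractile_strain": params.contractile_strain,
                "true_t_peak": params.t_peak,
                "true_t_cc": params.t_cc,
            }
            rows.append(row)
            if curves_out is not None:
                cf = res.curves.to_frame()
                cf.insert(0, "subject_id", sid)
                curves_out.append(cf)
            idx += 1
    table = pd.DataFrame(rows)
    if table["subject_id"].duplicated().any():
        raise RuntimeError("duplicated subject ids")
    return table, (sequences if return_sequences else None)
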