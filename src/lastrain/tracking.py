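"""Baseline 3D feature tracking for 4D cardiac volumes.

Frame-to-frame motion is estimated with a multi-resolution B-spline
free-form deformation maximizing normalized cross-correlation (LBFGSB,
full regular sampling, single-threaded -- deterministic by contract).
Consecutive-pair fields are composed back to the end-diastolic frame to
propagate the ED endocardial mesh through the cycle, which bounds the
per-pair motion compared with direct frame-0-to-k registration.

The tracker is pluggable: anything implementing ``track(volumes,
ed_mesh)`` can substitute for :class:`BaselineTracker` (e.g.
:class:`GroundTruthTracker`, which replays the synthetic generator's
exact motion for isolating downstream stages).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .image import Image3D
from .mesh import MeshFrameSequence

__all__ = [
    "RegistrationSettings",
    "DeformationField",
    "register_pair",
    "propagate_mesh",
    "BaselineTracker",
    "GroundTruthTracker",
]

logger = logging.getLogger(__name__)


@dataclass
class RegistrationSettings:
    """Deterministic B-spline FFD registration settings.

    ``grid_spacing_mm`` controls smoothness (coarser = smoother field);
    multi-resolution levels are defined by ``shrink_factors`` /
    ``smoothing_sigmas`` (voxel units).
    """

    grid_spacing_mm: float = 40.0
    shrink_factors: tuple[int, ...] = (4, 2)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0)
    n_iterations: int = 60
    convergence_tol: float = 1e-7


@dataclass
class DeformationField:
    """Point mapping from fixed-frame to moving-frame coordinates (mm).

    Wraps the fitted transform together with the domain it is valid on
    and the similarity achieved; ``composition`` records consecutive-pair
    provenance when fields are chained back to frame 0.
    """

    transform: object                     # sitk.Transform
    domain_lo: np.ndarray                 # mm
    domain_hi: np.ndarray                 # mm
    grid_spacing_mm: float
    metric_initial: float
    metric_final: float
    improved: bool
    composition: list = field(default_factory=list)

    def transform_points(self, points: np.ndarray, check_domain: bool = True) -> np.ndarray:
        pts = np.asarray(points, float)
        if check_domain:
            if np.any(pts < self.domain_lo - 1e-6) or np.any(pts > self.domain_hi + 1e-6):
                raise ValueError("point leaves the deformation domain")
        return np.array([self.transform.TransformPoint(tuple(p)) for p in pts])

    def compose_with(self, later: "DeformationField") -> "DeformationField":
        """Field applying ``self`` then ``later`` (frame a->b->c)."""
        import SimpleITK as sitk

        comp = sitk.CompositeTransform(3)
        # sitk composite applies transforms in reverse order of addition
        comp.AddTransform(later.transform)
        comp.AddTransform(self.transform)
        return DeformationField(
            transform=comp,
            domain_lo=self.domain_lo, domain_hi=self.domain_hi,
            grid_spacing_mm=self.grid_spacing_mm,
            metric_initial=np.nan, metric_final=np.nan,
            improved=self.improved and later.improved,
            composition=self.composition + later.composition,
        )


def register_pair(fixed: Image3D, moving: Image3D,
                  settings: RegistrationSettings | None = None) -> DeformationField:
    """B-spline FFD registration of one frame pair.

    Returns the field mapping fixed-frame coordinates to the
    corresponding anatomical location in the moving frame.  Registration
    is deterministic: full regular metric sampling, LBFGSB, one thread.
    Failure to improve the similarity beyond the identity initialization
    is flagged (``improved=False``) and logged, never silently accepted.
    """
    import SimpleITK as sitk

    settings = settings or RegistrationSettings()
    f_lo = np.asarray(fixed.origin)
    f_hi = f_lo + (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing)
    m_lo = np.asarray(moving.origin)
    m_hi = m_lo + (np.asarray(moving.shape) - 1) * np.asarray(moving.spacing)
    if np.any(f_hi < m_lo) or np.any(m_hi < f_lo):
        raise ValueError("fixed and moving fields of view do not overlap")

    fimg = fixed.to_sitk()
    mimg = moving.to_sitk()
    extent = f_hi - f_lo
    mesh_size = [max(1, int(np.round(e / settings.grid_spacing_mm)))
                 for e in extent]
    tx = sitk.BSplineTransformInitializer(fimg, mesh_size)

    reg = sitk.ImageRegistrationMethod()
    reg.SetNumberOfThreads(1)
    reg.SetMetricAsCorrelation()
    reg.SetMetricSamplingStrategy(reg.NONE)        # full, deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=settings.convergence_tol,
        numberOfIterations=settings.n_iterations)
    reg.SetInitialTransform(tx, inPlace=True)
    levels = len(settings.shrink_factors)
    reg.SetShrinkFactorsPerLevel(list(settings.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(settings.smoothing_sigmas[:levels]))

    eval_reg = sitk.ImageRegistrationMethod()
    eval_reg.SetNumberOfThreads(1)
    eval_reg.SetMetricAsCorrelation()
    eval_reg.SetMetricSamplingStrategy(eval_reg.NONE)
    eval_reg.SetInterpolator(sitk.sitkLinear)
    identity = sitk.Transform(3, sitk.sitkIdentity)
    eval_reg.SetInitialTransform(identity)
    metric_initial = eval_reg.MetricEvaluate(fimg, mimg)

    reg.Execute(fimg, mimg)
    metric_final = reg.GetMetricValue()
    improved = metric_final <= metric_initial + 1e-12
    if not improved:
        logger.warning("registration did not improve similarity "
                       "(initial %.6f, final %.6f)", metric_initial,
                       metric_final)
    return DeformationField(
        transform=tx,
        domain_lo=f_lo, domain_hi=f_hi,
        grid_spacing_mm=settings.grid_spacing_mm,
        metric_initial=float(metric_initial),
        metric_final=float(metric_final),
        improved=improved,
        composition=["pair"],
    )


def propagate_mesh(ed_mesh: MeshFrameSequence,
                   pair_fields: list[DeformationField],
                   frame_times: np.ndarray | None = None) -> MeshFrameSequence:
    """Transport the ED mesh through composed consecutive-pair fields.

    ``pair_fields[k]`` must map frame ``k`` coordinates to frame ``k+1``
    coordinates; the returned sequence has ``len(pair_fields) + 1``
    frames, frame 0 being the unchanged ED mesh with connectivity and
    region labels preserved.
    """
    v0 = ed_mesh.vertices_per_frame[0]
    n_frames = len(pair_fields) + 1
    if frame_times is None:
        frame_times = np.arange(n_frames) / n_frames
    verts = [v0.copy()]
    current = v0
    for fld in pair_fields:
        current = fld.transform_points(current)
        verts.append(current)
    return MeshFrameSequence(vertices_per_frame=verts,
                             faces=ed_mesh.faces.copy(),
                             frame_times=np.asarray(frame_times, float),
                             region_labels=ed_mesh.region_labels.copy())


class BaselineTracker:
    """Consecutive-pair B-spline tracker over a 4D volume stack."""

    def __init__(self, settings: RegistrationSettings | None = None) -> None:
        self.settings = settings or RegistrationSettings()

    def track(self, volumes: list[Image3D],
              ed_mesh: MeshFrameSequence) -> MeshFrameSequence:
        if len(volumes) < 2:
            raise ValueError("need at least 2 frames to track")
        fields = []
        for k in range(len(volumes) - 1):
            fields.append(register_pair(volumes[k], volumes[k + 1],
                                        self.settings))
        times = np.arange(len(volumes)) / len(volumes)
        return propagate_mesh(ed_mesh, fields, frame_times=times)


class GroundTruthTracker:
    """Replays the synthetic generator's exact (noise-free) motion.

    Useful to isolate downstream strain/phase stages from registration
    error when debugging the image path.
    """

    def __init__(self, reference_sequence) -> None:
        self.reference_sequence = reference_sequence

    def track(self, volumes, ed_mesh) -> MeshFrameSequence:
        seq = self.reference_sequence
        return MeshFrameSequence(
            vertices_per_frame=[v.copy() for v in seq.noise_free_vertices],
            faces=seq.faces.copy(),
            frame_times=seq.frame_times.copy(),
            region_labels=seq.region_labels.copy())
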