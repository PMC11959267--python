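"""Phasic 3D left-atrial strain measurement.

The measurement chain implemented here:

1. **Area strain** per surface element: percentage area change of each
   triangle relative to the end-diastolic (ED, frame-0) reference anatomy.
   Positive strain is endocardial expansion, negative is contraction.
2. **Global / regional curves**: unweighted means of elemental strains over
   the LA body and within each of the five wall regions.
3. **Phase detection** on the global curve: end-diastole is the strain
   minimum (curves are cyclically re-referenced if the minimum is not at
   frame 0), peak reservoir strain is the maximum, and the
   conduit--contractile boundary is the point where the curve levels off
   after the sharp conduit downslope.
4. **Phasic metrics**: reservoir / conduit / contractile strains and the
   corresponding peak strain rates (SR, first derivative with respect to
   normalized R-R time), globally and per region using the *global* phase
   boundaries; 36 features per subject in total.
5. **Volumetrics**: chamber EDV/ESV/SV, emptying/ejection fractions, and
   body-surface-area indexed volumes.

The user-facing entry point is :class:`PhasicStrainModel`, whose ``fit()``
returns a :class:`PhasicStrainResults` carrying the curves, detected
phases, metrics and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mesh import REGIONS, MeshFrameSequence, VolumeCurve, element_areas

__all__ = [
    "area_strain",
    "aggregate_curves",
    "strain_rate",
    "detect_phases",
    "phasic_metrics",
    "volumetrics",
    "mosteller_bsa",
    "frame_count_comparison",
    "StrainCurveSet",
    "PhaseBoundaries",
    "PhasicMetrics",
    "PhasicStrainModel",
    "PhasicStrainResults",
    "FEATURE_NAMES",
    "PHASES",
    "SCOPES",
]

logger = logging.getLogger(__name__)

PHASES = ("reservoir", "conduit", "contractile")
SCOPES = ("global",) + REGIONS

#: Canonical names of the 36 phasic features (3 phases x {strain, SR} x
#: {global + 5 regions}).
FEATURE_NAMES = tuple(
    f"{phase}_{kind}_{scope}"
    for scope in SCOPES for phase in PHASES for kind in ("strain", "sr")
)

#: Default level-off fraction for the conduit--contractile boundary: the
#: boundary is the first post-peak sample where the downslope magnitude has
#: fallen to this fraction of the steepest conduit downslope seen so far.
DEFAULT_LEVEL_OFF_ALPHA = 0.2


# ---------------------------------------------------------------------------
# elemental strain and curve aggregation
# ---------------------------------------------------------------------------

def area_strain(seq: MeshFrameSequence) -> np.ndarray:
    """Per-element area strain curves, (n_frames, n_faces), in percent.

    ``strain[t, e] = 100 * (A_e(t) - A_e(0)) / A_e(0)`` with frame 0 the
    end-diastolic reference.  Elements whose reference area is degenerate
    are set to NaN (excluded downstream) and logged.
    """
    ref = seq.element_areas(0)
    degenerate = ref < 1e-12
    if degenerate.any():
        logger.warning("excluding %d degenerate reference elements",
                       int(degenerate.sum()))
    safe_ref = np.where(degenerate, 1.0, ref)
    out = np.empty((seq.n_frames, seq.n_faces))
    for k in range(seq.n_frames):
        a = seq.element_areas(k)
        out[k] = 100.0 * (a - ref) / safe_ref
    out[:, degenerate] = np.nan
    return out


def strain_rate(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """First derivative of a strain curve w.r.t. normalized time.

    Central differences at interior samples, forward/backward at the ends
    (units: % per normalized R-R time).
    """
    return np.gradient(np.asarray(values, float), np.asarray(times, float))


@dataclass
class StrainCurveSet:
    """Global and per-region strain and strain-rate curves.

    Strains are % relative to the ED reference (0 at frame 0); strain
    rates are % per normalized R-R time.
    """

    frame_times: np.ndarray
    global_strain: np.ndarray
    regional_strain: dict[str, np.ndarray]
    global_sr: np.ndarray = field(default=None)  # type: ignore[assignment]
    regional_sr: dict[str, np.ndarray] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, float)
        self.global_strain = np.asarray(self.global_strain, float)
        if len(self.global_strain) != len(self.frame_times):
            raise ValueError("curve length must equal frame count")
        if abs(self.global_strain[0]) > 1e-9:
            raise ValueError("strain at the reference frame must be 0")
        self.regional_strain = {r: np.asarray(v, float)
                                for r, v in self.regional_strain.items()}
        if self.global_sr is None:
            self.global_sr = strain_rate(self.global_strain, self.frame_times)
        if self.regional_sr is None:
            self.regional_sr = {r: strain_rate(v, self.frame_times)
                                for r, v in self.regional_strain.items()}

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def curve(self, scope: str) -> np.ndarray:
        return self.global_strain if scope == "global" else self.regional_strain[scope]

    def to_frame(self) -> pd.DataFrame:
        """All curves as a tidy DataFrame (time, scope, strain, sr)."""
        rows = []
        for scope in ("global", *self.regional_strain):
            s = self.curve(scope)
            sr = self.global_sr if scope == "global" else self.regional_sr[scope]
            for t, v, r in zip(self.frame_times, s, sr):
                rows.append((t, scope, v, r))
        return pd.DataFrame(rows, columns=[
            "time_rr_fraction", "scope", "strain_pct", "sr_pct_per_nt"])

    def decimate(self, step: int = 2) -> "StrainCurveSet":
        idx = np.arange(0, self.n_frames, step)
        return StrainCurveSet(
            frame_times=self.frame_times[idx],
            global_strain=self.global_strain[idx],
            regional_strain={r: v[idx] for r, v in self.regional_strain.items()},
        )


def aggregate_curves(
    element_curves: np.ndarray,
    region_labels: np.ndarray,
    frame_times: np.ndarray,
    element_areas_ref: np.ndarray | None = None,
    area_weighted: bool = False,
) -> StrainCurveSet:
    """Global and regional mean elemental strain curves.

    The global curve is the unweighted mean of elemental strains over all
    LA-body elements (excluded regions and degenerate/NaN elements
    omitted); regional curves are means within each of the five wall
    regions.  ``area_weighted=True`` switches to reference-area weighting
    (off by default, matching the mean-of-elements convention).
    """
    curves = np.asarray(element_curves, float)
    labels = np.asarray(region_labels, dtype=str)
    valid = ~np.isnan(curves[0])
    body = (labels != "excluded") & valid

    def _mean(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            raise ValueError("empty region in aggregation")
        if area_weighted:
            w = np.asarray(element_areas_ref, float)[mask]
            return (curves[:, mask] * w).sum(axis=1) / w.sum()
        return curves[:, mask].mean(axis=1)

    if area_weighted and element_areas_ref is None:
        raise ValueError("area weighting requires reference element areas")
    regional = {}
    for region in REGIONS:
        mask = body & (labels == region)
        if mask.any():
            regional[region] = _mean(mask)
        else:
            raise ValueError(f"empty region: {region}")
    return StrainCurveSet(frame_times=np.asarray(frame_times, float),
                          global_strain=_mean(body),
                          regional_strain=regional)


# ---------------------------------------------------------------------------
# phase detection
# ---------------------------------------------------------------------------

@dataclass
class PhaseBoundaries:
    """Atrial phase boundaries on the normalized R-R axis.

    ``t_ed`` is always 0 after cyclic re-referencing; ``ed_frame_index``
    records which original frame was identified as end-diastole (strain
    minimum).  ``t_peak``/``t_cc`` are expressed on the re-referenced time
    axis; ``peak_index``/``cc_index`` index the re-referenced samples.
    """

    t_ed: float
    t_peak: float
    t_cc: float
    detection_mode: str          # "automatic" | "corrected"
    status: str                  # "ok" | "needs_correction"
    reason: str = ""
    ed_frame_index: int = 0
    peak_index: int = -1
    cc_index: int = -1

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def require_ok(self) -> None:
        if not self.ok:
            raise ValueError(
                f"phase detection needs manual correction: {self.reason}")


def _cyclic_rereference(values: np.ndarray, times: np.ndarray,
                        ed_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a cyclic curve so sample ``ed_index`` becomes t=0, re-zeroed."""
    n = len(values)
    order = np.r_[ed_index:n, 0:ed_index]
    v = values[order] - values[ed_index]
    t = np.mod(times[order] - times[ed_index], 1.0)
    t[0] = 0.0
    return v, t


def detect_phases(
    global_strain: np.ndarray,
    frame_times: np.ndarray,
    alpha: float = DEFAULT_LEVEL_OFF_ALPHA,
    t_cc_override: float | None = None,
) -> PhaseBoundaries:
    """Identify end-diastole, peak reservoir strain and the
    conduit--contractile boundary from the global strain curve.

    End-diastole is the strain minimum (the curve is cyclically
    re-referenced when the minimum is not at frame 0).  Peak reservoir
    strain is the curve maximum.  The conduit--contractile boundary is
    found by scanning the inter-sample slopes after the peak: the steepest
    downslope seen so far defines the conduit downslope, and the boundary
    is placed at the start of the first interval whose slope has levelled
    off to within ``alpha`` times that steepest downslope.

    A curve without a positive peak, or without any post-conduit
    level-off before the cycle end, is returned with
    ``status="needs_correction"`` and an explanatory reason -- never a
    silent default.  ``t_cc_override`` implements the manual-correction
    hook: the boundary is snapped to the nearest sample at or after the
    peak and the result is flagged ``detection_mode="corrected"``.
    """
    s = np.asarray(global_strain, float)
    t = np.asarray(frame_times, float)
    if len(s) < 8:
        raise ValueError("phase detection requires at least 8 samples")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    ed = int(np.argmin(s))
    r, rt = _cyclic_rereference(s, t, ed)
    peak = int(np.argmax(r))
    if r[peak] <= 0:
        return PhaseBoundaries(0.0, np.nan, np.nan, "automatic",
                               "needs_correction", "no positive peak",
                               ed_frame_index=ed)
    n = len(r)

    if t_cc_override is not None:
        # manual correction: snap to the nearest post-peak sample
        cand = np.arange(peak + 1, n)
        if cand.size == 0:
            return PhaseBoundaries(0.0, rt[peak], np.nan, "corrected",
                                   "needs_correction",
                                   "no samples after peak", ed_frame_index=ed,
                                   peak_index=peak)
        cc = int(cand[np.argmin(np.abs(rt[cand] - t_cc_override))])
        return PhaseBoundaries(0.0, float(rt[peak]), float(rt[cc]),
                               "corrected", "ok", ed_frame_index=ed,
                               peak_index=peak, cc_index=cc)

    slopes = np.diff(r) / np.diff(rt)
    steepest_down = 0.0
    cc = -1
    for i in range(peak, n - 1):
        d = slopes[i]
        if d < 0:
            mag = -d
            if steepest_down > 0 and mag <= alpha * steepest_down and i > peak:
                cc = i
                break
            steepest_down = max(steepest_down, mag)
        else:
            # flat or rising interval after a real downslope: levelled off
            if steepest_down > 0 and i > peak:
                cc = i
                break
    if cc < 0:
        return PhaseBoundaries(0.0, float(rt[peak]), np.nan, "automatic",
                               "needs_correction",
                               "no level-off after the conduit downslope",
                               ed_frame_index=ed, peak_index=peak)
    return PhaseBoundaries(0.0, float(rt[peak]), float(rt[cc]), "automatic",
                           "ok", ed_frame_index=ed, peak_index=peak,
                           cc_index=cc)


# ---------------------------------------------------------------------------
# phasic metrics
# ---------------------------------------------------------------------------

@dataclass
class PhasicMetrics:
    """Phasic strains and peak SRs per scope, plus optional volumetrics.

    ``strain_sr`` is a DataFrame indexed by scope (global + 5 regions)
    with columns reservoir/conduit/contractile strain (%) and SR (% per
    normalized time); conduit and contractile SRs are stored signed
    (negative).  ``volumetric`` optionally carries EDV/ESV/SV (mL),
    indexed volumes (mL/m^2), LAEF/LVEF (%) and BSA (m^2).
    """

    strain_sr: pd.DataFrame
    phases: PhaseBoundaries
    volumetric: dict[str, float] | None = None

    def feature_vector(self) -> pd.Series:
        """The 36 phasic features under their canonical names."""
        data = {}
        for scope in SCOPES:
            for phase in PHASES:
                data[f"{phase}_strain_{scope}"] = self.strain_sr.loc[scope, f"{phase}_strain"]
                data[f"{phase}_sr_{scope}"] = self.strain_sr.loc[scope, f"{phase}_sr"]
        return pd.Series({name: data[name] for name in FEATURE_NAMES})


def phasic_metrics(
    curves: StrainCurveSet,
    phases: PhaseBoundaries,
    la_volumes: VolumeCurve | None = None,
    lv_volumes: VolumeCurve | None = None,
    height_cm: float | None = None,
    weight_kg: float | None = None,
) -> PhasicMetrics:
    """Extract reservoir/conduit/contractile strains and peak SRs.

    The *global* phase boundaries are applied to every regional curve.
    Each curve is cyclically re-referenced to the detected end-diastolic
    frame and re-zeroed there, so for every scope::

        reservoir = S(t_peak),  conduit = S(t_peak) - S(t_cc),
        contractile = S(t_cc) - S(cycle end) = S(t_cc)

    and reservoir = conduit + contractile holds exactly by construction.
    Peak SRs: reservoir SR is the maximum SR in [t_ed, t_peak]; conduit
    and contractile SRs are the (signed, negative) minima in
    [t_peak, t_cc] and [t_cc, cycle end).
    """
    phases.require_ok()
    if phases.cc_index <= phases.peak_index:
        raise ValueError("conduit-contractile boundary must follow the peak")
    ed, pk, cc = phases.ed_frame_index, phases.peak_index, phases.cc_index
    rows = {}
    for scope in ("global", *curves.regional_strain):
        v, t = _cyclic_rereference(curves.curve(scope), curves.frame_times, ed)
        sr = strain_rate(v, t)
        rows[scope] = {
            "reservoir_strain": v[pk],
            "conduit_strain": v[pk] - v[cc],
            "contractile_strain": v[cc],
            "reservoir_sr": sr[: pk + 1].max(),
            "conduit_sr": sr[pk: cc + 1].min(),
            "contractile_sr": sr[cc:].min(),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    vol = None
    if la_volumes is not None:
        vol = volumetrics(la_volumes, lv_volumes, height_cm, weight_kg)
    return PhasicMetrics(strain_sr=table, phases=phases, volumetric=vol)


# ---------------------------------------------------------------------------
# volumetrics
# ---------------------------------------------------------------------------

def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2), Mosteller formula sqrt(h*w/3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return float(np.sqrt(height_cm * weight_kg / 3600.0))


def volumetrics(
    la_curve: VolumeCurve | None,
    lv_curve: VolumeCurve | None = None,
    height_cm: float | None = None,
    weight_kg: float | None = None,
) -> dict[str, float]:
    """Chamber volumetrics from the per-frame volume curves.

    For the LA, end-diastole (frame 0) is the volume minimum and
    end-systole the maximum (the atrium fills during ventricular systole):
    ``LAEF = 100 * (ESV - EDV) / ESV``.  For the LV the convention is the
    usual ``LVEF = 100 * (EDV - ESV) / EDV`` with EDV the maximum.
    Indexed volumes (mL/m^2) use the Mosteller BSA when height and weight
    are given.  A non-physiologic LA curve (maximum at frame 0) is
    flagged via ``ValueError``.
    """
    out: dict[str, float] = {}
    bsa = None
    if height_cm is not None and weight_kg is not None:
        bsa = mosteller_bsa(height_cm, weight_kg)
        out["bsa_m2"] = bsa
    if la_curve is not None:
        v = la_curve.volumes
        edv, esv = float(v[0]), float(v.max())
        if edv > float(v.min()) * 1.005:
            logger.warning("LA volume minimum is not at frame 0 "
                           "(%.2f vs %.2f mL); using frame 0 as EDV",
                           edv, float(v.min()))
        if esv <= edv:
            raise ValueError("non-physiologic LA curve: ESV <= EDV")
        out["la_edv_ml"] = edv
        out["la_esv_ml"] = esv
        out["la_sv_ml"] = esv - edv
        out["laef_pct"] = 100.0 * (esv - edv) / esv
        if bsa:
            out["la_edvi_ml_m2"] = edv / bsa
            out["la_esvi_ml_m2"] = esv / bsa
    if lv_curve is not None:
        v = lv_curve.volumes
        edv, esv = float(v.max()), float(v.min())
        out["lv_edv_ml"] = edv
        out["lv_esv_ml"] = esv
        out["lv_sv_ml"] = edv - esv
        out["lvef_pct"] = 0.0 if edv == 0 else 100.0 * (edv - esv) / edv
        if bsa:
            out["lv_edvi_ml_m2"] = edv / bsa
            out["lv_esvi_ml_m2"] = esv / bsa
    return out


# ---------------------------------------------------------------------------
# 10- vs 20-frame comparison
# ---------------------------------------------------------------------------

def frame_count_comparison(
    curves20: StrainCurveSet,
    alpha: float = DEFAULT_LEVEL_OFF_ALPHA,
    t_cc_fallback: float | None = None,
) -> pd.DataFrame:
    """Paired phasic metrics from 20-frame vs decimated 10-frame curves.

    The 10-frame analysis re-uses every other sample of the same
    underlying motion (10% vs 5% R-R increments) and re-runs phase
    detection and metric extraction from scratch.  When automatic
    detection fails on one sampling, the boundary detected on the other
    (or ``t_cc_fallback`` if given) is applied through the
    manual-correction hook -- the analysis analogue of the protocol's
    manual phase review.  Returns a DataFrame indexed by the 36 feature
    names with columns ``value_20``, ``value_10`` and ``abs_diff``.
    """
    if curves20.n_frames != 20:
        raise ValueError("frame-count comparison requires a 20-frame input")
    curves10 = curves20.decimate(2)

    def _extract(curves: StrainCurveSet, fallback: float | None):
        phases = detect_phases(curves.global_strain, curves.frame_times, alpha)
        if not phases.ok and fallback is not None:
            phases = detect_phases(curves.global_strain, curves.frame_times,
                                   alpha, t_cc_override=fallback)
        phases.require_ok()
        return phasic_metrics(curves, phases), phases

    m20, ph20 = _extract(curves20, t_cc_fallback)
    fallback10 = t_cc_fallback if t_cc_fallback is not None else ph20.t_cc
    m10, _ = _extract(curves10, fallback10)
    f20 = m20.feature_vector()
    f10 = m10.feature_vector()
    return pd.DataFrame({"value_20": f20, "value_10": f10,
                         "abs_diff": (f20 - f10).abs()})


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PhasicStrainModel:
    """Phasic strain analysis of one subject's 4D LA surface.

    Built either from a :class:`MeshFrameSequence` (the usual route) or
    directly from a precomputed :class:`StrainCurveSet`.  ``fit()``
    measures elemental area strain, aggregates global/regional curves,
    detects the atrial phases and extracts the 36 phasic features plus
    volumetrics.

    Parameters
    ----------
    data : MeshFrameSequence or StrainCurveSet
    lv_volumes : optional LV volume curve for LVEF (the LA curve is
        derived from the mesh when a mesh sequence is given).
    height_cm, weight_kg : optional, enable BSA-indexed volumes.
    level_off_alpha : conduit--contractile level-off fraction.
    """

    def __init__(
        self,
        data: MeshFrameSequence | StrainCurveSet,
        lv_volumes: VolumeCurve | None = None,
        la_volumes: VolumeCurve | None = None,
        height_cm: float | None = None,
        weight_kg: float | None = None,
        level_off_alpha: float = DEFAULT_LEVEL_OFF_ALPHA,
        area_weighted: bool = False,
    ) -> None:
        self.sequence = data if isinstance(data, MeshFrameSequence) else None
        self.curves = data if isinstance(data, StrainCurveSet) else None
        if self.sequence is None and self.curves is None:
            raise TypeError("data must be MeshFrameSequence or StrainCurveSet")
        self.lv_volumes = lv_volumes
        self.la_volumes = la_volumes
        self.height_cm = height_cm
        self.weight_kg = weight_kg
        self.level_off_alpha = level_off_alpha
        self.area_weighted = area_weighted

    @classmethod
    def from_mesh_sequence(cls, seq: MeshFrameSequence, **kwargs) -> "PhasicStrainModel":
        return cls(seq, **kwargs)

    def fit(self, t_cc_override: float | None = None) -> "PhasicStrainResults":
        element_curves = None
        curves = self.curves
        la_volumes = self.la_volumes
        if self.sequence is not None:
            element_curves = area_strain(self.sequence)
            curves = aggregate_curves(
                element_curves, self.sequence.region_labels,
                self.sequence.frame_times,
                element_areas_ref=self.sequence.element_areas(0),
                area_weighted=self.area_weighted)
            if la_volumes is None:
                la_volumes = self.sequence.volume_curve("LA")
        phases = detect_phases(curves.global_strain, curves.frame_times,
                               self.level_off_alpha, t_cc_override)
        metrics = None
        if phases.ok:
            metrics = phasic_metrics(curves, phases, la_volumes,
                                     self.lv_volumes, self.height_cm,
                                     self.weight_kg)
        return PhasicStrainResults(model=self, curves=curves, phases=phases,
                                   metrics=metrics,
                                   element_curves=element_curves,
                                   la_volumes=la_volumes)


@dataclass
class PhasicStrainResults:
    """Fitted phasic strain analysis for one subject."""

    model: PhasicStrainModel
    curves: StrainCurveSet
    phases: PhaseBoundaries
    metrics: PhasicMetrics | None
    element_curves: np.ndarray | None = None
    la_volumes: VolumeCurve | None = None

    def feature_vector(self) -> pd.Series:
        if self.metrics is None:
            raise ValueError("phase detection needs correction; refit with "
                             "t_cc_override")
        return self.metrics.feature_vector()

    def correct(self, t_cc: float) -> "PhasicStrainResults":
        """Re-extract with a manually corrected conduit--contractile time."""
        return self.model.fit(t_cc_override=t_cc)

    def summary(self) -> str:
        lines = ["Phasic 3D LA strain analysis",
                 "=" * 60,
                 f"frames: {self.curves.n_frames}   "
                 f"phase detection: {self.phases.detection_mode} "
                 f"({self.phases.status})",
                 f"t_ed = 0.00   t_peak = {self.phases.t_peak:.2f}   "
                 f"t_cc = {self.phases.t_cc:.2f}  (normalized R-R)"]
        if self.metrics is not None:
            lines.append("")
            lines.append("Strain [%] and peak SR [% per normalized time]:")
            lines.append(self.metrics.strain_sr.round(2).to_string())
            if self.metrics.volumetric:
                lines.append("")
                lines.append("Volumetrics:")
                for k, v in self.metrics.volumetric.items():
                    lines.append(f"  {k:18s} {v:8.2f}")
        else:
            lines.append(f"needs correction: {self.phases.reason}")
        return "\n".join(lines)

    def plot_curves(self, ax=None):
        """Plot the global and regional strain curves with phase marks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        t = self.curves.frame_times
        for region, v in self.curves.regional_strain.items():
            ax.plot(t, v, lw=0.8, alpha=0.6, label=region)
        ax.plot(t, self.curves.global_strain, "k-", lw=2, label="global")
        if self.phases.ok:
            ax.axvline(self.phases.t_peak, ls="--", c="grey")
            ax.axvline(self.phases.t_cc, ls=":", c="grey")
        ax.set_xlabel("normalized R-R time")
        ax.set_ylabel("area strain [%]")
        ax.legend(fontsize=7)
        return ax
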