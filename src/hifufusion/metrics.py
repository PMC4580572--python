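"""Volumetric lesion metrics: overlap, targeting and homogeneity.

A lesion is the set of voxels whose CEM43 thermal dose reached the
irreversible-damage threshold.  Motion effects are quantified against the
stationary (control) lesion V by the Dice similarity coefficient
DSC = 2 |V n V'| / (|V| + |V'|), the volumetric undertreatment
VUt = |V \\ V'| (control tissue left untreated) and overtreatment
VOt = |V' \\ V| (extra tissue ablated), off-centering of the centroid
along the motion axis, lesion diameters and the treatment rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bioheat import ExposurePlan
from .grids import Grid

__all__ = ["LesionMask", "LesionReport", "dsc", "under_over", "geometry", "treatment_rate", "report"]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class LesionMask:
    """Boolean lesion volume on a simulation grid, with provenance."""

    mask: np.ndarray
    grid: Grid
    label: str = ""

    def __post_init__(self) -> None:
        if tuple(self.mask.shape) != self.grid.shape:
            raise ValueError("mask shape must match the grid")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.grid.voxel_volume_mm3

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0

    def centroid_mm(self) -> np.ndarray:
        if not self.mask.any():
            raise ValueError("empty lesion has no centroid")
        idx = np.argwhere(self.mask)
        return np.asarray(self.grid.origin) + idx.mean(axis=0) * np.asarray(self.grid.spacing)


def _check_congruent(a: LesionMask, b: LesionMask) -> None:
    if not a.grid.same_geometry(b.grid):
        raise ValueError("lesion masks must live on congruent grids")


def dsc(control: LesionMask, moving: LesionMask) -> float:
    """Dice similarity coefficient, percent: ``2 |V n V'| / (|V| + |V'|) x 100``.

    Symmetric in its arguments.

    Raises
    ------
    ValueError
        If the grids differ or both masks are empty.
    """
    _check_congruent(control, moving)
    na = int(control.mask.sum())
    nb = int(moving.mask.sum())
    if na == 0 and nb == 0:
        raise ValueError("DSC undefined: both masks are empty")
    inter = int((control.mask & moving.mask).sum())
    return 200.0 * inter / (na + nb)


def under_over(control: LesionMask, moving: LesionMask) -> dict:
    """Volumetric under-/overtreatment of the moving lesion vs the control.

    VUt = |V \\ V'| (mm^3), VOt = |V' \\ V| (mm^3); percentages are relative
    to the control volume |V|.
    """
    _check_congruent(control, moving)
    v = int(control.mask.sum())
    if v == 0:
        raise ValueError("undertreatment percentages undefined for an empty control")
    vox = control.grid.voxel_volume_mm3
    vut = int((control.mask & ~moving.mask).sum())
    vot = int((moving.mask & ~control.mask).sum())
    return {
        "vut_mm3": vut * vox,
        "vut_pct": 100.0 * vut / v,
        "vot_mm3": vot * vox,
        "vot_pct": 100.0 * vot / v,
    }


def _axis_diameters(mask: np.ndarray, grid: Grid, axis: int, mode: str) -> tuple[float, float]:
    """Main/minor extents (mm) of the occupancy profile along ``axis``.

    ``mode='chord'``: chords (occupied-extent per line parallel to the axis)
    are measured within the slab through the mask centroid normal to the
    last remaining axis; main = largest chord, minor = smallest nonzero
    chord.  ``mode='bbox'``: both equal the bounding-box extent.
    """
    h = grid.spacing[axis]
    occ_axis = np.argwhere(mask)
    if mode == "bbox":
        ext = (occ_axis[:, axis].max() - occ_axis[:, axis].min() + 1) * h
        return float(ext), float(ext)
    centroid = occ_axis.mean(axis=0)
    slab_axis = [a for a in range(3) if a != axis][-1]
    plane = np.take(mask, int(round(centroid[slab_axis])), axis=slab_axis)  # 2D slab
    rem = [a for a in range(3) if a != slab_axis]
    if rem.index(axis) == 1:
        plane = plane.T  # chord axis first
    chords = []
    for j in range(plane.shape[1]):
        occ = np.flatnonzero(plane[:, j])
        if occ.size:
            chords.append((occ.max() - occ.min() + 1) * h)
    if not chords:
        ext = (occ_axis[:, axis].max() - occ_axis[:, axis].min() + 1) * h
        return float(ext), float(ext)
    return float(max(chords)), float(min(chords))


def geometry(
    lesion: LesionMask, control_centroid_mm: np.ndarray | None = None, diameter_mode: str = "chord"
) -> dict:
    """Diameters, depth, off-centering and homogeneity of a lesion.

    Diameters are main/minor chords of the occupancy profile along the
    cranial-caudal (x) and transverse (y) axes; depth is the extent along
    z.  Off-centering is the cranial-caudal centroid offset from the
    control.  A lesion is homogeneous iff it has exactly one 6-connected
    component and no fully enclosed untreated cavity (complement flood fill
    from the domain boundary).
    """
    m = lesion.mask
    if not m.any():
        raise ValueError("geometry undefined for an empty lesion")
    _, n_comp = ndimage.label(m, structure=_STRUCT6)
    filled = ndimage.binary_fill_holes(m)
    has_cavity = bool((filled & ~m).any())
    homogeneous = (n_comp == 1) and not has_cavity
    cc_main, cc_minor = _axis_diameters(m, lesion.grid, 0, diameter_mode)
    t_main, t_minor = _axis_diameters(m, lesion.grid, 1, diameter_mode)
    occ_z = np.argwhere(m)[:, 2]
    depth = float((occ_z.max() - occ_z.min() + 1) * lesion.grid.spacing[2])
    out = {
        "cc_main_diameter_mm": cc_main,
        "cc_minor_diameter_mm": cc_minor,
        "transverse_main_diameter_mm": t_main,
        "transverse_minor_diameter_mm": t_minor,
        "main_depth_mm": depth,
        "homogeneous": homogeneous,
        "n_components": int(n_comp),
    }
    if control_centroid_mm is not None:
        out["off_centering_mm"] = float(
            abs(lesion.centroid_mm()[0] - np.asarray(control_centroid_mm)[0])
        )
    return out


def treatment_rate(volume_cm3: float, plan: ExposurePlan) -> float:
    """Treated volume per unit exposure time, cm^3/min.

    The plan duration is the sum of all on and off times.
    """
    dur_min = plan.duration_s / 60.0
    if dur_min <= 0:
        raise ValueError("plan duration must be positive")
    return volume_cm3 / dur_min


@dataclass
class LesionReport:
    """Aggregated motion-effect metrics for one lesion vs its control."""

    volume_cm3: float
    dsc_pct: float | None
    vut_mm3: float | None
    vut_pct: float | None
    vot_mm3: float | None
    vot_pct: float | None
    off_centering_mm: float | None
    homogeneous: bool
    cc_main_diameter_mm: float
    cc_minor_diameter_mm: float
    transverse_main_diameter_mm: float
    transverse_minor_diameter_mm: float
    main_depth_mm: float
    treatment_rate_cm3_min: float
    label: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extra"}
        d.update(self.extra)
        return d


def report(
    lesion: LesionMask,
    plan: ExposurePlan,
    control: LesionMask | None = None,
    diameter_mode: str = "chord",
) -> LesionReport:
    """Build the full lesion report, with overlap metrics when a control is
    given.  The DSC/VUt/VOt identity ``DSC = 2 (V - VUt) / (V + V')`` holds
    exactly by construction."""
    geo = geometry(
        lesion,
        control.centroid_mm() if control is not None and control.mask.any() else None,
        diameter_mode,
    )
    overlap: dict = {}
    d = None
    if control is not None:
        d = dsc(control, lesion)
        overlap = under_over(control, lesion)
    return LesionReport(
        volume_cm3=lesion.volume_cm3,
        dsc_pct=d,
        vut_mm3=overlap.get("vut_mm3"),
        vut_pct=overlap.get("vut_pct"),
        vot_mm3=overlap.get("vot_mm3"),
        vot_pct=overlap.get("vot_pct"),
        off_centering_mm=geo.get("off_centering_mm"),
        homogeneous=geo["homogeneous"],
        cc_main_diameter_mm=geo["cc_main_diameter_mm"],
        cc_minor_diameter_mm=geo["cc_minor_diameter_mm"],
        transverse_main_diameter_mm=geo["transverse_main_diameter_mm"],
        transverse_minor_diameter_mm=geo["transverse_minor_diameter_mm"],
        main_depth_mm=geo["main_depth_mm"],
        treatment_rate_cm3_min=treatment_rate(lesion.volume_cm3, plan),
        label=lesion.label,
    )
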