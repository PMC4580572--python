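"""End-to-end treatment scenarios: field -> heat -> BHTE -> lesion metrics.

Three built-in exposure strategies are provided:

* ``single-spherical`` — one 5 s, 30 W shot of the truncated spherical
  transducer (Rc 45 mm), producing a millimetric "cigar-shaped" lesion;
* ``raster-7x7`` — 49 juxtaposed spherical shots (5 s on / 5 s off,
  1.6 mm lateral step), building a centimetric lesion in ~8 min;
* ``single-toroidal`` — one 40 s, 60 W shot of the spindle-torus
  transducer (Rc 70 mm, RM 5 mm), producing a large conical lesion.

Each scenario computes the control (stationary) lesion once, then one
lesion per motion phase of a ventilator-driven breathing trace, and
reports per-phase and mean +/- SD lesion metrics.

Numerical layout: all grids are cut from one 0.6 mm master lattice and
refined by integer factors, so heat maps computed on fine focal grids
block-average and embed exactly onto the thermal grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from pathlib import Path

import numpy as np

from . import acoustics, bioheat, metrics
from .acoustics import AcousticField, Medium, TISSUE
from .bioheat import ExposurePlan, TissueModel
from .grids import Grid
from .io import load_yaml_config
from .motion import MotionTrace, ventilator_motion

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "refine_grid",
    "subgrid",
    "spherical_fine_field",
    "toroidal_rz_field",
    "axial_focal_length",
    "run_scenario",
]

SCENARIOS = ("single-spherical", "raster-7x7", "single-toroidal")

_SCENARIO_DEFAULTS = {
    "single-spherical": {"power_w": 30.0, "on_s": 5.0, "off_s": 0.0, "d_t_t_mm": 35.0},
    "raster-7x7": {"power_w": 30.0, "on_s": 5.0, "off_s": 5.0, "d_t_t_mm": 35.0},
    "single-toroidal": {"power_w": 60.0, "on_s": 40.0, "off_s": 0.0, "d_t_t_mm": 60.0},
}

_VALID_KEYS = {"scenario", "power_w", "on_s", "off_s", "d_t_t_mm", "motion", "tissue", "numerics", "seed"}
_VALID_MOTION_KEYS = {"kind", "frequency_hz", "duty", "amp_cc_mm", "amp_ap_mm", "phases", "rise_frac", "trace_csv"}
_VALID_NUMERICS_KEYS = {"elements_per_wavelength", "dt_factor", "cooldown_s", "motion_quantum_mm"}
_VALID_TISSUE_KEYS = {"rho_t", "c_t", "k", "omega_b", "c_b", "t_b", "t_0", "attenuation_np_m_mhz", "beta"}


@dataclass
class ScenarioConfig:
    """Validated configuration of one treatment scenario.

    ``motion`` defaults to the measured breathing regime: 0.2 Hz ventilator
    waveform, 40 % duty, 13.3 mm cranial-caudal and 1.9 mm depth
    peak-to-peak excursion, evaluated at 6 evenly spaced start phases.
    """

    scenario: str
    power_w: float | None = None
    on_s: float | None = None
    off_s: float | None = None
    d_t_t_mm: float | None = None
    motion: dict = dc_field(default_factory=dict)
    tissue: dict = dc_field(default_factory=dict)
    numerics: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        defaults = _SCENARIO_DEFAULTS[self.scenario]
        for key in ("power_w", "on_s", "off_s", "d_t_t_mm"):
            if getattr(self, key) is None:
                setattr(self, key, defaults[key])
        for name, d, valid in (
            ("motion", self.motion, _VALID_MOTION_KEYS),
            ("tissue", self.tissue, _VALID_TISSUE_KEYS),
            ("numerics", self.numerics, _VALID_NUMERICS_KEYS),
        ):
            unknown = set(d) - valid
            if unknown:
                raise ValueError(
                    f"unknown {name} keys {sorted(unknown)}; valid keys are {sorted(valid)}"
                )
        self.motion = {
            "kind": "ventilator",
            "frequency_hz": 0.2,
            "duty": 0.4,
            "amp_cc_mm": 13.3,
            "amp_ap_mm": 1.9,
            "phases": 6,
            **self.motion,
        }
        self.numerics = {
            "elements_per_wavelength": 2.0,
            "dt_factor": 0.8,
            "cooldown_s": 20.0,
            "motion_quantum_mm": 0.02,
            **self.numerics,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        cfg = load_yaml_config(path, _VALID_KEYS)
        return cls(**cfg)

    def effective_parameters(self) -> dict:
        return {
            "scenario": self.scenario,
            "power_w": self.power_w,
            "on_s": self.on_s,
            "off_s": self.off_s,
            "d_t_t_mm": self.d_t_t_mm,
            "motion": dict(self.motion),
            "tissue": dict(self.tissue),
            "numerics": dict(self.numerics),
            "seed": self.seed,
        }


def refine_grid(coarse: Grid, factor: int) -> Grid:
    """Refine a grid by an integer factor so that block-averaging the fine
    grid by the same factor recovers the coarse voxel centers exactly."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    spacing = tuple(s / factor for s in coarse.spacing)
    origin = tuple(
        coarse.origin[a] - spacing[a] * (factor - 1) / 2.0 for a in range(3)
    )
    return Grid(origin, spacing, tuple(n * factor for n in coarse.shape))


def subgrid(grid: Grid, bounds: tuple[tuple[float, float], ...]) -> Grid:
    """The sub-block of a grid whose voxel centers lie within ``bounds``."""
    origin = []
    shape = []
    for a in range(3):
        c = grid.axis_coords(a)
        inside = np.flatnonzero((c >= bounds[a][0] - 1e-9) & (c <= bounds[a][1] + 1e-9))
        if inside.size == 0:
            raise ValueError("bounds select no voxel centers")
        origin.append(float(c[inside[0]]))
        shape.append(int(inside.size))
    return Grid(tuple(origin), grid.spacing, tuple(shape))


# ---------------------------------------------------------------------------
# master lattice and per-scenario grids

_MASTER_BOUNDS = ((-24.3, 24.3), (-18.3, 18.3), (30.9, 59.7))
_MASTER_SPACING = 0.6  # mm


def _master_lattice() -> Grid:
    return Grid.from_bounds(_MASTER_BOUNDS, _MASTER_SPACING)


def _thermal_grid(scenario: str) -> Grid:
    master = _master_lattice()
    if scenario == "single-spherical":
        return refine_grid(subgrid(master, ((-10.5, 10.5), (-6.9, 6.9), (35.1, 55.5))), 2)
    if scenario == "raster-7x7":
        return master
    # toroidal: independent 0.4 mm lattice centered on the beam axis
    return Grid.from_bounds(((-20.2, 20.2), (-20.2, 20.2), (52.2, 100.2)), 0.4)


def _fine_q_grid() -> Grid:
    """0.15 mm focal grid around the spherical focus, lattice-aligned."""
    master = _master_lattice()
    return refine_grid(subgrid(master, ((-5.7, 5.7), (-3.9, 3.9), (36.3, 56.7))), 4)


@lru_cache(maxsize=2)
def spherical_fine_field(
    power_w: float = 30.0,
    d_t_t_mm: float = 35.0,
    elements_per_wavelength: float = 2.0,
    attenuation: float = TISSUE.attenuation_np_m_mhz,
    beta: float = TISSUE.beta,
) -> AcousticField:
    """Pressure of the spherical transducer on the fine focal grid.

    Exploits the x -> -x and y -> -y mirror symmetry of the symmetrically
    truncated cap: only one quadrant is evaluated and mirrored.
    """
    medium = Medium(attenuation_np_m_mhz=attenuation, beta=beta)
    geom = acoustics.make_spherical(
        elements_per_wavelength=elements_per_wavelength, medium=medium
    )
    grid = _fine_q_grid()
    nx, ny, nz = grid.shape
    assert nx % 2 == 0 and ny % 2 == 0
    xq = grid.x[nx // 2 :]
    yq = grid.y[ny // 2 :]
    quad = Grid((float(xq[0]), float(yq[0]), grid.origin[2]), grid.spacing, (nx // 2, ny // 2, nz))
    pq = acoustics.rayleigh_field(geom, quad, medium, power_w, d_t_t_mm).p
    p = np.empty(grid.shape, dtype=complex)
    p[nx // 2 :, ny // 2 :, :] = pq
    p[nx // 2 :, : ny // 2, :] = pq[:, ::-1, :]
    p[: nx // 2, :, :] = p[nx // 2 :, :, :][::-1, :, :]
    return AcousticField(p, grid, geom.f_mhz, power_w, d_t_t_mm, medium)


@lru_cache(maxsize=2)
def toroidal_rz_field(
    power_w: float = 60.0,
    d_t_t_mm: float = 60.0,
    elements_per_wavelength: float = 2.0,
    attenuation: float = TISSUE.attenuation_np_m_mhz,
    beta: float = TISSUE.beta,
    dr_mm: float = 0.15,
    dz_mm: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(p_rz, r_mm, z_mm) of the axisymmetric toroidal transducer."""
    medium = Medium(attenuation_np_m_mhz=attenuation, beta=beta)
    geom = acoustics.make_toroidal(
        elements_per_wavelength=elements_per_wavelength, medium=medium
    )
    r = np.arange(0.0, 22.0 + dr_mm / 2, dr_mm)
    z = np.arange(50.0, 102.0 + dz_mm / 2, dz_mm)
    p_rz = acoustics.rayleigh_rz(geom, r, z, medium, power_w, d_t_t_mm)
    return p_rz, r, z


def axial_focal_length(
    power_w: float = 30.0,
    d_t_t_mm: float = 35.0,
    elements_per_wavelength: float = 2.0,
    medium: Medium = TISSUE,
    dz_mm: float = 0.05,
) -> dict:
    """Axial -6 dB focal length of the spherical field in tissue, from a
    fine on-axis pressure profile (interpolated half-maximum crossings)."""
    geom = acoustics.make_spherical(elements_per_wavelength=elements_per_wavelength, medium=medium)
    z = np.arange(36.0, 56.0 + dz_mm / 2, dz_mm)
    amp = np.abs(acoustics.rayleigh_onaxis(geom, z, medium, power_w, d_t_t_mm))
    k = int(np.argmax(amp))
    if k in (0, len(z) - 1):
        raise ValueError("axial peak on the profile boundary")
    length = acoustics._crossing_extent(amp, z, k, 0.5 * amp[k])
    return {"focal_peak_z_mm": float(z[k]), "focal_length_mm": float(length)}


def _tissue_model(grid: Grid, overrides: dict) -> TissueModel:
    kw = {k: v for k, v in overrides.items() if k in ("rho_t", "c_t", "k", "omega_b", "c_b", "t_b", "t_0")}
    return TissueModel(grid, **kw)


def _medium(overrides: dict) -> tuple[float, float]:
    return (
        float(overrides.get("attenuation_np_m_mhz", TISSUE.attenuation_np_m_mhz)),
        float(overrides.get("beta", TISSUE.beta)),
    )


def _q_on_thermal_grid(cfg: ScenarioConfig, thermal: Grid) -> np.ndarray:
    """Stationary single-shot heat map (W/m^3) embedded on the thermal grid."""
    att, beta = _medium(cfg.tissue)
    epw = cfg.numerics["elements_per_wavelength"]
    if cfg.scenario in ("single-spherical", "raster-7x7"):
        fld = spherical_fine_field(cfg.power_w, cfg.d_t_t_mm, epw, att, beta)
        q_fine = acoustics.heat_source(fld)
        factor = int(round(thermal.spacing[0] / fld.grid.spacing[0]))
        q_coarse, q_grid = bioheat.block_average(q_fine, fld.grid, factor)
        return bioheat.embed_map(q_coarse, q_grid, thermal)
    p_rz, r, z = toroidal_rz_field(cfg.power_w, cfg.d_t_t_mm, epw, att, beta)
    p2 = acoustics.revolve_rz(np.abs(p_rz) ** 2, r, z, thermal)
    medium = Medium(attenuation_np_m_mhz=att, beta=beta)
    fld3 = AcousticField(np.sqrt(p2), thermal, 3.0, cfg.power_w, cfg.d_t_t_mm, medium)
    return acoustics.heat_source(fld3)


def _build_plan(cfg: ScenarioConfig) -> ExposurePlan:
    if cfg.scenario == "single-spherical":
        return ExposurePlan.single_spherical(cfg.on_s, cfg.power_w)
    if cfg.scenario == "raster-7x7":
        return ExposurePlan.raster_7x7(1.6, cfg.on_s, cfg.off_s, cfg.power_w)
    return ExposurePlan.single_toroidal(cfg.on_s, cfg.power_w)


def _motion_traces(cfg: ScenarioConfig, plan: ExposurePlan) -> list[MotionTrace]:
    m = cfg.motion
    if m["kind"] == "none":
        return []
    if m["kind"] == "trace":
        from .io import read_trace_csv

        return [read_trace_csv(m["trace_csv"])]
    if m["kind"] != "ventilator":
        raise ValueError("motion kind must be 'none', 'ventilator' or 'trace'")
    period = 1.0 / m["frequency_hz"]
    duration = (np.ceil(plan.duration_s / period) + 1.0) * period
    base = ventilator_motion(
        frequency=m["frequency_hz"],
        duty=m["duty"],
        amp_cc=m["amp_cc_mm"],
        amp_ap=m["amp_ap_mm"],
        duration=duration,
        sample_rate=25.0,
        rise_frac=m.get("rise_frac", 0.35),
    )
    phases = m["phases"]
    if isinstance(phases, int):
        phases = [k / phases for k in range(phases)]
    return [base.shifted_phase(ph) for ph in phases]


def run_scenario(cfg: ScenarioConfig) -> dict:
    """Run one scenario end to end and return the full report dictionary.

    Computes the control lesion once, then one lesion per motion phase;
    the report carries per-phase metrics, mean +/- SD summaries and the
    complete effective parameter set.  Deterministic for a fixed config.
    """
    plan = _build_plan(cfg)
    thermal = _thermal_grid(cfg.scenario)
    tissue = _tissue_model(thermal, cfg.tissue)
    q_base = _q_on_thermal_grid(cfg, thermal)
    dt = cfg.numerics["dt_factor"] * bioheat.stability_dt(tissue)
    cooldown = cfg.numerics["cooldown_s"]

    def simulate(motion: MotionTrace | None) -> metrics.LesionMask:
        t2 = _tissue_model(thermal, cfg.tissue)
        _, mask = bioheat.run_treatment(
            plan,
            t2,
            q_base,
            motion=motion,
            dt=dt,
            cooldown_s=cooldown,
            motion_quantum_mm=cfg.numerics["motion_quantum_mm"],
        )
        return metrics.LesionMask(mask, thermal)

    control = simulate(None)
    control.label = "control"
    out: dict = {
        "params": cfg.effective_parameters(),
        "plan_duration_s": plan.duration_s,
        "control": metrics.report(control, plan).to_dict(),
    }
    traces = _motion_traces(cfg, plan)
    phase_reports = []
    for trace in traces:
        lesion = simulate(trace)
        lesion.label = f"phase-{trace.meta.get('phase', 0.0):.3f}"
        phase_reports.append(metrics.report(lesion, plan, control=control).to_dict())
    if phase_reports:
        out["phases"] = phase_reports
        keys = ("volume_cm3", "dsc_pct", "vut_pct", "vot_pct", "off_centering_mm", "treatment_rate_cm3_min")
        out["summary"] = {
            k: {
                "mean": float(np.mean([r[k] for r in phase_reports])),
                "sd": float(np.std([r[k] for r in phase_reports])),
            }
            for k in keys
        }
        out["summary"]["homogeneous_fraction"] = float(
            np.mean([r["homogeneous"] for r in phase_reports])
        )
    return out
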