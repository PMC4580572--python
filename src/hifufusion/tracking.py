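"""Incremental 2D speckle tracking by block-wise normalized cross-correlation.

A reference region (RR) from one frame is matched against all same-sized
search-region (SR) placements inside a search area (SA) of the next frame;
the displacement is the arg-max of the zero-normalized cross-correlation
coefficient, refined to subpixel precision by a 3-point parabolic fit along
each axis.  Frame-to-frame estimates are accumulated into a cumulative
trace; in rigid-average mode the per-frame displacement is the
correlation-weighted mean over blocks.

Image convention: row axis = depth (z, anterior-posterior), column axis =
lateral (x, cranial-caudal or transverse); displacements in mm, positive in
the direction of increasing index; 0-based pixel indexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np

from .phantom import SpeckleSequence

__all__ = [
    "UndefinedCorrelationError",
    "UndefinedFrequencyError",
    "TrackingConfig",
    "SpeckleBlock",
    "DisplacementField",
    "TrackedTrace",
    "ncc",
    "track_pair",
    "track_sequence",
    "correct_drift",
    "dominant_frequency",
    "detectability_limits",
]


class UndefinedCorrelationError(ValueError):
    """Both blocks are constant: the correlation coefficient is undefined."""


class UndefinedFrequencyError(ValueError):
    """The trace is constant: no spectral peak exists."""


@dataclass(frozen=True)
class TrackingConfig:
    """Block-matching window geometry, all sizes in mm as (lateral, depth).

    ``sr_mm`` defaults to ``rr_mm`` (the search region is an RR-sized window
    scanned across the search area).  ``overlap`` is the RR overlap along
    each axis, either in mm or as a fraction of RR (< 1).
    """

    rr_mm: tuple[float, float] = (10.3, 4.1)
    sa_mm: tuple[float, float] = (16.4, 6.2)
    roi_mm: tuple[float, float] = (10.6, 12.3)
    sr_mm: tuple[float, float] | None = None
    overlap: tuple[float, float] = (0.5, 0.5)
    pitch: float = 9.6
    frame_rate: float = 25.0
    mode: str = "rigid-average"
    corr_floor: float = 0.3

    def __post_init__(self) -> None:
        sr = self.sr_mm or self.rr_mm
        object.__setattr__(self, "sr_mm", tuple(sr))
        for a in range(2):
            if not self.rr_mm[a] <= self.sr_mm[a] <= self.sa_mm[a]:
                raise ValueError("window sizes must satisfy RR <= SR <= SA")
        ov = self._overlap_mm()
        if any(ov[a] >= self.rr_mm[a] for a in range(2)):
            raise ValueError("RR overlap must be smaller than RR")
        if self.mode not in ("rigid-average", "elastic-map"):
            raise ValueError("mode must be 'rigid-average' or 'elastic-map'")
        if self.pitch <= 0 or self.frame_rate <= 0:
            raise ValueError("pitch and frame rate must be positive")

    def _overlap_mm(self) -> tuple[float, float]:
        return tuple(
            o * self.rr_mm[a] if o < 1.0 else o for a, o in enumerate(self.overlap)
        )

    def px(self, mm_pair: tuple[float, float]) -> tuple[int, int]:
        """(lateral, depth) size in whole pixels, odd-rounded for centering."""
        out = []
        for v in mm_pair:
            n = max(3, int(round(v * self.pitch)))
            out.append(n if n % 2 == 1 else n + 1)
        return tuple(out)  # type: ignore[return-value]


@dataclass
class SpeckleBlock:
    """A rectangular block of grey levels with cached mean and pixel count."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.size < 4:
            raise ValueError("a block needs at least 4 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("grey levels must be finite")

    @property
    def mean(self) -> float:
        return float(self.pixels.mean())

    @property
    def n(self) -> int:
        return int(self.pixels.size)


def ncc(block_a: SpeckleBlock | np.ndarray, block_b: SpeckleBlock | np.ndarray) -> float:
    """Zero-normalized cross-correlation coefficient between two blocks.

    ``rho = sum (a - a_mean)(b - b_mean) / sqrt(sum (a - a_mean)^2 sum (b - b_mean)^2)``

    Symmetric in its arguments and invariant to positive affine rescaling of
    either block; lies in [-1, 1].

    Raises
    ------
    ValueError
        If the blocks differ in shape.
    UndefinedCorrelationError
        If both blocks are constant.
    """
    a = block_a.pixels if isinstance(block_a, SpeckleBlock) else np.asarray(block_a, float)
    b = block_b.pixels if isinstance(block_b, SpeckleBlock) else np.asarray(block_b, float)
    if a.shape != b.shape:
        raise ValueError(f"block shapes differ: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    va = float(np.sum(da * da))
    vb = float(np.sum(db * db))
    if va == 0.0 and vb == 0.0:
        raise UndefinedCorrelationError("both blocks are constant")
    if va == 0.0 or vb == 0.0:
        return 0.0
    rho = float(np.sum(da * db) / np.sqrt(va * vb))
    return float(np.clip(rho, -1.0, 1.0))


@dataclass
class DisplacementField:
    """Per-frame grids of block displacements and correlation coefficients.

    ``dx``/``dz`` are lateral/depth displacements in mm on the block-center
    grid; ``rho`` is the peak correlation per block (NaN for skipped blocks);
    ``saturated`` flags arg-maxima on the search-area border.
    """

    dx: np.ndarray
    dz: np.ndarray
    rho: np.ndarray
    centers_x_mm: np.ndarray
    centers_z_mm: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        if not (self.dx.shape == self.dz.shape == self.rho.shape == self.saturated.shape):
            raise ValueError("displacement and correlation grids must be congruent")
        finite = self.rho[np.isfinite(self.rho)]
        if finite.size and (finite.min() < -1.0 - 1e-9 or finite.max() > 1.0 + 1e-9):
            raise ValueError("correlation values must lie in [-1, 1]")


@dataclass
class TrackedTrace:
    """Cumulative rigid-average displacement over a tracked sequence."""

    t: np.ndarray
    dx: np.ndarray
    dz: np.ndarray
    mean_rho: np.ndarray
    drift_rate: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.t.shape == self.dx.shape == self.dz.shape):
            raise ValueError("t, dx, dz must have the same shape")
        if self.t.size and (abs(self.dx[0]) > 1e-12 or abs(self.dz[0]) > 1e-12):
            raise ValueError("cumulative trace must start at zero")


@numba.njit(cache=True)
def _zncc_map(template, search, moff_z, moff_x):  # pragma: no cover
    """Direct ZNCC of `template` against all placements in `search`."""
    th, tw = template.shape
    out = np.empty((2 * moff_z + 1, 2 * moff_x + 1))
    tm = template.mean()
    dt = template - tm
    vt = 0.0
    for i in range(th):
        for j in range(tw):
            vt += dt[i, j] * dt[i, j]
    for oz in range(2 * moff_z + 1):
        for ox in range(2 * moff_x + 1):
            num = 0.0
            vb = 0.0
            bm = 0.0
            for i in range(th):
                for j in range(tw):
                    bm += search[oz + i, ox + j]
            bm /= th * tw
            for i in range(th):
                for j in range(tw):
                    db = search[oz + i, ox + j] - bm
                    num += dt[i, j] * db
                    vb += db * db
            if vt == 0.0 or vb == 0.0:
                out[oz, ox] = 0.0
            else:
                out[oz, ox] = num / np.sqrt(vt * vb)
    return out


def _parabolic(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= 0.0:
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))


def _peak_with_ties(corr: np.ndarray, moff_z: int, moff_x: int) -> tuple[int, int]:
    """Arg-max with deterministic tie-breaking.

    At equal maxima (to 1e-12): smallest displacement magnitude first, then
    lexicographic (dz, dx).
    """
    cmax = corr.max()
    cand = np.argwhere(corr >= cmax - 1e-12)
    best = None
    for iz, ix in cand:
        oz, ox = int(iz) - moff_z, int(ix) - moff_x
        key = (oz * oz + ox * ox, oz, ox)
        if best is None or key < best[0]:
            best = (key, oz, ox)
    return best[1], best[2]


def track_pair(frame_a: np.ndarray, frame_b: np.ndarray, config: TrackingConfig) -> DisplacementField:
    """Estimate block displacements between two consecutive frames.

    For every RR center inside the ROI, scans all SR placements inside the
    SA of ``frame_b``, takes the ZNCC arg-max and refines it to subpixel by a
    3-point parabolic fit along each axis.  Blocks whose arg-max lies on the
    SA border are flagged as saturated (no subpixel refinement there);
    constant blocks are skipped with ``rho = NaN``.

    Raises
    ------
    ValueError
        If the frames differ in shape or the ROI plus SA margins does not
        fit inside the image.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    H, W = a.shape
    rr_x, rr_z = config.px(config.rr_mm)  # odd, for centering
    sa_x = max(rr_x, int(round(config.sa_mm[0] * config.pitch)))
    sa_z = max(rr_z, int(round(config.sa_mm[1] * config.pitch)))
    moff_x = (sa_x - rr_x) // 2
    moff_z = (sa_z - rr_z) // 2
    sa_x = rr_x + 2 * moff_x
    sa_z = rr_z + 2 * moff_z
    margin_x = rr_x // 2 + moff_x
    margin_z = rr_z // 2 + moff_z

    roi_x_px = int(round(config.roi_mm[0] * config.pitch))
    roi_z_px = int(round(config.roi_mm[1] * config.pitch))
    if roi_x_px > W - 2 * margin_x - 1 or roi_z_px > H - 2 * margin_z - 1:
        raise ValueError(
            f"ROI {config.roi_mm} mm plus search margins exceeds the "
            f"{W}x{H} px image extent"
        )

    ov_x, ov_z = config._overlap_mm()
    step_x = max(1, int(round((config.rr_mm[0] - ov_x) * config.pitch)))
    step_z = max(1, int(round((config.rr_mm[1] - ov_z) * config.pitch)))
    cx0 = (W - roi_x_px) // 2
    cz0 = (H - roi_z_px) // 2
    centers_x = np.arange(max(cx0, margin_x), min(cx0 + roi_x_px, W - margin_x - 1) + 1, step_x)
    centers_z = np.arange(max(cz0, margin_z), min(cz0 + roi_z_px, H - margin_z - 1) + 1, step_z)
    if centers_x.size == 0 or centers_z.size == 0:
        raise ValueError("no valid block centers inside the ROI")

    nz, nx = centers_z.size, centers_x.size
    dx = np.zeros((nz, nx))
    dz = np.zeros((nz, nx))
    rho = np.full((nz, nx), np.nan)
    sat = np.zeros((nz, nx), dtype=bool)
    hx, hz = rr_x // 2, rr_z // 2
    for i, cz in enumerate(centers_z):
        for j, cx in enumerate(centers_x):
            tmpl = a[cz - hz : cz + hz + 1, cx - hx : cx + hx + 1]
            if tmpl.max() == tmpl.min():
                continue  # constant reference: correlation undefined, skip
            srch = b[
                cz - hz - moff_z : cz + hz + moff_z + 1,
                cx - hx - moff_x : cx + hx + moff_x + 1,
            ]
            corr = _zncc_map(np.ascontiguousarray(tmpl), np.ascontiguousarray(srch), moff_z, moff_x)
            oz, ox = _peak_with_ties(corr, moff_z, moff_x)
            iz, ix = oz + moff_z, ox + moff_x
            peak = corr[iz, ix]
            on_border = iz in (0, corr.shape[0] - 1) or ix in (0, corr.shape[1] - 1)
            sub_z = sub_x = 0.0
            if not on_border and peak < 1.0 - 1e-9:
                sub_z = _parabolic(corr[iz - 1, ix], peak, corr[iz + 1, ix])
                sub_x = _parabolic(corr[iz, ix - 1], peak, corr[iz, ix + 1])
            dz[i, j] = (oz + sub_z) / config.pitch
            dx[i, j] = (ox + sub_x) / config.pitch
            rho[i, j] = peak
            sat[i, j] = on_border
    return DisplacementField(
        dx, dz, rho, centers_x / config.pitch, centers_z / config.pitch, sat
    )


def track_sequence(
    seq: SpeckleSequence, config: TrackingConfig
) -> tuple[list[DisplacementField], TrackedTrace]:
    """Track a full sequence incrementally (frame-to-frame) and accumulate.

    Returns the per-pair displacement fields and the cumulative rigid-average
    trace.  The per-frame rigid displacement is the correlation-weighted mean
    over blocks, excluding blocks below ``config.corr_floor``; a saturation
    warning is recorded in the trace metadata whenever more than half the
    blocks of a frame pair saturate.
    """
    if seq.n_frames < 2:
        raise ValueError("tracking needs at least 2 frames")
    fields: list[DisplacementField] = []
    n = seq.n_frames
    cum_dx = np.zeros(n)
    cum_dz = np.zeros(n)
    mean_rho = np.full(n, np.nan)
    saturated_frames: list[int] = []
    frames = seq.frames.astype(float)
    for f in range(n - 1):
        fld = track_pair(frames[f], frames[f + 1], config)
        fields.append(fld)
        valid = np.isfinite(fld.rho)
        w = np.where(valid & (fld.rho >= config.corr_floor), np.maximum(fld.rho, 0.0), 0.0)
        if w.sum() > 0:
            cum_dx[f + 1] = cum_dx[f] + float(np.sum(w * fld.dx) / w.sum())
            cum_dz[f + 1] = cum_dz[f] + float(np.sum(w * fld.dz) / w.sum())
        else:
            cum_dx[f + 1] = cum_dx[f]
            cum_dz[f + 1] = cum_dz[f]
        mean_rho[f + 1] = float(np.nanmean(fld.rho)) if valid.any() else np.nan
        if fld.saturated.mean() > 0.5:
            saturated_frames.append(f + 1)
    t = np.arange(n) / seq.frame_rate
    meta = {
        "mean_correlation": float(np.nanmean(mean_rho[1:])),
        "saturated_frames": saturated_frames,
    }
    if saturated_frames:
        meta["saturation_warning"] = (
            f">50% saturated blocks in {len(saturated_frames)} frame pair(s)"
        )
        warnings.warn(meta["saturation_warning"], stacklevel=2)
    return fields, TrackedTrace(t, cum_dx, cum_dz, mean_rho, meta=meta)


def _linear_drift_rate(t: np.ndarray, x: np.ndarray) -> float | None:
    """Drift rate (mm/s) of a periodic trace with a superimposed linear trend.

    A plain least-squares line through a sinusoid is biased by the sinusoid
    itself, so the periodic content is first averaged out: the trace is cut
    into whole periods of its dominant frequency and a line is fitted
    through the per-period means.  Returns None when the trace covers fewer
    than two periods (drift and periodic motion are then inseparable).
    """
    slope, intercept = np.polyfit(t, x, 1)
    residual = x - (slope * t + intercept)
    scale = max(1.0, float(np.max(np.abs(x))))
    if np.max(np.abs(residual)) <= 1e-9 * scale:
        return float(slope)  # pure line: exact
    spec = np.abs(np.fft.rfft(residual))
    freqs = np.fft.rfftfreq(t.size, d=float(t[1] - t[0]))
    f0 = float(freqs[1 + int(np.argmax(spec[1:]))])
    span = float(t[-1] - t[0])
    if f0 <= 0 or span < 2.0 / f0:
        return None
    period = 1.0 / f0
    n_cyc = int(span // period)
    tm, xm = [], []
    for c in range(n_cyc):
        m = (t - t[0] >= c * period) & (t - t[0] < (c + 1) * period)
        if m.sum() >= 2:
            tm.append(t[m].mean())
            xm.append(x[m].mean())
    if len(tm) < 2:
        return None
    return float(np.polyfit(tm, xm, 1)[0])


def correct_drift(trace: TrackedTrace, method: str = "linear") -> TrackedTrace:
    """Remove the best-fit linear trend from each displacement axis.

    Speckle decorrelation accumulates into a slow drift of the cumulative
    trace; the tracker's operating regime shows drift rates of order
    0.1 mm/s, well modeled as linear.  The removed rate (mm/s) is stored on
    the returned trace.  If the trace is shorter than two periods of its
    dominant frequency the correction is skipped (no-op with a warning).
    """
    if method != "linear":
        raise ValueError("only linear drift correction is supported")
    rates: list[float] = []
    detrended: list[np.ndarray] = []
    for comp in (trace.dx, trace.dz):
        if np.allclose(comp, comp[0]):
            rates.append(0.0)
            detrended.append(comp - comp[0])
            continue
        rate = _linear_drift_rate(trace.t, comp)
        if rate is None:
            warnings.warn(
                "trace shorter than 2 periods; drift correction skipped", stacklevel=2
            )
            out = TrackedTrace(
                trace.t.copy(), trace.dx.copy(), trace.dz.copy(), trace.mean_rho.copy(),
                drift_rate=(0.0, 0.0), meta=dict(trace.meta),
            )
            out.meta["drift_correction_skipped"] = True
            return out
        corrected = comp - rate * (trace.t - trace.t[0])
        detrended.append(corrected - corrected[0])
        rates.append(rate)
    out = TrackedTrace(
        trace.t.copy(), detrended[0], detrended[1], trace.mean_rho.copy(),
        drift_rate=(rates[0], rates[1]), meta=dict(trace.meta),
    )
    return out


def dominant_frequency(trace: TrackedTrace) -> float:
    """Frequency (Hz) of the largest non-DC spectral peak of the CC component.

    Requires at least 4 uniformly spaced samples.

    Raises
    ------
    UndefinedFrequencyError
        If the cranial-caudal component is constant.
    """
    if trace.t.size < 4:
        raise ValueError("need at least 4 samples")
    dts = np.diff(trace.t)
    if not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("trace must be uniformly sampled")
    x = trace.dx - trace.dx.mean()
    if np.allclose(x, 0.0):
        raise UndefinedFrequencyError("constant trace has no spectral peak")
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(trace.t.size, d=float(dts[0]))
    k = 1 + int(np.argmax(spec[1:]))
    return float(freqs[k])


def detectability_limits(config: TrackingConfig) -> dict:
    """Maximum detectable per-frame motion magnitude and tissue speed.

    Magnitude is half the search area per axis (mm); speed is that magnitude
    times the frame rate, converted to cm/s.
    """
    out = {}
    for name, a in (("lateral", 0), ("depth", 1)):
        mag = config.sa_mm[a] / 2.0
        out[name] = {
            "max_magnitude_mm": mag,
            "max_speed_cm_s": mag * config.frame_rate / 10.0,
        }
    return out
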