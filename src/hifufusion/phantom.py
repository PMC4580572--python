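"""Synthetic B-mode speckle sequences with known motion ground truth.

The generator follows the standard scatterer-convolution speckle model: a
cloud of sub-resolution point scatterers is convolved with a complex
Gaussian-windowed-cosine point-spread function; the envelope of the result
is a fully developed speckle image when the scatterer density exceeds a few
per resolution cell.  Frames are rendered by displacing the scatterers with
either a rigid motion trace or dense elastic displacement grids, so every
sequence carries exact ground truth for the tracker.

Default imaging parameters mirror an intraoperative 12 MHz linear probe:
field of view 45 mm (deep) x 27 mm (wide), 9.6 px/mm, 25 frames/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

from .motion import MotionTrace

__all__ = [
    "ScattererPhantom",
    "SpecklePsf",
    "SpeckleSequence",
    "render_speckle",
    "DEFAULT_PITCH",
    "DEFAULT_FRAME_RATE",
]

DEFAULT_PITCH = 9.6  # px/mm
DEFAULT_FRAME_RATE = 25.0  # frames/s


@dataclass(frozen=True)
class SpecklePsf:
    """Separable Gaussian-windowed cosine PSF.

    ``h(x, z) = exp(-x^2/2 sx^2 - z^2/2 sz^2) * exp(2 pi i z / carrier)``

    with all lengths in mm.  Defaults give a ~3-pixel axial speckle cell at
    the default 9.6 px/mm sampling (12 MHz-equivalent resolution).
    """

    sigma_x_mm: float = 4.0 / DEFAULT_PITCH
    sigma_z_mm: float = 1.6 / DEFAULT_PITCH
    carrier_period_mm: float = 4.0 / DEFAULT_PITCH

    def kernel(self, pitch: float = DEFAULT_PITCH, n_sigma: float = 3.5) -> np.ndarray:
        """Sampled complex kernel normalized to unit energy (sum |h|^2 = 1)."""
        hx = int(np.ceil(n_sigma * self.sigma_x_mm * pitch))
        hz = int(np.ceil(n_sigma * self.sigma_z_mm * pitch))
        x = np.arange(-hx, hx + 1) / pitch
        z = np.arange(-hz, hz + 1) / pitch
        X, Z = np.meshgrid(x, z)
        h = np.exp(
            -0.5 * (X / self.sigma_x_mm) ** 2 - 0.5 * (Z / self.sigma_z_mm) ** 2
        ) * np.exp(2j * np.pi * Z / self.carrier_period_mm)
        return h / np.sqrt(np.sum(np.abs(h) ** 2))

    @property
    def resolution_cell_mm2(self) -> float:
        """Approximate -6 dB envelope resolution-cell area (mm^2)."""
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))
        return float(fwhm * self.sigma_x_mm * fwhm * self.sigma_z_mm)


@dataclass
class ScattererPhantom:
    """A 2D cloud of point scatterers inside a rectangular field of view.

    Attributes
    ----------
    positions : ndarray, shape (n, 2)
        Scatterer (x, z) coordinates in mm, continuous.
    amplitudes : ndarray, shape (n,)
        Unitless complex scattering amplitudes; circular zero-mean
        amplitudes give fully developed speckle.
    fov : (float, float)
        (width, depth) of the field of view in mm; x in [0, width],
        z in [0, depth].
    vessel : dict or None
        Optional vessel record {"center": (x, z) mm, "radius": mm}.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    fov: tuple[float, float]
    vessel: dict | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        w, d = self.fov
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if self.positions.shape[0] != self.amplitudes.shape[0]:
            raise ValueError("positions and amplitudes must agree in length")
        x, z = self.positions[:, 0], self.positions[:, 1]
        if np.any(x < 0) or np.any(x > w) or np.any(z < 0) or np.any(z > d):
            raise ValueError("all scatterers must lie inside the field of view")
        if self.vessel is not None:
            cx, cz = self.vessel["center"]
            r = float(self.vessel["radius"])
            if r < 0:
                raise ValueError("vessel radius must be non-negative")
            if not (r <= cx <= w - r and r <= cz <= d - r):
                raise ValueError("vessel disk must lie inside the field of view")

    @classmethod
    def random(
        cls,
        fov: tuple[float, float] = (27.0, 45.0),
        density_per_mm2: float | None = None,
        psf: SpecklePsf | None = None,
        vessel: dict | None = None,
        seed: int | None = None,
    ) -> "ScattererPhantom":
        """Uniform random phantom with >= 5 scatterers per resolution cell.

        ``density_per_mm2`` defaults to 6 per resolution cell of ``psf``
        (fully developed speckle with margin).  Amplitudes are circular
        complex normal, giving Rayleigh-distributed envelope statistics.
        """
        psf = psf or SpecklePsf()
        if density_per_mm2 is None:
            density_per_mm2 = 6.0 / psf.resolution_cell_mm2
        min_density = 5.0 / psf.resolution_cell_mm2
        if density_per_mm2 < min_density:
            raise ValueError(
                f"density {density_per_mm2:.1f}/mm^2 below the fully-developed-speckle "
                f"floor of {min_density:.1f}/mm^2 (5 per resolution cell)"
            )
        rng = np.random.default_rng(seed)
        w, d = fov
        n = int(round(density_per_mm2 * w * d))
        pos = rng.uniform((0.0, 0.0), (w, d), size=(n, 2))
        # circular complex amplitudes give fully developed (Rayleigh) speckle
        amp = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2.0)
        return cls(pos, amp, (float(w), float(d)), vessel=vessel)


@dataclass
class SpeckleSequence:
    """A stack of grayscale speckle frames plus its ground truth.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, depth_px, width_px)
        Quantized frames (uint8 or uint16); row axis is depth.
    pitch : float
        Spatial sampling (px/mm).
    frame_rate : float
        Temporal sampling (frames/s).
    ground_truth : MotionTrace or None
        Rigid ground-truth trace sampled at the frame times.
    dense_truth : tuple or None
        For elastic motion: (t, ux, uz) dense per-frame displacement grids.
    envelope : ndarray or None
        Pre-quantization envelope frames (float), kept for statistics.
    """

    frames: np.ndarray
    pitch: float
    frame_rate: float
    ground_truth: MotionTrace | None = None
    dense_truth: tuple | None = None
    envelope: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pitch <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel pitch and frame rate must be positive")
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) stack")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.frame_rate


@numba.njit(cache=True)
def _render_frame(xs, zs, amp_re, amp_im, H, W, sig_x_px, sig_z_px, k_px, n_sigma):  # pragma: no cover
    re = np.zeros((H, W))
    im = np.zeros((H, W))
    hx = int(np.ceil(n_sigma * sig_x_px))
    hz = int(np.ceil(n_sigma * sig_z_px))
    for s in range(xs.size):
        xc = xs[s]
        zc = zs[s]
        ar = amp_re[s]
        ai = amp_im[s]
        i0 = max(0, int(np.floor(zc - hz)))
        i1 = min(H - 1, int(np.ceil(zc + hz)))
        j0 = max(0, int(np.floor(xc - hx)))
        j1 = min(W - 1, int(np.ceil(xc + hx)))
        for i in range(i0, i1 + 1):
            dz = i - zc
            gz = np.exp(-0.5 * (dz / sig_z_px) ** 2)
            ph = k_px * dz
            cr = np.cos(ph)
            ci = np.sin(ph)
            for j in range(j0, j1 + 1):
                dxp = j - xc
                g = gz * np.exp(-0.5 * (dxp / sig_x_px) ** 2)
                re[i, j] += g * (ar * cr - ai * ci)
                im[i, j] += g * (ar * ci + ai * cr)
    return np.sqrt(re * re + im * im)


def render_speckle(
    phantom: ScattererPhantom,
    motion: MotionTrace | tuple | None,
    psf: SpecklePsf | None = None,
    n_frames: int = 1,
    pitch: float = DEFAULT_PITCH,
    frame_rate: float = DEFAULT_FRAME_RATE,
    noise_sd: float = 0.0,
    bit_depth: int = 8,
    compression: str = "log",
    dynamic_range_db: float = 40.0,
    seed: int | None = None,
    keep_envelope: bool = True,
) -> SpeckleSequence:
    """Render a speckle image sequence from a scatterer phantom.

    Each frame is the envelope of the displaced scatterer cloud convolved
    with the complex PSF, plus optional additive Gaussian noise, quantized to
    ``bit_depth`` bits either linearly or after log compression over
    ``dynamic_range_db``.  Frame ``t`` uses the motion sample nearest in time.

    Parameters
    ----------
    phantom : ScattererPhantom
    motion : MotionTrace, (t, ux, uz) dense grids, or None
        Rigid trace (dx, dz in mm), dense elastic displacement grids as
        returned by :func:`hifufusion.motion.vessel_pulsation`, or no motion.
    psf : SpecklePsf
        Point-spread function; sampled kernel is unit-energy by construction.
    noise_sd : float
        Additive noise standard deviation as a fraction of the mean envelope.
    seed : int or None
        Seed for the noise generator; rendering is bit-reproducible for a
        fixed seed.

    Raises
    ------
    ValueError
        If the motion trace is shorter than the sequence duration or
        ``n_frames`` < 1.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    psf = psf or SpecklePsf()
    w_mm, d_mm = phantom.fov
    W = int(round(w_mm * pitch))
    H = int(round(d_mm * pitch))
    duration = (n_frames - 1) / frame_rate

    rigid = isinstance(motion, MotionTrace)
    dense = motion is not None and not rigid
    if rigid and motion.duration < duration - 1e-9:
        raise ValueError(
            f"motion trace ({motion.duration:.3f} s) shorter than sequence ({duration:.3f} s)"
        )
    if dense:
        t_dense, ux, uz = motion
        if t_dense[-1] < duration - 1e-9:
            raise ValueError("dense motion grids shorter than sequence duration")

    rng = np.random.default_rng(seed)
    k_px = 2.0 * np.pi / (psf.carrier_period_mm * pitch)
    sig_x_px = psf.sigma_x_mm * pitch
    sig_z_px = psf.sigma_z_mm * pitch

    env = np.empty((n_frames, H, W))
    base_x = phantom.positions[:, 0]
    base_z = phantom.positions[:, 1]
    gt_dx = np.zeros(n_frames)
    gt_dz = np.zeros(n_frames)
    for f in range(n_frames):
        tf = f / frame_rate
        if rigid:
            i = int(np.argmin(np.abs(motion.t - tf)))  # nearest motion sample
            dx, dz = motion.dx[i], motion.dz[i]
            gt_dx[f], gt_dz[f] = dx, dz
            xs = (base_x + dx) * pitch
            zs = (base_z + dz) * pitch
        elif dense:
            i = int(np.argmin(np.abs(np.asarray(t_dense) - tf)))
            gh, gw = ux[i].shape
            sx = np.clip(np.round(base_x * pitch).astype(int), 0, gw - 1)
            sz = np.clip(np.round(base_z * pitch).astype(int), 0, gh - 1)
            xs = (base_x + ux[i][sz, sx]) * pitch
            zs = (base_z + uz[i][sz, sx]) * pitch
        else:
            xs = base_x * pitch
            zs = base_z * pitch
        env[f] = _render_frame(
            np.ascontiguousarray(xs),
            np.ascontiguousarray(zs),
            np.ascontiguousarray(phantom.amplitudes.real),
            np.ascontiguousarray(phantom.amplitudes.imag),
            H,
            W,
            sig_x_px,
            sig_z_px,
            k_px,
            3.5,
        )
        if noise_sd > 0:
            env[f] = np.abs(env[f] + noise_sd * env[f].mean() * rng.standard_normal((H, W)))

    vmax = env.max()
    if vmax <= 0:
        vmax = 1.0
    levels = 2**bit_depth - 1
    if compression == "log":
        db = 20.0 * np.log10(np.maximum(env / vmax, 10 ** (-dynamic_range_db / 20.0 - 1)))
        scaled = np.clip(1.0 + db / dynamic_range_db, 0.0, 1.0)
    elif compression == "linear":
        scaled = env / vmax
    else:
        raise ValueError("compression must be 'log' or 'linear'")
    dtype = np.uint8 if bit_depth <= 8 else np.uint16
    frames = np.round(scaled * levels).astype(dtype)

    gt = None
    if rigid:
        gt = MotionTrace(
            np.arange(n_frames) / frame_rate,
            gt_dx - gt_dx[0],
            gt_dz - gt_dz[0],
            meta=dict(motion.meta),
        )
    return SpeckleSequence(
        frames,
        pitch,
        frame_rate,
        ground_truth=gt,
        dense_truth=motion if dense else None,
        envelope=env if keep_envelope else None,
        meta={"bit_depth": bit_depth, "compression": compression, "noise_sd": noise_sd},
    )
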