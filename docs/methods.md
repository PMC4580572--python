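# Methods

This note documents the models implemented in `hifufusion`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations of the baseline configuration.

## Speckle tracking

Motion is estimated between consecutive B-mode frames by block matching: a
reference region (RR) from frame *t* is compared against every same-sized
placement inside a search area (SA) of frame *t+1* using the
zero-normalized cross-correlation coefficient, computed by direct double
summation (not FFT) so that a perfect match scores exactly 1 and ties can
be broken deterministically — smallest displacement magnitude first, then
lexicographic (depth, lateral). The integer arg-max is refined per axis by
a 3-point parabolic fit of the correlation peak, clamped to half a pixel;
refinement is skipped when the peak is saturated on the SA border or when
the match is exact (correlation ≥ 1 − 1e−9), which makes integer
translations recover exactly. Frame-to-frame estimates are accumulated
(incremental tracking); in rigid-average mode the per-frame displacement
is the correlation-weighted mean over blocks, excluding blocks below a
configurable correlation floor (default 0.3).

Window geometry defaults follow the respiratory operating point of the
intraoperative acquisitions: RR 10.3 × 4.1 mm (lateral × depth), SA
16.4 × 6.2 mm, ROI 10.6 × 12.3 mm, 9.6 px/mm, 25 frames/s. The maximum
detectable per-frame displacement is SA/2 per axis, and SA/2 × frame rate
as a speed (8.2 mm and 20.5 cm/s laterally for these defaults).

**Drift correction.** Cumulative traces drift slowly (order 0.1 mm/s) due
to speckle decorrelation. A plain least-squares line through a
sinusoid-plus-ramp is biased by the sinusoid itself (≈ −0.13 mm/s on a
5 mm, 0.5 Hz example), so the drift rate is instead fitted through
whole-period means of the trace, after estimating the period from the
largest non-DC spectral peak; a pure ramp (no periodic content) is
detrended exactly, and a trace shorter than two periods is returned
unchanged with a warning, since drift and periodic motion are then
inseparable.

## Synthetic speckle and motion fixtures

Speckle sequences follow the scatterer-convolution model: ≥ 5 point
scatterers per resolution cell (default 6) with circular complex Gaussian
amplitudes, convolved with a separable Gaussian-windowed complex-cosine
PSF (σ_lateral ≈ 0.42 mm, σ_axial ≈ 0.17 mm, carrier period ≈ 0.42 mm at
9.6 px/mm — a ~3-pixel axial speckle cell). The envelope is optionally
log-compressed over 40 dB to 8 bits. Because scatterers live at
continuous coordinates and the PSF is evaluated analytically, subpixel
motion is rendered exactly; each sequence stores its ground-truth trace.
Circular complex amplitudes make the noise-free envelope Rayleigh
distributed (SD/mean ≈ 0.52), which the tests verify.

The ventilator waveform is a raised-cosine plateau-hold cycle: rise over
35 % of the period (raised cosine, C1), hold at full excursion until the
end of the 40 % duty window, symmetric fall, rest at zero. Motion
"magnitude" is interpreted throughout as **peak-to-peak excursion** (the
usual intraoperative report does not define it); defaults are 13.3 mm
cranial-caudal and 1.9 mm in depth at 0.2 Hz, giving a peak speed of
~11.9 mm/s, inside the measured 10.9–18.1 mm/s range. Vessel pulsation is
modeled as a purely radial field, sinusoidal at the heartbeat frequency
(default 0.96 Hz), maximal at the vessel wall and decaying as 1/r outside
(linear inside the lumen for continuity).

What the generator does **not** emulate: depth-dependent attenuation and
shadowing, out-of-plane decorrelation (only additive noise is available as
a decorrelation proxy), elastic shear of the parenchyma during breathing
(the rigid approximation the tracking study itself adopts), and real
scanner post-processing. Tracking results on these fixtures therefore
bound the algorithmic error, not the full in-vivo error budget.

## Acoustic fields

Transducer surfaces are discretized at λ/2 spacing (2 elements per
wavelength per dimension; λ = 0.513 mm at 3 MHz in tissue). Doubling the
density to λ/4 changes the focal-peak pressure by < 0.3 %, so the λ/2
default is used throughout; the under-sampling guard refuses spacings
above λ/2. The spherical cap (Rc 45 mm, aperture 56 mm cranial-caudal,
truncated to 33 mm transversally, 25 mm central hole) is sampled on a
projected grid with exact cap-area weights; the spindle torus (Rc 70 mm
minor, RM 5 mm major, aperture 68 mm, same hole) is sampled uniformly in
(arc length, azimuth) with all elements driven in phase, so its first
focus is a ring of diameter 2·RM at depth Rc and a second on-axis focus
forms near 86 mm where the converging cone crosses the axis.

Pressure follows the Rayleigh surface integral with uniform normal
velocity chosen so the radiated power (½ρc u² S) equals the requested
acoustic power; attenuation (4.5 Np/m/MHz) applies only along the tissue
part of each element-to-voxel ray beyond the entry plane at the
transducer-to-tissue distance d_t-t (= Rc − 10 mm in both study
configurations). The oscillatory factor is evaluated through a 2¹⁴-entry
interpolated sine table (relative error ~4 × 10⁻⁶); an on-axis closed-form
oracle for a focused bowl bounds the end-to-end error below 1 % of the
focal value. Observation points closer to an element than one element
radius are clamped to that radius. Mirror symmetry of the truncated cap
(x → −x, y → −y) and the axisymmetry of the in-phase torus (computed on an
(r, z) half-plane and revolved) are exploited purely as computational
shortcuts; tests compare both against direct evaluation.

Absorbed power density defaults to the small-volume limit
`Q = β p² A_Harm / (ρ_t c)` with β = 0.6 and `A_Harm = A·f`; the
saturating full expression `β p² (1 − e^(−2 A_Harm V)) / (2 ρ_t c V)` is
available behind a flag with V the voxel path length. `BubbleModel`
exposes a pluggable harmonic-attenuation enhancement (microbubble density
200 /mm³, initial radii 1–3 µm) with a documented saturating parametric
form; the default is **no enhancement**, and every simulation reported by
the acceptance script uses that default. The consequences are discussed
under Limitations.

## Bioheat, dose and motion warping

The Pennes equation is stepped explicitly (7-point Laplacian) at
dt = 0.8 × the stability bound ρC/(2k Σ 1/h²); the solver refuses larger
steps. Walls are Dirichlet at the 37 °C equilibrium on domains padded well
beyond the heated region (a zero-flux option exists for the conservation
tests); vessel-mask voxels are reset to blood temperature each step.
Thermal dose accumulates as R^(43−T)·dt/60 CEM with R = 0 below 37 °C,
0.25 on the closed interval [37 °C, 43 °C] (T = 43 °C deliberately takes
0.25, matching the stated dose model even though much of the hyperthermia
literature uses 0.5 there) and 0.5 above. Perfusion is annihilated,
per step and irreversibly, wherever the dose reaches 240 CEM (threshold
inclusive).

Motion enters through rigid heat-map warping: at every time step the
stationary single-shot heat map is resampled at (x − dx(t), y, z − dz(t))
by trilinear interpolation, zero outside the domain; a nearest-voxel mode
exists for exact-conservation tests. Motion samples are quantized to
0.02 mm so consecutive steps with near-identical displacement reuse the
warped map (a pure speed optimization, two orders of magnitude below the
grid spacing). Raster shots translate the same base map laterally by the
shot offset (instantaneous repositioning between shots); shot *i* starts
at *i*·(on+off). The motion phase at the first shot is configurable and
the scenario runner sweeps 6 evenly spaced phases by default, emulating
the six independent in-vivo motion recordings of the original study (whose
exposure/motion phase was uncontrolled).

**Grids.** All spherical-scenario grids are cut from one 0.6 mm master
lattice and refined by integer factors so heat maps computed on fine focal
grids block-average (energy-conserving) and embed exactly onto the thermal
grids: the heat map is computed at 0.15 mm around the focus, the
single-shot thermal grid is 21 × 14 × 20 mm at 0.3 mm, and the 49-shot
raster runs on 49 × 37 × 29 mm at 0.6 mm (scaled down so the ~8.5 min plan
times six phases stays tractable). The toroidal scenario runs on
40 × 40 × 48 mm at 0.4 mm with the field computed at 0.15/0.2 mm in (r, z).
Spot checks: the toroidal control volume is identical (4.94 cm³) at 0.4 mm
and 0.3 mm with a 0.1 mm field grid, and a generic Gaussian-source
refinement test keeps lesion volumes within 10 % under halving of h; the
raster Dice coefficient moves by <1 point (47.3 -> 47.9 % on a probe phase)
when the 0.6 mm raster grid is halved.

## Lesion metrics

Volume is voxel count × voxel volume above 240 CEM after a 20 s cooldown.
DSC, VUt (control tissue no longer necrosed) and VOt (newly necrosed
tissue outside the control) are exact voxel-set operations; percentages
are relative to the control volume. Homogeneity requires a single
6-connected component and no enclosed cavity (complement flood fill from
the domain boundary). "Main/minor diameter" along an axis — not defined in
the usual treatment reports — is implemented as the largest/smallest
nonzero chord of the mask within the centroid slab normal to the remaining
axis, with a bounding-box alternative behind a flag. Treatment rate is
volume divided by the full plan duration (on + off times).

## Limitations

* **No nonlinear propagation or microbubble harmonic absorption by
  default.** The original modeling chain estimated a harmonic attenuation
  from microbubble dynamics (Gilmore–Akulichev), which concentrates extra
  absorption where pressure is high. With the baseline `A_Harm = A·f`,
  the stationary control lesions and the field geometry reproduce the
  reported values (single spherical control ≈ 71 mm³ vs 60 mm³ printed;
  focal widths 0.46/0.77 mm and focal length 3.47 mm vs 0.5/0.7/3.5 mm;
  ring focus 9.3 mm × 2.1 mm vs 10 × 2 mm; second toroidal focus at
  86.4 mm with ≈ 3000 W/cm² vs 8.6 cm and 3200 W/cm²), but the
  **motion-case** quantities fall below the reported regime: the swept
  track between dwell positions receives too little absorbed energy to
  stay above 240 CEM, so the six-phase mean volume of the single spherical
  lesion computes to ≈ 11 mm³ (reported: 47 ± 3 mm³), the raster Dice
  coefficient to ≈ 55 % (reported 76 ± 8 %), and the toroidal motion
  volume to ≈ 2.8 cm³ (reported 4.0 ± 0.0 cm³). All deviations point in
  the direction expected from the omitted pressure-dependent absorption
  enhancement, which in the original chain keeps the swept track lethal.
  The `BubbleModel` hook accepts such an enhancement, but no attempt is
  made to tune it to reproduce those numbers.
* **No boiling cap.** Temperatures are not clamped at 100 °C, so focal
  temperatures (and hence mean doses inside lesions) are far above
  physical values; the 240 CEM iso-surface, which defines every reported
  lesion, is insensitive to this.
* The toroidal lesion extends along the axial caustic beyond the second
  focus (depth ≈ 44 mm vs 25 mm reported) because nothing shields the
  deep beam; the control volume computes to 4.94 cm³ vs 3.9 cm³ printed
  (27 % above, just outside the 25 % acceptance band) and is
  grid-converged.
* Acoustic and thermal tissue properties are temperature-independent, the
  tissue is homogeneous (vessels only as constant-temperature masks), and
  the pressure field is not recomputed as tissue moves — the same
  assumptions as the original modeling chain.
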