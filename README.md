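# hifufusion

Dynamic fusion modeling of intraoperative HIFU (High-Intensity Focused
Ultrasound) liver therapy: estimate in-vivo tissue motion from B-mode
ultrasound image sequences by incremental speckle tracking, inject that
motion into a 3D acoustic + bioheat + thermal-dose simulation, and quantify
what breathing does to the size, shape, homogeneity and targeting of the
thermal lesion.

The package is aimed at therapeutic-ultrasound researchers comparing
focusing strategies — here a classical truncated spherical transducer
(juxtaposing many millimetric "cigar-shaped" lesions) against a spindle-torus
transducer whose ring-shaped focus builds one large conical lesion in a
single 40 s exposure — under realistic ventilator-driven liver motion
(~0.2 Hz, >13 mm cranial-caudal excursion).

## The model

**Motion estimation.** Blocks of speckle are matched between consecutive
B-mode frames by the zero-normalized cross-correlation coefficient

    rho_AB = sum_i (a_i - A)(b_i - B) / sqrt( sum_j (a_j - A)^2 sum_k (b_k - B)^2 )

maximized over all search-region placements inside a search area, with
3-point parabolic subpixel refinement, correlation-weighted rigid averaging,
linear drift correction and spectral estimation of the breathing /
heartbeat frequencies.

**Acoustics.** The complex pressure of the discretized radiating surface is
the Rayleigh integral `p(r) = (i rho c k u_n / 2 pi) sum_e exp(-(ik + A f) d_e)
dS_e / d_e`, with attenuation `A = 4.5 Np/m/MHz` applied on the tissue
portion of each ray. Absorbed power density is `Q = beta p^2 A_Harm /
(rho_t c)` with absorbed fraction `beta = 0.6` and a pluggable harmonic
attenuation `A_Harm` (baseline `A f`).

**Thermal model.** Pennes' bioheat equation
`rho_t C_t dT/dt = k lap T - omega_b C_b (T - T_b) + Q` is stepped
explicitly; liver motion enters by resampling the heat map,
`Q_breath(x,y,z,t) = Q(x - dx(t), y, z - dz(t))`, zero outside the domain.
Damage is cumulative equivalent minutes at 43 C,
`t43 = integral R^(43-T) dt` with `R = 0.25` for `T in [37, 43]` C and
`0.5` above; 240 CEM marks irreversible necrosis and annihilates local
perfusion. Lesions are compared by volume, Dice similarity coefficient
`DSC = 2|V n V'| / (|V| + |V'|)`, volumetric under-/overtreatment,
off-centering, homogeneity and treatment rate.

## Worked example

```python
from hifufusion import (ScattererPhantom, ventilator_motion, render_speckle,
                        TrackingConfig, track_sequence,
                        dominant_frequency, derate_intensity)

# breathing speckle sequence with known ground truth (13.3 mm excursion)
phantom = ScattererPhantom.random(fov=(27.0, 18.5), seed=8)
motion = ventilator_motion(duration=5.5, amp_cc=13.3, amp_ap=1.9)
seq = render_speckle(phantom, motion, n_frames=131, seed=0)

fields, trace = track_sequence(seq, TrackingConfig())
print(f"recovered CC excursion : {trace.dx.max() - trace.dx.min():.2f} mm")
print(f"mean correlation       : {trace.meta['mean_correlation']:.3f}")
print(f"breathing frequency    : {dominant_frequency(trace):.3f} Hz")
print(f"focal derating 5000 -> {derate_intensity(5000.0, 4.5, 3.0, 10.0):.0f} W/cm^2")
```

prints

```
recovered CC excursion : 13.33 mm
mean correlation       : 0.969
breathing frequency    : 0.191 Hz
focal derating 5000 -> 3817 W/cm^2
```

i.e. the tracker recovers the 13.3 mm cranial-caudal excursion to 0.3%, the
0.2 Hz ventilator rate to one spectral bin of the 5.5 s window, and the
closed-form derating reproduces the 3800 W/cm^2 in-tissue focal intensity
(two significant figures) of the spherical device.

Full treatment scenarios run through `hifufusion.scenarios.run_scenario`
(or the CLI: `hifufusion scenario --preset single-toroidal --out report.json`);
each report carries the control lesion, one lesion per breathing phase and
mean +/- SD summaries of volume, DSC, under-/overtreatment, off-centering
and treatment rate.

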