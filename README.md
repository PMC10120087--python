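# tfflim — single-shot time-folded fluorescence lifetime imaging

Fluorescence lifetime imaging (FLIM) maps the nanosecond decay constant
τ of fluorophore emission across a scene; τ reports on the fluorophore
environment (pH, oxygen, binding state) independently of intensity.
Conventional wide-field time-gated systems scan a gate across many
exposures.  A *time-folded* system instead places an optical cavity in
front of a gated intensified camera (iCCD): each cavity round trip
re-images the same decay delayed by the round-trip time t_c ≈ 0.59 ns
and displaced by y pixels, so a **single exposure** records six
time-gated samples of every pixel's decay, side by side.  A companion
CMOS camera records the time-integrated intensity q = k·A·τ.

`tfflim` implements the full computational stack for this modality,
for anyone who wants to simulate, analyse, or reason about such a
system without owning one:

- **forward model** — gate-integrated, replica-summed, sheared iCCD
  images and time-integrated CMOS images from per-pixel lifetime and
  amplitude maps (`tfflim.forward`);
- **detector noise** — intensifier noise budget (Poisson signal, dark,
  clock-induced charge, readout, excess-noise factor F) with Gaussian
  and strict-Poisson sampling (`tfflim.noise`);
- **uncertainty bounds** — the Bayesian posterior lower bound on
  relative lifetime uncertainty versus true lifetime and photon budget
  (`tfflim.uncertainty`);
- **inverse retrieval** — regularized reconstruction
  `argmin_τ ‖P(τ) − ŝ‖₂ + α‖τ‖₂²` by projected gradient descent with
  the analytic adjoint gradient and Armijo line search
  (`tfflim.inversion`);
- **physics-inspired CNN** — a dilated convolutional network whose
  kernel taps land exactly on the replica displacements (11-tap
  kernels, dilation 10, a sparse 101-pixel causal receptive field),
  trained with intensity-weighted MSE; implemented as a compact numpy
  CNN (`tfflim.cnn`);
- **calibration** — replica separation and shear tilt from the 2-D
  Fourier transform of the iCCD image, plus rectification
  (`tfflim.calibration`);
- **phantoms** — synthetic bead / cell-like / texture / flat scenes and
  full training datasets with reproducible manifests
  (`tfflim.phantoms`).

A statsmodels-style interface ties reconstruction together:
`TimeFoldedLifetimeModel(cmos, iccd, config).fit()` returns a results
object with the lifetime map, validity mask, diagnostics and a
`summary()`.  A `tfflim` command-line tool exposes `simulate`,
`simulate-dataset`, `retrieve`, `uncertainty`, `calibrate`, `train` and
`predict`.

## Worked example

```python
import numpy as np
from tfflim import (SystemConfig, DetectorConfig, IRConfig,
                    TimeFoldedLifetimeModel, simulate_iccd, simulate_cmos,
                    sample_noisy_iccd)
from tfflim.phantoms import PhantomSpec, make_phantom

cfg, det = SystemConfig(), DetectorConfig()

# two bead populations, ~50k photoelectron-equivalent photons per bead
spec = PhantomSpec(kind="beads", fov=(96, 160), margin=cfg.margin,
                   bead_params=((4.0, 2.1, 7, 1866.0), (8.0, 4.0, 5, 311.0)),
                   background_amp=0.0, col_range=(100, 205), seed=7)
amp, tau = make_phantom(spec)
iccd = sample_noisy_iccd(simulate_iccd(tau, amp, cfg), det, seed=11)
cmos = simulate_cmos(tau, amp, cfg)

model = TimeFoldedLifetimeModel(cmos, iccd, cfg, det)
ir = IRConfig(init="constant", init_range=(2.0, 2.0), max_iter=1000,
              low_signal_frac=0.05)
res = model.fit(method="ir", ir_config=ir)
print(res.summary())

truth = tau.tau[:, cfg.margin:]
for t in (2.1, 4.0):
    sel = (np.abs(truth - t) < 1e-9) & res.mask
    print(f"population {t} ns -> median retrieved "
          f"{np.median(res.tau[sel]):.2f} ns")
```

prints (abridged):

```
Time-folded FLIM lifetime reconstruction
============================================
method:            ir
image shape:       96 x 160
valid pixels:      1526 (9.9%)
shear y:           10 px, t_c = 0.59 ns, N+1 = 6 replicas
gate:              [-0.20, 1.30] ns (smoothed_flat_top)
tau median:        3.628 ns
tau IQR:           [2.695, 4.450] ns
...
population 2.1 ns -> median retrieved 2.10 ns
population 4.0 ns -> median retrieved 3.96 ns
```

(The valid-pixel fraction is small because the dark background is
excluded by the low-signal cut; the global median mixes the two bead
populations.)

Both dye populations are recovered within ~2%, and the slower dye shows
the larger spread — the same qualitative pattern the physical system
exhibits, because late-decay photons are scarcer at long lifetimes.

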