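"""Intensified-CCD noise model.

The photocathode converts a gate-integrated expectation of P photons
into DQE*P photoelectrons (Poisson), the microchannel plate multiplies
them by the gain M with excess-noise factor F, and the readout adds
dark, clock-induced-charge and read noise.  In output counts the
variance at one pixel is

    sigma^2 = sigma_readout^2
              + F^2 * M^2 * (DQE * P + sigma_dark^2 + sigma_clc^2),

with sigma_dark^2 = dark_rate * exposure accumulated dark electrons.
The gain's temporal modulation is the gate itself (effective gain
M * G(t)), so this module only ever sees gate-integrated photon counts.

Sampling returns images in the same photon-equivalent units as the clean
input (count-space noise divided by M * DQE), so a noisy image is an
unbiased estimate of the clean one and zero noise reproduces it exactly.
Negative values are retained: read noise is signed.
"""

from __future__ import annotations

import numpy as np

from .config import DetectorConfig
from .forward import ICCDImage, _field

__all__ = ["noise_sigma", "sample_noisy_iccd", "photon_noise_sigma"]


def noise_sigma(clean_signal, det: DetectorConfig, dur: float | None = None):
    """Standard deviation, in output counts, of one pixel's measurement.

    ``clean_signal`` is the expected photon count at the photocathode
    within the gate (scalar or array).  ``dur`` is the exposure over
    which dark charge accumulates; defaults to ``det.exposure_s``.
    """
    p = np.asarray(clean_signal, dtype=float)
    if np.any(p < 0):
        raise ValueError("expected photon counts must be >= 0")
    if dur is None:
        dur = det.exposure_s
    if dur < 0:
        raise ValueError("duration must be >= 0")
    sig_dark2 = det.dark_rate * dur
    var = (det.sigma_readout ** 2
           + det.noise_factor ** 2 * det.gain ** 2
           * (det.dqe * p + sig_dark2 + det.sigma_clc ** 2))
    return np.sqrt(var)


def photon_noise_sigma(clean_signal, det: DetectorConfig,
                       dur: float | None = None):
    """:func:`noise_sigma` rescaled to photon-equivalent units."""
    return noise_sigma(clean_signal, det, dur) / (det.gain * det.dqe)


def sample_noisy_iccd(clean, det: DetectorConfig, seed=None,
                      mode: str = "gaussian") -> ICCDImage:
    """Draw one noisy realization of a clean iCCD image.

    ``mode="gaussian"`` draws every pixel from N(s, sigma) with sigma
    from :func:`noise_sigma` (the model's Gaussian approximation);
    ``mode="poisson"`` replaces the signal term by a strict Poisson draw
    of the photoelectrons (cross-check mode, same mean and variance in
    the large-count limit).  Reproducible for a fixed ``seed``.
    """
    s = _field(clean, "s")
    if np.any(s < 0):
        raise ValueError("clean image must be non-negative")
    rng = np.random.default_rng(seed)
    scale = det.gain * det.dqe
    if mode == "gaussian":
        sigma = noise_sigma(s, det)
        noisy = s + rng.standard_normal(s.shape) * sigma / scale
    elif mode == "poisson":
        # photoelectrons ~ Poisson(DQE*P), amplified with excess noise F:
        # model the amplification spread as Gaussian with the same excess
        # variance, then add the additive electron terms.
        ne = rng.poisson(det.dqe * s).astype(float)
        extra = (det.noise_factor ** 2 - 1.0) * det.dqe * s
        add = (det.sigma_readout ** 2 / det.gain ** 2
               + det.noise_factor ** 2
               * (det.dark_rate * det.exposure_s + det.sigma_clc ** 2))
        sigma_e = np.sqrt(extra + add)
        noisy = (ne + rng.standard_normal(s.shape) * sigma_e) / det.dqe
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return ICCDImage(noisy, is_noisy=True)
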