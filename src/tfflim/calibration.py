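"""Shear calibration from the iCCD image's 2-D Fourier transform.

The replica chain makes the sheared image quasi-periodic along the
shear axis with period y pixels.  Its windowed power spectrum is a
comb-modulated object spectrum; transforming the power spectrum back
(Wiener-Khinchin) gives the image autocorrelation, which carries sharp,
exactly-centred side peaks at every multiple of the replica
displacement vector.  The strongest side peak gives the fundamental
separation; the farthest detectable harmonic refines the tilt (angular
leverage grows with distance).  Peaks are refined to sub-pixel
precision by a local quadratic fit.

A measured tilt is removed by rotating the image back about its centre
before reconstruction; tilt of even a few degrees otherwise produces
banded lifetime artifacts in the retrieval.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .forward import ICCDImage, _field

__all__ = ["estimate_shear", "rectify", "CalibrationError"]


class CalibrationError(RuntimeError):
    """No significant off-centre correlation peak: cannot estimate shear."""

    def __init__(self, msg, spectrum=None):
        super().__init__(msg)
        self.spectrum = spectrum


def _quadratic_refine(y0, y1, y2):
    """Sub-pixel offset of a parabola's vertex through three samples."""
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-300:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def _autocorrelation(img):
    h, w = img.shape
    win = np.outer(np.hanning(h), np.hanning(w))
    f = np.fft.fft2((img - img.mean()) * win, s=(2 * h, 2 * w))
    acf = np.fft.fftshift(np.fft.ifft2(np.abs(f) ** 2).real)
    return acf


def _find_peak(acf, center, region):
    """Argmax over ``region`` that is a strict local maximum of ``acf``."""
    masked = np.where(region, acf, -np.inf)
    iy, ix = np.unravel_index(int(np.argmax(masked)), masked.shape)
    if not np.isfinite(masked[iy, ix]):
        return None
    patch = acf[iy - 1:iy + 2, ix - 1:ix + 2]
    if patch.shape != (3, 3) or acf[iy, ix] < patch.max():
        return None
    dy = _quadratic_refine(acf[iy - 1, ix], acf[iy, ix], acf[iy + 1, ix])
    dx = _quadratic_refine(acf[iy, ix - 1], acf[iy, ix], acf[iy, ix + 1])
    return (iy - center[0] + dy, ix - center[1] + dx, acf[iy, ix])


def estimate_shear(s, angle_tol: float = 10.0, min_sep: float = 3.0,
                   rel_height: float = 0.15, max_harmonic: int = 3):
    """Estimate (separation_px, tilt_deg) of the replica chain.

    The search is restricted to displacements of at least ``min_sep``
    pixels within ``angle_tol`` degrees of the nominal (column) shear
    axis; the fundamental peak must reach ``rel_height`` of the central
    autocorrelation value, otherwise a :class:`CalibrationError`
    carrying the autocorrelation map is raised (e.g. a single-replica
    image has no periodicity).  Tilt is measured in degrees from the
    column axis, with the same sign convention as ``SystemConfig.tilt``
    and :func:`rectify`.
    """
    img = _field(s, "s").astype(float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    acf = _autocorrelation(img)
    h2, w2 = acf.shape
    cy, cx = h2 // 2, w2 // 2
    c0 = acf[cy, cx]
    yy = np.arange(h2)[:, None] - cy
    xx = np.arange(w2)[None, :] - cx
    rr = np.hypot(yy, xx)
    ang = np.degrees(np.arctan2(yy, np.abs(xx) + 1e-300))
    base = (np.abs(ang) <= angle_tol) & (xx > 0)

    fund = _find_peak(acf, (cy, cx), base & (rr >= min_sep))
    if fund is None or fund[2] < rel_height * c0:
        raise CalibrationError(
            "no significant off-centre autocorrelation peak "
            "(need >= 2 visible replicas)", spectrum=acf)
    vy, vx, _ = fund
    # harmonic refinement: the k-th replica pair sits at exactly k times
    # the displacement vector, with growing angular leverage; each step
    # predicts the next peak from the current best estimate.
    best_k, best_v = 1, np.array([vy, vx])
    for k in range(2, max_harmonic + 1):
        target = best_v * (k / best_k)
        radius = max(1.5, 0.15 * np.hypot(*best_v) / best_k)
        near = np.hypot(yy - target[0], xx - target[1]) <= radius
        pk = _find_peak(acf, (cy, cx), near)
        if pk is None or pk[2] < 0.02 * c0:
            break
        best_k, best_v = k, np.array([pk[0], pk[1]])
    separation = float(np.hypot(*best_v)) / best_k
    tilt = -float(np.degrees(np.arctan2(best_v[0], best_v[1])))
    return separation, tilt


def rectify(s, tilt: float) -> ICCDImage:
    """Rotate an iCCD image by ``-tilt`` degrees about its centre.

    Aligns the measured shear direction with the nominal column axis
    (bilinear resampling).  ``tilt == 0`` is a bit-exact pass-through.
    Pixels rotated in from outside the frame are zero-filled.
    """
    if abs(tilt) >= 45.0:
        raise ValueError("|tilt| must be < 45 degrees")
    img = _field(s, "s")
    noisy = getattr(s, "is_noisy", True)
    if tilt == 0.0:
        return ICCDImage(img.copy(), is_noisy=noisy)
    out = ndimage.rotate(img, -tilt, reshape=False, order=1,
                         mode="constant", cval=0.0)
    return ICCDImage(out, is_noisy=True)
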