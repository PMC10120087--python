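"""Forward model of the time-folded FLIM system.

An optical cavity replicates the fluorescence decay of every scene pixel
``n_replicas`` times; pass ``n`` is delayed by ``n*t_c`` nanoseconds,
displaced by ``n*y`` detector columns, and attenuated by the splitter
weight ``r_n``.  A gated intensifier integrates each replica against the
gate profile ``G(t)``, so a single exposure samples several windows of
the same decay in parallel.  The clean signal at detector pixel (i, j) is

    s[i, j] = sum_n  r_n * Integral G(t) * A[i, j - n*y]
                     * exp(-(t - t0 - n*t_c) / tau[i, j - n*y])
                     * H(t - t0 - n*t_c) dt,

while the companion CMOS camera records the time integral of the full
decay, q[i, j] = k * A[i, j] * tau[i, j].

Seed maps (A, tau) must be ``margin = (n_replicas - 1) * y`` columns
wider than the output field of view: the extra upstream band supplies the
replicas that originate outside the FOV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from .config import GateProfile, SystemConfig, geometric_replica_weights

__all__ = [
    "LifetimeMap",
    "AmplitudeMap",
    "ICCDImage",
    "CMOSImage",
    "replica_weights",
    "gate_values",
    "decay_gate_integral",
    "replica_integrals",
    "simulate_iccd",
    "simulate_cmos",
    "valid_region",
    "reliable_region",
]

# Unique-lifetime count above which quadrature switches to a log-spaced
# interpolation table (relative accuracy ~1e-4, see docs/methods.md).
_TABLE_THRESHOLD = 512
_TABLE_NODES = 2048


def _field(x, name):
    """Accept either a typed wrapper or a bare ndarray."""
    arr = getattr(x, name, x)
    return np.asarray(arr, dtype=float)


@dataclass(frozen=True)
class LifetimeMap:
    """Per-pixel mono-exponential lifetime, ns.  Strictly positive."""

    tau: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.tau, dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("lifetimes must be finite and > 0")
        object.__setattr__(self, "tau", t)


@dataclass(frozen=True)
class AmplitudeMap:
    """Per-pixel decay amplitude (photons/ns scale).  Non-negative."""

    a: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("amplitudes must be finite and >= 0")
        object.__setattr__(self, "a", a)


@dataclass(frozen=True)
class ICCDImage:
    """Gate-integrated, replica-summed signal on the intensified camera."""

    s: np.ndarray
    is_noisy: bool = False

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        if not self.is_noisy and np.any(s < -1e-9):
            raise ValueError("clean iCCD images must be non-negative")
        object.__setattr__(self, "s", s)


@dataclass(frozen=True)
class CMOSImage:
    """Time-integrated fluorescence intensity on the companion camera."""

    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if np.any(q < 0):
            raise ValueError("CMOS intensities must be non-negative")
        object.__setattr__(self, "q", q)


def replica_weights(ratio_a: float, ratio_b: float, n: int) -> np.ndarray:
    """Replica power fractions r_0..r_{n-1} from a beamsplitter ratio.

    r_m = ratio_a * ratio_b**m: the direct pass exits with fraction
    ``ratio_a``, each further round trip multiplies by ``ratio_b``
    (lossless mirrors assumed).  Strictly decreasing for ratios in (0, 1).
    """
    return geometric_replica_weights(ratio_a, ratio_b, n)


def gate_values(gate: GateProfile, t_grid: np.ndarray) -> np.ndarray:
    """Evaluate the intensifier gate profile G(t) on a time grid (ns)."""
    t = np.asarray(t_grid, dtype=float)
    if t.ndim == 1 and t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    a, b = gate.t_start, gate.t_end
    if gate.shape == "rectangular" or gate.edge_sigma == 0:
        return ((t >= a) & (t < b)).astype(float)
    s = gate.edge_sigma
    return ndtr((t - a) / s) - ndtr((t - b) / s)


def _gate_support(gate: GateProfile):
    """Time interval outside which G(t) is numerically negligible."""
    pad = 6.0 * gate.edge_sigma if gate.shape == "smoothed_flat_top" else 0.0
    return gate.t_start - pad, gate.t_end + pad


def decay_gate_integral(tau, delay: float, cfg: SystemConfig,
                        derivative: bool = False):
    """Gate integral of a unit-amplitude decay started at ``delay``.

        I(tau) = Integral_{delay}^{inf} G(t) exp(-(t - delay)/tau) dt

    evaluated by trapezoidal quadrature on a uniform grid of step
    ``cfg.dt`` aligned to the gate support and the decay onset (so the
    integrand is smooth on the grid).  With ``derivative=True`` also
    returns dI/dtau = Integral G(t) e^{-(t-delay)/tau} (t-delay)/tau^2 dt.

    ``tau`` may be a scalar or an array; vectorized over pixels.
    """
    tau = np.asarray(tau, dtype=float)
    lo, hi = _gate_support(cfg.gate)
    if cfg.t_max is not None:
        hi = min(hi, cfg.t_max)
    lo = max(lo, delay)
    if hi <= lo:
        z = np.zeros_like(tau)
        return (z, z.copy()) if derivative else z
    n = max(int(np.ceil((hi - lo) / cfg.dt)), 2) + 1
    t = np.linspace(lo, hi, n)
    if cfg.gate.shape == "rectangular" or cfg.gate.edge_sigma == 0:
        # the grid is already clipped to the gate window, where G = 1;
        # sampling the half-open profile would zero the last node and
        # degrade the trapezoid rule to first order
        g = np.ones_like(t)
    else:
        g = gate_values(cfg.gate, t)
    flat = tau.reshape(-1)
    out = np.empty(flat.shape)
    dout = np.empty(flat.shape) if derivative else None
    # chunk pixels to bound the (pixels x time) exponential workspace
    step = max(1, int(4e6 // n))
    for i0 in range(0, flat.size, step):
        tt = flat[i0:i0 + step, None]
        e = np.exp((delay - t[None, :]) / tt) * g[None, :]
        out[i0:i0 + step] = np.trapezoid(e, t, axis=1)
        if derivative:
            de = e * (t[None, :] - delay) / tt ** 2
            dout[i0:i0 + step] = np.trapezoid(de, t, axis=1)
    out = out.reshape(tau.shape)
    if derivative:
        return out, dout.reshape(tau.shape)
    return out


def _interp_loglog(x, xn, yn):
    """Positive-function interpolation, linear in (log x, log y)."""
    logy = np.log(np.maximum(yn, 1e-300))
    return np.exp(np.interp(np.log(x), np.log(xn), logy))


def replica_integrals(tau, cfg: SystemConfig, derivative: bool = False,
                      method: str = "auto"):
    """Per-replica gate integrals I_n(tau) for every pixel.

    Returns an array of shape ``(n_replicas,) + tau.shape`` (plus the
    derivative stack when requested).  ``method``:

    - ``"quad"``: exact trapezoidal quadrature per unique lifetime;
    - ``"table"``: quadrature on a 2048-node log-spaced lifetime table,
      then log-log interpolation (fast for continuous lifetime maps);
    - ``"auto"``: quad when the map has few unique lifetimes, else table.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("lifetimes must be > 0")
    uniq, inv = np.unique(tau, return_inverse=True)
    if method == "auto":
        method = "quad" if uniq.size <= _TABLE_THRESHOLD else "table"
    shape = (cfg.n_replicas,) + tau.shape
    I = np.empty(shape)
    dI = np.empty(shape) if derivative else None

    if method == "quad":
        for n, delay in enumerate(cfg.delays):
            res = decay_gate_integral(uniq, delay, cfg, derivative=derivative)
            if derivative:
                I[n] = res[0][inv].reshape(tau.shape)
                dI[n] = res[1][inv].reshape(tau.shape)
            else:
                I[n] = res[inv].reshape(tau.shape)
    elif method == "table":
        nodes = np.geomspace(uniq[0] * 0.999, uniq[-1] * 1.001, _TABLE_NODES)
        for n, delay in enumerate(cfg.delays):
            res = decay_gate_integral(nodes, delay, cfg, derivative=derivative)
            vals = res[0] if derivative else res
            I[n] = _interp_loglog(tau, nodes, vals)
            if derivative:
                dI[n] = _interp_loglog(tau, nodes, res[1])
    else:
        raise ValueError(f"unknown integration method {method!r}")
    if derivative:
        return I, dI
    return I


def _check_seed(tau, a, cfg: SystemConfig):
    if tau.shape != a.shape:
        raise ValueError("lifetime and amplitude maps must share one shape")
    if tau.ndim != 2:
        raise ValueError("seed maps must be 2-D")
    if tau.shape[1] <= cfg.margin:
        raise ValueError(
            f"seed maps must be wider than the shear extent: need "
            f"> {cfg.margin} columns, got {tau.shape[1]}")


def simulate_iccd(tau, a, cfg: SystemConfig, method: str = "auto") -> ICCDImage:
    """Render the clean (noise-free) single-shot sheared iCCD image.

    Seed maps of shape (H, W) produce an output of shape
    (H, W - margin): the upstream ``margin`` columns only feed replicas
    and are cropped from the field of view.  A non-zero ``cfg.tilt``
    rotates the rendered image about its centre (bilinear), emulating a
    mis-aligned shear direction.
    """
    tau = _field(tau, "tau")
    a = _field(a, "a")
    if np.any(tau <= 0) or not np.all(np.isfinite(tau)):
        raise ValueError("lifetimes must be finite and > 0")
    if np.any(a < 0):
        raise ValueError("amplitudes must be >= 0")
    _check_seed(tau, a, cfg)
    m, y = cfg.margin, int(cfg.y)
    W = tau.shape[1]
    w = cfg.weights
    I = replica_integrals(tau, cfg, method=method)
    out = np.zeros((tau.shape[0], W - m))
    for n in range(cfg.n_replicas):
        contrib = a * I[n]
        out += w[n] * contrib[:, m - n * y: W - n * y]
    if cfg.tilt != 0.0:
        out = ndimage.rotate(out, cfg.tilt, reshape=False, order=1,
                             mode="constant", cval=0.0)
        np.clip(out, 0.0, None, out=out)
    return ICCDImage(out, is_noisy=False)


def simulate_cmos(tau, a, cfg: SystemConfig, method: str = "closed") -> CMOSImage:
    """Render the time-integrated CMOS image over the same FOV.

    ``method="closed"`` uses the exact integral q = k * A * tau;
    ``method="quad"`` integrates the decay numerically on a grid of step
    ``cfg.dt`` (agreement with the closed form is a quadrature check).
    """
    tau = _field(tau, "tau")
    a = _field(a, "a")
    _check_seed(tau, a, cfg)
    if method == "closed":
        q = cfg.k * a * tau
    elif method == "quad":
        horizon = cfg.t0 + 20.0 * float(tau.max())
        n = int(np.ceil((horizon - cfg.t0) / cfg.dt)) + 1
        t = np.linspace(cfg.t0, horizon, n)
        uniq, inv = np.unique(tau, return_inverse=True)
        vals = np.trapezoid(
            np.exp((cfg.t0 - t[None, :]) / uniq[:, None]), t, axis=1)
        q = cfg.k * a * vals[inv].reshape(tau.shape)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CMOSImage(q[:, cfg.margin:])


def valid_region(cfg: SystemConfig, fov_shape) -> np.ndarray:
    """Mask of FOV pixels whose full replica chain is observed.

    For an image whose replica sources live inside the same frame, pixel
    column j receives replica n from column j - n*y; the mask marks
    columns with every source in-frame (j >= (n_replicas - 1) * y).
    """
    h, wd = fov_shape
    m = cfg.margin
    if wd <= m:
        raise ValueError(f"FOV width {wd} not wider than shear extent {m}")
    mask = np.ones((h, wd), dtype=bool)
    mask[:, :m] = False
    return mask


def reliable_region(cfg: SystemConfig, fov_shape) -> np.ndarray:
    """Mask of FOV pixels whose lifetime is fully constrained by data.

    A lifetime at column j feeds measurements at columns j..j + N*y; all
    of them must lie inside the valid region, which confines reliable
    estimates to the centre band [N*y, W - N*y) of the field of view.
    """
    h, wd = fov_shape
    m = cfg.margin
    if wd <= 2 * m and m > 0:
        raise ValueError(f"FOV width {wd} too narrow for a reliable band "
                         f"(needs > {2 * m})")
    mask = np.ones((h, wd), dtype=bool)
    if m > 0:
        mask[:, :m] = False
        mask[:, wd - m:] = False
    return mask
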