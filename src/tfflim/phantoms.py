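"""Synthetic scene and dataset generation.

Scenes are (amplitude, lifetime) seed-map pairs carrying an upstream
margin along the shear axis, so every rendered detector pixel sees its
complete replica chain.  The full-scale recipe pairs 270x220 seeds with
220x220 single-shot images (margin 50 px at N=5, y=10); any FOV/margin
combination consistent with the system geometry is accepted.

Phantom kinds
-------------
``flat``            constant lifetime and amplitude (recovery baselines)
``beads``           anti-aliased, non-overlapping disks in one or more
                    (radius, lifetime, count) populations on a dark
                    background, mirroring the 2/4 micron bead samples
                    (2.1 / 4.0 ns dyes)
``cell_like``       thresholded smoothed Gaussian random field: thin
                    bright wall-like ridges with low-signal interiors,
                    a stand-in for Convallaria-style tissue
``random_texture``  independent smooth random lifetime and amplitude
                    textures (CNN training fodder)
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import DetectorConfig, SystemConfig
from .forward import AmplitudeMap, LifetimeMap, simulate_cmos, simulate_iccd
from .noise import sample_noisy_iccd

__all__ = ["PhantomSpec", "make_phantom", "simulate_triplet",
           "generate_dataset", "split_indices"]

_KINDS = ("beads", "cell_like", "random_texture", "flat")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic scene.

    ``fov`` is the rendered output size (rows, cols); seed maps are
    ``margin`` columns wider.  ``bead_params`` lists populations as
    (radius_px, lifetime_ns, count) with an optional fourth element
    fixing the population's amplitude; otherwise brightness is drawn
    from ``intensity_range``.  Lifetimes are drawn from
    ``lifetime_range`` where the kind does not fix them.
    """

    kind: str = "beads"
    fov: Tuple[int, int] = (220, 220)
    margin: int = 50
    lifetime_range: Tuple[float, float] = (0.1, 8.0)
    intensity_range: Tuple[float, float] = (50.0, 500.0)
    bead_params: Tuple[Tuple[float, float, int], ...] = ((4.0, 2.1, 6), (8.0, 4.0, 6))
    background_amp: float = 0.0
    col_range: Optional[Tuple[int, int]] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        lo, hi = self.lifetime_range
        if not (0 < lo <= hi):
            raise ValueError("lifetime_range must be within (0, inf)")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")

    @property
    def seed_shape(self) -> Tuple[int, int]:
        return (self.fov[0], self.fov[1] + self.margin)

    def check_geometry(self, cfg: SystemConfig) -> None:
        if self.margin < cfg.margin:
            raise ValueError(
                f"phantom margin {self.margin} < shear extent {cfg.margin}")


class PackingError(RuntimeError):
    """Could not place the requested beads without overlap."""


def _disk(shape, center, radius, supersample=4):
    """Anti-aliased disk mask via supersampled coverage."""
    h, w = shape
    cy, cx = center
    r = int(np.ceil(radius)) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 2)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 2)
    ss = supersample
    yy = (np.arange(y0 * ss, y1 * ss) + 0.5) / ss
    xx = (np.arange(x0 * ss, x1 * ss) + 0.5) / ss
    sub = ((yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2) <= radius ** 2
    cover = sub.reshape(y1 - y0, ss, x1 - x0, ss).mean(axis=(1, 3))
    out = np.zeros(shape)
    out[y0:y1, x0:x1] = cover
    return out


def _make_beads(spec: PhantomSpec, rng: np.random.Generator):
    shape = spec.seed_shape
    amp = np.full(shape, spec.background_amp, dtype=float)
    tau = np.full(shape, np.mean(spec.lifetime_range), dtype=float)
    placed: List[Tuple[float, float, float]] = []
    lo_a, hi_a = spec.intensity_range
    for pop in spec.bead_params:
        radius, lifetime, count = pop[:3]
        fixed_amp = pop[3] if len(pop) > 3 else None
        c_lo, c_hi = spec.col_range or (0, shape[1])
        for _ in range(int(count)):
            for _attempt in range(200):
                cy = rng.uniform(radius, shape[0] - radius)
                cx = rng.uniform(c_lo + radius, c_hi - radius)
                if all((cy - py) ** 2 + (cx - px) ** 2 > (radius + pr + 1) ** 2
                       for py, px, pr in placed):
                    break
            else:
                raise PackingError(
                    f"could not place bead of radius {radius} after 200 tries")
            placed.append((cy, cx, radius))
            disk = _disk(shape, (cy, cx), radius)
            brightness = fixed_amp if fixed_amp is not None else rng.uniform(lo_a, hi_a)
            amp += brightness * disk
            # every pixel receiving bead photons decays at the bead's
            # lifetime, including anti-aliased edge pixels
            tau = np.where(disk > 0, lifetime, tau)
    return amp, tau


def _smooth_field(shape, rng, scale=12.0):
    f = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(f, scale, mode="reflect")
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return f


def _make_cell_like(spec: PhantomSpec, rng: np.random.Generator):
    shape = spec.seed_shape
    f = _smooth_field(shape, rng, scale=6.0)
    # ridges: pixels near the median level of the smoothed field
    ridges = np.exp(-((f - np.median(f)) / 0.06) ** 2)
    lo_a, hi_a = spec.intensity_range
    amp = spec.background_amp + (lo_a + (hi_a - lo_a) * ridges) * (ridges > 0.05)
    lo_t, hi_t = spec.lifetime_range
    tau_field = _smooth_field(shape, rng, scale=15.0)
    tau = lo_t + (hi_t - lo_t) * (0.25 + 0.5 * tau_field)
    return amp, tau


def _make_random_texture(spec: PhantomSpec, rng: np.random.Generator):
    shape = spec.seed_shape
    lo_a, hi_a = spec.intensity_range
    lo_t, hi_t = spec.lifetime_range
    amp = lo_a + (hi_a - lo_a) * _smooth_field(shape, rng, scale=8.0)
    # log-uniform-ish lifetimes: smooth field warped onto the range
    t = _smooth_field(shape, rng, scale=10.0)
    tau = np.exp(np.log(lo_t) + (np.log(hi_t) - np.log(lo_t)) * t)
    return amp, tau


def _make_flat(spec: PhantomSpec, rng: np.random.Generator):
    # constant maps; the level is drawn from the configured ranges, so a
    # degenerate range (lo == hi) pins it exactly
    shape = spec.seed_shape
    tau0 = rng.uniform(*spec.lifetime_range)
    amp0 = rng.uniform(*spec.intensity_range)
    return np.full(shape, amp0), np.full(shape, tau0)


_BUILDERS = {
    "beads": _make_beads,
    "cell_like": _make_cell_like,
    "random_texture": _make_random_texture,
    "flat": _make_flat,
}


def make_phantom(spec: PhantomSpec):
    """Generate one (AmplitudeMap, LifetimeMap) seed pair.

    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    amp, tau = _BUILDERS[spec.kind](spec, rng)
    np.clip(tau, *spec.lifetime_range, out=tau)
    np.clip(amp, 0.0, None, out=amp)
    return AmplitudeMap(amp), LifetimeMap(tau)


def simulate_triplet(spec: PhantomSpec, cfg: SystemConfig,
                     det: Optional[DetectorConfig] = None,
                     noise_seed: Optional[int] = None):
    """One (CMOS, iCCD, lifetime-label) training triplet, in memory.

    The iCCD image carries detector noise when ``det`` is given,
    otherwise it is the clean render.  The label is the seed lifetime
    map cropped to the rendered FOV.
    """
    spec.check_geometry(cfg)
    amp, tau = make_phantom(spec)
    iccd = simulate_iccd(tau, amp, cfg)
    if det is not None:
        iccd = sample_noisy_iccd(iccd, det, seed=noise_seed)
    cmos = simulate_cmos(tau, amp, cfg)
    label = tau.tau[:, spec.margin:]
    return cmos.q, iccd.s, label


def split_indices(n: int, fractions: Sequence[float]) -> List[np.ndarray]:
    """Deterministic contiguous train/val/test index split.

    Counts are rounded down per split, remainders assigned left to
    right, e.g. n=8 at (0.75, 0.125, 0.125) gives 6/1/1.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    counts = [int(np.floor(f * n)) for f in fractions]
    i = 0
    while sum(counts) < n:
        counts[i % len(counts)] += 1
        i += 1
    bounds = np.cumsum([0] + counts)
    idx = np.arange(n)
    return [idx[bounds[k]:bounds[k + 1]] for k in range(len(fractions))]


def generate_dataset(n: int, spec: PhantomSpec, cfg: SystemConfig,
                     det: DetectorConfig, out: str,
                     split: Sequence[float] = (0.75, 0.125, 0.125),
                     seed: Optional[int] = None,
                     kinds: Optional[Sequence[str]] = None) -> dict:
    """Write ``n`` simulated triplets and a manifest to directory ``out``.

    Each triplet holds the clean CMOS image, a noisy iCCD image, and the
    lifetime label cropped to the rendered FOV, stored as 32-bit float
    TIFFs (``item_XXXX_cmos/_iccd/_tau.tif``).  The manifest records all
    seeds and configuration so the dataset can be regenerated
    bit-identically.  ``kinds`` optionally cycles phantom kinds across
    items; default is ``spec.kind`` throughout.
    """
    from . import io as tio

    spec.check_geometry(cfg)
    os.makedirs(out, exist_ok=True)
    master = np.random.default_rng(seed)
    item_seeds = master.integers(0, 2 ** 31 - 1, size=(n, 2))
    kinds = list(kinds) if kinds else [spec.kind]
    items = []
    for i in range(n):
        kind = kinds[i % len(kinds)]
        ispec = PhantomSpec(**{**asdict(spec), "kind": kind,
                               "seed": int(item_seeds[i, 0])})
        try:
            amp, tau = make_phantom(ispec)
            clean = simulate_iccd(tau, amp, cfg)
            noisy = sample_noisy_iccd(clean, det, seed=int(item_seeds[i, 1]))
            cmos = simulate_cmos(tau, amp, cfg)
        except Exception as exc:
            raise RuntimeError(f"failed generating item {i}: {exc}") from exc
        label = tau.tau[:, spec.margin:]
        paths = {}
        for name, arr in (("cmos", cmos.q), ("iccd", noisy.s), ("tau", label)):
            p = os.path.join(out, f"item_{i:04d}_{name}.tif")
            tio.write_image(arr, p)
            paths[name] = os.path.basename(p)
        items.append({"index": i, "kind": kind,
                      "phantom_seed": int(item_seeds[i, 0]),
                      "noise_seed": int(item_seeds[i, 1]), "files": paths})
    splits = split_indices(n, split)
    manifest = {
        "n": n,
        "seed": seed,
        "split": {name: idx.tolist() for name, idx in
                  zip(("train", "val", "test"), splits)},
        "phantom_spec": {**asdict(spec), "seed": None},
        "system": {"t_c": cfg.t_c, "y": cfg.y, "tilt": cfg.tilt,
                   "n_replicas": cfg.n_replicas, "t0": cfg.t0,
                   "dt": cfg.dt, "k": cfg.k,
                   "gate": asdict(cfg.gate),
                   "replica_weights": cfg.weights.tolist()},
        "detector": asdict(det),
        "items": items,
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
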