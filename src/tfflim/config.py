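"""Configuration objects shared across the time-folded FLIM stack.

Units are nanoseconds for times, pixels for distances, electrons for
detector noise terms.  The shear axis is the second (column) array axis
throughout the package: cavity replica ``n`` of source column ``j`` lands
on detector column ``j + n*y``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "GateProfile",
    "SystemConfig",
    "DetectorConfig",
    "IRConfig",
    "CNNSpec",
    "TrainConfig",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """A configuration field violates its invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class GateProfile:
    """Temporal transmission profile G(t) of the gated intensifier.

    ``rectangular`` is an ideal top-hat over ``[t_start, t_start + width)``;
    ``smoothed_flat_top`` is the same top-hat convolved with a Gaussian of
    scale ``edge_sigma`` (ns), giving realistic finite rise/fall edges.
    Profile values always lie in [0, 1].
    """

    shape: str = "smoothed_flat_top"
    t_start: float = -0.2
    width: float = 1.5
    edge_sigma: float = 0.1

    def __post_init__(self):
        _require(self.shape in ("rectangular", "smoothed_flat_top"),
                 f"unknown gate shape {self.shape!r}")
        _require(self.width > 0, "gate width must be > 0")
        _require(self.edge_sigma >= 0, "edge_sigma must be >= 0")

    @property
    def t_end(self) -> float:
        return self.t_start + self.width

    def __call__(self, t: np.ndarray) -> np.ndarray:
        from .forward import gate_values

        return gate_values(self, np.asarray(t, dtype=float))


def geometric_replica_weights(ratio_a: float, ratio_b: float, n: int) -> np.ndarray:
    """Power fraction carried by each cavity pass under a lossless splitter.

    The n-th round trip transmits ``ratio_a * ratio_b**n`` of the input
    power: the first pass exits through port *a* directly, every further
    round trip picks up another factor of the return-port fraction.
    """
    _require(n >= 1, "need at least one replica")
    _require(ratio_a >= 0 and ratio_b >= 0, "ratios must be non-negative")
    _require(abs(ratio_a + ratio_b - 1.0) < 1e-9,
             f"splitting ratios must sum to 1, got {ratio_a + ratio_b}")
    return ratio_a * ratio_b ** np.arange(n, dtype=float)


@dataclass(frozen=True)
class SystemConfig:
    """Cavity, shear, gate and time-grid parameters of the imaging system.

    Attributes
    ----------
    t_c : cavity round-trip time (ns); each replica is delayed by n*t_c.
    y : shear per round trip, integer pixels along the column axis.
    tilt : deviation of the actual shear direction from the column axis
        (degrees).  The forward model simulates on the nominal axis and
        rotates the result; calibration estimates and removes tilt.
    n_replicas : number of summed terms including the direct pass
        (6 terms = direct pass + 5 round trips).
    replica_weights : power fraction r_n per pass.  ``None`` selects the
        geometric law from the measured 51.5:48.5 splitting ratio.
    gate : temporal intensifier gate profile.
    t0 : decay start time on the direct pass (ns).
    dt : time-grid step for quadrature (ns).
    t_max : integration horizon (ns); ``None`` = gate end + 6 sigma.
    k : CMOS/iCCD amplitude ratio, so that q = k * A * tau.
    """

    t_c: float = 0.59
    y: int = 10
    tilt: float = 0.0
    n_replicas: int = 6
    replica_weights: Optional[Tuple[float, ...]] = None
    gate: GateProfile = field(default_factory=GateProfile)
    t0: float = 0.0
    dt: float = 0.01
    t_max: Optional[float] = None
    k: float = 1.0

    def __post_init__(self):
        _require(self.t_c > 0, "t_c must be > 0")
        _require(self.dt > 0, "dt must be > 0")
        _require(self.n_replicas >= 1, "n_replicas must be >= 1")
        _require(self.k > 0, "k must be > 0")
        _require(int(self.y) == self.y and self.y >= 0,
                 "shear y must be a non-negative integer")
        if self.replica_weights is not None:
            w = np.asarray(self.replica_weights, dtype=float)
            _require(w.size == self.n_replicas,
                     "replica_weights length must equal n_replicas")
            _require(np.all(w >= 0), "replica weights must be >= 0")
            _require(np.all(np.diff(w) <= 1e-12),
                     "replica weights must be non-increasing")

    @property
    def weights(self) -> np.ndarray:
        """Resolved replica weight vector r_0..r_{N}."""
        if self.replica_weights is not None:
            return np.asarray(self.replica_weights, dtype=float)
        return geometric_replica_weights(0.515, 0.485, self.n_replicas)

    @property
    def margin(self) -> int:
        """Seed margin along the shear axis: (n_replicas - 1) * y pixels."""
        return (self.n_replicas - 1) * int(self.y)

    @property
    def delays(self) -> np.ndarray:
        """Decay start time of each replica: t0 + n * t_c."""
        return self.t0 + self.t_c * np.arange(self.n_replicas, dtype=float)


@dataclass(frozen=True)
class DetectorConfig:
    """Noise budget of the intensified CCD.

    ``dqe`` converts photocathode photons to photoelectrons; the
    microchannel plate multiplies them by ``gain`` with excess-noise
    factor ``noise_factor`` (F >= 1); readout/dark/CIC terms are in
    electrons.  The gate profile modulates the gain in time, so the
    effective gain inside the gate is gain * G(t); the forward model
    hands this module gate-integrated expected photon counts.
    """

    dqe: float = 0.20
    sigma_readout: float = 8.0
    dark_rate: float = 0.03
    sigma_clc: float = 0.0
    noise_factor: float = 1.3
    gain: float = 500.0
    exposure_s: float = 1.0

    def __post_init__(self):
        _require(0 < self.dqe <= 1, "dqe must be in (0, 1]")
        _require(self.sigma_readout >= 0, "sigma_readout must be >= 0")
        _require(self.dark_rate >= 0, "dark_rate must be >= 0")
        _require(self.sigma_clc >= 0, "sigma_clc must be >= 0")
        _require(self.noise_factor >= 1, "noise_factor must be >= 1")
        _require(self.gain > 0, "gain must be > 0")
        _require(self.exposure_s > 0, "exposure_s must be > 0")


@dataclass(frozen=True)
class IRConfig:
    """Settings of the projected-gradient inverse retrieval."""

    alpha: float = 1e-3
    max_iter: int = 500
    rel_tol: float = 1e-6
    tau_floor: float = 0.02
    init: str = "random"
    init_range: Tuple[float, float] = (0.5, 5.0)
    armijo_c: float = 1e-4
    shrink: float = 0.5
    seed: Optional[int] = None
    squared_data_term: bool = False
    low_signal_frac: float = 0.0
    integrator: str = "auto"

    def __post_init__(self):
        _require(self.alpha >= 0, "alpha must be >= 0")
        _require(self.tau_floor > 0, "tau_floor must be > 0")
        _require(0 < self.shrink < 1, "shrink must be in (0, 1)")
        _require(0 < self.armijo_c < 1, "armijo_c must be in (0, 1)")
        _require(self.max_iter >= 1, "max_iter must be >= 1")
        _require(self.init in ("random", "constant", "provided"),
                 f"unknown init mode {self.init!r}")
        _require(0 <= self.low_signal_frac < 1,
                 "low_signal_frac must be in [0, 1)")
        _require(self.integrator in ("auto", "quad", "table"),
                 f"unknown integrator {self.integrator!r}")


@dataclass(frozen=True)
class CNNSpec:
    """Architecture of the physics-inspired dilated CNN.

    Three dilated Conv2D stages with kernels of extent
    ``kernel_shape[0]`` along the shear axis (1 across it) and dilation
    ``dilation`` matched to the replica separation, followed by a dense
    3x3 head.  With the defaults each dilated layer spans
    ``dilation * (kernel_shape[0] - 1) + 1 = 101`` pixels, covering the
    direct pass plus 5 replicas on either side at y = 10.
    """

    feature_widths: Tuple[int, ...] = (256, 64, 16)
    kernel_shape: Tuple[int, int] = (11, 1)
    dilation: int = 10
    head_kernel: Tuple[int, int] = (3, 3)
    padding_policy: str = "hybrid"
    pad_mode: str = "edge"
    seed: int = 0

    def __post_init__(self):
        _require(all(w > 0 for w in self.feature_widths),
                 "feature widths must be positive")
        _require(self.dilation >= 1, "dilation must be >= 1")
        _require(self.kernel_shape[0] >= 1 and self.kernel_shape[1] >= 1,
                 "kernel extents must be >= 1")
        _require(self.padding_policy in ("hybrid", "same", "valid"),
                 f"unknown padding policy {self.padding_policy!r}")
        _require(self.pad_mode in ("edge", "zero"),
                 f"unknown pad mode {self.pad_mode!r}")

    @property
    def receptive_span(self) -> int:
        """Pixels spanned along the shear axis by one dilated layer."""
        return self.dilation * (self.kernel_shape[0] - 1) + 1

    def check_geometry(self, cfg: SystemConfig) -> None:
        """Require the dilated span to cover the full replica chain."""
        span = self.dilation * (self.kernel_shape[0] - 1)
        need = 2 * (cfg.n_replicas - 1) * cfg.y
        _require(span >= need,
                 f"dilated span {span} px cannot cover the replica chain "
                 f"(+/-{need // 2} px); increase kernel extent or dilation")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for CNN training (Adam + exponential LR decay)."""

    epochs: int = 20
    batch_size: int = 8
    lr_initial: float = 2e-3
    lr_decay: float = 0.92
    split: Tuple[float, float, float] = (0.75, 0.125, 0.125)
    avg_epochs: int = 0
    seed: int = 0

    def __post_init__(self):
        _require(self.epochs >= 0, "epochs must be >= 0")
        _require(self.batch_size >= 1, "batch_size must be >= 1")
        _require(self.lr_initial >= 0, "lr_initial must be >= 0")
        _require(0 < self.lr_decay <= 1, "lr_decay must be in (0, 1]")
        _require(abs(sum(self.split) - 1.0) < 1e-9,
                 "split fractions must sum to 1")
        _require(self.avg_epochs >= 0, "avg_epochs must be >= 0")


_SECTIONS = {
    "system": SystemConfig,
    "gate": GateProfile,
    "detector": DetectorConfig,
    "ir": IRConfig,
    "cnn": CNNSpec,
    "train": TrainConfig,
}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    return cls(**coerced)


def load_config(path) -> dict:
    """Load a YAML configuration file into validated config objects.

    The file holds optional top-level sections ``system``, ``gate``,
    ``detector``, ``ir``, ``cnn``, ``train``; missing sections (and
    missing keys) take package defaults, unknown keys are rejected.
    Returns a dict mapping section name -> config object, with the gate
    folded into the returned ``system`` config.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")
    out = {}
    gate = _build(GateProfile, raw.get("gate", {}) or {})
    sysdata = dict(raw.get("system", {}) or {})
    sysdata["gate"] = gate
    out["system"] = _build(SystemConfig, sysdata)
    out["gate"] = gate
    for name in ("detector", "ir", "cnn", "train"):
        out[name] = _build(_SECTIONS[name], raw.get(name, {}) or {})
    return out


def save_config(configs: dict, path) -> None:
    """Write config objects back to YAML (inverse of :func:`load_config`)."""
    raw = {}
    for name, obj in configs.items():
        if name not in _SECTIONS:
            raise ConfigError(f"unknown configuration section {name!r}")
        d = dataclasses.asdict(obj)
        if name == "system":
            d.pop("gate", None)
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
            elif isinstance(v, np.ndarray):
                d[k] = v.tolist()
        raw[name] = d
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
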