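"""Bayesian lower bound on the lifetime-estimation uncertainty.

A pixel's decay of true lifetime tau is observed through the cavity as
``n_replicas`` gate-integrated signals s_n(tau).  Given a total photon
budget B incident on the intensifier photocathode (summed over all
replicas of the full decay), the per-replica expectations are

    s_n(tau) = B * r_n * I_n(tau) / (tau * sum_m r_m),

where I_n is the unit-amplitude gate integral of the n-delayed decay.
Each replica measurement is modelled as Gaussian around s_n with the
detector noise SD, the replica likelihoods multiply (independent
measurements of the same underlying lifetime), and a uniform prior on
[0.02, 20] ns closes Bayes' rule.  Evaluating the posterior at the
*expected* observation (the noise-free signal) yields a lower bound on
the relative estimation uncertainty sd/tau — thermal and CMOS-side
noise would only raise it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DetectorConfig, SystemConfig
from .forward import decay_gate_integral
from .noise import photon_noise_sigma

__all__ = [
    "LifetimePrior",
    "PosteriorCurve",
    "UncertaintyCurve",
    "expected_replica_signals",
    "replica_likelihood",
    "posterior",
    "uncertainty_curve",
]


def _default_grid():
    return np.geomspace(0.02, 20.0, 2000)


@dataclass(frozen=True)
class LifetimePrior:
    """Discretized prior p(tau) on a strictly increasing lifetime grid.

    Uniform (in tau) by default over [0.02, 20] ns; ``weights`` are
    per-node prior masses summing to 1.
    """

    tau_grid: np.ndarray = field(default_factory=_default_grid)
    weights: np.ndarray | None = None

    def __post_init__(self):
        g = np.asarray(self.tau_grid, dtype=float)
        if g.ndim != 1 or g.size < 2 or np.any(np.diff(g) <= 0):
            raise ValueError("tau_grid must be 1-D and strictly increasing")
        object.__setattr__(self, "tau_grid", g)
        if self.weights is None:
            w = np.full(g.size, 1.0 / g.size)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != g.shape or np.any(w < 0):
                raise ValueError("weights must be non-negative, one per node")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("prior weights must sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def density(self) -> np.ndarray:
        """Prior as a density on the grid, normalized by trapezoid rule."""
        d = self.weights.copy()
        z = np.trapezoid(d, self.tau_grid)
        return d / z


@dataclass(frozen=True)
class PosteriorCurve:
    """p(tau | observation) on a lifetime grid with summary statistics."""

    tau_grid: np.ndarray
    density: np.ndarray
    mean: float
    sd: float
    degenerate: bool = False

    def __post_init__(self):
        if np.any(np.asarray(self.density) < 0):
            raise ValueError("posterior density must be >= 0")

    @property
    def norm(self) -> float:
        return float(np.trapezoid(self.density, self.tau_grid))


@dataclass(frozen=True)
class UncertaintyCurve:
    """Relative lifetime-uncertainty lower bound sd/tau versus true tau."""

    tau_grid: np.ndarray
    rel_sd: np.ndarray
    photon_budget: float


def expected_replica_signals(tau, budget: float, cfg: SystemConfig) -> np.ndarray:
    """Expected gated photocathode photons per replica for one pixel.

    Scales the decay amplitude so ``budget`` equals the *total* photons
    incident on the intensifier from all replicas of the full (ungated)
    decay: A = B / (tau * sum_n r_n).

    Returns shape ``(n_replicas,) + tau.shape``.
    """
    tau = np.asarray(tau, dtype=float)
    if budget <= 0:
        raise ValueError("photon budget must be > 0")
    w = cfg.weights
    amp = budget / (tau * w.sum())
    out = np.empty((cfg.n_replicas,) + tau.shape)
    for n, delay in enumerate(cfg.delays):
        out[n] = w[n] * amp * decay_gate_integral(tau, delay, cfg)
    return out


def _incident_budget(budget: float, det: DetectorConfig,
                     budget_includes_dqe: bool) -> float:
    """Convert a quoted photon budget to photocathode photons.

    The quoted budgets behave as *detected* (photoelectron-equivalent)
    counts: the quantum efficiency is applied upstream of the number, so
    by default the incident photon flux is budget / DQE.  Set
    ``budget_includes_dqe=False`` to treat the budget as raw incident
    photons instead (DQE then thins them before detection).
    """
    return budget / det.dqe if budget_includes_dqe else budget


def replica_likelihood(s_obs, tau, budget: float, cfg: SystemConfig,
                       det: DetectorConfig, replica: int = 0,
                       budget_includes_dqe: bool = True):
    """Gaussian density p(S_replica = s_obs | tau) in photon units.

    Mean from the forward model, SD from the detector noise budget
    (converted to photon-equivalent units so observation and mean share
    a scale).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    b = _incident_budget(budget, det, budget_includes_dqe)
    sig = expected_replica_signals(tau, b, cfg)[replica]
    sd = photon_noise_sigma(sig, det)
    z = (np.asarray(s_obs, dtype=float) - sig) / sd
    return np.exp(-0.5 * z * z) / (np.sqrt(2 * np.pi) * sd)


def _log_likelihood(s_obs_vec, tau_grid, budget, cfg, det):
    """Summed replica log-likelihood on a lifetime grid."""
    sig = expected_replica_signals(tau_grid, budget, cfg)
    sd = photon_noise_sigma(sig, det)
    obs = np.asarray(s_obs_vec, dtype=float)[:, None]
    z = (obs - sig) / sd
    return np.sum(-0.5 * z * z - np.log(sd), axis=0)


def posterior(s_obs_vector, prior: LifetimePrior, budget: float,
              cfg: SystemConfig, det: DetectorConfig,
              budget_includes_dqe: bool = True) -> PosteriorCurve:
    """Posterior p(tau | s_hat) from one observation per replica.

    The replica likelihoods multiply; the prior weights the product; the
    result is normalized by trapezoidal quadrature on the prior grid.
    """
    s_obs = np.asarray(s_obs_vector, dtype=float)
    if s_obs.shape != (cfg.n_replicas,):
        raise ValueError(
            f"need one observation per replica ({cfg.n_replicas})")
    g = prior.tau_grid
    b = _incident_budget(budget, det, budget_includes_dqe)
    logl = _log_likelihood(s_obs, g, b, cfg, det)
    logp = logl + np.log(np.maximum(prior.density, 1e-300))
    m = logp.max()
    degenerate = not np.isfinite(m)
    un = np.exp(logp - (m if np.isfinite(m) else 0.0))
    z = np.trapezoid(un, g)
    if z <= 0 or not np.isfinite(z):
        degenerate = True
        dens = np.full_like(g, np.nan)
        mean = sd = float("nan")
    else:
        dens = un / z
        mean = float(np.trapezoid(dens * g, g))
        var = float(np.trapezoid(dens * (g - mean) ** 2, g))
        sd = float(np.sqrt(max(var, 0.0)))
    return PosteriorCurve(g, dens, mean, sd, degenerate=degenerate)


def uncertainty_curve(budget: float, prior: LifetimePrior,
                      cfg: SystemConfig, det: DetectorConfig,
                      tau_eval,
                      budget_includes_dqe: bool = True) -> UncertaintyCurve:
    """Lower-bound relative uncertainty sd/tau over a grid of true lifetimes.

    For each true tau the observation is set to its own expectation (the
    noise-free forward signal) and the posterior SD is reported relative
    to tau.
    """
    tau_eval = np.asarray(tau_eval, dtype=float)
    g = prior.tau_grid
    b = _incident_budget(budget, det, budget_includes_dqe)
    sig_grid = expected_replica_signals(g, b, cfg)
    sd_grid = photon_noise_sigma(sig_grid, det)
    sig_true = expected_replica_signals(tau_eval, b, cfg)
    log_prior = np.log(np.maximum(prior.density, 1e-300))
    rel = np.empty(tau_eval.shape)
    for i, t in enumerate(tau_eval):
        obs = sig_true[:, i][:, None]
        z = (obs - sig_grid) / sd_grid
        logp = np.sum(-0.5 * z * z - np.log(sd_grid), axis=0) + log_prior
        un = np.exp(logp - logp.max())
        zn = np.trapezoid(un, g)
        dens = un / zn
        mean = np.trapezoid(dens * g, g)
        var = np.trapezoid(dens * (g - mean) ** 2, g)
        rel[i] = np.sqrt(max(var, 0.0)) / t
    return UncertaintyCurve(tau_eval, rel, budget)
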