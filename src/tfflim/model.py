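"""Model/Results interface to lifetime reconstruction.

`TimeFoldedLifetimeModel` bundles one (CMOS, iCCD) measurement pair with
the system configuration, in the spirit of statsmodels model classes:
construct from arrays or TIFF files, call :meth:`fit` to estimate the
per-pixel lifetime map (inverse retrieval by default, or a trained CNN),
and receive a :class:`LifetimeResults` object carrying the estimates,
their validity mask, convergence diagnostics, posterior-based
uncertainty bounds and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .calibration import estimate_shear, rectify
from .config import DetectorConfig, IRConfig, SystemConfig
from .forward import _field, valid_region
from .inversion import IRResult, retrieve
from .uncertainty import LifetimePrior, uncertainty_curve

__all__ = ["TimeFoldedLifetimeModel", "LifetimeResults"]


class TimeFoldedLifetimeModel:
    """A lifetime-map estimation problem for one measurement pair.

    Parameters
    ----------
    cmos, iccd : 2-D arrays (or CMOSImage / ICCDImage)
        Time-integrated intensity and single-shot sheared gated image,
        aligned and equally shaped.
    config : SystemConfig
        Cavity/gate/shear description used by the forward model.
    detector : DetectorConfig, optional
        Needed only for uncertainty reporting.
    """

    def __init__(self, cmos, iccd, config: SystemConfig,
                 detector: Optional[DetectorConfig] = None):
        self.q = _field(cmos, "q")
        self.s = _field(iccd, "s")
        if self.q.shape != self.s.shape:
            raise ValueError("CMOS and iCCD images must share one shape")
        self.config = config
        self.detector = detector or DetectorConfig()

    @classmethod
    def from_tiff(cls, cmos_path, iccd_path, config: SystemConfig,
                  detector: Optional[DetectorConfig] = None):
        from . import io as tio
        return cls(tio.read_image(cmos_path), tio.read_image(iccd_path),
                   config, detector)

    def calibrate(self, apply: bool = True):
        """Estimate (separation, tilt) from the iCCD image's FFT.

        With ``apply=True`` the iCCD image is rectified in place and the
        estimate returned; the configured shear ``y`` is not changed.
        """
        sep, tilt = estimate_shear(self.s)
        if apply and tilt != 0.0:
            self.s = rectify(self.s, tilt).s
        return sep, tilt

    def fit(self, method: str = "ir", ir_config: Optional[IRConfig] = None,
            cnn_model=None, tau_init=None) -> "LifetimeResults":
        """Estimate the lifetime map.

        ``method="ir"`` runs regularized inverse retrieval;
        ``method="cnn"`` applies a trained :class:`~tfflim.cnn.DilatedCNN`
        (pass it as ``cnn_model``).
        """
        if method == "ir":
            ir = ir_config or IRConfig()
            res = retrieve(self.q, self.s, self.config, ir, tau_init=tau_init)
            return LifetimeResults(self, res.tau, res.mask, method="ir",
                                   ir_result=res)
        if method == "cnn":
            if cnn_model is None:
                raise ValueError("method='cnn' requires cnn_model")
            from .cnn import predict
            tau, off = predict(self.q, self.s, cnn_model)
            mask = valid_region(self.config, self.q.shape)[
                :tau.shape[0], off:off + tau.shape[1]]
            return LifetimeResults(self, tau, mask, method="cnn",
                                   col_offset=off)
        raise ValueError(f"unknown method {method!r}")


@dataclass
class LifetimeResults:
    """Fitted lifetime map plus diagnostics."""

    model: TimeFoldedLifetimeModel
    tau: np.ndarray
    mask: np.ndarray
    method: str
    ir_result: Optional[IRResult] = None
    col_offset: int = 0

    @property
    def tau_valid(self) -> np.ndarray:
        return self.tau[self.mask]

    def lifetime_bound(self, budget: float, tau_eval=None):
        """Posterior lower bound sd/tau at the model's configuration."""
        if tau_eval is None:
            tau_eval = np.geomspace(0.1, 10.0, 40)
        return uncertainty_curve(budget, LifetimePrior(), self.model.config,
                                 self.model.detector, tau_eval)

    def summary(self) -> str:
        v = self.tau_valid
        cfg = self.model.config
        lines = [
            "Time-folded FLIM lifetime reconstruction",
            "=" * 44,
            f"method:            {self.method}",
            f"image shape:       {self.tau.shape[0]} x {self.tau.shape[1]}",
            f"valid pixels:      {int(self.mask.sum())} "
            f"({100 * self.mask.mean():.1f}%)",
            f"shear y:           {cfg.y} px, t_c = {cfg.t_c} ns, "
            f"N+1 = {cfg.n_replicas} replicas",
            f"gate:              [{cfg.gate.t_start:.2f}, "
            f"{cfg.gate.t_end:.2f}] ns ({cfg.gate.shape})",
            f"tau median:        {np.median(v):.3f} ns",
            f"tau IQR:           [{np.percentile(v, 25):.3f}, "
            f"{np.percentile(v, 75):.3f}] ns",
            f"tau range:         [{v.min():.3f}, {v.max():.3f}] ns",
        ]
        if self.ir_result is not None:
            r = self.ir_result
            lines += [
                f"iterations:        {r.n_iter} "
                f"({'converged' if r.converged else 'iteration cap'})",
                f"final cost:        {r.cost_trace[-1]:.6g}",
            ]
        return "\n".join(lines)
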