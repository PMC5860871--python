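"""Canonical two-gamma hemodynamic response function.

The HRF links a train of neural events to the BOLD signal.  It is modeled
as a difference of two gamma densities: a positive peak (~5 s) and a
delayed undershoot (~15 s), the conventional "standard two-gamma" shape.
The kernel is normalized so that its maximum is 1; GLM amplitudes (betas)
therefore carry the units of the signal itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["HRFParams", "TwoGammaHRF"]


@dataclass(frozen=True)
class HRFParams:
    """Parameters of the two-gamma HRF.

    peak_shape / peak_rate
        Gamma shape and rate of the positive response lobe.  With the
        defaults (6, 1 /s) the density peaks at (shape-1)/rate = 5 s.
    undershoot_shape / undershoot_rate
        Gamma shape and rate of the undershoot lobe (defaults 16, 1 /s,
        peaking at 15 s).
    undershoot_ratio
        Amplitude of the undershoot relative to the peak (default 1/6).
    length_s
        Kernel support in seconds (response assumed zero afterwards).
    dt_s
        Sampling step used when a discretized kernel is requested.
    """

    peak_shape: float = 6.0
    peak_rate: float = 1.0
    undershoot_shape: float = 16.0
    undershoot_rate: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length_s: float = 32.0
    dt_s: float = 0.1

    def __post_init__(self) -> None:
        if self.peak_shape <= 0 or self.peak_rate <= 0:
            raise ValueError("peak gamma shape and rate must be positive")
        if self.undershoot_shape <= 0 or self.undershoot_rate <= 0:
            raise ValueError("undershoot gamma shape and rate must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be >= 0")
        if self.length_s <= 0 or self.dt_s <= 0:
            raise ValueError("length_s and dt_s must be positive")


class TwoGammaHRF:
    """Callable HRF h(t), max-normalized to 1 over [0, length_s].

    The normalization constant is found once on a dense (1 ms) grid so
    that analytic evaluation at arbitrary lags and the sampled kernel
    share exactly the same scale.
    """

    def __init__(self, params: HRFParams | None = None):
        self.params = params or HRFParams()
        p = self.params
        # scipy gamma uses scale = 1/rate
        dense_t = np.arange(0.0, p.length_s + 1e-9, 1e-3)
        raw = self._raw(dense_t)
        peak = raw.max()
        if peak <= 0:
            raise ValueError("HRF has non-positive peak; check parameters")
        self._norm = peak
        self.peak_time_s = float(dense_t[int(np.argmax(raw))])

    def _raw(self, t: np.ndarray) -> np.ndarray:
        p = self.params
        pos = sps.gamma.pdf(t, a=p.peak_shape, scale=1.0 / p.peak_rate)
        neg = sps.gamma.pdf(t, a=p.undershoot_shape, scale=1.0 / p.undershoot_rate)
        return pos - p.undershoot_ratio * neg

    def __call__(self, t) -> np.ndarray:
        """Evaluate the normalized HRF at times ``t`` (seconds).

        Zero outside [0, length_s].
        """
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        inside = (t >= 0) & (t <= self.params.length_s)
        out[inside] = self._raw(t[inside]) / self._norm
        return out

    def sample(self, dt_s: float | None = None) -> np.ndarray:
        """Kernel sampled on [0, length_s] at ``dt_s`` (default from params)."""
        dt = self.params.dt_s if dt_s is None else dt_s
        t = np.arange(0.0, self.params.length_s + dt / 2, dt)
        return self(t)
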