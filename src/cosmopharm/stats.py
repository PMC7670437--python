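"""Model-vs-experiment error statistics.

AAD% and RMSE are the usual per-system deviation measures; MSE/NRMSE/NMSE
follow the goodness-of-fit conventions in which 1 is a perfect fit and
values can go negative (NRMSE = 1 − ‖e‖/‖Ω_exp − mean‖,
NMSE = 1 − ‖e‖²/‖Ω_exp − mean‖², e = Ω_exp − Ω_cal), the only conventions
consistent with negative reported NMSE values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = ["PairedSeries", "FitMetrics", "aad_percent", "rmse", "fit_metrics"]


@dataclass
class PairedSeries:
    """Calculated and experimental values of one property, paired by index."""

    calculated: np.ndarray
    experimental: np.ndarray

    def __post_init__(self):
        self.calculated = np.asarray(self.calculated, dtype=float)
        self.experimental = np.asarray(self.experimental, dtype=float)
        if self.calculated.shape != self.experimental.shape:
            raise ValueError("calculated and experimental lengths differ")
        if self.calculated.ndim != 1 or self.calculated.size < 1:
            raise ValueError("need at least one paired value")

    @property
    def n(self) -> int:
        return self.calculated.size


class FitMetrics(NamedTuple):
    mse: float
    nrmse: float
    nmse: float


def aad_percent(s: PairedSeries) -> float:
    """Mean absolute relative deviation x 100 (scale-invariant)."""
    zeros = np.nonzero(s.experimental == 0.0)[0]
    if zeros.size:
        raise ValueError(
            f"experimental value is zero at index {zeros[0]}; AAD% undefined"
        )
    return float(
        np.mean(np.abs((s.calculated - s.experimental) / s.experimental)) * 100.0
    )


def rmse(s: PairedSeries) -> float:
    """Root mean squared deviation, in the units of the property."""
    e = s.calculated - s.experimental
    return float(np.sqrt(np.mean(e**2)))


def fit_metrics(s: PairedSeries) -> FitMetrics:
    """(MSE, NRMSE, NMSE) goodness-of-fit measures.

    The normalized measures reference the experimental series' spread about
    its mean and therefore require n ≥ 2 and a non-constant experimental
    series.  NMSE = 1 − (1 − NRMSE)² holds identically.
    """
    if s.n < 2:
        raise ValueError("normalized fit measures need at least 2 points")
    e = s.experimental - s.calculated
    ref = s.experimental - s.experimental.mean()
    ref_norm2 = float(ref @ ref)
    if ref_norm2 == 0.0:
        raise ValueError(
            "experimental series is constant; NRMSE/NMSE are undefined"
        )
    mse = float(np.mean(e**2))
    ratio2 = float(e @ e) / ref_norm2
    return FitMetrics(
        mse=mse,
        nrmse=float(1.0 - np.sqrt(ratio2)),
        nmse=float(1.0 - ratio2),
    )
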