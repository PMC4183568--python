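"""Empirical TRF-drift calibration for the AM1/NS31 TRFLP assay.

Dye-labelled fragments migrate slightly faster than the unlabelled size
standard in capillary electrophoresis, so observed TRF sizes consistently
under-read their in silico predictions ("TRF drift"). The pairs below are
the published predicted/observed sizes for the six reference AM-fungal
genotypes of this assay (HEX/AluI and FAM/HinfI channels); peaks identified
as under-digestion products carry no deviation and are excluded. A linear
drift model fitted to these pairs supplies the default bias parameters of
the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DRIFT_CALIBRATION_PAIRS",
    "OBSERVED_DEVIATION_RANGE",
    "DriftFit",
    "fit_drift",
]

#: (predicted complete TRF bp, observed peak bp) for the reference genotypes.
#: A split TRF contributes one pair per observed sub-peak.
DRIFT_CALIBRATION_PAIRS: tuple[tuple[float, float], ...] = (
    # HEX / AluI channel
    (162.0, 157.7),
    (309.0, 302.0), (309.0, 303.8), (309.0, 305.1),
    (416.0, 406.7), (416.0, 411.7),
    (449.0, 436.0), (449.0, 442.3), (449.0, 443.5),
    (469.0, 455.6), (469.0, 459.5), (469.0, 463.7),
    (504.0, 497.0), (504.0, 498.3), (504.0, 499.2),
    # FAM / HinfI channel
    (141.5, 137.6),
    (160.5, 154.4),
    (190.5, 188.2),
    (299.5, 297.4),
    (524.5, 523.6),
    (547.0, 548.1),
)

#: Range of (observed − predicted) deviations across the calibration pairs.
OBSERVED_DEVIATION_RANGE: tuple[float, float] = (-13.4, 1.1)


@dataclass(frozen=True)
class DriftFit:
    """Least-squares linear drift: observed = predicted + intercept +
    slope·predicted, with residual standard deviation in bp."""

    intercept: float
    slope: float
    residual_sd: float
    n: int

    def apply(self, predicted_bp):
        return predicted_bp + self.intercept + self.slope * np.asarray(predicted_bp)


def fit_drift(
    pairs: tuple[tuple[float, float], ...] = DRIFT_CALIBRATION_PAIRS,
) -> DriftFit:
    """Fit the linear drift model to (predicted, observed) size pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 calibration pairs")
    pred, obs = arr[:, 0], arr[:, 1]
    A = np.column_stack([np.ones_like(pred), pred])
    coef, *_ = np.linalg.lstsq(A, obs - pred, rcond=None)
    resid = (obs - pred) - A @ coef
    return DriftFit(
        intercept=float(coef[0]),
        slope=float(coef[1]),
        residual_sd=float(resid.std(ddof=2)),
        n=arr.shape[0],
    )


DEFAULT_DRIFT_FIT = fit_drift()
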