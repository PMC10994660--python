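"""GO-ATeam2 FRET -> ATP calibration.

The GO-ATeam2 biosensor reports cytosolic ATP through the ratio of FRET
(mKO acceptor) to EGFP donor fluorescence.  Fractional occupancy of the
sensor follows a Hill curve in free ATP,

    theta = [L]**n / (K_A**n + [L]**n),

and the measured FRET/EGFP ratio is theta plus a fixed instrument offset
(1.46 for this sensor/cytometer combination).  Parameters are estimated by
ordinary least squares on the log-linearized Hill form,

    log(theta / (1 - theta)) = n*log[L] - n*log(K_A).

Natural logarithms are used throughout; the fitted Hill coefficient is
base-invariant and the intercept is interpreted accordingly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: FRET-ratio offset of the sensor, treated as an instrument constant.
RATIO_OFFSET = 1.46

#: Occupancy clip bounds used in "clip" conversion mode.
THETA_CLIP = (1e-6, 1.0 - 1e-6)


class InvalidEventError(ValueError):
    """EGFP intensity was zero or negative; the ratio is undefined."""


class UndefinedConcentrationError(ValueError):
    """Occupancy outside (0, 1) has no finite ATP concentration."""


class InsufficientDataError(ValueError):
    """Too few usable titration points for the Hill regression."""


@dataclass
class HillCalibration:
    """Sensor calibration parameters.

    Parameters
    ----------
    n : float
        Hill coefficient (dimensionless, > 0).
    K_A : float
        ATP concentration at half saturation, in mM.
    offset : float
        FRET-ratio offset; fixed instrument constant unless overridden.
    fit_diagnostics : dict
        ``r_squared``, ``points_used``, ``points_excluded`` when the
        calibration came from :func:`fit_hill`; empty otherwise.
    """

    n: float
    K_A: float
    offset: float = RATIO_OFFSET
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.n > 0 and np.isfinite(self.n)):
            raise ValueError(f"Hill coefficient must be positive, got {self.n}")
        if not (self.K_A > 0 and np.isfinite(self.K_A)):
            raise ValueError(f"K_A must be positive, got {self.K_A}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HillCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


#: The calibration reported for the GO-ATeam2 sensor used throughout the
#: analyses (Hill coefficient, half-saturation in mM).
REPORTED_CALIBRATION = HillCalibration(n=3.1234, K_A=0.84699)


def fret_value(fret_fluor, egfp_fluor):
    """FRET value: ratio of FRET to EGFP fluorescence intensities."""
    fret_fluor = np.asarray(fret_fluor, dtype=float)
    egfp_fluor = np.asarray(egfp_fluor, dtype=float)
    if np.any(egfp_fluor <= 0):
        raise InvalidEventError("EGFP intensity must be positive")
    out = fret_fluor / egfp_fluor
    return float(out) if out.ndim == 0 else out


def ratio_to_theta(ratio, offset: float = RATIO_OFFSET):
    """Convert a FRET ratio to sensor occupancy theta = ratio - offset.

    Values outside the open interval (0, 1) are returned as-is; use
    ``flag_out_of_range`` to identify them.  Noisy single events routinely
    exceed the sensor's dynamic range, so this is not an error.
    """
    theta = np.asarray(ratio, dtype=float) - offset
    return float(theta) if theta.ndim == 0 else theta


def flag_out_of_range(theta) -> np.ndarray:
    """Boolean mask of occupancies at or beyond the sensor's dynamic range."""
    th = np.asarray(theta, dtype=float)
    return (th <= 0.0) | (th >= 1.0)


def theta_to_atp(theta, calib: HillCalibration, mode: str = "strict"):
    """Invert the Hill curve: [L] = K_A * (theta/(1-theta))**(1/n).

    ``mode="strict"`` raises on occupancies outside (0, 1); ``mode="clip"``
    clips them to ``THETA_CLIP`` first (for noisy per-event data).
    """
    th = np.asarray(theta, dtype=float)
    if mode == "clip":
        th = np.clip(th, *THETA_CLIP)
    elif np.any((th <= 0.0) | (th >= 1.0)):
        raise UndefinedConcentrationError(
            "occupancy outside (0, 1); use mode='clip' for flagged events"
        )
    atp = calib.K_A * (th / (1.0 - th)) ** (1.0 / calib.n)
    return float(atp) if atp.ndim == 0 else atp


def atp_to_theta(atp, calib: HillCalibration):
    """Hill occupancy theta = [L]^n / (K_A^n + [L]^n) for ATP in mM."""
    L = np.asarray(atp, dtype=float)
    if np.any(L < 0):
        raise ValueError("ATP concentration must be non-negative")
    Ln = L**calib.n
    theta = Ln / (calib.K_A**calib.n + Ln)
    return float(theta) if theta.ndim == 0 else theta


def atp_to_ratio(atp, calib: HillCalibration):
    """Forward sensor model: FRET ratio = offset + theta(ATP)."""
    return calib.offset + atp_to_theta(atp, calib)


def fit_hill(
    titration: pd.DataFrame,
    offset: float = RATIO_OFFSET,
    atp_col: str = "atp_mM",
    ratio_col: str = "fret_ratio",
) -> HillCalibration:
    """Fit the Hill calibration to a titration by log-linear regression.

    Points whose offset-subtracted occupancy falls outside (0, 1) cannot be
    log-transformed; they are excluded and counted in the diagnostics.  At
    least three usable points are required.
    """
    atp = np.asarray(titration[atp_col], dtype=float)
    ratio = np.asarray(titration[ratio_col], dtype=float)
    if np.any(atp <= 0):
        raise ValueError("titration ATP concentrations must be positive")

    theta = ratio - offset
    usable = (theta > 0.0) & (theta < 1.0)
    n_excluded = int((~usable).sum())
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"need >=3 titration points with occupancy in (0,1), have {int(usable.sum())}"
        )

    y = np.log(theta[usable] / (1.0 - theta[usable]))
    x = np.log(atp[usable])
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    if slope <= 0:
        raise ValueError("fitted Hill coefficient is non-positive; titration is not sigmoid in ATP")
    return HillCalibration(
        n=float(slope),
        K_A=float(math.exp(-intercept / slope)),
        offset=offset,
        fit_diagnostics={
            "r_squared": float(res.rsquared),
            "points_used": int(usable.sum()),
            "points_excluded": n_excluded,
        },
    )
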