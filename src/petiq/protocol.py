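"""Activity-administration protocols and the constant-SNR power law.

The chain: liver SNRs measured under the weight-linear protocol are
normalised by the square root of the time-activity product,

    SNR_Norm = SNR_L / sqrt(A_inj * t),            (A in MBq, t in min)

fitted against a body-size parameter p with a power function

    SNR_Fit = a * p^(-d),

and inverted into a prescription that targets a constant liver SNR:

    A_inj = (1/t) * (SNR_Const^2 / a^2) * p^(2d).

The MBq/minute unit convention is the one consistent with the published
prescription tables.  Three protocol kinds are supported: a fixed activity
(default 100 MBq), weight-linear scaling (default 2 MBq/kg), and the
power-law prescription (default SNR_Const = 15, t = 3 min).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .phantom import BodyMetrics

BODY_PARAMETERS = ("bmi", "weight", "bsa", "circumference")


@dataclass
class PowerLawFit:
    """SNR_Fit(p) = a * p^(-d) with its coefficient of determination."""

    body_parameter: str
    a: float
    d: float
    r_squared: float
    log_space: bool = False
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("power-law amplitude a must be positive")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")

    def predict(self, p) -> np.ndarray:
        return self.a * np.asarray(p, dtype=float) ** (-self.d)

    def to_dict(self) -> dict:
        return {
            "body_parameter": self.body_parameter,
            "a": self.a,
            "d": self.d,
            "r_squared": self.r_squared,
            "log_space": self.log_space,
            "n_points": self.n_points,
        }


@dataclass
class ProtocolSpec:
    """One activity-administration protocol.

    kind = "fixed" (A0 MBq), "linear_per_kg" (rate MBq/kg) or "power_law"
    (fit + SNR_Const target + acquisition time per bed).
    """

    kind: str
    fixed_mbq: float = 100.0
    rate_mbq_per_kg: float = 2.0
    fit: PowerLawFit | None = None
    snr_const: float = 15.0
    t_min: float = 3.0
    label: str = ""

    _KINDS = ("fixed", "linear_per_kg", "power_law")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if not self.label:
            self.label = {"fixed": "i", "linear_per_kg": "ii", "power_law": "iii"}[self.kind]


def normalize_snr(snr_l: float, a_inj_mbq: float, t_min: float) -> float:
    """SNR_Norm = SNR_L / sqrt(A_inj * t), A in MBq, t in minutes."""
    if a_inj_mbq <= 0 or t_min <= 0:
        raise ValueError("activity and acquisition time must be positive")
    return float(snr_l) / float(np.sqrt(a_inj_mbq * t_min))


def fit_power_law(
    p_values,
    snr_norm,
    body_parameter: str = "weight",
    log_space: bool = False,
) -> PowerLawFit:
    """Least-squares fit of a * p^(-d).

    Default: nonlinear least squares on the linear scale, initialised from
    the ordinary log-log regression; ``log_space=True`` returns the log-log
    regression itself (diagnostic).  R^2 = 1 - SS_res/SS_tot on the linear
    scale.  A zero-variance response yields d = 0 with R^2 reported as 0.
    """
    p = np.asarray(p_values, dtype=float)
    y = np.asarray(snr_norm, dtype=float)
    if p.size < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.any(p <= 0) or np.any(y <= 0):
        raise ValueError("p and SNR_Norm must be strictly positive")

    if np.ptp(y) == 0:
        return PowerLawFit(body_parameter, float(y[0]), 0.0, 0.0, log_space, p.size)

    # log-log OLS start values
    slope, intercept = np.polyfit(np.log(p), np.log(y), 1)
    a0, d0 = float(np.exp(intercept)), float(-slope)
    if log_space:
        a, d = a0, d0
    else:
        try:
            (a, d), _ = curve_fit(
                lambda pp, aa, dd: aa * pp ** (-dd), p, y, p0=[a0, d0], maxfev=10000
            )
        except RuntimeError as err:
            raise RuntimeError(
                f"power-law fit did not converge (start a={a0:.4g}, d={d0:.4g}): {err}"
            ) from err
    resid = y - a * p ** (-d)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return PowerLawFit(body_parameter, float(a), float(d), float(r2), log_space, p.size)


def select_body_parameter(fits: list[PowerLawFit]) -> PowerLawFit:
    """The fit with maximal R^2; exact ties prefer weight (clinical simplicity)."""
    if len(fits) < 2:
        if not fits:
            raise ValueError("no fits supplied")
        return fits[0]
    return max(fits, key=lambda f: (f.r_squared, f.body_parameter == "weight"))


def prescribe_activity(protocol: ProtocolSpec, metrics: BodyMetrics) -> float:
    """Administered activity (MBq) for one patient under a protocol.

    The power-law value is the activity administered one uptake period
    before imaging; decay to scan time is applied downstream when the
    activity map is painted, exactly as in the data the fit came from.
    """
    if protocol.kind == "fixed":
        return float(protocol.fixed_mbq)
    if protocol.kind == "linear_per_kg":
        return float(protocol.rate_mbq_per_kg * metrics.weight_kg)
    fit = protocol.fit
    if fit is None:
        raise ValueError("power-law protocol needs a PowerLawFit")
    p = metrics.parameter(fit.body_parameter)
    return float(
        (1.0 / protocol.t_min) * (protocol.snr_const**2 / fit.a**2) * p ** (2.0 * fit.d)
    )


def fits_to_json(fits: list[PowerLawFit], selected: PowerLawFit, path) -> None:
    payload = {
        "fits": [f.to_dict() for f in fits],
        "selected": selected.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
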