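"""Monotone calibration curves linking Raman parameters to ring counts.

Three curves are calibrated on the twelve elementary glycosides: the carbonyl
stretching wavenumber nu_CO against the number of C19-side rings, and the
areal intensity ratios R1 = I887/I898 and R2 = (I1192 + I1215)/I1204 against
the total ring count.  Each is least-squares fitted with a quadratic; if the
quadratic is not non-decreasing over the calibration domain (checked on a
0.01-step grid) the fit falls back to isotonic regression with linear
interpolation between the pooled means, so the stored model is monotone
non-decreasing by construction and can be inverted uniquely.

Inversion — the step that turns a measured parameter of an unknown product
into a continuous ring-count estimate — is a bisection solve on the domain;
values outside the calibrated range clamp to the domain endpoint and raise an
out-of-range flag rather than extrapolating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "CalibrationPoint",
    "CalibrationModel",
    "Prediction",
    "Inversion",
    "fit_calibration",
    "predict",
    "invert",
    "save_models",
    "load_models",
]

_GRID_STEP = 0.01
_DOMAIN_SLACK = 0.5  # prediction allowed this far beyond the domain without flag


@dataclass(frozen=True)
class CalibrationPoint:
    """One training point: a compound's ring count and measured parameter."""

    compound: str
    x: float  # ring count
    y: float  # parameter value (cm^-1 for nu_CO, dimensionless for R1/R2)


@dataclass(frozen=True)
class Prediction:
    value: float
    extrapolated: bool = False


@dataclass(frozen=True)
class Inversion:
    x: float
    out_of_range: bool = False


@dataclass
class CalibrationModel:
    """A monotone non-decreasing curve y(x) on [domain[0], domain[1]].

    ``form`` is ``"quadratic"`` (coefficients c0 + c1 x + c2 x^2) or
    ``"isotonic_linear"`` (knots interpolated linearly).  Training points are
    stored for provenance.
    """

    parameter: str  # nu_co | R1 | R2
    form: str
    coefficients: tuple[float, ...]  # quadratic coeffs, or interleaved knots
    domain: tuple[float, float]
    fit_rms: float
    points: tuple[CalibrationPoint, ...] = ()

    @property
    def knots(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.coefficients)
        return c[0::2], c[1::2]

    def _eval(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.form == "quadratic":
            return np.polynomial.polynomial.polyval(x, np.asarray(self.coefficients))
        kx, ky = self.knots
        return np.interp(x, kx, ky)

    @property
    def is_constant(self) -> bool:
        lo, hi = self.domain
        return abs(float(self._eval(hi)) - float(self._eval(lo))) < 1e-12

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "form": self.form,
            "coefficients": list(self.coefficients),
            "domain": list(self.domain),
            "fit_rms": self.fit_rms,
            "points": [{"compound": p.compound, "x": p.x, "y": p.y} for p in self.points],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            parameter=d["parameter"],
            form=d["form"],
            coefficients=tuple(d["coefficients"]),
            domain=tuple(d["domain"]),
            fit_rms=float(d["fit_rms"]),
            points=tuple(CalibrationPoint(p["compound"], p["x"], p["y"])
                         for p in d.get("points", [])),
        )


def _is_monotone(model_eval, lo: float, hi: float) -> bool:
    grid = np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP)
    vals = np.asarray(model_eval(grid))
    return bool((np.diff(vals) >= -1e-12).all())


def fit_calibration(points: Sequence[CalibrationPoint], parameter: str) -> CalibrationModel:
    """Fit a monotone calibration curve to (ring count, parameter) points.

    Replicated x values (several compounds share a ring count) are kept as
    separate points; least squares absorbs the spread.  Requires at least 3
    distinct x levels.  A constant-y point set yields a model that refuses
    inversion.
    """
    points = tuple(points)
    xs = np.array([p.x for p in points], float)
    ys = np.array([p.y for p in points], float)
    if np.unique(xs).size < 3:
        raise ValueError(
            f"calibration needs >= 3 distinct ring-count levels, got {np.unique(xs).size}"
        )
    lo, hi = float(xs.min()), float(xs.max())

    coeffs = np.polynomial.polynomial.polyfit(xs, ys, 2)
    quad = lambda g: np.polynomial.polynomial.polyval(g, coeffs)
    if _is_monotone(quad, lo, hi):
        resid = ys - quad(xs)
        return CalibrationModel(parameter, "quadratic", tuple(map(float, coeffs)),
                                (lo, hi), float(np.sqrt(np.mean(resid ** 2))), points)

    # quadratic dips somewhere on the domain -> isotonic fallback
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(xs, ys)
    kx = np.unique(xs)
    ky = iso.predict(kx)
    resid = ys - iso.predict(xs)
    interleaved = tuple(float(v) for pair in zip(kx, ky) for v in pair)
    return CalibrationModel(parameter, "isotonic_linear", interleaved,
                            (lo, hi), float(np.sqrt(np.mean(resid ** 2))), points)


def predict(m: CalibrationModel, x: float) -> Prediction:
    """Evaluate the curve at ring count ``x``.

    Evaluation outside the training domain is clamped to the nearest endpoint
    and flagged as extrapolated (no flag at the endpoints themselves).
    """
    lo, hi = m.domain
    extrapolated = x < lo - 1e-12 or x > hi + 1e-12
    xc = min(max(x, lo), hi)
    return Prediction(float(m._eval(xc)), extrapolated)


def invert(m: CalibrationModel, y: float) -> Inversion:
    """Solve predict(x) = y for the ring count by bisection on the domain.

    ``y`` outside the calibrated range clamps to the domain endpoint with the
    out-of-range flag set.  Constant models cannot be inverted.
    """
    if m.is_constant:
        raise ValueError(
            f"calibration for {m.parameter} is constant; inversion is undefined"
        )
    lo, hi = m.domain
    y_lo, y_hi = float(m._eval(lo)), float(m._eval(hi))
    if y <= y_lo:
        return Inversion(lo, out_of_range=y < y_lo - 1e-12)
    if y >= y_hi:
        return Inversion(hi, out_of_range=y > y_hi + 1e-12)
    x = brentq(lambda t: float(m._eval(t)) - y, lo, hi, xtol=1e-9)
    return Inversion(float(x), False)


def save_models(models: dict[str, CalibrationModel], path) -> Path:
    """Serialize calibration models to a small JSON artifact."""
    path = Path(path)
    payload = {name: m.to_dict() for name, m in models.items()}
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_models(path) -> dict[str, CalibrationModel]:
    payload = json.loads(Path(path).read_text())
    return {name: CalibrationModel.from_dict(d) for name, d in payload.items()}
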