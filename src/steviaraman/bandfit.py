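"""Pseudo-Voigt band deconvolution of spectral windows.

A Raman band is modelled as the linear-combination pseudo-Voigt — the sum of a
Lorentzian and a Gaussian of equal height sharing one center and one FWHM,

    PV(nu) = h * [eta * L(nu) + (1 - eta) * G(nu)],   0 <= eta <= 1,

the standard band shape in Raman deconvolution work (not the Gaussian x
Lorentzian product form).  A window of the spectrum is fitted as a sum of such
bands by trust-region nonlinear least squares over (center, fwhm, height, eta)
per band, with centers tethered to their seed positions.  Fits are fully
deterministic: initialization comes from the seeds and there are no random
restarts.

Areal intensities — the integrals that the R1 and R2 quality-control ratios
are built on — have a closed form:

    area = eta * (pi/2) * h * w  +  (1 - eta) * h * w * sqrt(pi / (4 ln 2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .spectra_io import Spectrum

__all__ = [
    "Band",
    "BandFitResult",
    "MissingBandError",
    "pseudo_voigt",
    "band_area",
    "fit_bands",
    "areal_intensity_at",
]

_GAUSS_AREA = math.sqrt(math.pi / (4.0 * math.log(2.0)))  # unit-height, unit-FWHM

# Default parameter bounds: bands assigned to neighbouring vibrations sit
# > 8 cm^-1 apart, so a seed may wander at most that far; FWHM limits bracket
# the widths seen in condensed-phase Raman bands.
DEFAULT_CENTER_TOL = 8.0
FWHM_BOUNDS = (4.0, 40.0)


class MissingBandError(LookupError):
    """No fitted band lies within tolerance of the requested center."""


@dataclass
class Band:
    """One pseudo-Voigt component.

    center and fwhm are in cm^-1; height is the peak value in the spectrum's
    (arbitrary) intensity units; eta is the Lorentzian fraction in [0, 1].
    ``area`` is the analytic integral and is kept consistent automatically.
    """

    center: float
    fwhm: float
    height: float = 0.0
    eta: float = 0.5

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.height < 0:
            raise ValueError("height must be non-negative")

    @property
    def area(self) -> float:
        return band_area(self)


@dataclass
class BandFitResult:
    """A fitted window: bands sorted by center, residual RMS, convergence.

    ``offset`` is the fitted constant background of the window — a nuisance
    term absorbing whatever the global baseline subtraction left behind; it
    contributes to the model but never to any band area.
    """

    window: tuple[float, float]
    bands: list[Band]
    residual_rms: float
    converged: bool
    n_points: int = 0
    merged: int = 0  # degenerate components merged post hoc
    offset: float = 0.0

    def model(self, nu: np.ndarray) -> np.ndarray:
        nu = np.asarray(nu, float)
        out = np.full_like(nu, self.offset)
        for b in self.bands:
            out += pseudo_voigt(nu, b)
        return out

    def total_area(self) -> float:
        return float(sum(b.area for b in self.bands))

    def to_rows(self) -> list[dict]:
        """Tabular form: one dict per band (serializes to CSV directly)."""
        return [
            {
                "window_lo": self.window[0], "window_hi": self.window[1],
                "center": b.center, "fwhm": b.fwhm, "height": b.height,
                "eta": b.eta, "area": b.area, "residual_rms": self.residual_rms,
                "converged": self.converged,
            }
            for b in self.bands
        ]


def pseudo_voigt(nu: np.ndarray | float, b: Band) -> np.ndarray | float:
    """Evaluate one pseudo-Voigt band at wavenumber(s) ``nu``."""
    nu = np.asarray(nu, float)
    x = (nu - b.center) / b.fwhm
    lorentz = 1.0 / (1.0 + 4.0 * x * x)
    gauss = np.exp(-4.0 * math.log(2.0) * x * x)
    out = b.height * (b.eta * lorentz + (1.0 - b.eta) * gauss)
    return float(out) if out.ndim == 0 else out


def band_area(b: Band) -> float:
    """Closed-form integral of the pseudo-Voigt over the whole axis."""
    lor = b.eta * (math.pi / 2.0) * b.height * b.fwhm
    gau = (1.0 - b.eta) * b.height * b.fwhm * _GAUSS_AREA
    return lor + gau


def _pack(bands: Sequence[Band]) -> np.ndarray:
    return np.array([[b.center, b.fwhm, b.height, b.eta] for b in bands]).ravel()


def _unpack(x: np.ndarray) -> list[Band]:
    out = []
    for c, w, h, e in x.reshape(-1, 4):
        out.append(Band(center=float(c), fwhm=float(w),
                        height=max(float(h), 0.0), eta=min(max(float(e), 0.0), 1.0)))
    return out


def _model(x: np.ndarray, nu: np.ndarray, with_offset: bool) -> np.ndarray:
    bandpart = x[:-1] if with_offset else x
    p = bandpart.reshape(-1, 4)
    xs = (nu[None, :] - p[:, 0:1]) / p[:, 1:2]
    lorentz = 1.0 / (1.0 + 4.0 * xs * xs)
    gauss = np.exp(-4.0 * math.log(2.0) * xs * xs)
    comps = p[:, 2:3] * (p[:, 3:4] * lorentz + (1.0 - p[:, 3:4]) * gauss)
    out = comps.sum(axis=0)
    return out + x[-1] if with_offset else out


def _run_fit(nu: np.ndarray, y: np.ndarray, seeds: list[Band],
             center_tol: float, fwhm_bounds: tuple[float, float],
             fit_offset: bool):
    x0 = _pack(seeds)
    lo = np.empty_like(x0)
    hi = np.empty_like(x0)
    ymax = max(float(np.abs(y).max()), 1e-12)
    for i, b in enumerate(seeds):
        lo[4 * i: 4 * i + 4] = [b.center - center_tol, fwhm_bounds[0], 0.0, 0.0]
        hi[4 * i: 4 * i + 4] = [b.center + center_tol, fwhm_bounds[1], 5.0 * ymax, 1.0]
        x0[4 * i + 1] = min(max(x0[4 * i + 1], fwhm_bounds[0]), fwhm_bounds[1])
        if x0[4 * i + 2] <= 0:  # seed height from the data at the seed center
            x0[4 * i + 2] = max(float(np.interp(b.center, nu, y)), 1e-6 * ymax)
        x0[4 * i + 2] = min(x0[4 * i + 2], 5.0 * ymax)
    if fit_offset:
        x0 = np.append(x0, 0.0)
        lo = np.append(lo, -ymax)
        hi = np.append(hi, ymax)
    return least_squares(
        lambda x: _model(x, nu, fit_offset) - y, x0, bounds=(lo, hi),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400 * len(seeds),
    )


def fit_bands(
    s: Spectrum,
    window: Sequence[float],
    seeds: Sequence[Band],
    center_tol: float = DEFAULT_CENTER_TOL,
    fwhm_bounds: tuple[float, float] = FWHM_BOUNDS,
    fit_offset: bool = True,
) -> BandFitResult:
    """Deconvolute a spectral window into pseudo-Voigt components.

    Parameters
    ----------
    s
        Preprocessed spectrum (baseline-removed, normalized).
    window
        (lo, hi) wavenumber interval to fit; data outside are ignored.
    seeds
        Initial bands.  Centers must lie inside the window and stay within
        ``center_tol`` of their seed value during the fit.
    center_tol, fwhm_bounds
        Box constraints on center drift and FWHM.
    fit_offset
        Also fit a constant window background (on by default); areal
        intensities are far less sensitive to residual baseline error with
        the nuisance offset absorbed here.

    Two components converging to the same position (centers within 0.5 cm^-1)
    are considered degenerate; the smaller one is dropped and the window is
    refitted so that each reported band keeps a self-consistent analytic area.
    Optimizer failure never raises — the result carries ``converged=False``
    with the seeds echoed.
    """
    lo_w, hi_w = float(window[0]), float(window[1])
    mask = (s.wavenumber >= lo_w) & (s.wavenumber <= hi_w)
    if not mask.any():
        raise ValueError(f"window ({lo_w}, {hi_w}) contains no data")
    seeds = [replace(b) for b in seeds]
    if not seeds:
        raise ValueError("fit_bands needs at least one seed band")
    for b in seeds:
        if not (lo_w <= b.center <= hi_w):
            raise ValueError(f"seed center {b.center} outside window ({lo_w}, {hi_w})")
    nu, y = s.wavenumber[mask], s.intensity[mask]

    def _finish(bands: list[Band], offset: float, converged: bool,
                merged: int) -> BandFitResult:
        bands = sorted(bands, key=lambda b: b.center)
        model = _model(_pack(bands), nu, False) + offset
        rms = float(np.sqrt(np.mean((y - model) ** 2)))
        return BandFitResult((lo_w, hi_w), bands, rms, converged, nu.size,
                             merged, offset)

    merged = 0
    current = seeds
    for _ in range(len(seeds)):  # at most n-1 degeneracy merges
        try:
            res = _run_fit(nu, y, current, center_tol, fwhm_bounds, fit_offset)
        except Exception:
            return BandFitResult((lo_w, hi_w), sorted(current, key=lambda b: b.center),
                                 float(np.sqrt(np.mean(y ** 2))), False, nu.size, merged)
        offset = float(res.x[-1]) if fit_offset else 0.0
        bands = _unpack(res.x[:-1] if fit_offset else res.x)
        # detect degenerate collapse: two centers within 0.5 cm^-1
        order = np.argsort([b.center for b in bands])
        drop = None
        for a, bi in zip(order[:-1], order[1:]):
            if abs(bands[bi].center - bands[a].center) < 0.5:
                drop = a if bands[a].area <= bands[bi].area else bi
                break
        if drop is None:
            return _finish(bands, offset, res.status > 0, merged)
        merged += 1
        current = [b for i, b in enumerate(bands) if i != drop] or bands[:1]
    return _finish(list(current), offset, True, merged)


def areal_intensity_at(fit: BandFitResult, target: float, tol: float = 5.0,
                       min_area: float = 0.0) -> float:
    """Area of the fitted band nearest ``target`` and within ``tol`` cm^-1.

    Distance ties are broken toward the larger-area band.  Bands whose area
    falls below ``min_area`` are treated as absent — a component whose height
    collapsed to numerical zero is not evidence of the vibration.  Raises
    :class:`MissingBandError` naming the target if nothing qualifies.
    """
    best: Band | None = None
    best_key: tuple[float, float] | None = None
    for b in fit.bands:
        d = abs(b.center - target)
        if d > tol or b.area < min_area:
            continue
        key = (round(d, 9), -b.area)  # nearest first, then larger area
        if best_key is None or key < best_key:
            best, best_key = b, key
    if best is None:
        raise MissingBandError(
            f"no fitted band within {tol} cm^-1 of {target} cm^-1 "
            f"(centers: {[round(b.center, 2) for b in fit.bands]})"
        )
    return best.area
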