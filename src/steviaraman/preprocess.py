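"""Baseline subtraction, normalization and window cropping.

The pipeline order is fixed and applied exactly once per spectrum:
``average -> subtract_baseline -> normalize_to_max -> crop``.  Normalizing
before cropping matters: the normalizer is the strongest signal of the whole
collected interval, not of a sub-window, and swapping the two steps would
change every intensity ratio downstream.

The baseline is a low-order polynomial least-squares fitted on *anchor
regions* — wavenumber intervals assumed band-free — and subtracted everywhere.
The default anchors (1550–1600 and 1800–2100 cm^-1 plus the outermost
10 cm^-1 at each end of the axis) sit outside every band window in the
steviol-glycoside assignment table.  Negative intensities after subtraction
are retained so that band-fit residuals stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spectra_io import DegenerateSpectrumError, Spectrum

__all__ = ["PreprocessConfig", "subtract_baseline", "normalize_to_max", "crop", "preprocess"]

#: Anchor intervals (cm^-1) free of steviol-glycoside bands.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = ((1550.0, 1600.0), (1800.0, 2100.0))

#: Width of the implicit edge anchors at both ends of the axis (cm^-1).
EDGE_ANCHOR_WIDTH = 10.0


@dataclass
class PreprocessConfig:
    """Settings for the fixed preprocessing chain.

    Parameters
    ----------
    baseline_degree
        Degree of the baseline polynomial, 0–6.  Default 3 (cubic): flexible
        enough for the smooth fluorescence background of 514 nm excitation,
        stiff enough not to eat into bands.
    anchor_regions
        Intervals (lo, hi) in cm^-1 assumed band-free; the baseline is fitted
        on these points only.  The first/last ``EDGE_ANCHOR_WIDTH`` cm^-1 of
        the axis are always added.
    normalization
        ``"max"`` divides by the strongest signal of the collected interval;
        ``"none"`` leaves intensities untouched.
    """

    baseline_degree: int = 3
    anchor_regions: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
    normalization: str = "max"

    def __post_init__(self) -> None:
        if not (0 <= self.baseline_degree <= 6):
            raise ValueError("baseline_degree must be in [0, 6]")
        if self.normalization not in ("max", "none"):
            raise ValueError("normalization must be 'max' or 'none'")
        self.anchor_regions = tuple((float(lo), float(hi)) for lo, hi in self.anchor_regions)
        for lo, hi in self.anchor_regions:
            if hi <= lo:
                raise ValueError(f"anchor region ({lo}, {hi}) is empty")

    def to_dict(self) -> dict:
        return {
            "baseline_degree": self.baseline_degree,
            "anchor_regions": [list(r) for r in self.anchor_regions],
            "normalization": self.normalization,
        }


def _anchor_mask(s: Spectrum, cfg: PreprocessConfig) -> np.ndarray:
    nu = s.wavenumber
    mask = np.zeros(nu.size, dtype=bool)
    regions = list(cfg.anchor_regions) + [
        (nu[0], nu[0] + EDGE_ANCHOR_WIDTH),
        (nu[-1] - EDGE_ANCHOR_WIDTH, nu[-1]),
    ]
    for lo, hi in regions:
        mask |= (nu >= lo) & (nu <= hi)
    return mask


def subtract_baseline(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Fit a polynomial on anchor-region points and subtract it everywhere.

    Raises if the anchors provide fewer than ``4 * (degree + 1)`` points — a
    cubic needs a few dozen anchor samples to be conditioned against noise.
    """
    cfg = cfg or PreprocessConfig()
    mask = _anchor_mask(s, cfg)
    n_anchor = int(mask.sum())
    needed = 4 * (cfg.baseline_degree + 1)
    if n_anchor < needed:
        raise ValueError(
            f"anchor regions cover {n_anchor} points; "
            f"degree {cfg.baseline_degree} needs at least {needed}"
        )
    # Fit in a scaled coordinate for numerical conditioning.
    nu = s.wavenumber
    u = (nu - nu[0]) / (nu[-1] - nu[0])
    coeffs = np.polynomial.polynomial.polyfit(u[mask], s.intensity[mask], cfg.baseline_degree)
    baseline = np.polynomial.polynomial.polyval(u, coeffs)
    return s.with_intensity(s.intensity - baseline, baseline_removed=True,
                            baseline_degree=cfg.baseline_degree)


def normalize_to_max(s: Spectrum) -> Spectrum:
    """Divide intensities by their maximum so the strongest signal becomes 1."""
    peak = float(s.intensity.max())
    if peak <= 0:
        raise ValueError("cannot normalize: maximum intensity is not positive")
    return s.with_intensity(s.intensity / peak, normalized="max")


def crop(s: Spectrum, window: Sequence[float]) -> Spectrum:
    """Restrict to wavenumbers in the closed interval ``[lo, hi]``."""
    lo, hi = float(window[0]), float(window[1])
    if hi < lo:
        lo, hi = hi, lo
    mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"crop window ({lo}, {hi}) does not overlap the axis "
            f"{s.span[0]}..{s.span[1]} cm^-1"
        )
    if n < 16:
        raise DegenerateSpectrumError(
            f"crop window ({lo}, {hi}) retains only {n} points (minimum 16)"
        )
    meta = dict(s.meta)
    meta["window"] = (lo, hi)
    return Spectrum(s.wavenumber[mask], s.intensity[mask], meta)


def preprocess(s: Spectrum, cfg: PreprocessConfig | None = None,
               window: Sequence[float] | None = None) -> Spectrum:
    """The fixed chain: baseline subtraction, then normalization, then crop."""
    cfg = cfg or PreprocessConfig()
    out = subtract_baseline(s, cfg)
    if cfg.normalization == "max":
        out = normalize_to_max(out)
    if window is not None:
        out = crop(out, window)
    return out
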