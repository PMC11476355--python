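"""Reading, writing, validating and averaging Raman spectra.

The in-memory currency of the whole package is :class:`Spectrum`: a strictly
increasing wavenumber axis (cm^-1), an intensity vector of the same length in
arbitrary units, and a free-form metadata dict.  Readers sort on load and
collapse duplicated wavenumbers by their mean, so every downstream operation
can assume an ascending, duplicate-free axis.

Supported on-disk formats are two-column CSV/TSV (optional header) and a
deliberately small JCAMP-DX subset: a single ``##XYDATA=(X++(Y..Y))`` block in
AFFN (plain decimal) form, which is enough for interchange with common
spectroscopy software without implementing the full standard.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

MIN_POINTS = 16

__all__ = [
    "Spectrum",
    "SpectrumFormatError",
    "DegenerateSpectrumError",
    "read_spectrum",
    "write_spectrum",
    "average_replicates",
]


class SpectrumFormatError(ValueError):
    """A file could not be parsed as a spectrum; the message names the line."""


class DegenerateSpectrumError(ValueError):
    """A spectrum (or requested window) has too few points to be usable."""


@dataclass
class Spectrum:
    """One Raman spectrum: ascending wavenumber axis plus intensity vector.

    Parameters
    ----------
    wavenumber
        Strictly increasing Raman shifts in cm^-1, at least ``MIN_POINTS`` of
        them, no NaN/inf.
    intensity
        Finite intensities in arbitrary units, same length as ``wavenumber``.
    meta
        Free-form provenance (sample name, replicate id, normalization state).
    """

    wavenumber: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("wavenumber and intensity must be 1-D vectors")
        if self.wavenumber.size != self.intensity.size:
            raise ValueError(
                f"axis length {self.wavenumber.size} != intensity length "
                f"{self.intensity.size}"
            )
        if self.wavenumber.size < MIN_POINTS:
            raise DegenerateSpectrumError(
                f"spectrum has {self.wavenumber.size} points; "
                f"at least {MIN_POINTS} required"
            )
        if not (np.isfinite(self.wavenumber).all() and np.isfinite(self.intensity).all()):
            raise ValueError("spectrum contains NaN or infinite values")
        if not (np.diff(self.wavenumber) > 0).all():
            raise ValueError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return self.wavenumber.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavenumber[0]), float(self.wavenumber[-1])

    def with_intensity(self, intensity: np.ndarray, **meta_updates) -> "Spectrum":
        """New Spectrum sharing this axis, with updated intensity and meta."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.wavenumber.copy(), np.asarray(intensity, float), meta)

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavenumber.copy(), self.intensity.copy(), dict(self.meta))


def _collapse_sort(nu: np.ndarray, y: np.ndarray, meta: dict) -> Spectrum:
    """Sort by wavenumber; average intensities at duplicated wavenumbers."""
    order = np.argsort(nu, kind="stable")
    nu, y = nu[order], y[order]
    uniq, inverse, counts = np.unique(nu, return_inverse=True, return_counts=True)
    if uniq.size != nu.size:
        sums = np.zeros(uniq.size)
        np.add.at(sums, inverse, y)
        y = sums / counts
        nu = uniq
    return Spectrum(nu, y, meta)


def _read_xy_text(path: Path, delimiter: str | None) -> tuple[np.ndarray, np.ndarray]:
    nus, ys = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            parts = [p for p in parts if p != ""]
            if len(parts) < 2:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: expected two columns, got {line!r}"
                )
            try:
                nus.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError:
                if lineno == 1:  # tolerate a single header line
                    continue
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: non-numeric value in {line!r}"
                ) from None
    return np.array(nus), np.array(ys)


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _read_jcamp(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a single-block AFFN ``##XYDATA=(X++(Y..Y))`` JCAMP-DX file.

    Each data line carries an abscissa value followed by one or more ordinates;
    intermediate abscissas are reconstructed from DELTAX (or FIRSTX/LASTX/
    NPOINTS).  XFACTOR/YFACTOR scalings are honoured.
    """
    xfactor = yfactor = 1.0
    deltax = None
    firstx = lastx = npoints = None
    in_data = False
    nus: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.split("$$")[0].strip()
                if key == "XFACTOR":
                    xfactor = float(value)
                elif key == "YFACTOR":
                    yfactor = float(value)
                elif key == "DELTAX":
                    deltax = float(value)
                elif key == "FIRSTX":
                    firstx = float(value)
                elif key == "LASTX":
                    lastx = float(value)
                elif key == "NPOINTS":
                    npoints = int(float(value))
                elif key == "XYDATA":
                    if "X++(Y..Y)" not in value:
                        raise SpectrumFormatError(
                            f"{path}: line {lineno}: unsupported XYDATA form {value!r}"
                        )
                    in_data = True
                elif key == "END":
                    in_data = False
                continue
            if not in_data:
                continue
            nums = _JCAMP_NUM.findall(line)
            if len(nums) < 2:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: XYDATA line needs X plus >=1 Y value"
                )
            x0 = float(nums[0])
            if deltax is None:
                if firstx is None or lastx is None or npoints is None or npoints < 2:
                    raise SpectrumFormatError(
                        f"{path}: DELTAX or FIRSTX/LASTX/NPOINTS required to "
                        "reconstruct the abscissa"
                    )
                deltax = (lastx - firstx) / (npoints - 1)
            for j, tok in enumerate(nums[1:]):
                nus.append((x0 + j * deltax) * xfactor)
                ys.append(float(tok) * yfactor)
    if not nus:
        raise SpectrumFormatError(f"{path}: no ##XYDATA block found")
    return np.array(nus), np.array(ys)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = {".csv": "csv", ".tsv": "tsv", ".txt": "csv",
               ".jdx": "jcamp", ".dx": "jcamp"}.get(path.suffix.lower(), "csv")
    if fmt not in ("csv", "tsv", "jcamp"):
        raise ValueError(f"unknown spectrum format {fmt!r}")
    return fmt


def read_spectrum(path, format: str | None = None, meta: Mapping | None = None) -> Spectrum:
    """Read a spectrum from ``path``.

    ``format`` is one of ``csv``, ``tsv``, ``jcamp``; when omitted it is
    inferred from the file suffix (``.jdx``/``.dx`` -> jcamp, else csv).  The
    result is sorted ascending in wavenumber, duplicated wavenumbers are
    collapsed by the mean, and the source path is recorded in ``meta``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "jcamp":
        nu, y = _read_jcamp(path)
    else:
        nu, y = _read_xy_text(path, "," if fmt == "csv" else "\t")
    if nu.size < MIN_POINTS:
        raise DegenerateSpectrumError(
            f"{path}: only {nu.size} data points (minimum {MIN_POINTS})"
        )
    m = {"source": str(path)}
    if meta:
        m.update(meta)
    return _collapse_sort(nu, y, m)


def write_spectrum(s: Spectrum, path, format: str | None = None) -> Path:
    """Write ``s`` to ``path``; round-trips through :func:`read_spectrum`
    reproduce the values to better than 1e-9 relative."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        with open(path, "w") as fh:
            fh.write(f"wavenumber{sep}intensity\n")
            for nu, y in zip(s.wavenumber, s.intensity):
                fh.write(f"{nu:.12g}{sep}{y:.12g}\n")
    else:
        step = np.diff(s.wavenumber)
        uniform = step.size > 0 and np.allclose(step, step[0], rtol=0, atol=1e-9)
        if not uniform:
            raise ValueError("JCAMP XYDATA requires a uniform wavenumber step")
        with open(path, "w") as fh:
            title = s.meta.get("sample", "spectrum")
            fh.write(f"##TITLE={title}\n##JCAMP-DX=4.24\n##DATA TYPE=RAMAN SPECTRUM\n")
            fh.write("##XUNITS=1/CM\n##YUNITS=ARBITRARY UNITS\n")
            fh.write(f"##XFACTOR=1\n##YFACTOR=1\n##FIRSTX={s.wavenumber[0]:.12g}\n")
            fh.write(f"##LASTX={s.wavenumber[-1]:.12g}\n##NPOINTS={len(s)}\n")
            fh.write(f"##DELTAX={step[0]:.12g}\n")
            fh.write("##XYDATA=(X++(Y..Y))\n")
            per_line = 4
            for i in range(0, len(s), per_line):
                ys = " ".join(f"{y:.12g}" for y in s.intensity[i:i + per_line])
                fh.write(f"{s.wavenumber[i]:.12g} {ys}\n")
            fh.write("##END=\n")
    return path


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra.

    Axes that agree within 1e-6 cm^-1 are averaged directly; otherwise each
    replicate is linearly resampled onto the first spectrum's axis, restricted
    to the common overlap.  The replicate count is recorded in ``meta``.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("average_replicates needs at least one spectrum")
    ref = spectra[0]
    same_axis = all(
        len(s) == len(ref) and np.allclose(s.wavenumber, ref.wavenumber, rtol=0, atol=1e-6)
        for s in spectra[1:]
    )
    if same_axis:
        axis = ref.wavenumber.copy()
        stack = np.vstack([s.intensity for s in spectra])
    else:
        lo = max(s.wavenumber[0] for s in spectra)
        hi = min(s.wavenumber[-1] for s in spectra)
        if lo >= hi:
            raise ValueError("replicate axes do not overlap")
        mask = (ref.wavenumber >= lo - 1e-12) & (ref.wavenumber <= hi + 1e-12)
        if mask.sum() < MIN_POINTS:
            raise DegenerateSpectrumError(
                f"replicate axis overlap has {int(mask.sum())} points "
                f"(minimum {MIN_POINTS})"
            )
        axis = ref.wavenumber[mask]
        stack = np.vstack([np.interp(axis, s.wavenumber, s.intensity) for s in spectra])
    meta = dict(ref.meta)
    meta["replicates"] = len(spectra)
    return Spectrum(axis, stack.mean(axis=0), meta)
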