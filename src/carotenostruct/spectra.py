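"""Absorption-spectrum utilities: peak calls and bathochromic shifts.

A carotenoprotein's color change on ligand binding is quantified by the
displacement of the visible absorption maximum: the bathochromic (red)
shift is bound-state lambda_max minus free-pigment lambda_max, positive
toward longer wavelength.  Peak detection is deliberately simple and fully
reproducible: a centered moving average (default 5 nm) followed by the
highest interior local maximum in the search range; a shoulder, if
requested, is called from the concavity pattern of the long-wavelength
flank and is reported without a precision claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoPeakError

MIN_POINTS = 10
MIN_SPAN_NM = 100.0


@dataclass
class Spectrum:
    wavelengths: np.ndarray  # nm, strictly increasing
    absorbance: np.ndarray   # arbitrary units
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance arrays differ in length")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) < 2:
            raise ValueError("need a 1D spectrum with >= 2 points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def grid_step(self) -> float:
        return float(np.median(np.diff(self.wavelengths)))


@dataclass
class PeakCall:
    lambda_max: float           # nm
    absorbance: float
    shoulder: float | None = None       # nm
    shift_vs_reference: float | None = None  # nm, bound - free


def read_spectrum(path, label: str = "") -> Spectrum:
    """Two-column wavelength/absorbance table (whitespace, comma or tab)."""
    data = np.genfromtxt(path, delimiter=None, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        data = np.genfromtxt(path, delimiter=",", comments="#")
    order = np.argsort(data[:, 0])
    return Spectrum(wavelengths=data[order, 0], absorbance=data[order, 1],
                    label=label or str(path))


def _smooth(y: np.ndarray, window_pts: int) -> np.ndarray:
    if window_pts <= 1:
        return y.copy()
    k = window_pts if window_pts % 2 else window_pts + 1
    pad = k // 2
    ypad = np.pad(y, pad, mode="edge")
    kernel = np.ones(k) / k
    return np.convolve(ypad, kernel, mode="valid")


def find_lambda_max(spectrum: Spectrum, smooth_window: float = 5.0,
                    search_range: tuple[float, float] | None = None,
                    detect_shoulder: bool = False) -> PeakCall:
    """Highest interior local maximum of the smoothed spectrum.

    ``smooth_window`` is in nm; ``search_range`` restricts the call (peak
    wavelengths come from the raw grid, so the resolution is one grid step).
    Flat or monotone input raises :class:`NoPeakError`.
    """
    wl, ab = spectrum.wavelengths, spectrum.absorbance
    if len(wl) < MIN_POINTS or wl[-1] - wl[0] < MIN_SPAN_NM:
        raise ValueError(
            f"peak calls need >= {MIN_POINTS} points spanning >= {MIN_SPAN_NM} nm")
    step = spectrum.grid_step
    smoothed = _smooth(ab, max(int(round(smooth_window / step)), 1))
    lo, hi = search_range if search_range else (wl[0], wl[-1])
    if lo < wl[0] - 1e-9 or hi > wl[-1] + 1e-9:
        raise ValueError("search range outside spectrum")
    mask = (wl >= lo) & (wl <= hi)
    idx = np.where(mask)[0]
    # interior local maxima of the smoothed trace
    cand = [i for i in idx[1:-1] if smoothed[i] >= smoothed[i - 1]
            and smoothed[i] >= smoothed[i + 1] and
            (smoothed[i] > smoothed[i - 1] or smoothed[i] > smoothed[i + 1])]
    if not cand:
        raise NoPeakError("no interior absorbance maximum in search range")
    best = max(cand, key=lambda i: (smoothed[i], -i))
    shoulder = None
    if detect_shoulder:
        shoulder = _find_shoulder(wl, smoothed, best)
    return PeakCall(lambda_max=float(wl[best]), absorbance=float(ab[best]),
                    shoulder=shoulder)


def _find_shoulder(wl: np.ndarray, smoothed: np.ndarray, peak_idx: int,
                   min_rel_height: float = 0.2) -> float | None:
    """Concavity minimum on the long-wavelength flank past the main peak."""
    if peak_idx >= len(wl) - 3:
        return None
    d2 = np.gradient(np.gradient(smoothed, wl), wl)
    flank = np.arange(peak_idx + 2, len(wl) - 2)
    # a shoulder shows as a local minimum of d2 (renewed concavity) with
    # appreciable absorbance, separated from the peak by a convex stretch
    seen_convex = False
    best = None
    for i in flank:
        if d2[i] > 0:
            seen_convex = True
        if (seen_convex and d2[i] < 0 and d2[i] <= d2[i - 1] and d2[i] <= d2[i + 1]
                and smoothed[i] >= min_rel_height * smoothed[peak_idx]):
            best = i
            break
    return float(wl[best]) if best is not None else None


def bathochromic_shift(free: PeakCall, bound: PeakCall) -> float:
    """Signed shift in nm, positive for a red (bathochromic) shift."""
    return bound.lambda_max - free.lambda_max
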