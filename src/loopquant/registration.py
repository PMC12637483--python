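"""Translation registration of sequential imaging rounds.

Sequential RNA-FISH and DNA-FISH acquisitions of the same fields are aligned
by a per-field integer-pixel translation estimated from the nuclear-stain
(DAPI) images via Fourier phase correlation: the normalized cross-power
spectrum of the two images inverse-transforms to a delta at the relative
shift. The estimated translation is then propagated to spot centroid
coordinates. Only rigid translation is modeled — fields drift by a few
pixels between rounds, never rotate or scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RegistrationResult:
    """An estimated per-field translation.

    ``shift`` is (dx, dy) in pixels, x along columns and y along rows, in the
    wrap-aware range (-N/2, N/2]: applying it to the first image reproduces
    the second. ``peak_value`` is the height of the normalized correlation
    peak (1.0 for an exact cyclic shift).
    """

    shift: tuple[int, int]
    peak_value: float
    field_id: str = ""


def _signed(index: int, n: int) -> int:
    """Map an FFT bin index to a signed shift in (-n/2, n/2]."""
    return index - n if index > n // 2 else index


def phase_correlation(image_a: np.ndarray, image_b: np.ndarray,
                      field_id: str = "", window: bool = False,
                      eps: float = 1e-12) -> RegistrationResult:
    """Estimate the integer translation taking ``image_a`` onto ``image_b``.

    Computes F(a)·conj(F(b)) / |F(a)·conj(F(b))|, inverse-transforms, and
    reads the argmax as a signed shift. Optional Hann windowing (default off)
    suppresses edge effects for non-cyclic content.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("expected 2D images")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant image: phase correlation undefined")
    if window:
        wy = np.hanning(a.shape[0])[:, None]
        wx = np.hanning(a.shape[1])[None, :]
        a = (a - a.mean()) * wy * wx
        b = (b - b.mean()) * wy * wx
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    surface = np.fft.ifft2(cross / np.maximum(mag, eps)).real
    iy, ix = np.unravel_index(int(np.argmax(surface)), surface.shape)
    # F(a)·conj(F(b)) peaks at the negated displacement of b relative to a
    dy = _signed((-iy) % a.shape[0], a.shape[0])
    dx = _signed((-ix) % a.shape[1], a.shape[1])
    return RegistrationResult(shift=(dx, dy),
                              peak_value=float(surface[iy, ix]),
                              field_id=field_id)


def apply_translation(spots: pd.DataFrame, result: RegistrationResult,
                      pixel_size: float = 0.108) -> pd.DataFrame:
    """Shift spot centroids by a registration result, pixels -> um.

    Returns a copy of the spot table with ``x_um`` and ``y_um`` translated by
    ``shift * pixel_size``; all other columns are unchanged.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    out = spots.copy()
    dx, dy = result.shift
    out["x_um"] = out["x_um"] + dx * pixel_size
    out["y_um"] = out["y_um"] + dy * pixel_size
    return out


def register_fields(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]], window: bool = False
) -> pd.DataFrame:
    """Phase-correlate each field's (round 1, round 2) nuclear-stain images.

    Returns a table {field_id, dx_px, dy_px, peak_value} with one row per
    field; alignment is estimated independently per field.
    """
    rows = []
    for field_id, (a, b) in pairs.items():
        res = phase_correlation(a, b, field_id=field_id, window=window)
        rows.append({"field_id": field_id, "dx_px": res.shift[0],
                     "dy_px": res.shift[1], "peak_value": res.peak_value})
    return pd.DataFrame(rows, columns=["field_id", "dx_px", "dy_px",
                                       "peak_value"])
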