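"""Brightness proxy Y and its logit normalization.

A cell darker than its background has negative background-subtracted
intensities (ΔR, ΔG, ΔB). Adding a virtual white background gives the
corrected color

    (Rcorr, Gcorr, Bcorr) = (255, 255, 255) + (ΔR, ΔG, ΔB),

from which the luma-weighted brightness is

    Y = 0.299·Rcorr + 0.587·Gcorr + 0.114·Bcorr        (Y ∈ (0, 255]).

Y piles up just below the white point, so it is mapped to the whole real
line with a logit transform,

    Ynorm = log( Y / (255 − Y) ),

which is approximately normal across a cohort of cells and serves as the
per-cell pigmentation covariate downstream (darker cell ⇒ lower Ynorm).

A corrected channel above 255 (cell brighter than background, within
noise) is replaced by the largest representable value below 255,
``255 − eps`` with ``eps = 2**-20`` by default, so the logit stays finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LUMA_WEIGHTS",
    "PROXY_WEIGHTS",
    "EPS_DEFAULT",
    "BrightnessRecord",
    "corrected_rgb",
    "brightness",
    "normalize_brightness",
    "brightness_record",
    "brightness_table",
]

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])
EPS_DEFAULT = 2.0**-20

#: Channel weightings for the brightness proxy. "luma" is the default used
#: by the enrichment analysis; "mean" and "blue" are the alternatives used
#: for descriptive color plots (the channels are near-identical, r > 0.99,
#: so the three proxies are almost interchangeable).
PROXY_WEIGHTS = {
    "luma": LUMA_WEIGHTS,
    "mean": np.full(3, 1.0 / 3.0),
    "blue": np.array([0.0, 0.0, 1.0]),
}


@dataclass
class BrightnessRecord:
    cell_id: str
    corrected_rgb: np.ndarray
    Y: float
    Ynorm: float
    clamped: bool


def corrected_rgb(
    delta, eps: float = EPS_DEFAULT, cell_id: str | None = None
) -> tuple[np.ndarray, bool]:
    """White-background-corrected channels, clamped below 255.

    Raises if a corrected channel is <= 0 (a cell cannot be darker than a
    pitch-black disk on this scale): such a value indicates a measurement
    error upstream.
    """
    delta = np.asarray(delta, dtype=float).reshape(3)
    if np.any(np.abs(delta) > 255):
        raise ValueError(f"delta outside [-255, 255]: {delta}" + _who(cell_id))
    corr = 255.0 + delta
    over = corr > 255.0  # only channels strictly above white are replaced
    clamped = bool(over.any())
    corr[over] = 255.0 - eps
    if np.any(corr <= 0):
        raise ValueError(
            f"corrected intensity <= 0 ({corr}); cell darker than representable"
            + _who(cell_id)
        )
    return corr, clamped


def _who(cell_id: str | None) -> str:
    return f" [cell_id={cell_id}]" if cell_id else ""


def brightness(corrected, weights=None) -> float:
    """Weighted sum of the corrected channels (luma weights by default).

    When the weights sum to one (all built-in proxies do), the sum is
    evaluated as ``B + wR·(R−B) + wG·(G−B)`` — algebraically identical,
    but exact for gray cells (R = G = B), where Y must equal the common
    channel value with no rounding residue.
    """
    corrected = np.asarray(corrected, dtype=float).reshape(3)
    if np.any(corrected <= 0) or np.any(corrected > 255):
        raise ValueError(f"corrected channels must lie in (0, 255], got {corrected}")
    w = LUMA_WEIGHTS if weights is None else np.asarray(weights, dtype=float)
    r, g, b = corrected
    if abs(w.sum() - 1.0) < 1e-9:
        return float(b + w[0] * (r - b) + w[1] * (g - b))
    return float(w @ corrected)


def normalize_brightness(y: float, log_base: float | None = None) -> float:
    """Logit transform Ynorm = log(Y / (255 − Y)); natural log by default.

    Requires 0 < Y < 255 — the clamp in :func:`corrected_rgb` guarantees
    the upper bound for measured cells.
    """
    if not 0 < y < 255:
        raise ValueError(f"Y must lie strictly inside (0, 255), got {y}")
    v = math.log(y / (255.0 - y))
    if log_base is not None:
        v /= math.log(log_base)
    return v


def brightness_record(
    cell_id: str,
    delta,
    proxy: str = "luma",
    eps: float = EPS_DEFAULT,
    log_base: float | None = None,
) -> BrightnessRecord:
    """Δ → corrected RGB → Y → Ynorm for one cell."""
    if proxy not in PROXY_WEIGHTS:
        raise ValueError(f"unknown proxy {proxy!r}; choose from {sorted(PROXY_WEIGHTS)}")
    corr, clamped = corrected_rgb(delta, eps=eps, cell_id=cell_id)
    y = brightness(corr, weights=PROXY_WEIGHTS[proxy])
    if y >= 255.0:  # cell exactly at the white point: keep the logit finite
        y = 255.0 - eps
        clamped = True
    return BrightnessRecord(
        cell_id=cell_id,
        corrected_rgb=corr,
        Y=y,
        Ynorm=normalize_brightness(y, log_base=log_base),
        clamped=clamped,
    )


def brightness_table(
    colors: pd.DataFrame,
    proxy: str = "luma",
    eps: float = EPS_DEFAULT,
    log_base: float | None = None,
) -> pd.DataFrame:
    """Vectorized per-cell brightness from a color table (cell_id, dR, dG, dB)."""
    rows = []
    for _, row in colors.iterrows():
        rec = brightness_record(
            str(row["cell_id"]),
            (row["dR"], row["dG"], row["dB"]),
            proxy=proxy,
            eps=eps,
            log_base=log_base,
        )
        rows.append(
            {
                "cell_id": rec.cell_id,
                "Rcorr": rec.corrected_rgb[0],
                "Gcorr": rec.corrected_rgb[1],
                "Bcorr": rec.corrected_rgb[2],
                "Y": rec.Y,
                "Ynorm": rec.Ynorm,
                "clamped": rec.clamped,
            }
        )
    return pd.DataFrame(rows)
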