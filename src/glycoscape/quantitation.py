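"""On-slide standard curves and absolute glycogen quantitation (ng/pixel).

Spotted standards of known glycogen amount are summed per spot, a line is
fit (ordinary least squares, intercept reported; a through-origin slope is
reported alongside), and tissue pixels are back-calculated through the
curve.  Quantitation runs on raw (non-TIC-normalized) signal since spots
and tissue share one acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StandardCurve", "fit_standard_curve", "quantify", "spot_signals"]


@dataclass(frozen=True)
class StandardCurve:
    slope: float                  # counts per ng (OLS with intercept)
    intercept: float              # counts
    r_squared: float
    slope_through_origin: float
    amounts: tuple[float, ...]    # ng, strictly increasing
    spot_signals: tuple[float, ...]
    linear_range: tuple[float, float]  # (min ng, max ng)

    def __post_init__(self) -> None:
        if len(self.amounts) < 3:
            raise ValueError("standard curve needs >= 3 spots")
        if any(b <= a for a, b in zip(self.amounts, self.amounts[1:])):
            raise ValueError("amounts must be strictly increasing")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")


def fit_standard_curve(spot_signals, amounts) -> StandardCurve:
    """OLS fit of summed spot signal on spotted amount.

    ``linear_range`` is the widest contiguous span of amounts on which every
    relative residual |signal - fit| / fit stays below 20% for a line refit
    to that span.
    """
    signals = np.asarray(spot_signals, dtype=np.float64)
    amounts_arr = np.asarray(amounts, dtype=np.float64)
    if signals.shape != amounts_arr.shape:
        raise ValueError("spot_signals and amounts must have equal length")
    if len(signals) < 3:
        raise ValueError("standard curve needs >= 3 spots")
    if np.ptp(amounts_arr) == 0:
        raise ValueError("amounts have zero variance")

    res = stats.linregress(amounts_arr, signals)
    slope0 = float(
        (amounts_arr @ signals) / (amounts_arr @ amounts_arr)
    )

    # widest contiguous amount span with all relative residuals < 20%
    best = (amounts_arr[0], amounts_arr[0])
    best_len = 0
    n = len(amounts_arr)
    for i in range(n):
        for j in range(i + 2, n):  # at least 3 points
            a, s = amounts_arr[i : j + 1], signals[i : j + 1]
            r = stats.linregress(a, s)
            fit = r.slope * a + r.intercept
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(s - fit) / np.abs(fit)
            if np.all(np.isfinite(rel)) and np.all(rel < 0.20):
                if j - i > best_len:
                    best_len = j - i
                    best = (float(a[0]), float(a[-1]))
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_through_origin=slope0,
        amounts=tuple(float(a) for a in amounts_arr),
        spot_signals=tuple(float(s) for s in signals),
        linear_range=best,
    )


def spot_signals(values: np.ndarray, spot_labels: np.ndarray,
                 spot_ids) -> np.ndarray:
    """Summed per-spot signal from per-pixel values and a spot label map."""
    values = np.asarray(values, dtype=np.float64)
    spot_labels = np.asarray(spot_labels)
    out = []
    for sid in spot_ids:
        sel = spot_labels == sid
        if not sel.any():
            raise ValueError(f"spot {sid!r} has no pixels")
        out.append(float(values[sel].sum()))
    return np.asarray(out)


def quantify(
    signal: np.ndarray,
    curve: StandardCurve,
    region_labels: np.ndarray | None = None,
) -> dict:
    """Back-calculate ng/pixel through a fitted standard curve.

    ng = (signal - intercept) / slope, clipped at 0 (clipped pixels are
    counted); pixels whose back-calculated amount falls outside the fitted
    amount range are flagged as extrapolated.  With ``region_labels``,
    per-region mean +/- SEM tables are included.
    """
    if curve.slope <= 0:
        raise ValueError("standard-curve slope must be positive")
    signal = np.asarray(signal, dtype=np.float64)
    ng = (signal - curve.intercept) / curve.slope
    clipped = ng < 0
    ng = np.clip(ng, 0.0, None)
    lo, hi = curve.amounts[0], curve.amounts[-1]
    extrapolated = (ng < lo) | (ng > hi)

    out = {
        "ng_per_pixel": ng,
        "clipped": clipped,
        "extrapolated": extrapolated,
        "n_clipped": int(clipped.sum()),
        "n_extrapolated": int(extrapolated.sum()),
    }
    if region_labels is not None:
        region_labels = np.asarray(region_labels)
        if len(region_labels) != len(signal):
            raise ValueError("region_labels length mismatch")
        rows = []
        for rid in np.unique(region_labels):
            sel = region_labels == rid
            vals = ng[sel]
            sem = float(stats.sem(vals)) if len(vals) > 1 else 0.0
            rows.append((rid, float(vals.mean()), sem, int(sel.sum())))
        out["regions"] = pd.DataFrame(
            rows, columns=["region", "mean_ng", "sem_ng", "n_pixels"]
        )
    return out
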