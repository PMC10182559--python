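"""Lock-mass recalibration, panel peak integration, TIC normalization.

The stage that turns a centroided :class:`~glycoscape.msi_io.MSIDataset`
into a pixels x features :class:`FeatureMatrix`:

1. ``recalibrate`` — estimate the slow mass-axis drift from a known lock
   mass, pooled over scan-index bins, and undo it.
2. ``integrate_panel`` — sum centroid intensities inside a narrow window
   (full width < 1 Da) around each panel target.
3. ``tic_normalize`` — divide each pixel's row by its total ion current.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .carbo_masses import DEFAULT_LOCK_MZ, PeakPanel
from .msi_io import MSIDataset

__all__ = [
    "RecalibrationConfig",
    "FeatureMatrix",
    "recalibrate",
    "integrate_panel",
    "tic_normalize",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecalibrationConfig:
    """Lock-mass QC and drift-pooling parameters.

    Defaults follow the acquisition settings of the source workflow: lock
    mass 1257.4296, tolerance 1 amu, minimum lock-peak intensity 100,000
    counts.  ``time_bin`` is the scan-index span pooled into one shift
    estimate.
    """

    lock_mz: float = DEFAULT_LOCK_MZ
    tolerance: float = 1.0
    min_counts: float = 100_000.0
    time_bin: int = 50

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.min_counts < 0:
            raise ValueError("min_counts must be >= 0")
        if self.time_bin < 1:
            raise ValueError("time_bin must be >= 1")


@dataclass
class FeatureMatrix:
    """Pixels x panel features with per-pixel TIC and normalization state.

    ``values`` rows follow ``frame`` (x, y, scan_index) order; columns are
    the panel's nominal integer labels as strings.
    """

    values: pd.DataFrame
    tic: np.ndarray
    frame: pd.DataFrame
    panel: PeakPanel
    normalized: bool = False
    flagged_empty: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.frame):
            raise ValueError("values and frame disagree on pixel count")
        if len(self.tic) != len(self.values):
            raise ValueError("tic length mismatch")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative feature values")

    @property
    def n_pixels(self) -> int:
        return len(self.values)

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy()

    def matrix_feature_columns(self) -> list[str]:
        return [str(self.panel.entries[i].nominal)
                for i in self.panel.by_class("matrix")]

    def class_columns(self, feature_class: str) -> list[str]:
        return [str(self.panel.entries[i].nominal)
                for i in self.panel.by_class(feature_class)]


def recalibrate(
    ds: MSIDataset, cfg: RecalibrationConfig | None = None
) -> tuple[MSIDataset, pd.DataFrame]:
    """Undo slow mass drift using the lock-mass ion.

    For each scan-index bin, the shift is the median of (observed lock m/z −
    lock m/z) over pixels whose lock peak passes QC: intensity >=
    ``min_counts`` and |Δm/z| <= ``tolerance``.  Every spectrum in the bin is
    shifted by −shift.  Bins with no qualifying pixel inherit the nearest
    qualifying bin's shift (logged).  Returns the corrected dataset and the
    per-bin shift table.
    """
    if cfg is None:
        cfg = RecalibrationConfig()
    n = ds.n_pixels
    bins = ds.scan_index // cfg.time_bin
    n_bins = int(bins.max()) + 1 if n else 0

    # per-pixel observed lock m/z: the most intense qualifying centroid
    deltas = np.full(n, np.nan)
    for i in range(n):
        mz, it = ds.mzs[i], ds.intensities[i]
        near = np.abs(mz - cfg.lock_mz) <= cfg.tolerance
        ok = near & (it >= cfg.min_counts)
        if ok.any():
            j = np.flatnonzero(ok)[np.argmax(it[ok])]
            deltas[i] = mz[j] - cfg.lock_mz

    shifts = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = (bins == b) & ~np.isnan(deltas)
        counts[b] = int(sel.sum())
        if counts[b]:
            shifts[b] = float(np.median(deltas[sel]))

    if np.isnan(shifts).all():
        raise ValueError(
            "cannot calibrate: no pixel has a qualifying lock-mass peak "
            f"(>= {cfg.min_counts:g} counts within {cfg.tolerance} Da of "
            f"{cfg.lock_mz})"
        )
    missing = np.flatnonzero(np.isnan(shifts))
    if missing.size:
        good = np.flatnonzero(~np.isnan(shifts))
        for b in missing:
            nearest = good[np.argmin(np.abs(good - b))]
            shifts[b] = shifts[nearest]
        log.info(
            "recalibrate: %d/%d bins had no qualifying lock peak; "
            "inherited nearest-bin shifts", missing.size, n_bins,
        )

    new_mzs = [ds.mzs[i] - shifts[bins[i]] for i in range(n)]
    out = MSIDataset(
        coords=ds.coords.copy(),
        scan_index=ds.scan_index.copy(),
        mzs=new_mzs,
        intensities=[it.copy() for it in ds.intensities],
        metadata={**ds.metadata, "recalibrated": True,
                  "lock_mz": cfg.lock_mz},
    )
    table = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "scan_start": np.arange(n_bins) * cfg.time_bin,
            "shift_da": shifts,
            "n_pixels_used": counts,
        }
    )
    return out, table


def integrate_panel(ds: MSIDataset, panel: PeakPanel) -> FeatureMatrix:
    """Sum centroid intensity inside each panel target's window, per pixel.

    value(pixel, feature) = Σ intensity of centroids with
    |m/z − target| <= window_halfwidth.  The TIC is the sum over the *full*
    spectrum, panel or not.  Pixels with empty spectra get a zero row and
    are flagged.
    """
    targets = np.asarray(panel.target_mzs)
    hw = panel.window_halfwidth
    cols = [str(lbl) for lbl in panel.nominal_labels]
    n = ds.n_pixels

    values = np.zeros((n, len(targets)))
    tic = np.zeros(n)
    flagged: list[int] = []
    for i in range(n):
        mz, it = ds.mzs[i], ds.intensities[i]
        if len(mz) == 0:
            flagged.append(i)
            continue
        tic[i] = it.sum()
        lo = np.searchsorted(mz, targets - hw, side="left")
        hi = np.searchsorted(mz, targets + hw, side="right")
        csum = np.concatenate(([0.0], np.cumsum(it)))
        values[i] = csum[hi] - csum[lo]

    frame = pd.DataFrame(
        {"x": ds.coords[:, 0], "y": ds.coords[:, 1],
         "scan_index": ds.scan_index}
    )
    if flagged:
        log.warning("integrate_panel: %d empty-spectrum pixels flagged",
                    len(flagged))
    return FeatureMatrix(
        values=pd.DataFrame(values, columns=cols),
        tic=tic,
        frame=frame,
        panel=panel,
        normalized=False,
        flagged_empty=flagged,
    )


def tic_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide each pixel's feature row by that pixel's total ion current.

    Pixels with TIC = 0 are dropped (and counted in the log).  Normalizing
    twice is rejected.
    """
    if fm.normalized:
        raise ValueError("feature matrix is already TIC-normalized")
    keep = fm.tic > 0
    dropped = int((~keep).sum())
    if dropped:
        log.info("tic_normalize: dropped %d zero-TIC pixels", dropped)
    values = fm.values.loc[keep].reset_index(drop=True)
    tic = fm.tic[keep]
    frame = fm.frame.loc[keep].reset_index(drop=True)
    normalized = values.div(tic, axis=0)
    return FeatureMatrix(
        values=normalized,
        tic=tic,
        frame=frame,
        panel=fm.panel,
        normalized=True,
        flagged_empty=[],
    )
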