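"""Synthetic MSI phantoms with known ground truth.

A phantom is a virtual slide: a rectangular pixel grid covered by disjoint
tissue regions (rectangles/ellipses), each carrying a per-feature mean
intensity signature, surrounded by an off-tissue matrix border.  Spectra are
centroided peak lists built from a peak panel:

* intensity = signature mean x lognormal(mean 1, cv) multiplicative noise
* observed m/z = theoretical target m/z + drift(scan index)
* a lock-mass peak well above the QC threshold is emitted in every pixel
* off-tissue pixels carry matrix-class peaks plus a small, configurable
  carbohydrate bleed-through so that matrix-cluster detection is nontrivial

The noiseless limit (cv = 0, drift = 0) is exactly region-piecewise-constant,
which downstream tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .carbo_masses import DEFAULT_LOCK_MZ, PeakPanel, build_default_panel
from .msi_io import MSIDataset

__all__ = [
    "RegionSpec",
    "PhantomConfig",
    "PhantomTruth",
    "drift",
    "make_phantom",
    "make_standard_spots",
    "default_config",
    "MATRIX_REGION_ID",
    "DEFAULT_SPOT_AMOUNTS",
]

#: Region id reserved for off-tissue (matrix) pixels.
MATRIX_REGION_ID = 0

#: Spotted standard amounts (ng) used for on-slide calibration.
DEFAULT_SPOT_AMOUNTS = (1.0, 10.0, 20.0, 40.0, 100.0, 1000.0)

MASS_RANGE = (500.0, 3000.0)

#: Intensity of the always-present lock-mass peak; above the 100,000-count
#: lock QC threshold but small next to the off-tissue CHCA signal, so matrix
#: pixels stay matrix-dominated even though the lock ion falls inside the
#: Hex5HexNAc2 panel window.
LOCK_INTENSITY = 150_000.0

#: Per-feature CHCA mean off tissue; matrix ions dominate bare-slide spectra.
MATRIX_MEAN = 200_000.0

#: Small per-feature CHCA signal on tissue (matrix is sprayed everywhere).
TISSUE_MATRIX_MEAN = 1_000.0


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned rectangle or ellipse mask on the pixel grid.

    Rectangles: (x0, y0, width, height), inclusive of x0..x0+w-1.
    Ellipses: (cx, cy, rx, ry) with membership ((x-cx)/rx)^2+((y-cy)/ry)^2 <= 1.
    """

    region_id: int
    shape: Literal["rect", "ellipse"]
    params: tuple[float, float, float, float]
    signature_id: str

    def mask(self, width: int, height: int) -> np.ndarray:
        xs, ys = np.meshgrid(np.arange(width), np.arange(height))
        if self.shape == "rect":
            x0, y0, w, h = self.params
            return (xs >= x0) & (xs < x0 + w) & (ys >= y0) & (ys < y0 + h)
        if self.shape == "ellipse":
            cx, cy, rx, ry = self.params
            return ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0
        raise ValueError(f"unknown region shape {self.shape!r}")


@dataclass
class PhantomConfig:
    grid_width: int = 40
    grid_height: int = 40
    regions: tuple[RegionSpec, ...] = ()
    signatures: dict[str, dict[str, float]] = field(default_factory=dict)
    matrix_border_width: int = 4
    noise_cv: float = 0.1
    drift_amplitude: float = 0.0
    drift_period: float = 0.0
    drift_shape: str = "linear"
    bleed_fraction: float = 0.02
    lock_mz: float = DEFAULT_LOCK_MZ
    seed: int = 0

    def validate(self, panel: PeakPanel) -> None:
        if self.grid_width < 1 or self.grid_height < 1:
            raise ValueError("grid dimensions must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.drift_amplitude < 0:
            raise ValueError("drift_amplitude must be >= 0")
        if self.drift_amplitude >= 1.0:
            raise ValueError(
                "drift_amplitude must stay below the 1 Da lock-mass tolerance"
            )
        if not (0 <= self.bleed_fraction <= 0.02):
            raise ValueError("bleed_fraction must lie in [0, 0.02]")
        if not self.regions:
            raise ValueError("phantom needs at least one tissue region")
        masks = []
        for r in self.regions:
            m = r.mask(self.grid_width, self.grid_height)
            if not m.any():
                raise ValueError(f"region {r.region_id} is empty")
            if r.region_id == MATRIX_REGION_ID:
                raise ValueError(
                    f"region_id {MATRIX_REGION_ID} is reserved for matrix"
                )
            if r.signature_id not in self.signatures:
                raise ValueError(
                    f"region {r.region_id}: unknown signature "
                    f"{r.signature_id!r}"
                )
            masks.append(m)
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region_id")
        union = np.zeros((self.grid_height, self.grid_width), dtype=int)
        for m in masks:
            union += m
        if (union > 1).any():
            ys, xs = np.nonzero(union > 1)
            raise ValueError(
                f"overlapping region masks at (x={xs[0]}, y={ys[0]})"
            )
        for sid, sig in self.signatures.items():
            for label, mean in sig.items():
                if mean < 0:
                    raise ValueError(
                        f"signature {sid!r}: negative mean for {label!r}"
                    )


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a phantom dataset."""

    label_map: np.ndarray                     # (h, w) region ids, matrix = 0
    signature_table: dict[str, dict[str, float]]
    region_signature: dict[int, str]          # region_id -> signature_id
    drift_offsets: np.ndarray                 # per scan index, Da
    spot_amounts: dict[int, float] = field(default_factory=dict)  # region -> ng

    def labels_for(self, coords: np.ndarray) -> np.ndarray:
        return self.label_map[coords[:, 1], coords[:, 0]]


def drift(
    scan_index,
    amplitude: float,
    period: float,
    shape: str = "linear",
):
    """Mass-axis drift offset (Da) as a smooth function of scan index.

    ``linear`` ramps 0 -> amplitude over ``period`` scans; ``sinusoid`` is
    amplitude x sin(2*pi*t/period); ``constant`` is amplitude everywhere.
    Bounded by |offset| <= amplitude.
    """
    t = np.asarray(scan_index, dtype=np.float64)
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if shape not in ("linear", "sinusoid", "constant"):
        raise ValueError(f"unknown drift shape {shape!r}")
    if amplitude == 0:
        out = np.zeros_like(t)
    elif shape == "constant":
        out = np.full_like(t, amplitude)
    elif shape == "linear":
        if period <= 0:
            raise ValueError("linear drift needs period > 0 (ramp length)")
        out = amplitude * np.clip(t / period, 0.0, 1.0)
    elif shape == "sinusoid":
        if period <= 0:
            raise ValueError("sinusoid drift needs period > 0")
        out = amplitude * np.sin(2 * math.pi * t / period)
    else:
        raise ValueError(f"unknown drift shape {shape!r}")
    return out if out.ndim else float(out)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    mu = -sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def _signature_vector(
    signature: dict[str, float], panel: PeakPanel
) -> np.ndarray:
    """Expand a label->mean mapping onto the panel's feature order.

    Labels may be panel entry labels (``DP7``, ``Hex5HexNAc4dHex1``,
    ``CHCA_779``) or nominal integer m/z labels as strings.
    """
    by_label = {e.label: i for i, e in enumerate(panel.entries) if e.label}
    by_nominal = {str(e.nominal): i for i, e in enumerate(panel.entries)}
    vec = np.zeros(len(panel))
    for label, mean in signature.items():
        if label in by_label:
            vec[by_label[label]] = mean
        elif label in by_nominal:
            vec[by_nominal[label]] = mean
        else:
            raise ValueError(f"signature refers to unknown feature {label!r}")
    return vec


def _matrix_signature(panel: PeakPanel, mean: float = MATRIX_MEAN) -> np.ndarray:
    vec = np.zeros(len(panel))
    vec[panel.by_class("matrix")] = mean
    return vec


def make_phantom(
    config: PhantomConfig, panel: PeakPanel | None = None
) -> tuple[MSIDataset, PhantomTruth]:
    """Render a phantom slide to a centroided dataset plus its ground truth.

    Scan order is row-major (y outer, x inner), mimicking a raster
    acquisition, so slow drift in scan index is also slow in y.
    """
    if panel is None:
        panel = build_default_panel()
    config.validate(panel)

    w, h = config.grid_width, config.grid_height
    label_map = np.full((h, w), MATRIX_REGION_ID, dtype=np.int64)
    sig_vectors: dict[int, np.ndarray] = {}
    region_signature: dict[int, str] = {}
    for r in config.regions:
        m = r.mask(w, h)
        label_map[m] = r.region_id
        sig_vectors[r.region_id] = _signature_vector(
            config.signatures[r.signature_id], panel
        )
        region_signature[r.region_id] = r.signature_id

    matrix_vec = _matrix_signature(panel)
    if config.bleed_fraction > 0 and sig_vectors:
        # faint carbohydrate bleed-through on off-tissue pixels
        carb = np.mean(list(sig_vectors.values()), axis=0)
        carb[panel.by_class("matrix")] = 0.0
        matrix_vec = matrix_vec + config.bleed_fraction * carb
    sig_vectors[MATRIX_REGION_ID] = matrix_vec

    rng = np.random.default_rng(config.seed)
    target_mz = np.asarray(panel.target_mzs)

    coords = []
    scan_order = []
    idx = 0
    for y in range(h):
        for x in range(w):
            coords.append((x, y))
            scan_order.append(idx)
            idx += 1
    coords = np.asarray(coords, dtype=np.int64)
    scan_order = np.asarray(scan_order, dtype=np.int64)
    n = len(coords)

    offsets = np.asarray(
        drift(
            np.arange(n),
            config.drift_amplitude,
            config.drift_period if config.drift_period > 0 else max(n - 1, 1),
            config.drift_shape,
        )
    )

    mzs: list[np.ndarray] = []
    intensities: list[np.ndarray] = []
    for i in range(n):
        x, y = coords[i]
        region = label_map[y, x]
        mean_vec = sig_vectors[int(region)]
        noise = _lognormal_factors(rng, config.noise_cv, len(mean_vec))
        vals = mean_vec * noise
        keep = vals > 0
        mz = target_mz[keep] + offsets[scan_order[i]]
        it = vals[keep]
        # lock-mass reference ion, always present and above QC threshold
        mz = np.append(mz, config.lock_mz + offsets[scan_order[i]])
        it = np.append(it, LOCK_INTENSITY)
        order = np.argsort(mz, kind="stable")
        mzs.append(mz[order])
        intensities.append(it[order])

    ds = MSIDataset(
        coords=coords,
        scan_index=scan_order,
        mzs=mzs,
        intensities=intensities,
        metadata={
            "step_um": 75,
            "mass_range": list(MASS_RANGE),
            "mode": "processed",
            "lock_mz": config.lock_mz,
        },
    )
    truth = PhantomTruth(
        label_map=label_map,
        signature_table=config.signatures,
        region_signature=region_signature,
        drift_offsets=offsets,
    )
    return ds, truth


def make_standard_spots(
    amounts: Sequence[float] = DEFAULT_SPOT_AMOUNTS,
    response_slope: float = 50.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    spot_size: int = 3,
    dp_range: tuple[int, int] = (3, 14),
    panel: PeakPanel | None = None,
) -> tuple[MSIDataset, PhantomTruth]:
    """Virtual calibration spots: one square ROI per spotted amount.

    The per-spot *summed* DP-ladder signal is amount x response_slope
    (counts per ng) in expectation, spread uniformly over the spot's pixels
    and across the DP ladder with a fixed unimodal chain-length profile.
    """
    amounts = [float(a) for a in amounts]
    if any(a <= 0 for a in amounts):
        raise ValueError("spot amounts must be positive")
    if any(b <= a for a, b in zip(amounts, amounts[1:])):
        raise ValueError("spot amounts must be strictly increasing")
    if response_slope <= 0:
        raise ValueError("response_slope must be positive")
    if panel is None:
        panel = build_default_panel(dp_min=dp_range[0], dp_max=dp_range[1])

    dp_cols = panel.by_class("glycogen_dp")
    if not dp_cols:
        raise ValueError("panel has no glycogen_dp features")
    n_dp = len(dp_cols)
    # fixed unimodal DP profile peaking mid-ladder, normalized to sum 1
    prof = np.exp(-0.5 * ((np.arange(n_dp) - (n_dp - 1) / 2) / (n_dp / 4)) ** 2)
    prof /= prof.sum()

    rng = np.random.default_rng(seed)
    target_mz = np.asarray(panel.target_mzs)
    gap = 2
    w = len(amounts) * (spot_size + gap) + gap
    h = spot_size + 2 * gap

    label_map = np.full((h, w), MATRIX_REGION_ID, dtype=np.int64)
    spot_amounts: dict[int, float] = {}
    coords, mzs, its = [], [], []
    px_per_spot = spot_size * spot_size

    for y in range(h):
        for x in range(w):
            coords.append((x, y))
    coords = np.asarray(coords, dtype=np.int64)

    for k, amount in enumerate(amounts):
        rid = k + 1
        x0 = gap + k * (spot_size + gap)
        label_map[gap : gap + spot_size, x0 : x0 + spot_size] = rid
        spot_amounts[rid] = amount

    for x, y in coords:
        rid = int(label_map[y, x])
        vec = np.zeros(len(panel))
        if rid != MATRIX_REGION_ID:
            amount = spot_amounts[rid]
            per_pixel = amount * response_slope / px_per_spot
            vec[dp_cols] = per_pixel * prof
        else:
            vec = _matrix_signature(panel, mean=5_000.0)
        vec = vec * _lognormal_factors(rng, noise_cv, len(vec))
        keep = vec > 0
        mz = np.append(target_mz[keep], DEFAULT_LOCK_MZ)
        it = np.append(vec[keep], LOCK_INTENSITY)
        order = np.argsort(mz, kind="stable")
        mzs.append(mz[order])
        its.append(it[order])

    ds = MSIDataset(
        coords=coords,
        scan_index=np.arange(len(coords)),
        mzs=mzs,
        intensities=its,
        metadata={"step_um": 75, "mode": "processed", "kind": "standard_spots"},
    )
    truth = PhantomTruth(
        label_map=label_map,
        signature_table={},
        region_signature={},
        drift_offsets=np.zeros(len(coords)),
        spot_amounts=spot_amounts,
    )
    return ds, truth


def default_config(
    noise_cv: float = 0.1,
    drift_amplitude: float = 0.0,
    seed: int = 0,
    grid: tuple[int, int] = (40, 40),
    fibrotic_glycogen_fold: float = 2.4,
    panel: PeakPanel | None = None,
) -> PhantomConfig:
    """Three-region demo phantom: normal tissue, fibrotic tissue, airway.

    The fibrotic signature scales every glycogen DP feature by
    ``fibrotic_glycogen_fold`` over normal and carries elevated
    core-fucosylated N-glycans; the airway region is glycogen-poor.
    """
    if panel is None:
        panel = build_default_panel()
    w, h = grid
    b = 5  # matrix border width

    dp_labels = [panel.entries[i].label for i in panel.by_class("glycogen_dp")]
    ng_labels = [panel.entries[i].label for i in panel.by_class("nglycan")]
    fuc_labels = [
        panel.entries[i].label
        for i in panel.by_class("nglycan")
        if panel.entries[i].composition and panel.entries[i].composition.n_dhex
    ]

    mx_labels = [panel.entries[i].label for i in panel.by_class("matrix")]

    normal = {lab: 10_000.0 for lab in dp_labels}
    normal.update({lab: 8_000.0 for lab in ng_labels})
    fibrotic = {lab: 10_000.0 * fibrotic_glycogen_fold for lab in dp_labels}
    fibrotic.update({lab: 8_000.0 for lab in ng_labels})
    fibrotic.update({lab: 24_000.0 for lab in fuc_labels})
    airway = {lab: 1_500.0 for lab in dp_labels}
    airway.update({lab: 12_000.0 for lab in ng_labels})
    for sig in (normal, fibrotic, airway):
        sig.update({lab: TISSUE_MATRIX_MEAN for lab in mx_labels})

    # left/right tissue rectangles with a central channel holding the airway
    # ellipse; the three masks are pairwise disjoint by construction
    gap_half = max(3, w // 12)
    left_w = (w - 2 * b - 2 * gap_half) // 2
    regions = (
        RegionSpec(1, "rect", (b, b, left_w, h - 2 * b), "normal"),
        RegionSpec(
            2, "rect", (w - b - left_w, b, left_w, h - 2 * b), "fibrotic"
        ),
        RegionSpec(
            3,
            "ellipse",
            (w / 2 - 0.5, h / 2 - 0.5, gap_half - 1, (h - 2 * b) / 2 - 1),
            "airway",
        ),
    )
    return PhantomConfig(
        grid_width=w,
        grid_height=h,
        regions=regions,
        signatures={"normal": normal, "fibrotic": fibrotic, "airway": airway},
        matrix_border_width=b,
        noise_cv=noise_cv,
        drift_amplitude=drift_amplitude,
        drift_shape="linear",
        seed=seed,
    )
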