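"""Readers and writers for the formats the pipeline touches.

Coordinate convention everywhere: 0-based integer grid, x is the column
(left to right), y is the row (top to bottom).  Rasters are indexed
``[y, x]``.

The on-disk native form is imzML *processed* mode (per-pixel centroided
peak lists).  The reader/writer here is a deliberately small, standalone
implementation of that subset of the imzML 1.1 standard: continuous-mode
files and vendor extensions are out of scope.
"""

from __future__ import annotations

import hashlib
import json
import struct
import uuid as _uuid
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MSIDataset",
    "read_imzml",
    "write_imzml",
    "read_pixel_table",
    "write_pixel_table",
    "write_label_map",
    "read_label_map_csv",
]


@dataclass
class MSIDataset:
    """Pixel grid with coordinates, acquisition order, and centroid spectra.

    Attributes
    ----------
    coords : (n, 2) int array of (x, y) pairs, unique per pixel.
    scan_index : (n,) int array; a permutation of 0..n-1 giving acquisition
        order (pixel i was the scan_index[i]-th scan).
    mzs, intensities : per-pixel float arrays, m/z ascending.
    metadata : step size (um), mass range (Da), mode, free-form extras.
    """

    coords: np.ndarray
    scan_index: np.ndarray
    mzs: list[np.ndarray]
    intensities: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.scan_index = np.asarray(self.scan_index, dtype=np.int64)
        n = len(self.coords)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array of (x, y)")
        if len(self.scan_index) != n:
            raise ValueError("scan_index length mismatch")
        if len(self.mzs) != n or len(self.intensities) != n:
            raise ValueError("spectrum list length mismatch")
        seen = set(map(tuple, self.coords))
        if len(seen) != n:
            raise ValueError("duplicate (x, y) coordinates")
        if sorted(self.scan_index) != list(range(n)):
            raise ValueError("scan_index must be a permutation of 0..n-1")
        for i in range(n):
            mz = np.asarray(self.mzs[i], dtype=np.float64)
            it = np.asarray(self.intensities[i], dtype=np.float64)
            if mz.shape != it.shape:
                raise ValueError(f"pixel {i}: m/z and intensity length differ")
            if np.any(np.diff(mz) <= 0):
                raise ValueError(f"pixel {i}: m/z values not strictly ascending")
            if np.any(it < 0):
                raise ValueError(f"pixel {i}: negative intensity")
            self.mzs[i] = mz
            self.intensities[i] = it

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the bounding grid."""
        return (
            int(self.coords[:, 1].max()) + 1,
            int(self.coords[:, 0].max()) + 1,
        )

    def pixel_frame(self) -> pd.DataFrame:
        """x, y, scan_index table in canonical (y, x) order."""
        df = pd.DataFrame(
            {
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "scan_index": self.scan_index,
            }
        )
        return df.sort_values(["y", "x"], kind="stable").reset_index(drop=True)

    def content_hash(self) -> str:
        """SHA-256 over coordinates and spectra; used by idempotence checks."""
        h = hashlib.sha256()
        h.update(self.coords.tobytes())
        h.update(self.scan_index.tobytes())
        for mz, it in zip(self.mzs, self.intensities):
            h.update(mz.tobytes())
            h.update(it.tobytes())
        return h.hexdigest()


_CV = "{http://psi.hupo.org/ms/mzml}"
_NS = {"mz": "http://psi.hupo.org/ms/mzml"}

_IMZML_TEMPLATE_HEAD = """\
<?xml version="1.0" encoding="UTF-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="IMS" fullName="Imaging MS Ontology" URI="https://ms-imaging.org/wp/wp-content/uploads/2009/08/imagingMS.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="IMS" accession="IMS:1000031" name="processed" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000080" name="universally unique identifier" value="{uuid}"/>
      <cvParam cvRef="IMS" accession="IMS:1000091" name="ibd SHA-256" value="{sha256}"/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <referenceableParamGroupList count="2">
    <referenceableParamGroup id="mzArray">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000101" name="external data" value="true"/>
    </referenceableParamGroup>
    <referenceableParamGroup id="intensityArray">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000101" name="external data" value="true"/>
    </referenceableParamGroup>
  </referenceableParamGroupList>
  <scanSettingsList count="1">
    <scanSettings id="scanSettings1">
      <cvParam cvRef="IMS" accession="IMS:1000042" name="max count of pixels x" value="{max_x}"/>
      <cvParam cvRef="IMS" accession="IMS:1000043" name="max count of pixels y" value="{max_y}"/>
      <cvParam cvRef="IMS" accession="IMS:1000046" name="pixel size (x)" value="{step_um}"/>
      <userParam name="glycoscape:metadata" value="{meta_json}"/>
    </scanSettings>
  </scanSettingsList>
  <run id="run1">
    <spectrumList count="{n}">
"""

_IMZML_SPECTRUM = """\
      <spectrum id="spectrum={idx}" index="{idx}" defaultArrayLength="{length}">
        <scanList count="1">
          <scan>
            <cvParam cvRef="IMS" accession="IMS:1000050" name="position x" value="{px}"/>
            <cvParam cvRef="IMS" accession="IMS:1000051" name="position y" value="{py}"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="0">
            <referenceableParamGroupRef ref="mzArray"/>
            <cvParam cvRef="IMS" accession="IMS:1000103" name="external array length" value="{length}"/>
            <cvParam cvRef="IMS" accession="IMS:1000102" name="external offset" value="{mz_offset}"/>
            <binary/>
          </binaryDataArray>
          <binaryDataArray encodedLength="0">
            <referenceableParamGroupRef ref="intensityArray"/>
            <cvParam cvRef="IMS" accession="IMS:1000103" name="external array length" value="{length}"/>
            <cvParam cvRef="IMS" accession="IMS:1000102" name="external offset" value="{it_offset}"/>
            <binary/>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_IMZML_TAIL = """\
    </spectrumList>
  </run>
</mzML>
"""


def write_imzml(ds: MSIDataset, path: str | Path) -> None:
    """Write an imzML (processed mode) + .ibd pair.

    imzML stores 1-based pixel positions; the dataset's 0-based (x, y) are
    shifted on write and back on read.  Spectra are written in scan order so
    acquisition order survives the round trip.
    """
    path = Path(path)
    if path.suffix.lower() != ".imzml":
        path = path.with_suffix(".imzML")
    ibd_path = path.with_suffix(".ibd")

    order = np.argsort(ds.scan_index, kind="stable")
    # content-derived UUID keeps writes bit-reproducible for identical data
    uid = _uuid.UUID(bytes=hashlib.sha256(
        ds.content_hash().encode()).digest()[:16])

    offsets: list[tuple[int, int, int]] = []  # (mz_offset, it_offset, length)
    with open(ibd_path, "wb") as ibd:
        ibd.write(uid.bytes)
        for i in order:
            mz = np.asarray(ds.mzs[i], dtype=np.float64)
            it = np.asarray(ds.intensities[i], dtype=np.float64)
            mz_off = ibd.tell()
            ibd.write(mz.tobytes())
            it_off = ibd.tell()
            ibd.write(it.tobytes())
            offsets.append((mz_off, it_off, len(mz)))
    sha256 = hashlib.sha256(ibd_path.read_bytes()).hexdigest()

    meta = dict(ds.metadata)
    meta_json = json.dumps(meta, sort_keys=True).replace('"', "&quot;")
    parts = [
        _IMZML_TEMPLATE_HEAD.format(
            uuid=str(uid),
            sha256=sha256,
            max_x=int(ds.coords[:, 0].max()) + 1,
            max_y=int(ds.coords[:, 1].max()) + 1,
            step_um=meta.get("step_um", 75),
            meta_json=meta_json,
            n=ds.n_pixels,
        )
    ]
    for idx, i in enumerate(order):
        mz_off, it_off, length = offsets[idx]
        parts.append(
            _IMZML_SPECTRUM.format(
                idx=idx,
                length=length,
                px=int(ds.coords[i, 0]) + 1,
                py=int(ds.coords[i, 1]) + 1,
                mz_offset=mz_off,
                it_offset=it_off,
            )
        )
    parts.append(_IMZML_TAIL)
    path.write_text("".join(parts))


def _cv_params(elem: ET.Element) -> dict[str, str]:
    out = {}
    for cv in elem.findall(f"{_CV}cvParam"):
        out[cv.get("name", "")] = cv.get("value", "")
    return out


def read_imzml(path: str | Path) -> MSIDataset:
    """Read a processed-mode imzML/.ibd pair written by :func:`write_imzml`.

    Verifies the binary file's UUID (and SHA-256 when recorded) against the
    XML before touching spectra; a mismatch is rejected naming the .ibd file.
    """
    path = Path(path)
    ibd_path = path.with_suffix(".ibd")
    if not path.exists():
        raise FileNotFoundError(path)
    if not ibd_path.exists():
        raise FileNotFoundError(f"missing binary companion {ibd_path}")

    tree = ET.parse(path)
    root = tree.getroot()
    content = root.find(f"{_CV}fileDescription/{_CV}fileContent")
    if content is None:
        raise ValueError(f"{path}: missing fileContent element")
    fc = _cv_params(content)
    if "processed" not in fc:
        raise ValueError(f"{path}: only processed-mode imzML is supported")

    ibd_bytes = ibd_path.read_bytes()
    declared_uuid = fc.get("universally unique identifier", "")
    if declared_uuid:
        actual = str(_uuid.UUID(bytes=ibd_bytes[:16]))
        if actual != declared_uuid.strip("{}").lower():
            raise ValueError(
                f"{ibd_path}: UUID mismatch (imzML declares {declared_uuid}, "
                f"binary holds {actual})"
            )
    declared_sha = fc.get("ibd SHA-256", "")
    if declared_sha:
        actual_sha = hashlib.sha256(ibd_bytes).hexdigest()
        if actual_sha != declared_sha.lower():
            raise ValueError(
                f"{ibd_path}: SHA-256 checksum mismatch against imzML header"
            )

    meta: dict = {}
    up = root.find(f".//{_CV}scanSettings/{_CV}userParam[@name='glycoscape:metadata']")
    if up is not None:
        meta = json.loads(up.get("value", "{}").replace("&quot;", '"'))

    coords: list[tuple[int, int]] = []
    mzs: list[np.ndarray] = []
    its: list[np.ndarray] = []
    skipped = 0
    for spec in root.iterfind(f".//{_CV}spectrum"):
        scan = spec.find(f".//{_CV}scan")
        if scan is None:
            skipped += 1
            continue
        sp = _cv_params(scan)
        try:
            px = int(sp["position x"]) - 1
            py = int(sp["position y"]) - 1
        except KeyError:
            skipped += 1
            continue
        arrays = {}
        for bda in spec.iterfind(f".//{_CV}binaryDataArray"):
            ref = bda.find(f"{_CV}referenceableParamGroupRef")
            kind = ref.get("ref") if ref is not None else None
            bp = _cv_params(bda)
            offset = int(bp["external offset"])
            length = int(bp["external array length"])
            raw = ibd_bytes[offset : offset + 8 * length]
            if len(raw) != 8 * length:
                raise ValueError(
                    f"{ibd_path}: truncated array at offset {offset} "
                    f"(wanted {8 * length} bytes)"
                )
            arrays[kind] = np.frombuffer(raw, dtype=np.float64).copy()
        if "mzArray" not in arrays or "intensityArray" not in arrays:
            skipped += 1
            continue
        coords.append((px, py))
        mzs.append(arrays["mzArray"])
        its.append(arrays["intensityArray"])
    if skipped:
        meta = dict(meta)
        meta["skipped_spectra"] = skipped

    n = len(coords)
    ds = MSIDataset(
        coords=np.array(coords, dtype=np.int64).reshape(n, 2),
        scan_index=np.arange(n),
        mzs=mzs,
        intensities=its,
        metadata=meta,
    )
    return ds


def write_pixel_table(
    values: pd.DataFrame, frame: pd.DataFrame, path: str | Path
) -> None:
    """CSV export: x, y, scan_index, then feature columns (nominal labels)."""
    if len(values) != len(frame):
        raise ValueError("values and pixel frame disagree on pixel count")
    out = pd.concat(
        [frame[["x", "y", "scan_index"]].reset_index(drop=True),
         values.reset_index(drop=True)],
        axis=1,
    )
    out = out.sort_values(["y", "x"], kind="stable")
    out.to_csv(path, index=False)


def read_pixel_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a pixel-table CSV into (feature values, coordinate frame).

    Strict: the header must start with x, y, scan_index; missing or
    non-numeric cells and duplicate coordinates are rejected with locations.
    Rows are returned in canonical (y, x) order regardless of file order.
    """
    df = pd.read_csv(path)
    required = ["x", "y", "scan_index"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"{path}: header must start with {required}, got "
            f"{list(df.columns[:3])}"
        )
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        raise ValueError(
            f"{path}: missing/non-numeric value at row {rows[0] + 2}, "
            f"column {df.columns[cols[0]]!r}"
        )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ValueError(
                f"{path}: non-numeric cell at row {bad[0] + 2}, column {col!r}"
            )
    dup = df.duplicated(subset=["x", "y"])
    if dup.any():
        i = int(np.nonzero(dup.to_numpy())[0][0])
        raise ValueError(
            f"{path}: duplicate coordinate (x={df.iloc[i]['x']:.0f}, "
            f"y={df.iloc[i]['y']:.0f}) at row {i + 2}"
        )
    df = df.sort_values(["y", "x"], kind="stable").reset_index(drop=True)
    frame = df[required].astype(np.int64)
    values = df.drop(columns=required)
    return values, frame


def write_label_map(
    values,
    coords: np.ndarray,
    out_prefix: str | Path,
    categorical: bool | None = None,
    background=np.nan,
) -> Path:
    """Write a per-pixel value map as CSV + PNG raster.

    ``values`` is one value per pixel (cluster ids -> categorical palette,
    floats such as ng/pixel -> continuous colormap; auto-detected from dtype
    unless ``categorical`` is given).  Returns the CSV path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords, dtype=np.int64)
    values = np.asarray(values)
    if len(values) != len(coords):
        raise ValueError(
            f"{len(values)} values for {len(coords)} pixels"
        )
    if categorical is None:
        categorical = np.issubdtype(values.dtype, np.integer)

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = out_prefix.with_suffix(".csv")
    png_path = out_prefix.with_suffix(".png")

    df = pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], "value": values}
    ).sort_values(["y", "x"], kind="stable")
    df.to_csv(csv_path, index=False)

    h = int(coords[:, 1].max()) + 1
    w = int(coords[:, 0].max()) + 1
    raster = np.full((h, w), np.nan)
    raster[coords[:, 1], coords[:, 0]] = values

    fig, ax = plt.subplots(figsize=(max(2, w / 20), max(2, h / 20)))
    if categorical:
        # deterministic palette: tab20 indexed by label id
        cmap = plt.get_cmap("tab20")
        shown = np.ma.masked_invalid(raster)
        ax.imshow(shown % 20, cmap=cmap, vmin=0, vmax=19, interpolation="nearest")
    else:
        im = ax.imshow(raster, cmap="viridis", interpolation="nearest")
        fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.savefig(png_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return csv_path


def read_label_map_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != ["x", "y", "value"]:
        raise ValueError(f"{path}: expected columns x, y, value")
    return df
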