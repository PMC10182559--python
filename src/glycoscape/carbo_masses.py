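"""Composition model and exact mass arithmetic for glucans and N-glycans.

Monoisotopic residue masses for the four monosaccharide building blocks,
sodiated-adduct m/z calculation, the glycogen degree-of-polymerization (DP)
ladder, tolerance-based composition annotation, and the curated peak panel
consumed by the integration stage.

All masses are monoisotopic and in daltons.  Imaging features are named by
their *nominal label*: the integer-truncated (floored) sodiated monoisotopic
m/z.  Flooring, not rounding, is the convention that reproduces the printed
feature names (e.g. 1444.507 -> 1444, 1485.534 -> 1485).
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "MASS_HEX",
    "MASS_HEXNAC",
    "MASS_DHEX",
    "MASS_NEUAC",
    "MASS_WATER",
    "MASS_NA",
    "DEFAULT_LOCK_MZ",
    "GlycanComposition",
    "PanelEntry",
    "PeakPanel",
    "composition_mass",
    "sodiated_mz",
    "nominal_label",
    "dp_ladder",
    "annotate_mz",
    "build_default_panel",
    "parse_composition",
    "format_composition",
    "read_panel_tsv",
    "write_panel_tsv",
    "DEFAULT_NGLYCANS",
    "DEFAULT_MATRIX_MZ",
]

# Monoisotopic residue masses (Da): residue = monosaccharide minus water.
MASS_HEX = 162.052824       # C6H10O5
MASS_HEXNAC = 203.079373    # C8H13NO5
MASS_DHEX = 146.057909      # C6H10O4 (deoxyhexose / fucose)
MASS_NEUAC = 291.095417     # C11H17NO8 (N-acetylneuraminic acid)
MASS_WATER = 18.010565      # H2O
MASS_NA = 22.989218         # Na+ cation, electron mass subtracted

#: Conventional lock-mass value for the Hex5HexNAc2 reference glycan.  This is
#: a user-supplied instrument constant, not a computed mass: it sits ~7 mDa
#: above the theoretical [Hex5HexNAc2+Na]+ of 1257.4226.
DEFAULT_LOCK_MZ = 1257.4296

_RESIDUE_MASSES = {
    "Hex": MASS_HEX,
    "HexNAc": MASS_HEXNAC,
    "dHex": MASS_DHEX,
    "NeuAc": MASS_NEUAC,
}


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Residue-count composition of a glucan chain or an N-glycan.

    ``kind`` is ``"glucan_dp"`` for linear glucose polymers (hexoses only)
    and ``"nglycan"`` otherwise.  Topology is out of scope: a composition is
    just the four counts.
    """

    n_hex: int = 0
    n_hexnac: int = 0
    n_dhex: int = 0
    n_neuac: int = 0
    kind: str = field(default="nglycan", compare=False)

    def __post_init__(self) -> None:
        counts = (self.n_hex, self.n_hexnac, self.n_dhex, self.n_neuac)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative residue count in {counts}")
        if sum(counts) < 1:
            raise ValueError("composition must contain at least one residue")
        if self.kind not in ("glucan_dp", "nglycan"):
            raise ValueError(f"unknown composition kind {self.kind!r}")
        if self.kind == "glucan_dp" and (
            self.n_hexnac or self.n_dhex or self.n_neuac
        ):
            raise ValueError("glucan_dp compositions contain only hexoses")

    @property
    def total_residues(self) -> int:
        return self.n_hex + self.n_hexnac + self.n_dhex + self.n_neuac

    def __str__(self) -> str:
        return format_composition(self)


def composition_mass(comp: GlycanComposition) -> float:
    """Neutral monoisotopic mass in Da: sum of residue masses plus one water."""
    return (
        comp.n_hex * MASS_HEX
        + comp.n_hexnac * MASS_HEXNAC
        + comp.n_dhex * MASS_DHEX
        + comp.n_neuac * MASS_NEUAC
        + MASS_WATER
    )


def sodiated_mz(comp: GlycanComposition) -> float:
    """m/z of the singly sodiated adduct [M+Na]+."""
    return composition_mass(comp) + MASS_NA


def nominal_label(mz: float) -> int:
    """Integer feature label for an m/z value: floor, not round."""
    return math.floor(mz)


def dp_ladder(dp_min: int, dp_max: int) -> list[tuple[int, float]]:
    """Sodiated m/z ladder for linear glucose chains of DP dp_min..dp_max.

    Consecutive rungs are spaced by exactly one hexose residue
    (162.052824 Da).
    """
    if dp_min < 1:
        raise ValueError("dp_min must be >= 1")
    if dp_min > dp_max:
        raise ValueError(f"inverted DP range {dp_min}..{dp_max}")
    return [
        (n, n * MASS_HEX + MASS_WATER + MASS_NA)
        for n in range(dp_min, dp_max + 1)
    ]


#: Composition-lattice search bounds used by :func:`annotate_mz`.  They cover
#: sodiated masses well past the 3000 Da acquisition ceiling.
DEFAULT_BOUNDS = {"Hex": 15, "HexNAc": 8, "dHex": 3, "NeuAc": 4}


def annotate_mz(
    mz: float,
    tolerance_da: float,
    bounds: dict[str, int] | None = None,
    glucan_only: bool = False,
) -> list[tuple[GlycanComposition, float]]:
    """Candidate compositions whose [M+Na]+ m/z is within ``tolerance_da``.

    Exhaustively enumerates the bounded composition lattice and returns
    ``(composition, delta_mz)`` pairs sorted by |delta| then composition.
    An empty list means no candidate, which is not an error.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    if any(v < 0 or not math.isfinite(v) for v in b.values()):
        raise ValueError(f"invalid bounds {b}")
    if glucan_only:
        b = {"Hex": b["Hex"], "HexNAc": 0, "dHex": 0, "NeuAc": 0}

    hits: list[tuple[GlycanComposition, float]] = []
    base = MASS_WATER + MASS_NA
    for nh in range(b["Hex"] + 1):
        m_h = base + nh * MASS_HEX
        if m_h - mz > tolerance_da:
            break
        for nn in range(b["HexNAc"] + 1):
            m_hn = m_h + nn * MASS_HEXNAC
            if m_hn - mz > tolerance_da:
                break
            for nd in range(b["dHex"] + 1):
                m_hnd = m_hn + nd * MASS_DHEX
                if m_hnd - mz > tolerance_da:
                    break
                for ns in range(b["NeuAc"] + 1):
                    m = m_hnd + ns * MASS_NEUAC
                    if m - mz > tolerance_da:
                        break
                    if nh + nn + nd + ns == 0:
                        continue
                    delta = m - mz
                    if abs(delta) <= tolerance_da:
                        kind = (
                            "glucan_dp"
                            if (nn == 0 and nd == 0 and ns == 0)
                            else "nglycan"
                        )
                        hits.append(
                            (GlycanComposition(nh, nn, nd, ns, kind), delta)
                        )
    hits.sort(key=lambda t: (abs(t[1]), t[0]))
    return hits


_COMP_TOKEN = re.compile(r"(Hex(?!NAc)|HexNAc|dHex|NeuAc)(\d+)")


def parse_composition(text: str, kind: str | None = None) -> GlycanComposition:
    """Parse ``Hex5HexNAc4dHex1``-style composition strings."""
    text = text.strip()
    pos = 0
    counts = {"Hex": 0, "HexNAc": 0, "dHex": 0, "NeuAc": 0}
    seen: set[str] = set()
    while pos < len(text):
        m = _COMP_TOKEN.match(text, pos)
        if m is None:
            raise ValueError(f"cannot parse composition {text!r} at offset {pos}")
        name, count = m.group(1), int(m.group(2))
        if name in seen:
            raise ValueError(f"residue {name} repeated in {text!r}")
        seen.add(name)
        counts[name] = count
        pos = m.end()
    if kind is None:
        kind = (
            "glucan_dp"
            if counts["HexNAc"] == counts["dHex"] == counts["NeuAc"] == 0
            else "nglycan"
        )
    return GlycanComposition(
        counts["Hex"], counts["HexNAc"], counts["dHex"], counts["NeuAc"], kind
    )


def format_composition(comp: GlycanComposition) -> str:
    parts = []
    for name, n in (
        ("Hex", comp.n_hex),
        ("HexNAc", comp.n_hexnac),
        ("dHex", comp.n_dhex),
        ("NeuAc", comp.n_neuac),
    ):
        if n:
            parts.append(f"{name}{n}")
    return "".join(parts)


VALID_CLASSES = ("matrix", "glycogen_dp", "nglycan")


@dataclass(frozen=True)
class PanelEntry:
    target_mz: float
    feature_class: str  # matrix | glycogen_dp | nglycan
    composition: GlycanComposition | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.feature_class not in VALID_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.target_mz <= 0:
            raise ValueError("target m/z must be positive")

    @property
    def nominal(self) -> int:
        return nominal_label(self.target_mz)


@dataclass(frozen=True)
class PeakPanel:
    """Curated list of target m/z values with class labels.

    Entries are kept sorted by target m/z; integration windows of
    ``window_halfwidth`` around each target must not overlap, which the
    constructor enforces.
    """

    entries: tuple[PanelEntry, ...]
    window_halfwidth: float = 0.4

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("panel is empty")
        if not (0 < self.window_halfwidth < 0.5):
            raise ValueError(
                "window_halfwidth must lie in (0, 0.5) Da so that full "
                "windows stay under 1 Da and DP-ladder neighbors never overlap"
            )
        object.__setattr__(
            self,
            "entries",
            tuple(sorted(self.entries, key=lambda e: e.target_mz)),
        )
        prev = None
        for e in self.entries:
            if prev is not None:
                gap = e.target_mz - prev.target_mz
                if gap <= 0:
                    raise ValueError(
                        f"duplicate target m/z {e.target_mz:.4f}"
                    )
                if gap < 2 * self.window_halfwidth:
                    raise ValueError(
                        "overlapping integration windows: "
                        f"{prev.target_mz:.4f} and {e.target_mz:.4f} are "
                        f"{gap:.4f} Da apart (< {2 * self.window_halfwidth} Da)"
                    )
            prev = e
        for e in self.entries:
            if e.feature_class == "glycogen_dp" and e.composition is not None:
                expect = sodiated_mz(e.composition)
                if abs(expect - e.target_mz) > 0.01:
                    raise ValueError(
                        f"glycogen_dp entry {e.label or e.target_mz} is "
                        f"{abs(expect - e.target_mz):.4f} Da off the DP ladder"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def target_mzs(self) -> list[float]:
        return [e.target_mz for e in self.entries]

    @property
    def nominal_labels(self) -> list[int]:
        return [e.nominal for e in self.entries]

    @property
    def classes(self) -> list[str]:
        return [e.feature_class for e in self.entries]

    def by_class(self, feature_class: str) -> list[int]:
        """Column indices of entries of one class."""
        return [
            i
            for i, e in enumerate(self.entries)
            if e.feature_class == feature_class
        ]

    def entry_for_nominal(self, label: int) -> PanelEntry:
        for e in self.entries:
            if e.nominal == label:
                return e
        raise KeyError(f"no panel entry with nominal label {label}")


# Canonical N-glycan compositions for the default panel: high-mannose series,
# biantennary/triantennary complex types with and without core fucose, and
# sialylated variants.  The set includes every composition printed in the
# figure assignments (nominal 1485, 1743, 1809, 2012, 1444).
DEFAULT_NGLYCANS: tuple[str, ...] = (
    "Hex5HexNAc2",
    "Hex6HexNAc2",
    "Hex7HexNAc2",
    "Hex8HexNAc2",
    "Hex9HexNAc2",
    "Hex3HexNAc3dHex1",
    "Hex4HexNAc3dHex1",
    "Hex3HexNAc4",
    "Hex3HexNAc4dHex1",
    "Hex4HexNAc4dHex1",
    "Hex5HexNAc4",
    "Hex5HexNAc4dHex1",
    "Hex5HexNAc5dHex1",
    "Hex6HexNAc5dHex1",
    "Hex5HexNAc4NeuAc1",
    "Hex5HexNAc4dHex1NeuAc1",
)

# CHCA cluster/adduct ions commonly observed in positive mode, restricted to
# the acquired 500-3000 m/z range (CHCA monomer M = 189.0426):
# [nM+H/Na/K]+ combinations.  These stand in for the instrument-specific
# matrix list, which is user-replaceable via TSV.
DEFAULT_MATRIX_MZ: tuple[float, ...] = (
    568.1401,   # [3M+H]+
    590.1220,   # [3M+Na]+
    612.1040,   # [3M+2Na-H]+
    628.0779,   # [3M+Na+K-H]+
    757.1827,   # [4M+H]+
    779.1646,   # [4M+Na]+
    801.1466,   # [4M+2Na-H]+
    823.1285,   # [4M+3Na-2H]+
    946.2253,   # [5M+H]+
    968.2072,   # [5M+Na]+
    990.1892,   # [5M+2Na-H]+
    1135.2679,  # [6M+H]+
    1157.2498,  # [6M+Na]+
    1179.2318,  # [6M+2Na-H]+
    1346.2924,  # [7M+Na]+
    1368.2744,  # [7M+2Na-H]+
)


def build_default_panel(
    dp_min: int = 3,
    dp_max: int = 14,
    nglycan_list: Sequence[str | GlycanComposition] | None = None,
    matrix_mz_list: Sequence[float] | None = None,
    window_halfwidth: float = 0.4,
) -> PeakPanel:
    """Reconstructed default panel: DP ladder + canonical N-glycans + CHCA ions.

    The source panel (50 matrix + 155 carbohydrate targets) is not public;
    this default is a faithful, smaller stand-in and fully user-replaceable
    via :func:`read_panel_tsv`.
    """
    if nglycan_list is None:
        nglycan_list = DEFAULT_NGLYCANS
    if matrix_mz_list is None:
        matrix_mz_list = DEFAULT_MATRIX_MZ

    entries: list[PanelEntry] = []
    for dp, mz in dp_ladder(dp_min, dp_max):
        comp = GlycanComposition(n_hex=dp, kind="glucan_dp")
        entries.append(
            PanelEntry(mz, "glycogen_dp", comp, label=f"DP{dp}")
        )
    for item in nglycan_list:
        comp = (
            parse_composition(item) if isinstance(item, str) else item
        )
        entries.append(
            PanelEntry(
                sodiated_mz(comp), "nglycan", comp, label=format_composition(comp)
            )
        )
    for mz in matrix_mz_list:
        entries.append(PanelEntry(float(mz), "matrix", None, label=f"CHCA_{mz:.0f}"))
    return PeakPanel(tuple(entries), window_halfwidth=window_halfwidth)


def write_panel_tsv(panel: PeakPanel, path: str | Path) -> None:
    """Serialize a panel to TSV: target_mz, class, composition, label."""
    lines = ["target_mz\tclass\tcomposition\tlabel"]
    for e in panel.entries:
        comp = format_composition(e.composition) if e.composition else ""
        lines.append(f"{e.target_mz:.6f}\t{e.feature_class}\t{comp}\t{e.label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_panel_tsv(path: str | Path, window_halfwidth: float = 0.4) -> PeakPanel:
    """Strict TSV panel parser; errors carry 1-based line numbers."""
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty panel file")
    header = lines[0].rstrip("\n").split("\t")
    expected = ["target_mz", "class", "composition", "label"]
    if header != expected:
        raise ValueError(
            f"{path}:1: bad header {header!r}, expected {expected!r}"
        )
    entries: list[PanelEntry] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(
                f"{path}:{lineno}: expected 4 tab-separated fields, "
                f"got {len(fields)}"
            )
        mz_text, cls, comp_text, label = fields
        try:
            mz = float(mz_text)
        except ValueError as exc:
            raise ValueError(
                f"{path}:{lineno}: non-numeric target_mz {mz_text!r}"
            ) from exc
        if cls not in VALID_CLASSES:
            raise ValueError(f"{path}:{lineno}: unknown class {cls!r}")
        comp = None
        if comp_text:
            try:
                comp = parse_composition(
                    comp_text, kind="glucan_dp" if cls == "glycogen_dp" else None
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
        entries.append(PanelEntry(mz, cls, comp, label))
    return PeakPanel(tuple(entries), window_halfwidth=window_halfwidth)
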