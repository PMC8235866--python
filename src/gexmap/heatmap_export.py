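"""Heat-map layout, coloring, raster export (PNG/TIFF) and CSV export.

Values are mapped to colors by piecewise-linear interpolation between the
evenly spaced RGB anchors of a named :class:`ColorGradient`; channel
rounding is half-up and fixed so identical inputs always render to
byte-identical PNG output.  A registry of 30 named gradients ships with
the package and user-defined gradients can be registered at run time.

Rendering is done directly with Pillow rather than a plotting library so
that the raster geometry is exact: the data region is precisely
``cols x cell_size`` by ``rows x cell_size`` pixels, with label and title
margins added only when the corresponding text is present.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .errors import FormatError, ValidationError
from .expression_query import AnnotatedResultTable, ResultRow

__all__ = [
    "ColorGradient",
    "GRADIENTS",
    "register_gradient",
    "get_gradient",
    "map_value_to_color",
    "Transform",
    "LabelField",
    "HeatmapSpec",
    "HeatmapGrid",
    "layout_heatmap",
    "render_image",
    "export_csv",
    "read_result_csv",
]

RGB = tuple[int, int, int]


@dataclass(frozen=True)
class ColorGradient:
    """Named gradient: >= 2 RGB anchors at evenly spaced positions in [0, 1]."""

    name: str
    anchors: tuple[RGB, ...]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValidationError(f"gradient {self.name!r}: needs at least 2 anchors")
        for anchor in self.anchors:
            if len(anchor) != 3 or any(not (0 <= c <= 255) for c in anchor):
                raise ValidationError(
                    f"gradient {self.name!r}: anchor {anchor!r} outside RGB range 0-255"
                )


def _g(name: str, *anchors: RGB) -> ColorGradient:
    return ColorGradient(name=name, anchors=tuple(anchors))


#: Built-in registry.  Two-anchor ramps, diverging three-anchor schemes
#: (including the classic green-black-red microarray palette), and
#: multi-anchor approximations of the common perceptual colormaps.
GRADIENTS: dict[str, ColorGradient] = {
    g.name: g
    for g in [
        _g("white_red", (255, 255, 255), (200, 0, 0)),
        _g("white_blue", (255, 255, 255), (0, 60, 180)),
        _g("white_green", (255, 255, 255), (0, 130, 60)),
        _g("white_purple", (255, 255, 255), (110, 30, 150)),
        _g("white_orange", (255, 255, 255), (230, 120, 0)),
        _g("black_white", (0, 0, 0), (255, 255, 255)),
        _g("white_black", (255, 255, 255), (0, 0, 0)),
        _g("black_red", (0, 0, 0), (255, 0, 0)),
        _g("black_green", (0, 0, 0), (0, 255, 0)),
        _g("black_blue", (0, 0, 0), (60, 120, 255)),
        _g("yellow_red", (255, 240, 100), (200, 20, 20)),
        _g("navy_gold", (20, 30, 90), (240, 200, 60)),
        _g("blue_white_red", (0, 60, 180), (255, 255, 255), (200, 0, 0)),
        _g("red_white_blue", (200, 0, 0), (255, 255, 255), (0, 60, 180)),
        _g("green_black_red", (0, 255, 0), (0, 0, 0), (255, 0, 0)),
        _g("red_black_green", (255, 0, 0), (0, 0, 0), (0, 255, 0)),
        _g("blue_black_yellow", (40, 90, 255), (0, 0, 0), (255, 220, 0)),
        _g("purple_white_green", (110, 30, 150), (255, 255, 255), (0, 130, 60)),
        _g("orange_white_blue", (230, 120, 0), (255, 255, 255), (0, 60, 180)),
        _g("red_yellow_green", (200, 20, 20), (255, 240, 100), (0, 130, 60)),
        _g("viridis", (68, 1, 84), (59, 82, 139), (33, 145, 140), (94, 201, 98), (253, 231, 37)),
        _g("magma", (0, 0, 4), (81, 18, 124), (183, 55, 121), (252, 137, 97), (252, 253, 191)),
        _g("inferno", (0, 0, 4), (87, 16, 110), (188, 55, 84), (249, 142, 9), (252, 255, 164)),
        _g("plasma", (13, 8, 135), (126, 3, 168), (204, 71, 120), (248, 149, 64), (240, 249, 33)),
        _g("cividis", (0, 32, 76), (77, 77, 109), (124, 123, 120), (187, 173, 108), (255, 234, 70)),
        _g("spectral", (158, 1, 66), (244, 109, 67), (255, 255, 191), (102, 194, 165), (50, 136, 189)),
        _g("fire", (0, 0, 0), (128, 0, 0), (255, 64, 0), (255, 200, 0), (255, 255, 255)),
        _g("ice", (255, 255, 255), (170, 220, 255), (60, 120, 200), (10, 30, 80)),
        _g("ocean", (0, 20, 60), (0, 90, 140), (0, 160, 180), (200, 250, 255)),
        _g("sunset", (40, 0, 70), (150, 30, 90), (240, 100, 60), (255, 200, 100)),
    ]
}


def register_gradient(gradient: ColorGradient, overwrite: bool = False) -> None:
    """Add a user-defined gradient to the registry."""
    if gradient.name in GRADIENTS and not overwrite:
        raise ValidationError(f"gradient {gradient.name!r} already registered")
    GRADIENTS[gradient.name] = gradient


def get_gradient(name: str) -> ColorGradient:
    try:
        return GRADIENTS[name]
    except KeyError:
        raise ValidationError(
            f"unknown gradient {name!r} (registered: {', '.join(sorted(GRADIENTS))})"
        ) from None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def map_value_to_color(value: float, vmin: float, vmax: float, gradient: ColorGradient) -> RGB:
    """Interpolate a value to an RGB triple.

    ``t = clamp((value - vmin) / (vmax - vmin), 0, 1)`` selects a position
    along the gradient; each channel interpolates linearly between the two
    bracketing anchors and rounds half-up to an integer.
    """
    if not vmin < vmax:
        raise ValidationError(f"vmin ({vmin}) must be strictly less than vmax ({vmax})")
    t = (value - vmin) / (vmax - vmin)
    t = min(1.0, max(0.0, t))
    n = len(gradient.anchors)
    position = t * (n - 1)
    i = min(int(position), n - 2)
    frac = position - i
    lo, hi = gradient.anchors[i], gradient.anchors[i + 1]
    return tuple(_round_half_up(lo[c] + (hi[c] - lo[c]) * frac) for c in range(3))  # type: ignore[return-value]


class Transform(enum.Enum):
    LINEAR = "linear"
    LOG10_PLUS1 = "log10_plus1"

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self is Transform.LOG10_PLUS1:
            return np.log10(np.asarray(values, dtype=float) + 1.0)
        return np.asarray(values, dtype=float)


class LabelField(enum.Enum):
    GENE_SYMBOL = "gene_symbol"
    ENSEMBL_ID = "ensembl_id"
    DISEASES = "diseases"
    NONE = "none"


@dataclass
class HeatmapSpec:
    """Rendering configuration: titles, gradient, row labels, value transform.

    ``vmin``/``vmax`` default to the matrix min/max after ``transform``
    (auto-range); when both are given explicitly they must satisfy
    vmin < vmax.
    """

    title_header: str = ""
    title_x: str = ""
    title_y_left: str = ""
    title_y_right: str = ""
    gradient_name: str = "white_red"
    left_label_field: LabelField = LabelField.GENE_SYMBOL
    right_label_field: LabelField = LabelField.DISEASES
    transform: Transform = Transform.LINEAR
    vmin: float | None = None
    vmax: float | None = None

    def __post_init__(self) -> None:
        get_gradient(self.gradient_name)
        if self.vmin is not None and self.vmax is not None and not self.vmin < self.vmax:
            raise ValidationError(f"vmin ({self.vmin}) must be < vmax ({self.vmax})")

    def to_dict(self) -> dict:
        return {
            "title_header": self.title_header,
            "title_x": self.title_x,
            "title_y_left": self.title_y_left,
            "title_y_right": self.title_y_right,
            "gradient_name": self.gradient_name,
            "left_label_field": self.left_label_field.value,
            "right_label_field": self.right_label_field.value,
            "transform": self.transform.value,
            "vmin": self.vmin,
            "vmax": self.vmax,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "HeatmapSpec":
        def _enum(enum_cls, key, default):
            raw = data.get(key, default)
            if isinstance(raw, enum_cls):
                return raw
            try:
                return enum_cls(str(raw))
            except ValueError:
                choices = ", ".join(e.value for e in enum_cls)
                raise ValidationError(f"invalid {key} {raw!r} (expected one of: {choices})") from None

        return cls(
            title_header=str(data.get("title_header", "")),
            title_x=str(data.get("title_x", "")),
            title_y_left=str(data.get("title_y_left", "")),
            title_y_right=str(data.get("title_y_right", "")),
            gradient_name=str(data.get("gradient_name", "white_red")),
            left_label_field=_enum(LabelField, "left_label_field", LabelField.GENE_SYMBOL.value),
            right_label_field=_enum(LabelField, "right_label_field", LabelField.DISEASES.value),
            transform=_enum(Transform, "transform", Transform.LINEAR.value),
            vmin=None if data.get("vmin") is None else float(data["vmin"]),
            vmax=None if data.get("vmax") is None else float(data["vmax"]),
        )


@dataclass
class HeatmapGrid:
    """The laid-out heat map: per-cell colors plus labels and titles."""

    cell_colors: list[list[RGB]]
    row_labels_left: list[str]
    row_labels_right: list[str]
    col_labels: list[str]
    title_header: str = ""
    title_x: str = ""
    title_y_left: str = ""
    title_y_right: str = ""

    def __post_init__(self) -> None:
        rows = len(self.cell_colors)
        cols = len(self.cell_colors[0]) if rows else 0
        if any(len(r) != cols for r in self.cell_colors):
            raise ValidationError("cell_colors rows have unequal lengths")
        if len(self.row_labels_left) != rows or len(self.row_labels_right) != rows:
            raise ValidationError("row label lists must match the number of rows")
        if len(self.col_labels) != cols:
            raise ValidationError("col_labels must match the number of columns")

    @property
    def n_rows(self) -> int:
        return len(self.cell_colors)

    @property
    def n_cols(self) -> int:
        return len(self.cell_colors[0]) if self.cell_colors else 0


def _labels_for(rows: Sequence[ResultRow], which: LabelField) -> list[str]:
    if which is LabelField.GENE_SYMBOL:
        return [r.gene_symbol for r in rows]
    if which is LabelField.ENSEMBL_ID:
        return [r.ensembl_id for r in rows]
    if which is LabelField.DISEASES:
        return ["; ".join(r.diseases) for r in rows]
    return ["" for _ in rows]


def layout_heatmap(table: AnnotatedResultTable, spec: HeatmapSpec) -> HeatmapGrid:
    """Color the table's abundance matrix and attach labels and titles.

    Rows keep the table's deterministic order.  The transform is applied
    before auto-ranging; a constant matrix (vmin == vmax under auto-range)
    maps every cell to the gradient's first anchor.
    """
    gradient = get_gradient(spec.gradient_name)
    values = spec.transform.apply(table.values_matrix())
    if values.size:
        vmin = float(values.min()) if spec.vmin is None else float(spec.vmin)
        vmax = float(values.max()) if spec.vmax is None else float(spec.vmax)
        if not vmin < vmax:  # constant matrix under auto-range
            vmax = vmin + 1.0
        colors = [
            [map_value_to_color(float(v), vmin, vmax, gradient) for v in row]
            for row in values
        ]
    else:
        colors = []
    return HeatmapGrid(
        cell_colors=colors,
        row_labels_left=_labels_for(table.rows, spec.left_label_field),
        row_labels_right=_labels_for(table.rows, spec.right_label_field),
        col_labels=list(table.sample_ids) if table.rows else [],
        title_header=spec.title_header,
        title_x=spec.title_x,
        title_y_left=spec.title_y_left,
        title_y_right=spec.title_y_right,
    )


_PAD = 4


def _font() -> ImageFont.ImageFont:
    # Pillow's built-in bitmap font: identical on every platform, so
    # renders stay byte-stable.
    return ImageFont.load_default()


def _text_size(draw: ImageDraw.ImageDraw, text: str, font) -> tuple[int, int]:
    if not text:
        return (0, 0)
    left, top, right, bottom = draw.textbbox((0, 0), text, font=font)
    return (right - left, bottom - top)


def render_image(
    grid: HeatmapGrid,
    path: str | Path,
    format: str = "png",
    cell_size: int = 20,
    dpi: int = 96,
) -> Path:
    """Rasterize a grid to PNG or uncompressed TIFF.

    The data region is exactly ``n_cols x cell_size`` wide and
    ``n_rows x cell_size`` tall; margins are added only for non-empty
    titles/labels, so a label-free, title-free grid renders to exactly the
    data region.  Re-rendering identical inputs yields identical PNG bytes.
    An empty grid renders as a small annotated "no genes" canvas.
    """
    fmt = format.lower()
    if fmt not in ("png", "tiff"):
        raise ValidationError(f"unknown image format {format!r} (expected png or tiff)")
    path = Path(path)
    font = _font()
    probe = ImageDraw.Draw(Image.new("RGB", (1, 1)))

    if grid.n_rows == 0 or grid.n_cols == 0:
        img = Image.new("RGB", (360, 80), (255, 255, 255))
        draw = ImageDraw.Draw(img)
        message = "no genes matched the query"
        if grid.title_header:
            message = f"{grid.title_header}: {message}"
        draw.text((_PAD, 30), message, fill=(0, 0, 0), font=font)
        _save(img, path, fmt, dpi)
        return path

    data_w = grid.n_cols * cell_size
    data_h = grid.n_rows * cell_size

    left_labels_w = max((_text_size(probe, t, font)[0] for t in grid.row_labels_left), default=0)
    right_labels_w = max((_text_size(probe, t, font)[0] for t in grid.row_labels_right), default=0)
    col_label_h = max((_text_size(probe, t, font)[1] for t in grid.col_labels), default=0)
    header_h = _text_size(probe, grid.title_header, font)[1]
    x_title_h = _text_size(probe, grid.title_x, font)[1]
    # vertical y-axis titles are drawn rotated; their footprint is one text height wide
    y_left_w = _text_size(probe, grid.title_y_left, font)[1]
    y_right_w = _text_size(probe, grid.title_y_right, font)[1]

    margin_left = (y_left_w + _PAD if y_left_w else 0) + (left_labels_w + _PAD if left_labels_w else 0)
    margin_right = (right_labels_w + _PAD if right_labels_w else 0) + (y_right_w + _PAD if y_right_w else 0)
    margin_top = (header_h + 2 * _PAD if header_h else 0) + (col_label_h + _PAD if col_label_h else 0)
    margin_bottom = x_title_h + 2 * _PAD if x_title_h else 0

    width = margin_left + data_w + margin_right
    height = margin_top + data_h + margin_bottom
    img = Image.new("RGB", (width, height), (255, 255, 255))

    # paint the data region from a numpy block (fast and exact)
    cells = np.asarray(grid.cell_colors, dtype=np.uint8)  # rows x cols x 3
    block = np.repeat(np.repeat(cells, cell_size, axis=0), cell_size, axis=1)
    img.paste(Image.fromarray(block, mode="RGB"), (margin_left, margin_top))

    draw = ImageDraw.Draw(img)
    if header_h:
        w = _text_size(draw, grid.title_header, font)[0]
        draw.text(((width - w) // 2, _PAD), grid.title_header, fill=(0, 0, 0), font=font)
    if col_label_h:
        for j, text in enumerate(grid.col_labels):
            if not text:
                continue
            w = _text_size(draw, text, font)[0]
            x = margin_left + j * cell_size + (cell_size - w) // 2
            draw.text((x, margin_top - col_label_h - _PAD // 2), text, fill=(0, 0, 0), font=font)
    for i in range(grid.n_rows):
        y = margin_top + i * cell_size + max(0, (cell_size - 10) // 2)
        left = grid.row_labels_left[i]
        if left:
            w = _text_size(draw, left, font)[0]
            draw.text((margin_left - _PAD - w, y), left, fill=(0, 0, 0), font=font)
        right = grid.row_labels_right[i]
        if right:
            draw.text((margin_left + data_w + _PAD, y), right, fill=(0, 0, 0), font=font)
    if x_title_h:
        w = _text_size(draw, grid.title_x, font)[0]
        draw.text(((width - w) // 2, height - margin_bottom + _PAD), grid.title_x,
                  fill=(0, 0, 0), font=font)
    for text, x in ((grid.title_y_left, 0), (grid.title_y_right, width - y_right_w - _PAD)):
        if not text:
            continue
        w, h = _text_size(draw, text, font)
        strip = Image.new("RGB", (w + 2, h + 2), (255, 255, 255))
        ImageDraw.Draw(strip).text((1, 1), text, fill=(0, 0, 0), font=font)
        rotated = strip.rotate(90, expand=True)
        img.paste(rotated, (x, margin_top + (data_h - rotated.height) // 2))

    _save(img, path, fmt, dpi)
    return path


def data_region_origin(grid: HeatmapGrid, cell_size: int = 20) -> tuple[int, int]:
    """Pixel offset of the data region's top-left corner for a given grid,
    mirroring :func:`render_image`'s margin arithmetic (read-back helper)."""
    font = _font()
    probe = ImageDraw.Draw(Image.new("RGB", (1, 1)))
    left_labels_w = max((_text_size(probe, t, font)[0] for t in grid.row_labels_left), default=0)
    col_label_h = max((_text_size(probe, t, font)[1] for t in grid.col_labels), default=0)
    header_h = _text_size(probe, grid.title_header, font)[1]
    y_left_w = _text_size(probe, grid.title_y_left, font)[1]
    margin_left = (y_left_w + _PAD if y_left_w else 0) + (left_labels_w + _PAD if left_labels_w else 0)
    margin_top = (header_h + 2 * _PAD if header_h else 0) + (col_label_h + _PAD if col_label_h else 0)
    return margin_left, margin_top


def _save(img: Image.Image, path: Path, fmt: str, dpi: int) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        img.save(path, format="PNG", dpi=(dpi, dpi))
    else:
        img.save(path, format="TIFF", compression=None, dpi=(dpi, dpi))


_FIXED_COLUMNS = ("gene_symbol", "ensembl_id")
_TRAILING_COLUMNS = ("mean_transcript_length", "diseases")


def _fmt(value: float) -> str:
    return repr(float(value))


def export_csv(table: AnnotatedResultTable, path: str | Path) -> Path:
    """Write the annotated result table as RFC-4180 CSV.

    Header: ``gene_symbol, ensembl_id, <one column per sample>,
    mean_transcript_length, diseases`` with disease terms joined by "; ".
    Floats are written with full round-trip precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow([*_FIXED_COLUMNS, *table.sample_ids, *_TRAILING_COLUMNS])
        for row in table.rows:
            writer.writerow([
                row.gene_symbol,
                row.ensembl_id,
                *[_fmt(v) for v in row.abundances],
                _fmt(row.mean_transcript_length),
                "; ".join(row.diseases),
            ])
    return path


def read_result_csv(path: str | Path) -> AnnotatedResultTable:
    """Re-load a CSV written by :func:`export_csv`."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty file, expected a result-table header")
        expected_fixed = list(_FIXED_COLUMNS)
        expected_trailing = list(_TRAILING_COLUMNS)
        if header[:2] != expected_fixed or header[-2:] != expected_trailing:
            raise FormatError(
                f"{path}: header does not match the result-table contract: {header!r}"
            )
        sample_ids = header[2:-2]
        rows: list[ResultRow] = []
        for lineno, record in enumerate(reader, start=2):
            if not record:
                continue
            if len(record) != len(header):
                raise FormatError(f"{path}, line {lineno}: expected {len(header)} fields")
            diseases = tuple(t for t in record[-1].split("; ") if t)
            rows.append(ResultRow(
                gene_symbol=record[0],
                ensembl_id=record[1],
                abundances=tuple(float(v) for v in record[2:-2]),
                mean_transcript_length=float(record[-2]),
                diseases=diseases,
            ))
    return AnnotatedResultTable(sample_ids=sample_ids, rows=rows)
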