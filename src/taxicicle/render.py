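"""SVG serialization of the two coordinated views.

The document places the rectangular phylogram on the left and the
taxonomic icicle on the right; by default 30% of the page width goes
to the tree view and the rest to the icicle.  Both panels share one
font so the display stays consistent.  Output is byte-deterministic
for fixed inputs: coordinates are rounded to 3 decimals, elements are
emitted in a fixed order (background → icicle rects by (depth, x) →
tree edges → labels), and there are no timestamps or generated ids.
"""

from __future__ import annotations

from lxml import etree

from .errors import LayoutError
from .icicle_layout import IcicleRect
from .matching import normalize_accession
from .phylogram_layout import TreeLayout
from .style import Palette, label_style
from .view_state import ViewState

__all__ = ["render_document", "export_icicle", "write_html"]

SVG_NS = "http://www.w3.org/2000/svg"
DEFAULT_TREE_FRACTION = 0.30
DEFAULT_FONT_FAMILY = "sans-serif"
DEFAULT_FONT_SIZE = 12.0
#: Fill painted on leaf labels inside a completed ROI selection.
SELECTION_FILL = "#9ECAE1"
TEXT_FILL = "#000000"
RECT_STROKE = "#FFFFFF"
BACKGROUND_FILL = "#FAFAFA"
#: Labels longer than this are clipped with an ellipsis.
DEFAULT_LABEL_MAX_CHARS = 30


def _fmt(value: float) -> str:
    """Serialize a coordinate at 3 decimal places, trimming zeros."""
    text = f"{value:.3f}".rstrip("0").rstrip(".")
    return text if text else "0"


def _clip(text: str, max_chars: int) -> str:
    return text if len(text) <= max_chars else text[: max_chars - 1] + "…"


def _svg_root(width: float, height: float) -> etree._Element:
    root = etree.Element(
        f"{{{SVG_NS}}}svg",
        nsmap={None: SVG_NS},
        width=_fmt(width),
        height=_fmt(height),
        viewBox=f"0 0 {_fmt(width)} {_fmt(height)}",
    )
    root.set("version", "1.1")
    return root


def _add_rect(parent, x, y, w, h, fill, stroke=None):
    rect = etree.SubElement(
        parent,
        f"{{{SVG_NS}}}rect",
        x=_fmt(x),
        y=_fmt(y),
        width=_fmt(w),
        height=_fmt(h),
        fill=fill,
    )
    if stroke:
        rect.set("stroke", stroke)
        rect.set("stroke-width", "0.5")
    return rect


def _add_text(parent, x, y, content, fill, font_size, *, anchor="start", rotate=0.0):
    text = etree.SubElement(
        parent,
        f"{{{SVG_NS}}}text",
        x=_fmt(x),
        y=_fmt(y),
        fill=fill,
    )
    text.set("font-size", _fmt(font_size))
    text.set("text-anchor", anchor)
    if rotate:
        text.set("transform", f"rotate({_fmt(rotate)} {_fmt(x)} {_fmt(y)})")
    text.text = content
    return text


def _add_line(parent, x1, y1, x2, y2, stroke="#333333"):
    line = etree.SubElement(
        parent,
        f"{{{SVG_NS}}}line",
        x1=_fmt(x1),
        y1=_fmt(y1),
        x2=_fmt(x2),
        y2=_fmt(y2),
    )
    line.set("stroke", stroke)
    line.set("stroke-width", "1")
    return line


def _icicle_label_elements(
    group,
    rects: list[IcicleRect],
    hovered_key: str | None,
    font_size: float,
    label_max_chars: int,
    highlight: str = "#B56521",
) -> None:
    for rect in sorted(rects, key=lambda r: (r.node.depth, r.x)):
        rotation, placement = label_style(rect.node.depth)
        is_hover = (
            hovered_key is not None
            and rect.node.depth == 6
            and rect.node.id is not None
            and normalize_accession(rect.node.id) == hovered_key
        )
        fill = highlight if is_hover else TEXT_FILL
        content = _clip(rect.node.name, label_max_chars)
        if placement == "outside":  # species: diagonal, below the minimized row
            _add_text(
                group,
                rect.x + rect.w / 2,
                rect.y + rect.h + font_size * 0.4,
                content,
                fill,
                font_size,
                anchor="start",
                rotate=rotation,
            )
        elif rotation == 90.0:  # family/genus: vertical, inside
            _add_text(
                group,
                rect.x + rect.w / 2 + font_size / 3,
                rect.y + rect.h / 2,
                content,
                fill,
                font_size,
                anchor="middle",
                rotate=rotation,
            )
        else:  # domain..order: horizontal, centered inside
            _add_text(
                group,
                rect.x + rect.w / 2,
                rect.y + rect.h / 2 + font_size / 3,
                content,
                fill,
                font_size,
                anchor="middle",
            )


def _check_consistency(
    tree_layout: TreeLayout,
    icicle_rects: list[IcicleRect],
    state: ViewState,
    tree_width: float,
    icicle_width: float,
) -> None:
    if abs(tree_layout.panel_width - tree_width) > 1e-6:
        raise LayoutError(
            f"tree layout panel width {tree_layout.panel_width} does not match "
            f"the document's tree panel ({tree_width})"
        )
    if icicle_rects:
        max_extent = max(r.x + r.w for r in icicle_rects)
        if max_extent > icicle_width + 1e-6:
            raise LayoutError(
                f"icicle extent {max_extent} exceeds its panel width {icicle_width}"
            )
        selection_keys = {normalize_accession(a) for a in state.selection}
        for rect in icicle_rects:
            if rect.node.depth == 6 and rect.node.id is not None:
                if normalize_accession(rect.node.id) not in selection_keys:
                    raise LayoutError(
                        f"icicle species {rect.node.id!r} is not in the "
                        "current selection; views are out of sync"
                    )


def render_document(
    tree_layout: TreeLayout,
    icicle_rects: list[IcicleRect],
    state: ViewState,
    palette: Palette,
    tree_fraction: float = DEFAULT_TREE_FRACTION,
    font_family: str = DEFAULT_FONT_FAMILY,
    font_size: float = DEFAULT_FONT_SIZE,
    label_max_chars: int = DEFAULT_LABEL_MAX_CHARS,
) -> str:
    """Render both views into one SVG document.

    The tree panel occupies ``tree_fraction`` (default 0.30) of the
    canvas width, the icicle the rest.  Selected leaves carry the
    selection fill; the hovered species — if any — is painted in the
    palette's highlight orange in BOTH panels, and nowhere else.
    Raises :class:`LayoutError` when the layouts disagree with the
    state or the panel split.
    """
    canvas_w, canvas_h = state.canvas
    tree_w = tree_fraction * canvas_w
    icicle_w = canvas_w - tree_w
    _check_consistency(tree_layout, icicle_rects, state, tree_w, icicle_w)

    svg = _svg_root(canvas_w, canvas_h)
    svg.set("font-family", font_family)
    svg.set("font-size", _fmt(font_size))
    _add_rect(svg, 0, 0, canvas_w, canvas_h, BACKGROUND_FILL)

    icicle_group = etree.SubElement(svg, f"{{{SVG_NS}}}g")
    icicle_group.set("transform", f"translate({_fmt(tree_w)} 0)")
    for rect in sorted(icicle_rects, key=lambda r: (r.node.depth, r.x)):
        _add_rect(
            icicle_group,
            rect.x,
            rect.y,
            rect.w,
            rect.h,
            palette.color_for_depth(rect.node.depth),
            stroke=RECT_STROKE,
        )

    tree_group = etree.SubElement(svg, f"{{{SVG_NS}}}g")
    positions = tree_layout.positions
    for node in tree_layout.tree.root.walk():
        if node.children:
            x, _ = positions[node]
            child_ys = [positions[c][1] for c in node.children]
            _add_line(tree_group, x, min(child_ys), x, max(child_ys))
            for child in node.children:
                cx, cy = positions[child]
                _add_line(tree_group, x, cy, cx, cy)

    hovered_key = normalize_accession(state.hovered) if state.hovered else None
    selection_keys = {normalize_accession(a) for a in state.selection}
    labels_group = etree.SubElement(svg, f"{{{SVG_NS}}}g")
    for leaf in tree_layout.tree.leaves():
        x, y = positions[leaf]
        key = normalize_accession(leaf.label or "")
        if hovered_key is not None and key == hovered_key:
            fill = palette.highlight
        elif key in selection_keys:
            fill = SELECTION_FILL
        else:
            fill = TEXT_FILL
        _add_text(
            labels_group,
            x + font_size / 3,
            y + font_size / 3,
            _clip(leaf.label or "", label_max_chars),
            fill,
            font_size,
        )

    icicle_labels = etree.SubElement(svg, f"{{{SVG_NS}}}g")
    icicle_labels.set("transform", f"translate({_fmt(tree_w)} 0)")
    _icicle_label_elements(
        icicle_labels,
        icicle_rects,
        hovered_key,
        font_size,
        label_max_chars,
        highlight=palette.highlight,
    )
    return etree.tostring(svg, pretty_print=True, encoding="unicode")


def icicle_svg_text(
    icicle_rects: list[IcicleRect],
    palette: Palette,
    font_size: float = DEFAULT_FONT_SIZE,
    label_max_chars: int = DEFAULT_LABEL_MAX_CHARS,
) -> str:
    """Standalone SVG of the icicle alone, as text.

    Contains exactly one ``rect`` element per hierarchy node (plus the
    labels), so re-parsing recovers the rectangle count and
    coordinates.
    """
    if not icicle_rects:
        raise LayoutError("cannot export an empty icicle")
    width = max(r.x + r.w for r in icicle_rects)
    height = max(r.y + r.h for r in icicle_rects) + 4 * font_size  # label apron
    svg = _svg_root(width, height)
    svg.set("font-family", DEFAULT_FONT_FAMILY)
    svg.set("font-size", _fmt(font_size))
    for rect in sorted(icicle_rects, key=lambda r: (r.node.depth, r.x)):
        _add_rect(
            svg,
            rect.x,
            rect.y,
            rect.w,
            rect.h,
            palette.color_for_depth(rect.node.depth),
            stroke=RECT_STROKE,
        )
    labels = etree.SubElement(svg, f"{{{SVG_NS}}}g")
    _icicle_label_elements(labels, icicle_rects, None, font_size, label_max_chars)
    return etree.tostring(svg, pretty_print=True, encoding="unicode")


def export_icicle(
    icicle_rects: list[IcicleRect],
    palette: Palette,
    path: str,
    font_size: float = DEFAULT_FONT_SIZE,
    label_max_chars: int = DEFAULT_LABEL_MAX_CHARS,
) -> str:
    """Write a standalone SVG of the current icicle; returns the text."""
    text = icicle_svg_text(icicle_rects, palette, font_size, label_max_chars)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return text


def write_html(path: str, svg_text: str, title: str = "taxicicle view") -> None:
    """Wrap an SVG document in a minimal self-contained HTML page."""
    html = (
        "<!DOCTYPE html>\n<html>\n<head>\n"
        f"<meta charset=\"utf-8\"/>\n<title>{title}</title>\n"
        "</head>\n<body>\n"
        f"{svg_text}\n"
        "</body>\n</html>\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(html)
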