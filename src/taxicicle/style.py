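"""Color palette and rank-dependent label styling for the icicle view.

The default palette is a clipped sequential blue ramp over the six
upper ranks with white added for the species layer to maximize label
contrast, plus the complementary orange used to highlight the species
under the cursor in both views.  Users may override any entry from a
flat key→hex config file; the defaults are immutable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import StyleError

__all__ = [
    "DEFAULT_LEVEL_COLORS",
    "HIGHLIGHT_COLOR",
    "Palette",
    "color_for_depth",
    "label_style",
    "load_palette",
]

#: Sequential blue ramp, domain (0) through species (6).
DEFAULT_LEVEL_COLORS = (
    "#2171B5",  # domain
    "#4292C6",  # phylum
    "#6BAED6",  # class
    "#9ECAE1",  # order
    "#C6DBEF",  # family
    "#EFF3FF",  # genus
    "#FFFFFF",  # species
)
#: Complementary orange of the domain blue; linked-highlight color.
HIGHLIGHT_COLOR = "#B56521"

_RANK_KEYS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def _normalize_hex(value: str, key: str) -> str:
    value = value.strip()
    if not (
        value.startswith("#")
        and len(value) == 7
        and all(c in "0123456789abcdefABCDEF" for c in value[1:])
    ):
        raise StyleError(f"invalid hex color for {key!r}: {value!r}")
    return value.upper()


@dataclass(frozen=True)
class Palette:
    """Seven level colors plus the highlight orange.

    Hex codes are compared case-insensitively and serialized uppercase.
    """

    level_colors: tuple[str, ...] = DEFAULT_LEVEL_COLORS
    highlight: str = HIGHLIGHT_COLOR

    def __post_init__(self):
        if len(self.level_colors) != 7:
            raise StyleError(
                f"palette needs exactly 7 level colors, got {len(self.level_colors)}"
            )
        object.__setattr__(
            self,
            "level_colors",
            tuple(
                _normalize_hex(c, rank)
                for c, rank in zip(self.level_colors, _RANK_KEYS)
            ),
        )
        object.__setattr__(self, "highlight", _normalize_hex(self.highlight, "highlight"))

    def color_for_depth(self, depth: int) -> str:
        if not 0 <= depth <= 6:
            raise StyleError(f"rank depth must be in [0, 6], got {depth}")
        return self.level_colors[depth]


DEFAULT_PALETTE = Palette()


def color_for_depth(depth: int, palette: Palette = DEFAULT_PALETTE) -> str:
    """Fill color for an icicle rectangle at the given rank depth."""
    return palette.color_for_depth(depth)


def label_style(depth: int) -> tuple[float, str]:
    """(rotation in degrees, placement) for a rank's labels.

    Species labels are diagonal (45°) and sit outside/below their
    minimized rectangles; the lengthy family and genus labels run
    vertically (90°) inside theirs; all other ranks are horizontal.
    """
    if not 0 <= depth <= 6:
        raise StyleError(f"rank depth must be in [0, 6], got {depth}")
    if depth == 6:
        return 45.0, "outside"
    if depth in (4, 5):
        return 90.0, "inside"
    return 0.0, "inside"


def load_palette(path: str) -> Palette:
    """Load palette overrides from a flat key→hex mapping file (YAML).

    Recognized keys: the seven rank names plus ``highlight``; missing
    keys keep their defaults, unknown keys are an error.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise StyleError(f"palette file {path!r} must be a flat key: hex mapping")
    unknown = set(raw) - set(_RANK_KEYS) - {"highlight"}
    if unknown:
        raise StyleError(f"unknown palette keys: {sorted(unknown)}")
    colors = list(DEFAULT_LEVEL_COLORS)
    for i, rank in enumerate(_RANK_KEYS):
        if rank in raw:
            colors[i] = str(raw[rank])
    highlight = str(raw.get("highlight", HIGHLIGHT_COLOR))
    return Palette(tuple(colors), highlight)
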