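"""Interaction state of the two coordinated views, as pure data.

Browser events (drag-select, domain dropdown, mouseover, click-zoom)
are modeled as transition functions that take a state and return a new
one, so every interactive behavior is assertable in tests and an event
log replays deterministically.  No transition mutates its input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .errors import ViewStateError
from .matching import MatchResult, TaxonNode, match_selection, normalize_accession
from .phylogram_layout import ROI, TreeLayout, select_roi
from .taxonomy_io import TaxonomyTable

__all__ = [
    "ViewState",
    "SUPPORTED_DOMAINS",
    "WRONG_DOMAIN_WARNING",
    "TOOLTIP_PLACEMENT",
    "apply_selection",
    "set_domain",
    "hover",
    "tooltip_content",
    "replay_events",
]

SUPPORTED_DOMAINS = ("Archaea", "Bacteria")
WRONG_DOMAIN_WARNING = (
    "No selected species matched the chosen domain's taxonomy; "
    "pick the other domain — your tree selection is retained."
)
#: Rendering hint: tooltips sit left of the hovered label so they never
#: leave the canvas near the right edge.
TOOLTIP_PLACEMENT = "left-of-label"


@dataclass(frozen=True)
class ViewState:
    """Snapshot of both views' interaction state.

    ``selection`` holds original leaf labels in top-to-bottom tree
    order; ``zoom_target`` is a (rank-depth, name) path into the
    current hierarchy; ``warning`` is set only when the last transition
    failed non-fatally (wrong domain).
    """

    canvas: tuple[float, float] = (1200.0, 600.0)
    domain_choice: str | None = None
    selection: tuple[str, ...] = ()
    hovered: str | None = None
    zoom_target: tuple[tuple[int, str], ...] | None = None
    warning: str | None = None


def apply_selection(state: ViewState, roi: ROI, layout: TreeLayout) -> ViewState:
    """Replace the selection with the leaves inside the ROI.

    Mirrors completing a drag: the new selection supersedes the old
    one, and any zoom or pending warning is cleared.
    """
    selected = tuple(select_roi(layout, roi))
    return replace(
        state, selection=selected, hovered=None, zoom_target=None, warning=None
    )


def set_domain(
    state: ViewState,
    domain_name: str,
    tables: Mapping[str, TaxonomyTable],
) -> tuple[ViewState, MatchResult | None]:
    """Choose a domain and match the current selection against its table.

    On at least one match the domain is set and the match result
    returned.  On zero matches the wrong-domain warning is raised into
    the state and the selection is retained untouched, so the user need
    not redraw the ROI.
    """
    if domain_name not in SUPPORTED_DOMAINS:
        raise ViewStateError(
            f"unsupported domain {domain_name!r}; expected one of {SUPPORTED_DOMAINS}"
        )
    if domain_name not in tables:
        raise ViewStateError(f"no taxonomy table loaded for domain {domain_name!r}")
    if not state.selection:
        raise ViewStateError("cannot set a domain before any species are selected")
    result = match_selection(state.selection, tables[domain_name])
    if result.is_empty:
        return replace(state, domain_choice=None, warning=WRONG_DOMAIN_WARNING), None
    return replace(state, domain_choice=domain_name, warning=None), result


def hover(
    state: ViewState, accession: str | None, matched: MatchResult | None = None
) -> ViewState:
    """Set or clear the species under the cursor.

    The hovered accession must belong to the matched selection — it is
    what both views will paint in the highlight orange.  Passing None
    clears the hover.
    """
    if accession is None:
        return replace(state, hovered=None)
    keys = {
        normalize_accession(a)
        for a in (matched.matched_accessions() if matched else state.selection)
    }
    if normalize_accession(accession) not in keys:
        raise ViewStateError(
            f"cannot hover {accession!r}: not in the matched selection"
        )
    return replace(state, hovered=accession)


def tooltip_content(node: TaxonNode) -> tuple[str, str | None, int]:
    """(name, id, size) triple shown in the tooltip for a hierarchy node.

    The id is the original (pre-normalization) accession and is present
    only for species-level nodes; higher ranks report an undefined id.
    """
    return node.name, (node.id if node.depth == 6 else None), node.size


def replay_events(
    state: ViewState,
    events: Sequence[Mapping[str, object]],
    *,
    layout: TreeLayout,
    tables: Mapping[str, TaxonomyTable],
) -> tuple[ViewState, MatchResult | None]:
    """Replay a session's event log (plain key-value records).

    Supported records: ``{"op": "select", "roi": [x0, y0, x1, y1]}``,
    ``{"op": "domain", "name": ...}``, ``{"op": "hover", "accession": ...}``.
    Returns the final state and the last match result.
    """
    result: MatchResult | None = None
    for event in events:
        op = event.get("op")
        if op == "select":
            x0, y0, x1, y1 = event["roi"]  # type: ignore[misc]
            state = apply_selection(state, ROI(x0, y0, x1, y1), layout)
            result = None
        elif op == "domain":
            state, result = set_domain(state, str(event["name"]), tables)
        elif op == "hover":
            accession = event.get("accession")
            state = hover(state, None if accession is None else str(accession), result)
        else:
            raise ViewStateError(f"unknown event op {op!r}")
    return state, result
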