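"""Sensitivity benchmark: icicle drawing time versus selection size.

Measures the elapsed time to produce the icicle view for selections of
increasing size, in two variants: drawing only (partition layout + SVG
serialization of a prebuilt hierarchy) and the full path including the
matching/grouping algorithm.  Each scenario is repeated and summarized
as mean ± sd in milliseconds on a monotonic high-resolution clock; an
ordinary least-squares line of mean time on selection size quantifies
the expected linear growth.
"""

from __future__ import annotations

import gc
import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import TaxicicleError
from .icicle_layout import layout_icicle
from .matching import build_hierarchy, match_selection
from .render import icicle_svg_text
from .style import DEFAULT_PALETTE
from .taxonomy_io import TaxonomyTable
from .tree_io import PhyloTree

__all__ = [
    "BenchmarkRecord",
    "run_sensitivity",
    "run_sensitivity_both",
    "fit_linear",
    "format_table",
]

DEFAULT_NS = (20, 40, 60, 80, 100)
DEFAULT_RUNS = 100
_PANEL_W, _PANEL_H = 840.0, 600.0


@dataclass(frozen=True)
class BenchmarkRecord:
    """Timing summary for one selection size."""

    n_selected: int
    mean_ms: float
    sd_ms: float
    runs: int
    include_matching: bool


def run_sensitivity(
    tree: PhyloTree,
    table: TaxonomyTable,
    ns: Sequence[int] = DEFAULT_NS,
    runs: int = DEFAULT_RUNS,
    include_matching: bool = True,
    seed: int = 0,
) -> list[BenchmarkRecord]:
    """Time icicle creation for seeded random selections of each size.

    For every n a fixed uniform draw of n leaves is made; each of the
    ``runs`` repetitions then times either layout + serialization alone
    (the hierarchy prebuilt outside the clock) or matching + grouping +
    layout + serialization.  SVG serialization (to an in-memory string)
    is included in the drawing time.  Repetitions are blocked: every
    round visits all selection sizes once, so slow machine drift (CPU
    frequency, cache state) is shared across sizes instead of biasing
    one scenario.  A few untimed warm-up rounds precede the clocked
    ones and the garbage collector is paused while the clock runs.
    """
    return _run_blocked(tree, table, ns, runs, (include_matching,), seed)[
        include_matching
    ]


def run_sensitivity_both(
    tree: PhyloTree,
    table: TaxonomyTable,
    ns: Sequence[int] = DEFAULT_NS,
    runs: int = DEFAULT_RUNS,
    seed: int = 0,
) -> dict[bool, list[BenchmarkRecord]]:
    """Time both variants in one interleaved blocked loop.

    Keyed by ``include_matching``.  Because every round visits every
    (size, variant) scenario, the with/without comparison at each n is
    taken under the same machine conditions.
    """
    return _run_blocked(tree, table, ns, runs, (False, True), seed)


def _run_blocked(
    tree: PhyloTree,
    table: TaxonomyTable,
    ns: Sequence[int],
    runs: int,
    variants: Sequence[bool],
    seed: int,
) -> dict[bool, list[BenchmarkRecord]]:
    if runs < 1:
        raise TaxicicleError("runs must be >= 1")
    leaves = tree.leaf_labels()
    rng = np.random.default_rng(seed)
    selections: list[tuple[int, list[str], object]] = []
    for n in ns:
        if n > len(leaves):
            raise TaxicicleError(
                f"cannot select {n} species from a tree with {len(leaves)} leaves"
            )
        idx = rng.choice(len(leaves), size=n, replace=False)
        selection = [leaves[int(i)] for i in sorted(idx)]
        prebuilt = build_hierarchy(match_selection(selection, table).matched)
        selections.append((int(n), selection, prebuilt))
    scenarios = [
        (include, n, selection, prebuilt)
        for include in variants
        for n, selection, prebuilt in selections
    ]

    def one_pass(include: bool, selection, prebuilt) -> None:
        if include:
            result = match_selection(selection, table)
            hierarchy = build_hierarchy(result.matched)
        else:
            hierarchy = prebuilt
        rects = layout_icicle(hierarchy, _PANEL_W, _PANEL_H)
        icicle_svg_text(rects, DEFAULT_PALETTE)

    samples = {(include, n): np.empty(runs) for include, n, _, _ in scenarios}
    for _ in range(min(3, runs)):  # warm-up rounds, untimed
        for include, _, selection, prebuilt in scenarios:
            one_pass(include, selection, prebuilt)
    gc_was_enabled = gc.isenabled()
    gc.disable()
    try:
        for r in range(runs):
            for include, n, selection, prebuilt in scenarios:
                t0 = time.perf_counter()
                one_pass(include, selection, prebuilt)
                samples[(include, n)][r] = (time.perf_counter() - t0) * 1000.0
    finally:
        if gc_was_enabled:
            gc.enable()
    return {
        include: [
            BenchmarkRecord(
                n_selected=n,
                mean_ms=float(samples[(include, n)].mean()),
                sd_ms=float(samples[(include, n)].std(ddof=0)),
                runs=runs,
                include_matching=include,
            )
            for n, _, _ in selections
        ]
        for include in variants
    }


def fit_linear(
    records: Sequence[BenchmarkRecord] | Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """OLS fit of mean time on selection size: (slope, intercept, correlation).

    Accepts benchmark records or plain (n, mean_ms) pairs, so printed
    summary tables can be refit directly.
    """
    if len(records) < 2:
        raise TaxicicleError("need at least 2 points for a linear fit")
    if isinstance(records[0], BenchmarkRecord):
        xs = [r.n_selected for r in records]  # type: ignore[union-attr]
        ys = [r.mean_ms for r in records]  # type: ignore[union-attr]
    else:
        xs = [float(p[0]) for p in records]  # type: ignore[index]
        ys = [float(p[1]) for p in records]  # type: ignore[index]
    fit = stats.linregress(xs, ys)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def format_table(records: Sequence[BenchmarkRecord]) -> str:
    """Tab-separated summary table (selection size, mean ms, sd ms)."""
    lines = [
        "Number of selected species in ROI on phylogenetic tree\t"
        "Average elapsed time (ms)\tStandard deviation (ms)"
    ]
    for record in records:
        lines.append(
            f"{record.n_selected}\t{record.mean_ms:.2f}\t{record.sd_ms:.2f}"
        )
    return "\n".join(lines) + "\n"
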