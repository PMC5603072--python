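"""Scaffold ordering and orientation from pairwise recombination fractions.

Within one linkage group, markers are already ordered inside each scaffold by
their physical position, so a scaffold is a rigid block that can only be
placed and flipped.  The mean recombination fraction between two scaffolds'
marker sets (their *divergence*) drives an agglomerative, UPGMA-like merge:
the two closest blocks are joined end-to-end, choosing among the four
possible junctions the one with the lowest mean rf between the facing
terminal markers.  A round of steepest-descent optimization (single-scaffold
flips, adjacent swaps, relocations) then polishes the layout against the
same terminal-junction objective.

Whole-chromosome reflection is unresolvable from rf alone; layouts are
canonicalized with the lexicographically smaller end scaffold leftmost.
Scaffolds with fewer than two distinct marker positions have no internal
direction and are reported as ``+`` with an orientation-unknown flag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .linkage import LinkageGroupAssignment, RecombinationMatrix

logger = logging.getLogger(__name__)

Order = list[tuple[str, str]]  # ordered (scaffold_id, "+"/"-")


@dataclass
class MarkerMap:
    """Marker placement on scaffolds, as indices into a RecombinationMatrix."""

    order: dict[str, list[int]]  # scaffold -> marker rm-indices sorted by bp
    n_distinct_positions: dict[str, int]

    def orientable(self, sid: str) -> bool:
        return self.n_distinct_positions.get(sid, 0) >= 2


def build_marker_map(
    rm: RecombinationMatrix,
    marker_to_scaffold: Mapping[str, str],
    marker_position: Mapping[str, int],
) -> MarkerMap:
    index = rm.index()
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for mid, sid in marker_to_scaffold.items():
        if mid not in index:
            continue
        by_scaffold.setdefault(sid, []).append((marker_position[mid], index[mid]))
    order = {}
    n_distinct = {}
    for sid, entries in by_scaffold.items():
        entries.sort()
        order[sid] = [k for _, k in entries]
        n_distinct[sid] = len({p for p, _ in entries})
    return MarkerMap(order, n_distinct)


@dataclass
class ScaffoldDivergence:
    """Mean pairwise marker rf between scaffolds of one linkage group."""

    scaffold_ids: list[str]
    d: np.ndarray  # NaN where undefined
    support: np.ndarray  # usable marker-pair counts

    def index(self) -> dict[str, int]:
        return {sid: k for k, sid in enumerate(self.scaffold_ids)}


def scaffold_divergence(
    rm: RecombinationMatrix,
    marker_map: MarkerMap,
    scaffold_ids: Sequence[str],
) -> ScaffoldDivergence:
    """Unweighted mean of usable rf entries across two scaffolds' marker sets."""
    sids = sorted(scaffold_ids)
    m = rm.n_markers
    sel = np.zeros((len(sids), m))
    for k, sid in enumerate(sids):
        sel[k, marker_map.order[sid]] = 1.0
    usable = rm.usable()
    rf0 = np.where(usable, np.nan_to_num(rm.rf), 0.0)
    sums = sel @ rf0 @ sel.T
    counts = sel @ usable.astype(float) @ sel.T
    with np.errstate(invalid="ignore"):
        d = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)
    np.fill_diagonal(d, np.nan)
    return ScaffoldDivergence(sids, d, counts.astype(np.int64))


@dataclass
class ScaffoldLayout:
    """Ordered, signed scaffold lists per chromosome-scale group."""

    groups: dict[Any, Order] = field(default_factory=dict)
    orientation_known: dict[str, bool] = field(default_factory=dict)

    def all_scaffolds(self) -> list[str]:
        return [sid for order in self.groups.values() for sid, _ in order]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, order in self.groups.items():
            for rank, (sid, orient) in enumerate(order, 1):
                rows.append(
                    {
                        "chromosome": g,
                        "scaffold": sid,
                        "orientation": orient,
                        "rank": rank,
                        "orientation_known": self.orientation_known.get(sid, False),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["chromosome", "scaffold", "orientation", "rank",
                     "orientation_known"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScaffoldLayout":
        layout = cls()
        for g, grp in df.groupby("chromosome", sort=False):
            grp = grp.sort_values("rank")
            layout.groups[g] = list(zip(grp["scaffold"], grp["orientation"]))
            for sid, known in zip(grp["scaffold"], grp["orientation_known"]):
                layout.orientation_known[sid] = bool(known)
        return layout


def _oriented_markers(sid: str, orient: str, marker_map: MarkerMap) -> list[int]:
    order = marker_map.order[sid]
    return order if orient == "+" else order[::-1]


def _junction_rf(
    left: tuple[str, str],
    right: tuple[str, str],
    rm: RecombinationMatrix,
    marker_map: MarkerMap,
    k_terminal: int,
) -> float:
    """Mean usable rf between the facing terminal markers of two scaffolds.

    A junction with no usable marker pair contributes the maximum (0.5), so
    uninformative junctions are never preferred.
    """
    lm = _oriented_markers(*left, marker_map)[-k_terminal:]
    rmk = _oriented_markers(*right, marker_map)[:k_terminal]
    sub = rm.rf[np.ix_(lm, rmk)]
    ok = rm.usable()[np.ix_(lm, rmk)]
    if not ok.any():
        return 0.5
    return float(sub[ok].mean())


def junction_cost(
    order: Order,
    rm: RecombinationMatrix,
    marker_map: MarkerMap,
    k_terminal: int = 3,
) -> float:
    """Sum of terminal-marker mean rf over adjacent scaffold junctions."""
    return sum(
        _junction_rf(order[k], order[k + 1], rm, marker_map, k_terminal)
        for k in range(len(order) - 1)
    )


def _flip_block(block: Order) -> Order:
    return [(sid, "-" if o == "+" else "+") for sid, o in reversed(block)]


def canonicalize(order: Order) -> Order:
    """Reflect so the lexicographically smaller end scaffold is leftmost."""
    if order and order[-1][0] < order[0][0]:
        return _flip_block(order)
    return list(order)


def upgma_order(
    sd: ScaffoldDivergence,
    rm: RecombinationMatrix,
    marker_map: MarkerMap,
    k_terminal: int = 3,
) -> list[Order]:
    """Initial layout by agglomerative average-linkage merging of blocks.

    Block-pair distance is the mean of the *defined* scaffold divergences
    across the two blocks (+inf when none is defined, so disconnected
    components never merge).  Each merge joins the two closest blocks at the
    end-to-end junction minimizing the terminal-marker mean rf; ties in
    distance break on the lexicographically smallest scaffold-id pair.
    Returns one block per connected component, largest first.
    """
    idx = sd.index()
    blocks: list[Order] = [[(sid, "+")] for sid in sd.scaffold_ids]

    def block_distance(x: Order, y: Order) -> float:
        vals = [
            sd.d[idx[a], idx[b]]
            for (a, _), (b, _) in itertools.product(x, y)
            if not np.isnan(sd.d[idx[a], idx[b]])
        ]
        return float(np.mean(vals)) if vals else float("inf")

    while len(blocks) > 1:
        best = None
        for i, j in itertools.combinations(range(len(blocks)), 2):
            dist = block_distance(blocks[i], blocks[j])
            if not np.isfinite(dist):
                continue
            tie = tuple(sorted((min(s for s, _ in blocks[i]),
                                min(s for s, _ in blocks[j]))))
            key = (dist, tie)
            if best is None or key < best[0]:
                best = (key, i, j)
        if best is None:
            break  # disconnected divergence graph
        _, i, j = best
        a, b = blocks[i], blocks[j]
        candidates = [a + b, a + _flip_block(b), _flip_block(a) + b, b + a]
        costs = [
            _junction_rf(cand[len_left - 1], cand[len_left], rm, marker_map,
                         k_terminal)
            for cand, len_left in zip(
                candidates, [len(a), len(a), len(a), len(b)]
            )
        ]
        merged = candidates[int(np.argmin(costs))]
        blocks = [blk for k, blk in enumerate(blocks) if k not in (i, j)]
        blocks.append(merged)
    if len(blocks) > 1:
        logger.warning(
            "divergence graph disconnected: %d blocks returned", len(blocks)
        )
    blocks.sort(key=lambda blk: (-len(blk), blk[0][0]))
    return [canonicalize(blk) for blk in blocks]


def _moves(order: Order) -> Iterable[Order]:
    n = len(order)
    for i in range(n):  # single-scaffold flip
        new = list(order)
        sid, o = new[i]
        new[i] = (sid, "-" if o == "+" else "+")
        yield new
    for i in range(n - 1):  # adjacent-pair swap
        new = list(order)
        new[i], new[i + 1] = new[i + 1], new[i]
        yield new
    for i in range(n):  # single-scaffold relocation
        rest = order[:i] + order[i + 1:]
        for j in range(n):
            if j == i:
                continue
            yield rest[:j] + [order[i]] + rest[j:]


def optimize_layout(
    order: Order,
    rm: RecombinationMatrix,
    marker_map: MarkerMap,
    k_terminal: int = 3,
    max_rounds: int = 1,
) -> Order:
    """Steepest-descent polish of a layout under the junction-cost objective.

    A round applies the best cost-reducing move (flip, adjacent swap or
    relocation) repeatedly until no move improves — a local fixed point.  The
    cost never increases.
    """
    current = list(order)
    cost = junction_cost(current, rm, marker_map, k_terminal)
    for _ in range(max_rounds):
        improved_in_round = False
        while True:
            best_cost, best_order = cost, None
            for cand in _moves(current):
                c = junction_cost(cand, rm, marker_map, k_terminal)
                if c < best_cost - 1e-12:
                    best_cost, best_order = c, cand
            if best_order is None:
                break
            current, cost = best_order, best_cost
            improved_in_round = True
        if not improved_in_round:
            break
    return canonicalize(current)


def anchor(
    rm: RecombinationMatrix,
    lga: LinkageGroupAssignment,
    marker_to_scaffold: Mapping[str, str],
    marker_position: Mapping[str, int],
    k_terminal: int = 3,
    rounds: int = 1,
    min_group_size: int = 2,
) -> ScaffoldLayout:
    """Order and orient the scaffolds of every non-singleton linkage group.

    Each scaffold joins the linkage group holding the majority of its
    markers.  Disconnected sub-blocks of a group are laid out separately and
    keyed ``(group, part)``.
    """
    marker_map = build_marker_map(rm, marker_to_scaffold, marker_position)
    scaffold_group: dict[str, int] = {}
    for sid, members in marker_map.order.items():
        votes: dict[int, int] = {}
        for k in members:
            g = lga.groups[rm.marker_ids[k]]
            if lga.sizes[g] >= min_group_size:
                votes[g] = votes.get(g, 0) + 1
        if votes:
            scaffold_group[sid] = max(votes, key=lambda g: (votes[g], -g))

    layout = ScaffoldLayout()
    for g in sorted(set(scaffold_group.values())):
        sids = sorted(s for s, gg in scaffold_group.items() if gg == g)
        group_map = MarkerMap(
            {s: marker_map.order[s] for s in sids},
            {s: marker_map.n_distinct_positions[s] for s in sids},
        )
        sd = scaffold_divergence(rm, group_map, sids)
        blocks = upgma_order(sd, rm, group_map, k_terminal)
        for part, block in enumerate(blocks):
            order = optimize_layout(block, rm, group_map, k_terminal, rounds)
            final: Order = []
            for sid, orient in order:
                if group_map.orientable(sid):
                    final.append((sid, orient))
                    layout.orientation_known[sid] = True
                else:
                    final.append((sid, "+"))
                    layout.orientation_known[sid] = False
            key = g if len(blocks) == 1 else (g, part + 1)
            layout.groups[key] = final
    return layout


def export_linkage_heatmap(
    rm: RecombinationMatrix,
    order: Order,
    marker_map: MarkerMap,
) -> tuple[list[str], np.ndarray, list[int]]:
    """rf matrix reordered along a layout, with scaffold boundary offsets.

    Markers are sorted by layout position, then by orientation-adjusted
    within-scaffold position.  Boundaries include 0 and the total marker
    count, so consecutive pairs delimit each scaffold's markers (the grey
    bars of a linkage dot plot).
    """
    indices: list[int] = []
    boundaries = [0]
    for sid, orient in order:
        indices.extend(_oriented_markers(sid, orient, marker_map))
        boundaries.append(len(indices))
    ids = [rm.marker_ids[k] for k in indices]
    return ids, rm.rf[np.ix_(indices, indices)], boundaries


# ---------------------------------------------------------------------------
# Evaluation against a known truth
# ---------------------------------------------------------------------------


def layout_accuracy(
    layouts: Mapping[Any, Order],
    true_layout: Mapping[str, Order],
    orientable: set[str] | None = None,
) -> dict:
    """Adjacency and orientation recovery of a layout versus the truth.

    Adjacency recall is the fraction of true adjacent scaffold pairs that are
    adjacent in the recovered layout (reflection-invariant).  Orientation
    accuracy is computed per recovered group against the true chromosome
    holding the majority of its scaffolds, under the better of the two
    whole-group reflections, over orientable scaffolds only.
    """
    true_adj = {
        frozenset((a[0], b[0]))
        for order in true_layout.values()
        for a, b in zip(order, order[1:])
    }
    pred_adj = {
        frozenset((a[0], b[0]))
        for order in layouts.values()
        for a, b in zip(order, order[1:])
    }
    adjacency = len(true_adj & pred_adj) / len(true_adj) if true_adj else 1.0

    true_orient = {
        sid: o for order in true_layout.values() for sid, o in order
    }
    chrom_of = {
        sid: chrom for chrom, order in true_layout.items() for sid, _ in order
    }
    matches = 0
    denom = 0
    for order in layouts.values():
        chroms = [chrom_of[sid] for sid, _ in order if sid in chrom_of]
        if not chroms:
            continue
        target = max(set(chroms), key=chroms.count)
        scored = [
            (sid, o)
            for sid, o in order
            if chrom_of.get(sid) == target
            and (orientable is None or sid in orientable)
        ]
        same = sum(o == true_orient[sid] for sid, o in scored)
        matches += max(same, len(scored) - same)
        denom += len(scored)
    orientation = matches / denom if denom else 1.0
    return {
        "adjacency_recall": adjacency,
        "orientation_accuracy": orientation,
        "n_true_adjacencies": len(true_adj),
        "n_orientable_scored": denom,
    }
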