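"""Linkage-group formation, marker ordering, cM positions, bins, summaries.

Grouping takes the transitive closure of the pairwise linkage graph (edge
when LOD >= lod_min and r <= r_max).  Ordering minimizes the lexicographic
objective (total obligate crossovers, summed adjacent Kosambi length),
starting from greedy nearest-neighbour chaining on r-hat and refining with
2-opt segment reversals and window ripple (windows of 2-4) until no move
improves.  Positions are cumulative Kosambi distances over adjacent
two-point estimates; markers showing no recombination with their
predecessor share a genetic bin and a position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genodata import CODE_MISSING, MapTable, MarkerGenotypeMatrix
from .linkage import _crossovers_from_doses, map_function, pairwise_estimates


class MapBuildError(ValueError):
    """Raised for unbuildable groups (e.g. an infinite adjacent gap)."""


@dataclass
class LinkageGroup:
    group_id: str
    marker_ids: list[str]
    positions: np.ndarray  # cM, nondecreasing, starts at 0
    bins: np.ndarray  # bin index per marker, 0-based, nondecreasing

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_bins(self) -> int:
        return int(self.bins[-1]) + 1 if len(self.bins) else 0

    @property
    def coverage_cm(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    def bin_positions(self) -> np.ndarray:
        """Unique map positions, one per genetic bin."""
        _, first = np.unique(self.bins, return_index=True)
        return self.positions[first]


@dataclass
class LinkageMap:
    groups: list[LinkageGroup]

    def group(self, group_id: str) -> LinkageGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    def to_map_table(self) -> MapTable:
        rows = []
        for g in self.groups:
            for mk, pos, b in zip(g.marker_ids, g.positions, g.bins):
                rows.append((mk, g.group_id, float(pos), int(b)))
        df = pd.DataFrame(rows, columns=list(MapTable.COLUMNS))
        return MapTable(df)

    def total_length_cm(self) -> float:
        return float(sum(g.coverage_cm for g in self.groups))


def map_from_table(table: MapTable) -> LinkageMap:
    """Rebuild a LinkageMap view from a tidy map table."""
    groups = []
    for gid, sub in table.table.groupby("group_id", sort=True):
        sub = sub.sort_values(["position_cM", "marker_id"], kind="stable")
        positions = sub["position_cM"].to_numpy(dtype=float)
        bin_raw = sub["bin_id"].to_numpy()
        _, bins = np.unique(bin_raw, return_inverse=True)
        groups.append(LinkageGroup(str(gid), list(sub["marker_id"]), positions, bins))
    return LinkageMap(groups)


# ---------------------------------------------------------------------------
# Grouping


def group_markers(
    marker_ids: list[str],
    r: np.ndarray,
    lod: np.ndarray,
    lod_min: float = 6.0,
    r_max: float = 0.45,
) -> list[list[str]]:
    """Partition markers into linkage groups (connected components).

    An edge joins two markers when ``lod >= lod_min`` and ``r <= r_max``;
    groups are the transitive closure.  Singleton groups are returned last.
    """
    with np.errstate(invalid="ignore"):
        adj = (lod >= lod_min) & (r <= r_max)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [[] for _ in range(n_comp)]
    for k, lab in enumerate(labels):
        groups[lab].append(marker_ids[k])
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


# ---------------------------------------------------------------------------
# Ordering


def _surrogate_matrices(m: MarkerGenotypeMatrix, idx: np.ndarray, r: np.ndarray):
    """Crossover-cost and length matrices restricted to one group.

    The crossover cost between two markers counts, over individuals observed
    at both, the gametes that must be recombinant: 1 per A-H/H-B pair and 2
    per A-B pair.  Summed over adjacent pairs of an order this equals the
    total obligate crossover count whenever there are no missing calls.
    """
    calls = m.calls[:, idx]
    onehot = [(calls == c).astype(float) for c in (0, 1, 2)]
    t = {}
    for a in range(3):
        for b in range(3):
            t[a, b] = onehot[a].T @ onehot[b]
    xcost = t[0, 1] + t[1, 0] + t[1, 2] + t[2, 1] + 2.0 * (t[0, 2] + t[2, 0])
    r_sub = r[np.ix_(idx, idx)]
    r_cap = np.minimum(np.nan_to_num(r_sub, nan=0.4999), 0.4999)
    with np.errstate(divide="ignore"):
        length = 25.0 * np.log((1.0 + 2.0 * r_cap) / (1.0 - 2.0 * r_cap))
    return xcost, length


def _adjacent_cost(order: np.ndarray, mat: np.ndarray) -> float:
    return float(mat[order[:-1], order[1:]].sum())


def _greedy_chain(r_sub: np.ndarray, rng: np.random.Generator) -> list[int]:
    """Initial order: start at the tightest pair, extend ends by nearest r."""
    n = r_sub.shape[0]
    if n <= 2:
        return list(range(n))
    d = np.nan_to_num(r_sub.copy(), nan=1.0)
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    chain = [int(i), int(j)]
    free = set(range(n)) - set(chain)
    while free:
        free_list = sorted(free)
        head, tail = chain[0], chain[-1]
        dh = np.array([d[head, k] for k in free_list])
        dt = np.array([d[tail, k] for k in free_list])
        if dh.min() < dt.min():
            k = free_list[int(np.argmin(dh))]
            chain.insert(0, k)
        else:
            k = free_list[int(np.argmin(dt))]
            chain.append(k)
        free.discard(k)
    return chain


def _two_opt_pass(order: np.ndarray, xcost: np.ndarray, length: np.ndarray) -> bool:
    """One sweep of segment reversals; returns True if any move improved."""
    n = len(order)
    improved = False
    eps = 1e-12
    for i in range(n - 1):
        for j in range(i + 1, n):
            a = order[i - 1] if i > 0 else -1
            b = order[i]
            c = order[j]
            dnext = order[j + 1] if j + 1 < n else -1
            dx = 0.0
            dl = 0.0
            if a >= 0:
                dx += xcost[a, c] - xcost[a, b]
                dl += length[a, c] - length[a, b]
            if dnext >= 0:
                dx += xcost[b, dnext] - xcost[c, dnext]
                dl += length[b, dnext] - length[c, dnext]
            if dx < -eps or (abs(dx) <= eps and dl < -eps):
                order[i : j + 1] = order[i : j + 1][::-1]
                improved = True
    return improved


def _lex_better(key: tuple[float, float], ref: tuple[float, float], eps: float = 1e-9) -> bool:
    return key[0] < ref[0] - eps or (abs(key[0] - ref[0]) <= eps and key[1] < ref[1] - eps)


def _ripple_pass(order: np.ndarray, xcost: np.ndarray, length: np.ndarray) -> bool:
    """Window ripple: remove a window of 2-4 markers, reinsert anywhere
    (either orientation) if the lexicographic objective improves."""
    improved = False
    for w in (2, 3, 4):
        if len(order) <= w + 1:
            continue
        i = 0
        while i + w <= len(order):
            window = order[i : i + w].copy()
            rest = np.concatenate([order[:i], order[i + w :]])
            best_key = (_adjacent_cost(order, xcost), _adjacent_cost(order, length))
            best_cand = None
            for pos in range(len(rest) + 1):
                for seg in (window, window[::-1]):
                    cand = np.concatenate([rest[:pos], seg, rest[pos:]])
                    key = (_adjacent_cost(cand, xcost), _adjacent_cost(cand, length))
                    if _lex_better(key, best_key):
                        best_key, best_cand = key, cand
            if best_cand is not None:
                order[:] = best_cand
                improved = True
            i += 1
    return improved


def order_markers(
    group: list[str],
    m: MarkerGenotypeMatrix,
    r: np.ndarray,
    seed: int = 0,
    reference_order: list[str] | None = None,
    max_rounds: int = 40,
) -> list[str]:
    """Order one linkage group's markers.

    ``r`` is the full all-pairs recombination-fraction matrix over
    ``m.marker_ids``.  The returned order (or its mirror — orientation is
    arbitrary unless ``reference_order`` is given) minimizes the
    lexicographic objective (obligate crossovers, Kosambi length) found by
    the chaining + 2-opt + ripple heuristic.
    """
    if len(group) < 2:
        return list(group)
    idx = np.array([m.marker_index(mk) for mk in group])
    r_sub = r[np.ix_(idx, idx)]
    if np.isnan(r_sub).any():
        finite = ~np.isnan(r_sub)
        np.fill_diagonal(finite, False)
        lonely = np.where(~finite.any(axis=1))[0]
        if lonely.size:
            raise MapBuildError(
                f"marker {group[int(lonely[0])]!r} shares no observed individuals "
                "with the rest of its group"
            )
    rng = np.random.default_rng(seed)
    xcost, length = _surrogate_matrices(m, idx, r)
    order = np.array(_greedy_chain(r_sub, rng), dtype=int)
    for _ in range(max_rounds):
        moved = _two_opt_pass(order, xcost, length)
        moved |= _ripple_pass(order, xcost, length)
        if not moved:
            break
    result = [group[k] for k in order]
    if reference_order is not None:
        ref_rank = {mk: k for k, mk in enumerate(reference_order)}
        common = [mk for mk in result if mk in ref_rank]
        if len(common) >= 2:
            ours = np.arange(len(common))
            theirs = np.array([ref_rank[mk] for mk in common])
            if np.corrcoef(ours, theirs)[0, 1] < 0:
                result = result[::-1]
    else:
        if result[0] > result[-1]:
            result = result[::-1]
    return result


def ordering_objective(
    order: list[str], m: MarkerGenotypeMatrix, r: np.ndarray
) -> tuple[float, float]:
    """Exact (obligate crossovers, Kosambi length) for a candidate order."""
    idx = [m.marker_index(mk) for mk in order]
    doses = m.calls[:, idx].astype(float)
    doses[doses == CODE_MISSING] = np.nan
    xo = _crossovers_from_doses(doses)
    r_adj = np.minimum(np.nan_to_num(r[idx[:-1], idx[1:]], nan=0.4999), 0.4999)
    length = float(np.sum(25.0 * np.log((1.0 + 2.0 * r_adj) / (1.0 - 2.0 * r_adj))))
    return xo, length


# ---------------------------------------------------------------------------
# Positions and bins


def assign_positions_and_bins(
    ordered: list[str],
    m: MarkerGenotypeMatrix,
    r: np.ndarray,
    group_id: str = "LG1",
    bin_tol: float = 1e-6,
) -> LinkageGroup:
    """Cumulative Kosambi positions along a fixed order; r-hat = 0 joins bins."""
    idx = [m.marker_index(mk) for mk in ordered]
    positions = np.zeros(len(ordered))
    bins = np.zeros(len(ordered), dtype=int)
    for k in range(1, len(ordered)):
        r_adj = r[idx[k - 1], idx[k]]
        if np.isnan(r_adj) or r_adj >= 0.5 - 1e-9:
            raise MapBuildError(
                f"adjacent markers {ordered[k - 1]!r} and {ordered[k]!r} are unlinked "
                "(r = 0.5): infinite gap"
            )
        if r_adj < bin_tol:
            positions[k] = positions[k - 1]
            bins[k] = bins[k - 1]
        else:
            positions[k] = positions[k - 1] + map_function(float(r_adj), "kosambi", "r_to_cM")
            bins[k] = bins[k - 1] + 1
    return LinkageGroup(group_id, list(ordered), positions, bins)


def build_map(
    m: MarkerGenotypeMatrix,
    lod_min: float = 6.0,
    r_max: float = 0.45,
    seed: int = 0,
    tol: float = 1e-6,
    reference_orders: dict[str, list[str]] | None = None,
) -> LinkageMap:
    """End-to-end map construction: estimates, grouping, ordering, positions.

    Groups are named LG1, LG2, ... from largest to smallest.  When
    ``reference_orders`` maps a group id to a marker order, that group's
    orientation is normalized against it.
    """
    r, lod, _ = pairwise_estimates(m, tol=tol)
    groups = group_markers(m.marker_ids, r, lod, lod_min=lod_min, r_max=r_max)
    built = []
    for g_num, members in enumerate(groups, start=1):
        gid = f"LG{g_num}"
        if len(members) == 1:
            built.append(LinkageGroup(gid, members, np.zeros(1), np.zeros(1, dtype=int)))
            continue
        ref = reference_orders.get(gid) if reference_orders else None
        ordered = order_markers(members, m, r, seed=seed, reference_order=ref)
        built.append(assign_positions_and_bins(ordered, m, r, group_id=gid))
    return LinkageMap(built)


# ---------------------------------------------------------------------------
# Summaries


def average_bin_interval(coverage_cm: float, n_bins: int) -> float:
    """Average marker-bin interval, reported to one decimal (coverage / bins)."""
    if n_bins <= 0:
        return 0.0
    return round(coverage_cm / n_bins, 1)


def summarize_map(lmap: LinkageMap) -> pd.DataFrame:
    """Per-group and total marker/bin counts, coverage, and bin intervals.

    Columns: group_id, n_markers, n_bins, coverage_cM, max_interval_cM,
    average_interval_cM (= coverage / bins, one decimal).  The final row
    aggregates totals; its max interval is the genome-wide maximum.
    """
    rows = []
    for g in lmap.groups:
        bp = g.bin_positions()
        max_gap = float(np.diff(bp).max()) if len(bp) > 1 else 0.0
        rows.append(
            {
                "group_id": g.group_id,
                "n_markers": g.n_markers,
                "n_bins": g.n_bins,
                "coverage_cM": round(g.coverage_cm, 1),
                "max_interval_cM": round(max_gap, 1),
                "average_interval_cM": average_bin_interval(g.coverage_cm, g.n_bins),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        total_cov = float(sum(g.coverage_cm for g in lmap.groups))
        total_bins = int(sum(g.n_bins for g in lmap.groups))
        total = {
            "group_id": "Total",
            "n_markers": int(df["n_markers"].sum()),
            "n_bins": total_bins,
            "coverage_cM": round(total_cov, 1),
            "max_interval_cM": df["max_interval_cM"].max(),
            "average_interval_cM": average_bin_interval(total_cov, total_bins),
        }
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return df
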