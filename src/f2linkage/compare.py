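"""Map comparison: distortion scan, resampled map lengths, colinearity.

Covers the comparative analyses run between F2 maps of different crosses:
a per-marker chi-square scan for segregation distortion against the 1:2:1
F2 expectation; ordinary least squares of per-group map-expansion ratios
on distorted-marker fractions; construction of >= 5 cM spaced marker
subsets and the distribution of map lengths re-estimated from them;
one-way ANOVA between populations' length distributions; rank-based
colinearity R^2 between maps; and detection of locally inverted marker
blocks (runs with strongly negative rank correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import CODE_MISSING, MarkerGenotypeMatrix
from .linkage import pairwise_estimates
from .mapbuild import LinkageMap, MapBuildError, assign_positions_and_bins, order_markers


class CompareError(ValueError):
    """Raised when a comparison is undefined on the given inputs."""


# ---------------------------------------------------------------------------
# Segregation distortion


@dataclass
class DistortionResult:
    marker_id: str
    n_aa: int
    n_h: int
    n_bb: int
    chi2: float
    p: float
    distorted: bool
    testable: bool


def distortion_chisq_scan(
    m: MarkerGenotypeMatrix, alpha: float = 0.05, min_calls: int = 10
) -> pd.DataFrame:
    """Chi-square goodness-of-fit against 1:2:1 per marker (df = 2).

    Markers with fewer than ``min_calls`` observed genotypes are flagged
    untestable and never counted as distorted.  Returns one row per marker:
    marker_id, n_aa, n_h, n_bb, chi2, p, distorted, testable.
    """
    calls = m.calls
    counts = np.stack([(calls == c).sum(axis=0) for c in (0, 1, 2)], axis=1).astype(float)
    n_obs = counts.sum(axis=1)
    expected = n_obs[:, None] * np.array([0.25, 0.5, 0.25])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(n_obs > 0, ((counts - expected) ** 2 / np.where(expected > 0, expected, 1)).sum(axis=1), np.nan)
    p = stats.chi2.sf(chi2, df=2)
    testable = n_obs >= min_calls
    distorted = testable & (p < alpha)
    return pd.DataFrame(
        {
            "marker_id": m.marker_ids,
            "n_aa": counts[:, 0].astype(int),
            "n_h": counts[:, 1].astype(int),
            "n_bb": counts[:, 2].astype(int),
            "chi2": chi2,
            "p": p,
            "distorted": distorted,
            "testable": testable,
        }
    )


def distorted_fraction_by_group(scan: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Fraction of testable markers flagged distorted, per linkage group."""
    df = scan.merge(groups.rename("group_id"), left_on="marker_id", right_index=True)
    df = df[df["testable"]]
    return df.groupby("group_id")["distorted"].mean()


def distortion_expansion_regression(
    distorted_fraction: np.ndarray | pd.Series,
    length_ratio: np.ndarray | pd.Series,
) -> tuple[float, float, float]:
    """OLS of per-group length ratio on distorted fraction.

    Returns ``(slope, r_squared, p)`` with a two-sided p-value for slope != 0.
    """
    x = np.asarray(distorted_fraction, dtype=float)
    y = np.asarray(length_ratio, dtype=float)
    if len(x) < 3:
        raise CompareError("need at least 3 groups for the regression")
    if np.allclose(x, x[0]):
        raise CompareError("zero variance in the distorted-fraction predictor")
    if np.allclose(y, y[0]):  # flat response: no expansion signal
        return 0.0, 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


# ---------------------------------------------------------------------------
# Spaced-subset resampling


def select_spaced_subset(
    lmap: LinkageMap,
    min_spacing: float = 5.0,
    rng: np.random.Generator | int = 0,
) -> list[str]:
    """Random marker subset with consecutive retained positions >= min_spacing.

    Per group, a random bin within the first ``min_spacing`` cM anchors a
    greedy sweep in both directions that keeps bins at least ``min_spacing``
    apart; one random marker represents each retained bin.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    subset: list[str] = []
    for g in lmap.groups:
        if g.n_markers == 0:
            continue
        bin_pos = g.bin_positions()
        n_bins = len(bin_pos)
        anchors = np.where(bin_pos <= min_spacing)[0]
        anchor = int(rng.choice(anchors)) if len(anchors) else 0
        keep = [anchor]
        last = bin_pos[anchor]
        for b in range(anchor + 1, n_bins):  # rightward sweep
            if bin_pos[b] - last >= min_spacing:
                keep.append(b)
                last = bin_pos[b]
        last = bin_pos[anchor]
        for b in range(anchor - 1, -1, -1):  # leftward sweep
            if last - bin_pos[b] >= min_spacing:
                keep.append(b)
                last = bin_pos[b]
        keep.sort()
        bins = np.asarray(g.bins)
        for b in keep:
            members = [g.marker_ids[k] for k in np.where(bins == b)[0]]
            subset.append(members[int(rng.integers(0, len(members)))])
    return subset


@dataclass
class ResampleResult:
    """Resampled map lengths: one row per successful iteration."""

    lengths: pd.DataFrame  # columns: iteration, group_id columns..., total
    subset_sizes: list[int]
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def total_lengths(self) -> np.ndarray:
        return self.lengths["total"].to_numpy()


def resampled_length_distribution(
    m: MarkerGenotypeMatrix,
    lmap: LinkageMap,
    iterations: int = 60,
    min_spacing: float = 5.0,
    seed: int = 0,
    tol: float = 1e-6,
) -> ResampleResult:
    """Re-estimate map length from spaced subsets, ``iterations`` times.

    Each iteration draws a >= ``min_spacing`` spaced subset, then — from the
    genotypes alone — re-estimates pairwise linkage, re-orders each group's
    subset markers, and rebuilds cumulative Kosambi positions.  Group
    membership follows the source map; the order is not reused.  Iterations
    whose subset cannot be rebuilt (e.g. an unlinked adjacent pair) are
    recorded as failures and skipped.
    """
    if iterations < 1:
        raise CompareError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    group_of = {mk: g.group_id for g in lmap.groups for mk in g.marker_ids}
    rows = []
    sizes = []
    failures = []
    for it in range(iterations):
        subset = select_spaced_subset(lmap, min_spacing=min_spacing, rng=rng)
        sizes.append(len(subset))
        sub = m.subset_markers(subset)
        r, _, _ = pairwise_estimates(sub, tol=tol)
        order_seed = int(rng.integers(0, 2**31 - 1))
        row = {"iteration": it}
        try:
            total = 0.0
            for g in lmap.groups:
                members = [mk for mk in subset if group_of[mk] == g.group_id]
                if len(members) < 2:
                    row[g.group_id] = 0.0
                    continue
                ordered = order_markers(members, sub, r, seed=order_seed)
                built = assign_positions_and_bins(ordered, sub, r, group_id=g.group_id)
                row[g.group_id] = built.coverage_cm
                total += built.coverage_cm
            row["total"] = total
        except MapBuildError as exc:
            failures.append((it, str(exc)))
            continue
        rows.append(row)
    if not rows:
        raise CompareError("every resampling iteration failed")
    return ResampleResult(pd.DataFrame(rows), sizes, failures)


def anova_compare(length_vectors: dict[str, np.ndarray]) -> tuple[float, tuple[int, int], float]:
    """One-way fixed-effects ANOVA across populations' length vectors.

    Returns ``(F, (df_between, df_within), p)``.  Zero within-group variance
    with unequal means yields ``F = inf, p = 0.0`` (flagged by the caller).
    """
    groups = [np.asarray(v, dtype=float) for v in length_vectors.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise CompareError("need >= 2 groups with >= 2 values each")
    df_b = len(groups) - 1
    df_w = sum(len(g) for g in groups) - len(groups)
    means = [g.mean() for g in groups]
    if all(np.allclose(g, g[0]) for g in groups):
        if np.allclose(means, means[0]):
            return 0.0, (df_b, df_w), 1.0
        return float("inf"), (df_b, df_w), 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), (df_b, df_w), float(p)


# ---------------------------------------------------------------------------
# Colinearity and inversions


@dataclass
class ColinearityResult:
    group_a: str
    group_b: str
    n_common: int
    r_squared: float
    slope_sign: int
    common_markers: list[str]
    ranks_a: np.ndarray
    ranks_b: np.ndarray
    inverted_blocks: list[tuple[int, int, float]] = field(default_factory=list)


def colinearity_r2(
    map_a: LinkageMap,
    map_b: LinkageMap,
    group_a: str,
    group_b: str,
    min_common: int = 3,
) -> ColinearityResult:
    """Rank-regression R^2 between two maps on their common markers.

    Positions within each group are converted to ranks (ties — co-binned
    markers — get average ranks) and rank_B is regressed on rank_A.
    """
    ga = map_a.group(group_a)
    gb = map_b.group(group_b)
    pos_a = dict(zip(ga.marker_ids, ga.positions))
    pos_b = dict(zip(gb.marker_ids, gb.positions))
    common = [mk for mk in ga.marker_ids if mk in pos_b]
    if len(common) < min_common:
        raise CompareError(
            f"only {len(common)} common markers between {group_a} and {group_b}; need {min_common}"
        )
    ranks_a = stats.rankdata([pos_a[mk] for mk in common])
    ranks_b = stats.rankdata([pos_b[mk] for mk in common])
    res = stats.linregress(ranks_a, ranks_b)
    return ColinearityResult(
        group_a,
        group_b,
        len(common),
        float(res.rvalue**2),
        int(np.sign(res.slope)) if res.slope != 0 else 0,
        common,
        ranks_a,
        ranks_b,
    )


def detect_inverted_blocks(
    ranks_a: np.ndarray,
    ranks_b: np.ndarray,
    min_block: int = 4,
    slope_threshold: float = 0.8,
) -> list[tuple[int, int, float]]:
    """Maximal runs of consecutive markers with strongly negative local order.

    Markers are taken in map-A order; map B is flipped first if the global
    rank correlation is negative (orientation, not disorder).  A block is a
    maximal run of >= ``min_block`` consecutive markers whose within-run
    Spearman correlation is <= ``-slope_threshold``.  Returns
    ``(start_index, end_index, local_correlation)`` tuples (inclusive ends).
    """
    ranks_a = np.asarray(ranks_a, dtype=float)
    ranks_b = np.asarray(ranks_b, dtype=float)
    order = np.argsort(ranks_a, kind="stable")
    b_seq = ranks_b[order]
    n = len(b_seq)
    if n >= 2:
        rho_all = stats.spearmanr(np.arange(n), b_seq).statistic
        if rho_all is not None and not np.isnan(rho_all) and rho_all < 0:
            b_seq = b_seq[::-1]
            # report indices in the original (un-flipped) A order
            flipped = True
        else:
            flipped = False
    else:
        return []
    blocks: list[tuple[int, int, float]] = []
    s = 0
    while s + min_block <= n:
        best_e = -1
        best_rho = 0.0
        for e in range(s + min_block - 1, n):
            seg = b_seq[s : e + 1]
            rho = stats.spearmanr(np.arange(len(seg)), seg).statistic
            if rho is not None and not np.isnan(rho) and rho <= -slope_threshold:
                best_e, best_rho = e, float(rho)
        if best_e >= 0:
            blocks.append((s, best_e, best_rho))
            s = best_e + 1
        else:
            s += 1
    if flipped:
        blocks = [(n - 1 - e, n - 1 - s, rho) for s, e, rho in blocks][::-1]
    return blocks


def compare_maps(
    map_a: LinkageMap,
    map_b: LinkageMap,
    min_common: int = 3,
    min_block: int = 4,
    slope_threshold: float = 0.8,
) -> list[ColinearityResult]:
    """Colinearity + inverted-block scan for every group pair sharing markers.

    Group pairing is by shared marker content: each group of map A is paired
    with the map-B group holding the most of its markers.
    """
    results = []
    member_of_b = {mk: g.group_id for g in map_b.groups for mk in g.marker_ids}
    for ga in map_a.groups:
        hits = pd.Series([member_of_b.get(mk) for mk in ga.marker_ids]).dropna()
        if hits.empty:
            continue
        gb_id = hits.mode().iloc[0]
        try:
            res = colinearity_r2(map_a, map_b, ga.group_id, gb_id, min_common=min_common)
        except CompareError:
            continue
        res.inverted_blocks = detect_inverted_blocks(
            res.ranks_a, res.ranks_b, min_block=min_block, slope_threshold=slope_threshold
        )
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Printed-summary arithmetic


def percent_longer(length_a: float, length_b: float) -> float:
    """How much longer map A is than map B, in percent of B."""
    if length_b <= 0:
        raise CompareError("reference length must be positive")
    return (length_a / length_b - 1.0) * 100.0


def percent_reduction(full_length: float, resampled_length: float) -> float:
    """Reduction of a resampled length relative to the full-map length (%)."""
    if full_length <= 0:
        raise CompareError("full length must be positive")
    return (1.0 - resampled_length / full_length) * 100.0
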