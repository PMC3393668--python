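"""Two-point linkage estimation for codominant F2 markers.

For a pair of codominant loci in coupling phase with recombination fraction
``r`` (and ``q = 1 - r``), the nine F2 joint-genotype classes have
probabilities

======== ========== =========
class    cells       probability
======== ========== =========
corner   AA, BB      q^2 / 4
anti     AB, BA      r^2 / 4
edge     AH, HA, HB, BH   q r / 2
center   HH          (q^2 + r^2) / 2
======== ========== =========

The maximum-likelihood estimate of ``r`` is found by EM over the hidden
number of recombinant gametes: corners carry 0, edges 1, anti-corners 2, and
each double heterozygote contributes an expected ``2 r^2 / (q^2 + r^2)``
(the two phase configurations of HH are indistinguishable).  The M-step is
``r <- E[recombinant gametes] / 2N``.  The LOD score compares the likelihood
at the estimate with independence (``r = 0.5``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genodata import CODE_A, CODE_B, CODE_H, CODE_MISSING, MarkerGenotypeMatrix


class EstimateError(ValueError):
    """Raised when an estimate is undefined (e.g. no jointly observed calls)."""


@dataclass
class PairCounts:
    """3x3 joint genotype table for one marker pair.

    ``counts[g1, g2]`` with genotype order (A, H, B) on both axes; individuals
    missing at either marker are excluded.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (3, 3):
            raise ValueError("PairCounts requires a 3x3 table")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n(self) -> float:
        return float(self.counts.sum())


@dataclass
class PairwiseEstimate:
    marker_i: str
    marker_j: str
    r_hat: float
    lod: float
    n_informative: int


def pair_counts(m: MarkerGenotypeMatrix, i: str, j: str) -> PairCounts:
    """Joint 3x3 genotype counts for markers ``i`` and ``j``."""
    if i == j:
        raise ValueError("pair_counts requires two distinct markers")
    ci = m.calls[:, m.marker_index(i)]
    cj = m.calls[:, m.marker_index(j)]
    ok = (ci != CODE_MISSING) & (cj != CODE_MISSING)
    table = np.zeros((3, 3))
    np.add.at(table, (ci[ok], cj[ok]), 1.0)
    return PairCounts(table)


def class_probabilities(r: float | np.ndarray) -> np.ndarray:
    """3x3 class probabilities at recombination fraction ``r`` (coupling F2)."""
    r = np.asarray(r, dtype=float)
    q = 1.0 - r
    p = np.empty(r.shape + (3, 3))
    p[..., 0, 0] = p[..., 2, 2] = q * q / 4.0
    p[..., 0, 2] = p[..., 2, 0] = r * r / 4.0
    p[..., 0, 1] = p[..., 1, 0] = p[..., 1, 2] = p[..., 2, 1] = q * r / 2.0
    p[..., 1, 1] = (q * q + r * r) / 2.0
    return p


def _em_r(
    n_edge: np.ndarray,
    n_anti: np.ndarray,
    n_hh: np.ndarray,
    n_total: np.ndarray,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Vectorized EM for arrays of collapsed class counts."""
    r = np.full(np.shape(n_total), 0.25)
    unambig = n_edge + 2.0 * n_anti
    with np.errstate(divide="ignore", invalid="ignore"):
        for _ in range(max_iter):
            q = 1.0 - r
            denom = q * q + r * r
            hh_exp = np.where(denom > 0, n_hh * 2.0 * r * r / np.where(denom > 0, denom, 1.0), 0.0)
            r_new = np.clip((unambig + hh_exp) / (2.0 * n_total), 0.0, 0.5)
            done = np.all(np.abs(r_new - r) < tol)
            r = r_new
            if done:
                break
    return r


def _lod(counts: np.ndarray, r: np.ndarray) -> np.ndarray:
    """LOD = sum_k n_k log10(p_k(r) / p_k(0.5)); 0*log(0) treated as 0."""
    p_hat = class_probabilities(r)
    p_null = class_probabilities(np.full(np.shape(r), 0.5))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = counts * (np.log10(p_hat) - np.log10(p_null))
    term = np.where(counts > 0, term, 0.0)
    lod = term.sum(axis=(-2, -1))
    # clamp tiny negative round-off; a true optimum can never beat r=0.5
    return np.maximum(lod, 0.0)


def estimate_r_lod(c: PairCounts, tol: float = 1e-6, max_iter: int = 500) -> tuple[float, float]:
    """Maximum-likelihood recombination fraction and LOD for one count table.

    Returns ``(r_hat, lod)``; raises :class:`EstimateError` when the table is
    empty.
    """
    n = c.counts
    total = n.sum()
    if total <= 0:
        raise EstimateError("no jointly observed individuals; estimate undefined")
    n_edge = n[0, 1] + n[1, 0] + n[1, 2] + n[2, 1]
    n_anti = n[0, 2] + n[2, 0]
    n_hh = n[1, 1]
    r = float(_em_r(np.array(n_edge), np.array(n_anti), np.array(n_hh), np.array(total), tol, max_iter))
    lod = float(_lod(n, np.array(r)))
    return r, lod


def pairwise_estimates(
    m: MarkerGenotypeMatrix, tol: float = 1e-6, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs recombination fractions, LODs, and informative counts.

    Returns ``(r, lod, n)`` square arrays over ``m.marker_ids``.  Joint counts
    come from one-hot indicator products, and EM runs simultaneously on all
    pairs.  The diagonal is set to ``r=0, lod=inf`` by convention; pairs with
    no jointly observed individual get ``r = nan``.
    """
    calls = m.calls
    onehot = [(calls == code).astype(float) for code in (CODE_A, CODE_H, CODE_B)]
    tables = np.empty((3, 3, m.n_markers, m.n_markers))
    for a in range(3):
        for b in range(3):
            tables[a, b] = onehot[a].T @ onehot[b]
    n_total = tables.sum(axis=(0, 1))
    n_edge = tables[0, 1] + tables[1, 0] + tables[1, 2] + tables[2, 1]
    n_anti = tables[0, 2] + tables[2, 0]
    n_hh = tables[1, 1]

    safe_total = np.where(n_total > 0, n_total, 1.0)
    r = _em_r(n_edge, n_anti, n_hh, safe_total, tol, max_iter)
    counts = np.moveaxis(tables, (0, 1), (-2, -1))
    lod = _lod(counts, r)
    r = np.where(n_total > 0, r, np.nan)
    lod = np.where(n_total > 0, lod, 0.0)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, np.inf)
    return r, lod, n_total.astype(int)


def estimate_pair(m: MarkerGenotypeMatrix, i: str, j: str, tol: float = 1e-6) -> PairwiseEstimate:
    """Two-point estimate for one named marker pair."""
    c = pair_counts(m, i, j)
    r, lod = estimate_r_lod(c, tol=tol)
    return PairwiseEstimate(i, j, r, lod, int(c.n))


# ---------------------------------------------------------------------------
# Map functions


def map_function(x, kind: str = "kosambi", direction: str = "r_to_cM"):
    """Convert between recombination fraction and map distance (cM).

    Kosambi: ``d = 25 ln((1+2r)/(1-2r))``, inverse ``r = tanh(d/50)/2``.
    Haldane: ``d = -50 ln(1-2r)``, inverse ``r = (1 - e^(-d/50))/2``.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    if direction == "r_to_cM":
        if np.any(x < 0) or np.any(x > 0.5):
            raise ValueError("recombination fraction outside [0, 0.5]")
        if np.any(x >= 0.5):
            raise ValueError("r = 0.5 corresponds to infinite map distance")
        if kind == "kosambi":
            out = 25.0 * np.log((1.0 + 2.0 * x) / (1.0 - 2.0 * x))
        elif kind == "haldane":
            out = -50.0 * np.log(1.0 - 2.0 * x)
        else:
            raise ValueError(f"unknown map function {kind!r}")
    elif direction == "cM_to_r":
        if np.any(x < 0):
            raise ValueError("map distance must be nonnegative")
        if kind == "kosambi":
            out = 0.5 * np.tanh(x / 50.0)
        elif kind == "haldane":
            out = 0.5 * (1.0 - np.exp(-x / 50.0))
        else:
            raise ValueError(f"unknown map function {kind!r}")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if scalar else out


# ---------------------------------------------------------------------------
# Obligate crossovers


def count_obligate_crossovers(order: list[str] | np.ndarray, m: MarkerGenotypeMatrix) -> int:
    """Minimum crossovers implied by ordered genotypes, summed over individuals.

    Per individual the missing calls are skipped and consecutive observed
    genotypes ``g, g'`` contribute ``|dose(g) - dose(g')|`` with dose(A)=0,
    dose(H)=1, dose(B)=2.
    """
    if len(order) and isinstance(order[0], (str, np.str_)):
        idx = [m.marker_index(mk) for mk in order]
    else:
        idx = list(np.asarray(order, dtype=int))
    doses = m.calls[:, idx].astype(float)
    doses[doses == CODE_MISSING] = np.nan
    return int(_crossovers_from_doses(doses))


def _crossovers_from_doses(doses: np.ndarray) -> float:
    """Sum of |diff| over consecutive observed calls per row; nan = missing."""
    n_ind, n_mark = doses.shape
    if n_mark < 2:
        return 0.0
    observed = ~np.isnan(doses)
    # forward-fill each row so position k holds the last observed dose <= k
    col = np.arange(n_mark)
    last_idx = np.where(observed, col, -1)
    last_idx = np.maximum.accumulate(last_idx, axis=1)
    filled = np.where(
        last_idx >= 0, np.take_along_axis(doses, np.maximum(last_idx, 0), axis=1), np.nan
    )
    prev = filled[:, :-1]
    cur = doses[:, 1:]
    contrib = np.abs(cur - prev)
    return float(np.nansum(contrib))
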