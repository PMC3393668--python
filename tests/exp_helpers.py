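"""Shared simulation experiments used by unit and acceptance tests."""

import numpy as np
from scipy import stats

from f2linkage import compare as cp, linkage as lk, mapbuild as mb, simulate as sim


def mapped_rank_pair(seed: int, n_markers: int = 30, length_cm: float = 50.0, n: int = 150):
    """Rank vectors from two independently simulated and mapped populations
    of the same chromosome layout (a colinear map pair)."""
    ch = sim.uniform_chromosome("c", n_markers, length_cm)
    ranks = []
    for pop_seed in (seed, seed + 1):
        cfg = sim.SimConfig(n_individuals=n, chromosomes=[ch], seed=pop_seed)
        m, _ = sim.simulate_f2_population(cfg)
        r, _, _ = lk.pairwise_estimates(m)
        ordered = mb.order_markers(list(m.marker_ids), m, r, seed=0, reference_order=ch.marker_ids)
        group = mb.assign_positions_and_bins(ordered, m, r)
        pos = dict(zip(group.marker_ids, group.positions))
        ranks.append(stats.rankdata([pos[mk] for mk in ch.marker_ids]))
    return ranks[0], ranks[1]


def count_inversion_false_positives(
    n_pairs: int, seed0: int, min_block: int = 4, slope_threshold: float = 0.8
) -> int:
    """Inversion calls on colinear (no-inversion) mapped pairs."""
    false_positives = 0
    for k in range(n_pairs):
        ra, rb = mapped_rank_pair(seed0 + 2 * k)
        blocks = cp.detect_inverted_blocks(
            ra, rb, min_block=min_block, slope_threshold=slope_threshold
        )
        false_positives += len(blocks)
    return false_positives


def build_total_length(matrix, seed: int = 0) -> float:
    return mb.build_map(matrix, seed=seed).total_length_cm()


def paired_inflation_lengths(
    n_reps: int,
    seed0: int,
    n_small: int = 79,
    n_large: int = 160,
    n_markers: int = 120,
    length_cm: float = 60.0,
    error_rate: float = 0.01,
):
    """Map lengths at two population sizes with common random numbers.

    Each replicate simulates one population of ``n_large`` individuals with
    genotyping error and maps both the full population and its first
    ``n_small`` individuals, so the pair shares gametes and error calls.
    Returns (lengths_small, lengths_large) arrays.
    """
    from f2linkage.genodata import MarkerGenotypeMatrix

    small, large = [], []
    for rep in range(n_reps):
        ch = sim.uniform_chromosome("c", n_markers, length_cm)
        cfg = sim.SimConfig(
            n_individuals=n_large, chromosomes=[ch], error_rate=error_rate, seed=seed0 + rep
        )
        m, _ = sim.simulate_f2_population(cfg)
        sub = MarkerGenotypeMatrix(m.individual_ids[:n_small], m.marker_ids, m.calls[:n_small])
        large.append(build_total_length(m))
        small.append(build_total_length(sub))
    return np.asarray(small), np.asarray(large)
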