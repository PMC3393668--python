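"""Synthetic F2 intercross populations with known truth.

Each F2 individual is the union of two independent gametes.  A gamete is
generated by placing crossovers along the true genetic (cM) axis — as a
Poisson process at 1 crossover per 100 cM (no interference, matching the
Haldane map function) or as a gamma-renewal process (positive interference)
— and reading the parental phase at every marker.  The genotype at a marker
is the dose of parent-2 alleles, coded A/H/B.

Known departures from ideal Mendelian data are injected on top of the
meiotic model: uniform genotyping error, missing calls, viability selection
at chosen loci (which produces segregation distortion), and inter-parent
inversions (crossover suppression inside the interval, with the marker order
reversed in the carrier parent's coordinate system).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .genodata import CODE_MISSING, MarkerGenotypeMatrix


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimChromosome:
    """True layout of one simulated chromosome.

    ``cm_positions`` are nondecreasing and start at 0.  ``inversions`` are
    (start_cM, end_cM) intervals heterozygous between the parents: crossovers
    falling inside are suppressed (no recombinant gametes are emitted for the
    interval).
    """

    name: str
    marker_ids: list[str]
    cm_positions: np.ndarray
    bp_positions: np.ndarray | None = None
    inversions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cm_positions = np.asarray(self.cm_positions, dtype=float)
        if len(self.marker_ids) != len(self.cm_positions):
            raise SimConfigError(f"{self.name}: marker/position length mismatch")
        if len(self.cm_positions) and self.cm_positions[0] != 0.0:
            raise SimConfigError(f"{self.name}: cM positions must start at 0")
        if np.any(np.diff(self.cm_positions) < 0):
            raise SimConfigError(f"{self.name}: cM positions must be nondecreasing")
        span = float(self.cm_positions[-1]) if len(self.cm_positions) else 0.0
        for lo, hi in self.inversions:
            if not (0.0 <= lo < hi <= span):
                raise SimConfigError(
                    f"{self.name}: inversion ({lo}, {hi}) outside chromosome span [0, {span}]"
                )
        if self.bp_positions is not None:
            self.bp_positions = np.asarray(self.bp_positions, dtype=np.int64)
            if len(self.bp_positions) != len(self.marker_ids):
                raise SimConfigError(f"{self.name}: bp/marker length mismatch")
            if np.any(self.bp_positions < 1):
                raise SimConfigError(f"{self.name}: bp positions must be >= 1")

    @property
    def length_cm(self) -> float:
        return float(self.cm_positions[-1]) if len(self.cm_positions) else 0.0


def uniform_chromosome(
    name: str, n_markers: int, length_cm: float, prefix: str | None = None
) -> SimChromosome:
    """Convenience layout: markers evenly spaced from 0 to ``length_cm``."""
    prefix = prefix or name
    ids = [f"{prefix}_m{k:04d}" for k in range(n_markers)]
    pos = np.linspace(0.0, length_cm, n_markers) if n_markers > 1 else np.zeros(n_markers)
    return SimChromosome(name, ids, pos)


@dataclass
class SimConfig:
    """Generative parameters for one simulated F2 population.

    ``viability`` maps marker id -> (wAA, wAH, wBB) relative fitnesses; zygotes
    are rejection-sampled by the product of fitnesses across those loci.
    """

    n_individuals: int
    chromosomes: list[SimChromosome]
    interference_model: str = "haldane-poisson"  # or "gamma"
    gamma_shape: float = 2.6
    error_rate: float = 0.0
    missing_rate: float = 0.0
    viability: dict[str, tuple[float, float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise SimConfigError("n_individuals must be >= 2")
        for rate, name in ((self.error_rate, "error_rate"), (self.missing_rate, "missing_rate")):
            if not 0.0 <= rate <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1]")
        if self.interference_model not in ("haldane-poisson", "gamma"):
            raise SimConfigError(f"unknown interference model {self.interference_model!r}")
        all_ids = [mk for ch in self.chromosomes for mk in ch.marker_ids]
        if len(set(all_ids)) != len(all_ids):
            raise SimConfigError("marker ids must be unique across chromosomes")
        if self.viability:
            known = set(all_ids)
            for mk, w in self.viability.items():
                if mk not in known:
                    raise SimConfigError(f"viability locus {mk!r} not among markers")
                if min(w) < 0 or max(w) <= 0:
                    raise SimConfigError(f"invalid fitness triple for {mk!r}")


@dataclass
class SimTruth:
    """Ground truth for a simulated population."""

    config: SimConfig
    crossovers: list[list[tuple[np.ndarray, np.ndarray]]]  # [individual][chrom] -> (gamete1, gamete2) cM
    pre_noise: MarkerGenotypeMatrix

    def true_order(self, chrom_name: str) -> list[str]:
        for ch in self.config.chromosomes:
            if ch.name == chrom_name:
                return list(ch.marker_ids)
        raise KeyError(chrom_name)


def _gamete_crossovers(length_cm: float, model: str, shape: float, rng: np.random.Generator) -> np.ndarray:
    """Crossover positions (cM) on one gamete of a chromosome of given length."""
    if length_cm <= 0:
        return np.empty(0)
    if model == "haldane-poisson":
        k = rng.poisson(length_cm / 100.0)
        return np.sort(rng.uniform(0.0, length_cm, size=k))
    # gamma renewal with mean spacing 100 cM; burn in from upstream of the
    # chromosome so the process is approximately stationary at position 0
    scale = 100.0 / shape
    burn = 500.0
    pos = -burn + rng.uniform(0.0, 100.0)
    points = []
    while pos <= length_cm:
        pos += rng.gamma(shape, scale)
        if 0.0 <= pos <= length_cm:
            points.append(pos)
    return np.asarray(points)


def _suppress(points: np.ndarray, inversions: list[tuple[float, float]]) -> np.ndarray:
    for lo, hi in inversions:
        points = points[(points < lo) | (points > hi)]
    return points


def _phase_at_markers(points: np.ndarray, start_phase: int, positions: np.ndarray) -> np.ndarray:
    """Parental phase (0/1) at each marker given crossover points on the gamete."""
    n_before = np.searchsorted(points, positions, side="right")
    return (start_phase + n_before) % 2


def simulate_f2_population(cfg: SimConfig) -> tuple[MarkerGenotypeMatrix, SimTruth]:
    """Draw an F2 population; returns the observed matrix and its truth.

    The pre-noise matrix in the truth record is the error- and missing-free
    genotype matrix implied by the recorded crossovers; the returned matrix
    additionally carries genotyping error and missing calls as configured.
    """
    rng = np.random.default_rng(cfg.seed)
    n_mark = sum(len(ch.marker_ids) for ch in cfg.chromosomes)
    marker_ids = [mk for ch in cfg.chromosomes for mk in ch.marker_ids]
    viability_idx: list[tuple[int, tuple[float, float, float]]] = []
    if cfg.viability:
        lookup = {mk: k for k, mk in enumerate(marker_ids)}
        viability_idx = [(lookup[mk], w) for mk, w in cfg.viability.items()]
        w_max = [max(w) for _, w in viability_idx]

    calls = np.empty((cfg.n_individuals, n_mark), dtype=np.int8)
    crossovers: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for ind in range(cfg.n_individuals):
        while True:  # rejection sampling under viability selection
            row = np.empty(n_mark, dtype=np.int8)
            per_chrom: list[tuple[np.ndarray, np.ndarray]] = []
            col = 0
            for ch in cfg.chromosomes:
                gametes = []
                doses = np.zeros(len(ch.marker_ids), dtype=np.int8)
                for _ in range(2):
                    pts = _gamete_crossovers(
                        ch.length_cm, cfg.interference_model, cfg.gamma_shape, rng
                    )
                    pts = _suppress(pts, ch.inversions)
                    phase0 = int(rng.integers(0, 2))
                    doses += _phase_at_markers(pts, phase0, ch.cm_positions).astype(np.int8)
                    gametes.append(pts)
                row[col : col + len(doses)] = doses
                per_chrom.append((gametes[0], gametes[1]))
                col += len(doses)
            if not viability_idx:
                break
            accept = 1.0
            for (k, w), wm in zip(viability_idx, w_max):
                accept *= w[row[k]] / wm
            if rng.uniform() < accept:
                break
        calls[ind] = row
        crossovers.append(per_chrom)

    individual_ids = [f"F2_{k:04d}" for k in range(cfg.n_individuals)]
    pre_noise = MarkerGenotypeMatrix(individual_ids, marker_ids, calls.copy())
    observed = pre_noise
    if cfg.error_rate > 0 or cfg.missing_rate > 0:
        noise_seed = int(rng.integers(0, 2**31 - 1))
        observed = apply_observation_noise(pre_noise, cfg.error_rate, cfg.missing_rate, noise_seed)
    return observed, SimTruth(cfg, crossovers, pre_noise)


def apply_observation_noise(
    m: MarkerGenotypeMatrix, error_rate: float, missing_rate: float, seed: int
) -> MarkerGenotypeMatrix:
    """Corrupt calls: each observed call is flipped to one of the other two
    genotypes with probability ``error_rate``, then masked to missing with
    probability ``missing_rate``."""
    for rate, name in ((error_rate, "error_rate"), (missing_rate, "missing_rate")):
        if not 0.0 <= rate <= 1.0:
            raise SimConfigError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = m.calls.copy()
    observed = calls != CODE_MISSING
    if error_rate > 0:
        flip = observed & (rng.uniform(size=calls.shape) < error_rate)
        # add 1 or 2 mod 3 maps each genotype to one of the other two uniformly
        shift = rng.integers(1, 3, size=calls.shape).astype(np.int8)
        calls[flip] = (calls[flip] + shift[flip]) % 3
    if missing_rate > 0:
        mask = observed & (rng.uniform(size=calls.shape) < missing_rate)
        calls[mask] = CODE_MISSING
    return MarkerGenotypeMatrix(list(m.individual_ids), list(m.marker_ids), calls)


def simulate_physical_coordinates(
    chrom: SimChromosome,
    pericentromere: tuple[float, float] = (0.25, 0.75),
    compression: float = 1.0,
    bp_span: int | None = None,
) -> np.ndarray:
    """Strictly increasing bp positions with a pericentromeric plateau.

    The central fraction ``pericentromere`` of the physical axis carries
    ``compression``-fold less cM per Mbp than the arms, giving the Marey curve
    (cM vs Mbp) a sigmoidal shape with a central plateau; ``compression=1``
    makes cM and bp exactly proportional.
    """
    a, b = pericentromere
    if not (0.0 <= a < b <= 1.0):
        raise SimConfigError("pericentromere fractions must satisfy 0 <= start < end <= 1")
    if compression < 1.0:
        raise SimConfigError("compression must be >= 1")
    length_cm = chrom.length_cm
    if bp_span is None:
        bp_span = max(int(length_cm * 1_000_000), len(chrom.marker_ids) + 1)
    # piecewise-linear cM(bp): arm slope s, plateau slope s / compression
    s, cm_at_a, cm_at_b = _marey_params(length_cm, bp_span, pericentromere, compression)

    def bp_of_cm(d: float) -> float:
        if s == 0.0:
            return 1.0
        if d <= cm_at_a:
            return d / s
        if d <= cm_at_b:
            return a * bp_span + (d - cm_at_a) * compression / s
        return b * bp_span + (d - cm_at_b) / s

    bp = np.array([bp_of_cm(d) for d in chrom.cm_positions])
    bp = np.floor(bp).astype(np.int64) + 1  # 1-based
    # enforce strict monotonicity for co-located markers
    for k in range(1, len(bp)):
        if bp[k] <= bp[k - 1]:
            bp[k] = bp[k - 1] + 1
    return bp


def _marey_params(
    length_cm: float, bp_span: int, pericentromere: tuple[float, float], compression: float
) -> tuple[float, float, float]:
    """Arm slope and the cM values at the plateau boundaries."""
    a, b = pericentromere
    plateau_bp = (b - a) * bp_span
    arm_bp = bp_span - plateau_bp
    s = length_cm / (arm_bp + plateau_bp / compression) if length_cm > 0 else 0.0
    cm_at_a = s * a * bp_span
    cm_at_b = cm_at_a + (s / compression) * plateau_bp
    return s, cm_at_a, cm_at_b


def cm_from_bp(
    bp: np.ndarray,
    length_cm: float,
    bp_span: int,
    pericentromere: tuple[float, float] = (0.25, 0.75),
    compression: float = 1.0,
) -> np.ndarray:
    """Genetic position along the piecewise-linear Marey curve."""
    a, b = pericentromere
    s, cm_at_a, cm_at_b = _marey_params(length_cm, bp_span, pericentromere, compression)
    bp = np.asarray(bp, dtype=float)
    out = np.where(
        bp <= a * bp_span,
        s * bp,
        np.where(
            bp <= b * bp_span,
            cm_at_a + (bp - a * bp_span) * s / compression,
            cm_at_b + (bp - b * bp_span) * s,
        ),
    )
    return out


def bp_uniform_chromosome(
    name: str,
    n_markers: int,
    length_cm: float,
    pericentromere: tuple[float, float] = (0.25, 0.75),
    compression: float = 1.0,
    bp_span: int | None = None,
    prefix: str | None = None,
) -> SimChromosome:
    """Markers evenly spaced on the physical axis, cM from the Marey curve.

    Mimics gene-based array design, where marker density is roughly uniform
    in bp so pericentromeric recombination suppression shows up as a plateau
    of the cM(bp) curve rather than as a physical marker desert.
    """
    a, b = pericentromere
    if not (0.0 <= a < b <= 1.0):
        raise SimConfigError("pericentromere fractions must satisfy 0 <= start < end <= 1")
    if compression < 1.0:
        raise SimConfigError("compression must be >= 1")
    if bp_span is None:
        bp_span = max(int(length_cm * 1_000_000), n_markers + 1)
    prefix = prefix or name
    ids = [f"{prefix}_m{k:04d}" for k in range(n_markers)]
    bp = np.linspace(1, bp_span, n_markers).astype(np.int64)
    cm = cm_from_bp(bp, length_cm, bp_span, pericentromere, compression)
    cm = cm - cm[0]
    cm = np.maximum.accumulate(cm)
    return SimChromosome(name, ids, cm, bp)


def reverse_segment(chrom: SimChromosome, start_cm: float, end_cm: float) -> SimChromosome:
    """Chromosome as carried by a parent with an inverted segment.

    Marker ids whose true position falls in [start_cm, end_cm] are reversed in
    order while the position grid is kept, modeling the reversed local marker
    order seen when two mapping populations differ by a small inversion.
    """
    pos = chrom.cm_positions
    inside = np.where((pos >= start_cm) & (pos <= end_cm))[0]
    ids = list(chrom.marker_ids)
    for k, src in zip(inside, inside[::-1]):
        ids[k] = chrom.marker_ids[src]
    return SimChromosome(chrom.name, ids, pos.copy(), chrom.bp_positions, list(chrom.inversions))


def config_to_dict(cfg: SimConfig) -> dict:
    """JSON/YAML-serializable view of a configuration (for run manifests)."""
    out = dataclasses.asdict(cfg)
    for ch in out["chromosomes"]:
        ch["cm_positions"] = [float(x) for x in ch["cm_positions"]]
        if ch["bp_positions"] is not None:
            ch["bp_positions"] = [int(x) for x in ch["bp_positions"]]
        ch["inversions"] = [[float(a), float(b)] for a, b in ch["inversions"]]
    if out["viability"]:
        out["viability"] = {k: list(map(float, v)) for k, v in out["viability"].items()}
    return out
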