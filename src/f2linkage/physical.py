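"""SNP physical placement from alignment hits, synteny, Marey profiles.

A SNP assayed from a flanking sequence ``LEFT[X/Y]RIGHT`` sits ``f = len(LEFT)``
bases into its query.  Given the best tabular alignment hit of that query
against a chromosome, the SNP's 1-based genomic position follows from the
subject start, the strand (forward iff subject start <= subject end), and the
offset of the SNP site within the aligned part of the query:
``offset = f - (qstart - 1)``; forward hits place at ``sstart + offset``,
reverse hits at ``sstart - offset``.

The Marey profile is the local slope of genetic position (cM) on physical
position (Mbp) in sliding windows; long runs of near-zero slope mark
recombination-suppressed (typically pericentromeric) regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mapbuild import LinkageMap


class PhysicalError(ValueError):
    """Base class for placement errors."""


BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

_BRACKET = re.compile(r"\[([ACGTacgt])/([ACGTacgt])\]")


@dataclass
class FlankedSnp:
    """SNP with its 5' flank length (and optionally the bracket sequence)."""

    marker_id: str
    flank5_len: int
    bracket_seq: str | None = None

    def __post_init__(self) -> None:
        if self.flank5_len < 0:
            raise PhysicalError(f"{self.marker_id}: negative flank length")
        if self.bracket_seq is not None:
            derived = flank_length_from_bracket(self.bracket_seq)
            if derived != self.flank5_len:
                raise PhysicalError(
                    f"{self.marker_id}: flank5_len={self.flank5_len} disagrees with "
                    f"bracket sequence (left flank {derived})"
                )


def flank_length_from_bracket(seq: str) -> int:
    """Length of the sequence left of the single ``[X/Y]`` allele token."""
    matches = list(_BRACKET.finditer(seq))
    if len(matches) != 1:
        raise PhysicalError(
            f"expected exactly one [X/Y] token with single-base alleles, found {len(matches)}"
        )
    return matches[0].start()


@dataclass
class AlignmentHit:
    """One row of 12-column tabular alignment output (1-based inclusive)."""

    qseqid: str
    sseqid: str
    qstart: int
    qend: int
    sstart: int
    send: int
    bitscore: float
    evalue: float
    pident: float = 100.0
    length: int = 0
    mismatch: int = 0
    gapopen: int = 0

    def __post_init__(self) -> None:
        for name in ("qstart", "qend", "sstart", "send"):
            if getattr(self, name) < 1:
                raise PhysicalError(f"{self.qseqid}: {name} must be >= 1")

    @property
    def forward(self) -> bool:
        return self.sstart <= self.send


def read_alignment_tabular(path: str | Path) -> pd.DataFrame:
    """Read standard 12-column tabular alignment output (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_COLUMNS, comment="#")
    return df


def hits_from_frame(df: pd.DataFrame) -> dict[str, list[AlignmentHit]]:
    """Group a tabular-alignment frame into AlignmentHit lists per query."""
    out: dict[str, list[AlignmentHit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.qseqid), []).append(
            AlignmentHit(
                str(row.qseqid),
                str(row.sseqid),
                int(row.qstart),
                int(row.qend),
                int(row.sstart),
                int(row.send),
                float(row.bitscore),
                float(row.evalue),
                float(row.pident),
                int(row.length),
                int(row.mismatch),
                int(row.gapopen),
            )
        )
    return out


def select_best_hit(hits: list[AlignmentHit]) -> tuple[AlignmentHit | None, bool]:
    """Best hit by (highest bitscore, lowest e-value); ties are ambiguous.

    Returns ``(hit, ambiguous)``; with an ambiguous tie the hit is ``None``.
    Raises :class:`PhysicalError` on an empty list.
    """
    if not hits:
        raise PhysicalError("no alignment hits for query")
    ranked = sorted(hits, key=lambda h: (-h.bitscore, h.evalue))
    best = ranked[0]
    if len(ranked) > 1:
        second = ranked[1]
        if second.bitscore == best.bitscore and second.evalue == best.evalue:
            return None, True
    return best, False


@dataclass
class PhysicalPlacement:
    marker_id: str
    chromosome: str
    position_bp: int

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise PhysicalError(f"{self.marker_id}: position must be >= 1")


def snp_position_from_hit(hit: AlignmentHit, snp: FlankedSnp) -> PhysicalPlacement:
    """Strand-aware SNP position from the best hit and the 5' flank length."""
    f = snp.flank5_len
    if not (hit.qstart <= f + 1 <= hit.qend):
        raise PhysicalError(
            f"{snp.marker_id}: SNP site (query base {f + 1}) outside aligned "
            f"query interval [{hit.qstart}, {hit.qend}]"
        )
    offset = f - (hit.qstart - 1)
    pos = hit.sstart + offset if hit.forward else hit.sstart - offset
    return PhysicalPlacement(snp.marker_id, hit.sseqid, int(pos))


def place_snps(
    hits: dict[str, list[AlignmentHit]] | pd.DataFrame,
    snps: list[FlankedSnp],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place every SNP with a usable best hit.

    Returns ``(placements, report)``: placements has columns marker_id /
    chromosome / position_bp; the report lists SNPs that could not be placed
    with a reason (no_hit, ambiguous_best_hit, uncovered_site).
    """
    if isinstance(hits, pd.DataFrame):
        hits = hits_from_frame(hits)
    placed = []
    skipped = []
    for snp in snps:
        cand = hits.get(snp.marker_id, [])
        if not cand:
            skipped.append((snp.marker_id, "no_hit"))
            continue
        best, ambiguous = select_best_hit(cand)
        if ambiguous:
            skipped.append((snp.marker_id, "ambiguous_best_hit"))
            continue
        try:
            p = snp_position_from_hit(best, snp)
        except PhysicalError:
            skipped.append((snp.marker_id, "uncovered_site"))
            continue
        placed.append((p.marker_id, p.chromosome, p.position_bp))
    placements = pd.DataFrame(placed, columns=["marker_id", "chromosome", "position_bp"])
    report = pd.DataFrame(skipped, columns=["marker_id", "reason"])
    return placements, report


# ---------------------------------------------------------------------------
# Synteny


def synteny_classify(
    lmap: LinkageMap,
    placements: pd.DataFrame,
    group_to_chromosome: dict[str, str] | None = None,
) -> tuple[list[str], list[str], dict[str, str]]:
    """Split shared markers into syntenic / non-syntenic sets.

    A marker is non-syntenic when the chromosome assigned to its linkage
    group differs from its physical chromosome.  When
    ``group_to_chromosome`` is not given, each group is assigned the
    majority chromosome among its placed markers.
    """
    chrom_of = dict(zip(placements["marker_id"], placements["chromosome"]))
    if group_to_chromosome is None:
        group_to_chromosome = {}
        for g in lmap.groups:
            chroms = [chrom_of[mk] for mk in g.marker_ids if mk in chrom_of]
            if chroms:
                group_to_chromosome[g.group_id] = pd.Series(chroms).mode().iloc[0]
    syntenic, non_syntenic = [], []
    for g in lmap.groups:
        assigned = group_to_chromosome.get(g.group_id)
        for mk in g.marker_ids:
            if mk not in chrom_of:
                continue
            if assigned is None:
                continue
            (syntenic if chrom_of[mk] == assigned else non_syntenic).append(mk)
    return syntenic, non_syntenic, group_to_chromosome


def physical_summary(placements: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome marker count, coverage (Mbp), max gap (Mbp), and totals.

    Coverage is (max - min position) / 1e6; the average interval is
    recomputed as coverage / count.  The Total row sums counts and coverage;
    its average is total coverage / total count.
    """
    rows = []
    for chrom, sub in placements.groupby("chromosome", sort=True):
        pos = np.sort(sub["position_bp"].to_numpy())
        cov = (pos[-1] - pos[0]) / 1e6 if len(pos) > 1 else 0.0
        gap = float(np.diff(pos).max()) / 1e6 if len(pos) > 1 else 0.0
        rows.append(
            {
                "chromosome": chrom,
                "n_markers": len(pos),
                "coverage_Mbp": cov,
                "max_gap_Mbp": gap,
                "average_interval_Mbp": cov / len(pos) if len(pos) else 0.0,
                "single_marker": len(pos) == 1,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        total_cov = float(df["coverage_Mbp"].sum())
        total_n = int(df["n_markers"].sum())
        total = {
            "chromosome": "Total",
            "n_markers": total_n,
            "coverage_Mbp": total_cov,
            "max_gap_Mbp": float(df["max_gap_Mbp"].max()),
            "average_interval_Mbp": total_cov / total_n if total_n else 0.0,
            "single_marker": False,
        }
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# Marey profiles


@dataclass
class MareyProfile:
    chromosome: str
    windows: pd.DataFrame  # bp_start, bp_end, n_markers, rate_cM_per_Mbp
    suppression_regions: list[tuple[int, int]] = field(default_factory=list)
    clamped_windows: int = 0


def marey_rate_profile(
    positions_cm: np.ndarray,
    positions_bp: np.ndarray,
    chromosome: str = "chr",
    window_mb: float = 2.0,
    step_mb: float = 0.5,
    suppression_rate: float = 0.2,
    suppression_span_mb: float = 2.0,
) -> MareyProfile:
    """Windowed recombination rate (cM/Mbp) along one chromosome.

    Each window's rate is the OLS slope of cM on Mbp over the markers it
    contains (>= 2 markers at distinct bp positions required); negative
    slopes are clamped to 0 and counted.  Suppression regions are maximal
    runs of windows with rate < ``suppression_rate`` spanning at least
    ``suppression_span_mb``.
    """
    bp = np.asarray(positions_bp, dtype=float)
    cm = np.asarray(positions_cm, dtype=float)
    if len(bp) != len(cm):
        raise PhysicalError("cM and bp vectors differ in length")
    order = np.argsort(bp)
    bp, cm = bp[order], cm[order]
    win = window_mb * 1e6
    step = step_mb * 1e6
    starts = np.arange(bp.min(), max(bp.max() - win, bp.min()) + step, step)
    rows = []
    clamped = 0
    for s in starts:
        e = s + win
        inside = (bp >= s) & (bp <= e)
        if inside.sum() < 2 or np.unique(bp[inside]).size < 2:
            rate = np.nan
        else:
            slope = np.polyfit(bp[inside] / 1e6, cm[inside], 1)[0]
            if slope < 0:
                clamped += 1
                slope = 0.0
            rate = float(slope)
        rows.append({"bp_start": int(s), "bp_end": int(e), "n_markers": int(inside.sum()), "rate_cM_per_Mbp": rate})
    windows = pd.DataFrame(rows)

    regions: list[tuple[int, int]] = []
    run_start = None
    prev_end = None
    rates = windows["rate_cM_per_Mbp"].to_numpy()
    for k in range(len(windows)):
        low = not np.isnan(rates[k]) and rates[k] < suppression_rate
        if low and run_start is None:
            run_start = int(windows["bp_start"].iloc[k])
        if low:
            prev_end = int(windows["bp_end"].iloc[k])
        if not low and run_start is not None:
            if prev_end - run_start >= suppression_span_mb * 1e6:
                regions.append((run_start, prev_end))
            run_start, prev_end = None, None
    if run_start is not None and prev_end is not None:
        if prev_end - run_start >= suppression_span_mb * 1e6:
            regions.append((run_start, prev_end))
    return MareyProfile(chromosome, windows, regions, clamped)
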