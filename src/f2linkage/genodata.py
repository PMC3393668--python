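"""ABH genotype matrices and genetic-map tables: domain types, TSV I/O, filtering.

Genotypes of an F2 intercross are coded ``A`` (homozygous for the parent-1
allele), ``B`` (homozygous for the parent-2 allele), ``H`` (heterozygous), and
a missing token.  Internally calls are stored as an ``int8`` matrix of
individuals x markers with codes ``A=0, H=1, B=2, missing=-1`` so that the
code value equals the dose of parent-2 alleles for observed calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# dose of parent-2 alleles; -1 marks a missing call
CODE_A: int = 0
CODE_H: int = 1
CODE_B: int = 2
CODE_MISSING: int = -1

#: canonical missing token on output; alternatives accepted on input
MISSING_TOKEN = "-"
_EXTRA_MISSING_TOKENS = ("U", "NA", "")

CODE_TO_TOKEN = {CODE_A: "A", CODE_H: "H", CODE_B: "B", CODE_MISSING: MISSING_TOKEN}


class GenodataError(ValueError):
    """Base class for genotype-data errors."""


class ParseError(GenodataError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(GenodataError):
    """Parsed content violates a matrix or map-table invariant."""


def _token_map(missing_token: str) -> dict[str, int]:
    mapping = {"A": CODE_A, "H": CODE_H, "B": CODE_B, missing_token: CODE_MISSING}
    for tok in _EXTRA_MISSING_TOKENS:
        mapping.setdefault(tok, CODE_MISSING)
    mapping.setdefault(MISSING_TOKEN, CODE_MISSING)
    return mapping


@dataclass
class MarkerGenotypeMatrix:
    """Individuals x markers matrix of ABH calls.

    Parameters
    ----------
    individual_ids
        Unique identifiers of the F2 individuals (rows).
    marker_ids
        Unique marker identifiers (columns).
    calls
        ``int8`` array of shape ``(n_individuals, n_markers)`` with values in
        ``{0, 1, 2, -1}``.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(x) for x in self.individual_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D array")
        n_ind, n_mark = self.calls.shape
        if n_ind != len(self.individual_ids) or n_mark != len(self.marker_ids):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        if len(set(self.individual_ids)) != n_ind:
            raise ValidationError("duplicate individual id")
        if len(set(self.marker_ids)) != n_mark:
            dupes = pd.Index(self.marker_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate marker id(s): {dupes}")
        bad = ~np.isin(self.calls, (CODE_A, CODE_H, CODE_B, CODE_MISSING))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid genotype code {self.calls[r, c]} at "
                f"individual {self.individual_ids[r]!r}, marker {self.marker_ids[c]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def missing_fraction(self) -> np.ndarray:
        """Fraction of missing calls per marker."""
        return (self.calls == CODE_MISSING).mean(axis=0)

    def subset_markers(self, marker_ids: list[str]) -> "MarkerGenotypeMatrix":
        idx = [self.marker_index(m) for m in marker_ids]
        return MarkerGenotypeMatrix(
            list(self.individual_ids), list(marker_ids), self.calls[:, idx].copy()
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Token (string) representation, individuals as rows."""
        tokens = np.vectorize(CODE_TO_TOKEN.get)(self.calls)
        return pd.DataFrame(tokens, index=self.individual_ids, columns=self.marker_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerGenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
        )


def read_abh_matrix(
    path: str | Path,
    orientation: str = "markers-in-columns",
    missing_token: str = MISSING_TOKEN,
) -> MarkerGenotypeMatrix:
    """Read an ABH genotype TSV.

    With ``markers-in-columns`` the header row carries marker ids and the
    first column individual ids; ``markers-in-rows`` is the transpose.
    Tokens other than A/H/B and the accepted missing tokens raise
    :class:`ValidationError` naming the offending cell.
    """
    if orientation not in ("markers-in-columns", "markers-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    header_ids = header[1:]
    if len(set(header_ids)) != len(header_ids):
        dupes = sorted({h for h in header_ids if header_ids.count(h) > 1})
        raise ValidationError(f"{path}: duplicate marker id(s) in header: {dupes}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas names the line
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.hasnans or df.columns.hasnans:
        raise ParseError(f"{path}: empty header field")
    if orientation == "markers-in-rows":
        df = df.T
    individual_ids = [str(x) for x in df.index]
    marker_ids = [str(x) for x in df.columns]

    mapping = _token_map(missing_token)
    raw = df.to_numpy(dtype=object)
    calls = np.empty(raw.shape, dtype=np.int8)
    for tok, code in mapping.items():
        calls[raw == tok] = code
    known = np.isin(raw, list(mapping))
    if not known.all():
        r, c = np.argwhere(~known)[0]
        raise ValidationError(
            f"{path}: unknown genotype token {raw[r, c]!r} at data row {r + 1}, "
            f"column {c + 1} (individual {individual_ids[r]!r}, marker {marker_ids[c]!r})"
        )
    return MarkerGenotypeMatrix(individual_ids, marker_ids, calls)


def write_abh_matrix(
    m: MarkerGenotypeMatrix,
    path: str | Path,
    orientation: str = "markers-in-columns",
) -> None:
    """Write an ABH genotype TSV (missing always written as ``-``)."""
    df = m.to_dataframe()
    if orientation == "markers-in-rows":
        df = df.T
    elif orientation != "markers-in-columns":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t", index_label="id")


@dataclass
class FilterReport:
    """Markers removed by :func:`validate_and_filter_matrix` and the reasons."""

    removed: list[tuple[str, str]] = field(default_factory=list)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["marker_id", "reason"])


def validate_and_filter_matrix(
    m: MarkerGenotypeMatrix,
    max_missing_frac: float = 0.2,
    drop_monomorphic: bool = True,
) -> tuple[MarkerGenotypeMatrix, FilterReport]:
    """Drop markers by missingness and (optionally) monomorphism.

    A marker is monomorphic when at most one distinct genotype code is
    observed among its non-missing calls.  Raises :class:`ValidationError`
    if no markers remain.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    report = FilterReport()
    keep: list[int] = []
    miss = m.missing_fraction()
    for j, marker in enumerate(m.marker_ids):
        if miss[j] > max_missing_frac:
            report.removed.append((marker, f"missing_frac={miss[j]:.2f}"))
            continue
        if drop_monomorphic:
            observed = m.calls[:, j]
            observed = observed[observed != CODE_MISSING]
            if np.unique(observed).size <= 1:
                report.removed.append((marker, "monomorphic"))
                continue
        keep.append(j)
    if not keep:
        raise ValidationError("no markers remain after filtering")
    filtered = MarkerGenotypeMatrix(
        list(m.individual_ids), [m.marker_ids[j] for j in keep], m.calls[:, keep].copy()
    )
    return filtered, report


# ---------------------------------------------------------------------------
# Map tables


@dataclass
class MapTable:
    """Tidy per-marker map rows: marker_id, group_id, position_cM, bin_id."""

    table: pd.DataFrame

    COLUMNS = ("marker_id", "group_id", "position_cM", "bin_id")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing_cols = set(self.COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValidationError(f"map table missing columns {sorted(missing_cols)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["position_cM"] = df["position_cM"].astype(float)
        self.table = df
        self.validate()

    def validate(self) -> None:
        df = self.table
        if df["marker_id"].duplicated().any():
            raise ValidationError("duplicate marker_id in map table")
        if (df["position_cM"] < 0).any():
            raise ValidationError("negative cM position")
        for gid, sub in df.groupby("group_id", sort=False):
            pos = sub["position_cM"].to_numpy()
            if len(pos) and pos[0] != 0.0:
                raise ValidationError(f"group {gid}: first position is not 0")
            if np.any(np.diff(pos) < 0):
                raise ValidationError(f"group {gid}: positions decrease in row order")
            for _, binsub in sub.groupby("bin_id", sort=False):
                if binsub["position_cM"].nunique() > 1:
                    raise ValidationError(f"group {gid}: co-binned markers at different positions")

    def positions_by_marker(self) -> pd.Series:
        return self.table.set_index("marker_id")["position_cM"]

    def groups_by_marker(self) -> pd.Series:
        return self.table.set_index("marker_id")["group_id"]


def write_map_table(map_table: MapTable, path: str | Path) -> None:
    """Serialize a map table as TSV with a stable (group, position, marker) order.

    Positions are written with :func:`repr` so a read round-trips exactly while
    always carrying at least one decimal place.
    """
    map_table.validate()
    df = map_table.table.sort_values(
        ["group_id", "position_cM", "marker_id"], kind="stable"
    ).copy()
    df["position_cM"] = df["position_cM"].map(lambda p: repr(float(p)))
    df.to_csv(path, sep="\t", index=False)


def read_map_table(path: str | Path) -> MapTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "group_id": str, "bin_id": int})
    return MapTable(df)
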