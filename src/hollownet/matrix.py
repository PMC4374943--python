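"""Labeled bipartite abundance/incidence matrices and their file formats.

The central object is :class:`AbundanceMatrix`: a species-by-hollow table of
nonnegative integer emergence counts.  Rows are saproxylic insect species
(the higher trophic level), columns are tree hollows (the lower level, the
microhabitat being colonised).  Every statistic in this package is defined
on this object or on its 0/1 view (:class:`IncidenceMatrix`).

File formats are deliberately plain: wide CSV/TSV (header row = hollow IDs,
first column = species IDs), a 3-column weighted edge list, GraphML via
networkx, and a 2-column species→guild CSV.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Saproxylic trophic guild codes: xylophagous, saprophagous,
#: saproxylophagous, xylomycetophagous, predator.
GUILD_CODES = frozenset({"X", "SA", "SX", "XM", "P"})


class MatrixInputError(ValueError):
    """Malformed matrix input: negative or non-integer cells, duplicate labels."""


class DegenerateNetworkError(ValueError):
    """A network with no rows, no columns or no links where some are required."""


def _clean_labels(labels: Iterable, axis: str) -> tuple[str, ...]:
    out = tuple(str(lab).strip() for lab in labels)
    if any(lab == "" for lab in out):
        raise MatrixInputError(f"empty {axis} label")
    seen: set[str] = set()
    dupes = sorted({lab for lab in out if lab in seen or seen.add(lab)})
    if dupes:
        raise MatrixInputError(f"duplicate {axis} labels: {dupes}")
    return out


@dataclass(frozen=True)
class AbundanceMatrix:
    """Species × tree-hollow matrix of nonnegative integer counts.

    Parameters
    ----------
    values:
        2-D array-like of nonnegative integers; ``values[i, j]`` is the
        number of individuals of species ``row_labels[i]`` that emerged
        from hollow ``col_labels[j]``.
    row_labels, col_labels:
        Unique identifiers (whitespace-trimmed, case-sensitive) for insect
        species (rows) and tree hollows (columns).
    """

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise MatrixInputError(f"matrix must be 2-D, got shape {arr.shape}")
        rows = _clean_labels(self.row_labels, "species (row)")
        cols = _clean_labels(self.col_labels, "hollow (column)")
        if arr.shape != (len(rows), len(cols)):
            raise MatrixInputError(
                f"shape {arr.shape} does not match {len(rows)} row and "
                f"{len(cols)} column labels"
            )
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac = np.mod(arr.astype(float), 1.0)
            if np.any(frac != 0) or np.any(~np.isfinite(arr.astype(float))):
                i, j = np.argwhere((frac != 0) | ~np.isfinite(arr.astype(float)))[0]
                raise MatrixInputError(
                    f"non-integer count {arr[i, j]!r} at species "
                    f"{rows[i]!r}, hollow {cols[j]!r}"
                )
        arr = arr.astype(np.int64, copy=True)
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise MatrixInputError(
                f"negative count {arr[i, j]} at species {rows[i]!r}, "
                f"hollow {cols[j]!r}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "row_labels", rows)
        object.__setattr__(self, "col_labels", cols)

    # -- basic quantities ---------------------------------------------------

    @property
    def n_rows(self) -> int:
        """Number of insect species S_rows."""
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        """Number of tree hollows S_cols (H)."""
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def links(self) -> int:
        """L: number of realised species-hollow interactions (positive cells)."""
        return int(np.count_nonzero(self.values))

    @property
    def individuals(self) -> int:
        """m: grand total of individuals."""
        return int(self.values.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)

    @property
    def row_degrees(self) -> np.ndarray:
        """Per-species degree: number of hollows the species occurs in."""
        return np.count_nonzero(self.values, axis=1)

    @property
    def col_degrees(self) -> np.ndarray:
        """Per-hollow degree: number of species recorded in the hollow."""
        return np.count_nonzero(self.values, axis=0)

    # -- transforms ---------------------------------------------------------

    def binarize(self) -> "IncidenceMatrix":
        """0/1 view: cell is 1 iff the abundance cell is positive."""
        return IncidenceMatrix(
            (self.values > 0).astype(np.int64), self.row_labels, self.col_labels
        )

    def drop_empty(self) -> "AbundanceMatrix":
        """Remove all-zero rows and columns, logging the dropped labels.

        Raises
        ------
        DegenerateNetworkError
            If nothing is left on either axis.
        """
        keep_r = self.row_totals > 0
        keep_c = self.col_totals > 0
        if not keep_r.any() or not keep_c.any():
            raise DegenerateNetworkError("matrix has no positive cells")
        dropped_r = [lab for lab, k in zip(self.row_labels, keep_r) if not k]
        dropped_c = [lab for lab, k in zip(self.col_labels, keep_c) if not k]
        if dropped_r:
            logger.warning("dropping %d empty species rows: %s", len(dropped_r), dropped_r)
        if dropped_c:
            logger.warning("dropping %d empty hollow columns: %s", len(dropped_c), dropped_c)
        if not dropped_r and not dropped_c:
            return self
        return type(self)(
            self.values[np.ix_(keep_r, keep_c)],
            tuple(lab for lab, k in zip(self.row_labels, keep_r) if k),
            tuple(lab for lab, k in zip(self.col_labels, keep_c) if k),
        )

    def permuted(self, row_order: Iterable[int], col_order: Iterable[int]) -> "AbundanceMatrix":
        """Reorder rows/columns (used by permutation-invariance checks)."""
        ro = np.asarray(list(row_order))
        co = np.asarray(list(col_order))
        return type(self)(
            self.values[np.ix_(ro, co)],
            tuple(self.row_labels[i] for i in ro),
            tuple(self.col_labels[j] for j in co),
        )

    # -- pandas bridge ------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.row_labels), columns=list(self.col_labels)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        return cls(df.to_numpy(), tuple(map(str, df.index)), tuple(map(str, df.columns)))


class IncidenceMatrix(AbundanceMatrix):
    """Binary species × hollow matrix; cells restricted to {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.size and self.values.max(initial=0) > 1:
            i, j = np.argwhere(self.values > 1)[0]
            raise MatrixInputError(
                f"incidence cell {self.values[i, j]} > 1 at species "
                f"{self.row_labels[i]!r}, hollow {self.col_labels[j]!r}"
            )

    def binarize(self) -> "IncidenceMatrix":  # idempotent
        return self


def binarize(a: AbundanceMatrix) -> IncidenceMatrix:
    """Functional alias for :meth:`AbundanceMatrix.binarize`."""
    return a.binarize()


def drop_empty(a: AbundanceMatrix) -> AbundanceMatrix:
    """Functional alias for :meth:`AbundanceMatrix.drop_empty`."""
    return a.drop_empty()


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"csv", "tsv"}:
            raise ValueError(f"format must be 'csv' or 'tsv', got {fmt!r}")
        return "," if fmt == "csv" else "\t"
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_matrix(path: str | Path, fmt: str | None = None) -> AbundanceMatrix:
    """Read a wide CSV/TSV abundance matrix.

    Layout: first row = hollow IDs, first column = species IDs, body =
    nonnegative integer counts.  Duplicate labels and negative or
    non-integer cells are rejected with an error naming the offender.
    """
    path = Path(path)
    sep = _sniff_sep(path, fmt)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    # pandas silently mangles duplicate header fields, so check them raw
    _clean_labels(header.split(sep)[1:], "hollow (column)")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[1] == 0:
        raise MatrixInputError(f"{path}: no hollow columns found")
    rows = _clean_labels(df.index, "species (row)")
    cols = _clean_labels(df.columns, "hollow (column)")
    body = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = str(raw[i, j]).strip()
            try:
                val = int(cell)
            except ValueError:
                raise MatrixInputError(
                    f"{path}: non-integer cell {cell!r} at species "
                    f"{rows[i]!r}, hollow {cols[j]!r}"
                ) from None
            if val < 0:
                raise MatrixInputError(
                    f"{path}: negative cell {val} at species {rows[i]!r}, "
                    f"hollow {cols[j]!r}"
                )
            body[i, j] = val
    return AbundanceMatrix(body, rows, cols)


def write_matrix(a: AbundanceMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write the wide-format counterpart of :func:`read_matrix`."""
    path = Path(path)
    a.to_dataframe().to_csv(path, sep=_sniff_sep(path, fmt))


def read_guilds(path: str | Path) -> dict[str, str]:
    """Read a 2-column species,guild CSV into a guild map.

    Guild codes are restricted to the five saproxylic trophic guilds
    (X, SA, SX, XM, P).
    """
    path = Path(path)
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, record in enumerate(reader, start=1):
            if not record or (lineno == 1 and record[0].strip().lower() == "species"):
                continue
            if len(record) < 2:
                raise MatrixInputError(f"{path}:{lineno}: expected 'species,guild'")
            species, guild = record[0].strip(), record[1].strip()
            if guild not in GUILD_CODES:
                raise MatrixInputError(
                    f"{path}:{lineno}: unknown guild code {guild!r} "
                    f"(allowed: {sorted(GUILD_CODES)})"
                )
            if species in out:
                raise MatrixInputError(f"{path}:{lineno}: duplicate species {species!r}")
            out[species] = guild
    return out


def to_graph(
    a: AbundanceMatrix,
    guilds: Mapping[str, str] | None = None,
    tiers: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Bipartite weighted graph; node attributes carry level/guild/core tier."""
    g = nx.Graph()
    for lab in a.row_labels:
        attrs = {"level": "species", "bipartite": 0}
        if guilds and lab in guilds:
            attrs["guild"] = guilds[lab]
        if tiers and lab in tiers:
            attrs["core_tier"] = tiers[lab]
        g.add_node(lab, **attrs)
    for lab in a.col_labels:
        attrs = {"level": "hollow", "bipartite": 1}
        if tiers and lab in tiers:
            attrs["core_tier"] = tiers[lab]
        g.add_node(lab, **attrs)
    for i, j in zip(*np.nonzero(a.values)):
        g.add_edge(a.row_labels[i], a.col_labels[j], weight=int(a.values[i, j]))
    return g


def export_edges(
    a: AbundanceMatrix,
    path: str | Path,
    fmt: str = "edgelist",
    guilds: Mapping[str, str] | None = None,
    tiers: Mapping[str, str] | None = None,
) -> None:
    """Export one weighted edge per positive cell.

    ``fmt="edgelist"`` writes a 3-column CSV (species,hollow,count);
    ``fmt="graphml"`` writes GraphML with level/guild/core-tier node
    attributes.
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "edgelist":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["species", "hollow", "count"])
            for i, j in zip(*np.nonzero(a.values)):
                writer.writerow([a.row_labels[i], a.col_labels[j], int(a.values[i, j])])
    elif fmt == "graphml":
        nx.write_graphml(to_graph(a, guilds=guilds, tiers=tiers), path)
    else:
        raise ValueError(f"format must be 'edgelist' or 'graphml', got {fmt!r}")


def read_edges(path: str | Path) -> AbundanceMatrix:
    """Rebuild a matrix from an exported edge list (labels in file order)."""
    rows: list[str] = []
    cols: list[str] = []
    cells: list[tuple[str, str, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise MatrixInputError(f"{path}: empty edge list")
        for lineno, record in enumerate(reader, start=2):
            if not record:
                continue
            if len(record) != 3:
                raise MatrixInputError(f"{path}:{lineno}: expected species,hollow,count")
            sp, ho, cnt = record[0].strip(), record[1].strip(), record[2].strip()
            try:
                w = int(cnt)
            except ValueError:
                raise MatrixInputError(f"{path}:{lineno}: non-integer count {cnt!r}") from None
            if sp not in rows:
                rows.append(sp)
            if ho not in cols:
                cols.append(ho)
            cells.append((sp, ho, w))
    if not cells:
        raise DegenerateNetworkError(f"{path}: no edges")
    body = np.zeros((len(rows), len(cols)), dtype=np.int64)
    ridx = {lab: i for i, lab in enumerate(rows)}
    cidx = {lab: j for j, lab in enumerate(cols)}
    for sp, ho, w in cells:
        body[ridx[sp], cidx[ho]] += w
    return AbundanceMatrix(body, tuple(rows), tuple(cols))
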