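"""Network-level and node-level descriptors of the bipartite matrix.

Covers the classic report block: links per species L/S, connectance C,
quantitative linkage density LD, the Schluter variance ratio (V-ratio),
and the per-node degree/strength table built from dependencies
d_ij = a_ij / row_total_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix, DegenerateNetworkError


def _check_nondegenerate(a: AbundanceMatrix) -> None:
    if a.n_rows == 0 or a.n_cols == 0 or a.links == 0:
        raise DegenerateNetworkError("descriptor undefined on an empty network")


def links_per_species(a: AbundanceMatrix) -> float:
    """L/S: realised links divided by the number of species at both levels."""
    _check_nondegenerate(a)
    return a.links / (a.n_rows + a.n_cols)


def connectance(a: AbundanceMatrix) -> float:
    """C: realised links divided by the number of cells in the matrix."""
    _check_nondegenerate(a)
    return a.links / (a.n_rows * a.n_cols)


def degree_and_strength(a: AbundanceMatrix) -> pd.DataFrame:
    """Per-node degree and interaction strength.

    The dependency of species i on hollow j is d_ij = a_ij / row_total_i;
    the strength of hollow j is the sum of the dependencies of all species
    on it, so hollow strengths sum to the number of (non-empty) species.
    Symmetrically, species strength sums column-wise dependencies
    a_ij / col_total_j.  Columns: node, level, degree, strength.
    """
    vals = a.values.astype(float)
    row_tot = vals.sum(axis=1)
    col_tot = vals.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dep_on_hollow = np.where(row_tot[:, None] > 0, vals / row_tot[:, None], 0.0)
        dep_on_species = np.where(col_tot[None, :] > 0, vals / col_tot[None, :], 0.0)
    records = []
    row_strength = dep_on_species.sum(axis=1)
    col_strength = dep_on_hollow.sum(axis=0)
    for i, lab in enumerate(a.row_labels):
        records.append(
            {"node": lab, "level": "species",
             "degree": int(a.row_degrees[i]), "strength": float(row_strength[i])}
        )
    for j, lab in enumerate(a.col_labels):
        records.append(
            {"node": lab, "level": "hollow",
             "degree": int(a.col_degrees[j]), "strength": float(col_strength[j])}
        )
    return pd.DataFrame.from_records(records, columns=["node", "level", "degree", "strength"])


def _effective_partners(weights: np.ndarray) -> np.ndarray:
    """2**H per row of ``weights``, H = base-2 Shannon entropy of the row.

    Rows summing to zero get 0 effective partners.
    """
    totals = weights.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, weights / totals, 0.0)
    logp = np.log2(np.where(p > 0, p, 1.0))
    h = -(p * logp).sum(axis=1)
    return np.where(totals[:, 0] > 0, 2.0 ** h, 0.0)


def linkage_density(a: AbundanceMatrix) -> float:
    """Quantitative (weighted) linkage density LD.

    Each node's effective number of partners is 2**H_k with H_k the base-2
    Shannon entropy of its interaction weights; LD is the mean of the two
    marginal-total-weighted level averages:

        LD = 1/2 [ sum_i (r_i/m) 2**H_i  +  sum_j (c_j/m) 2**H_j ].

    On an n x n matrix with all cells equal this equals n.
    """
    _check_nondegenerate(a)
    vals = a.values.astype(float)
    m = vals.sum()
    n_rows_eff = _effective_partners(vals)
    n_cols_eff = _effective_partners(vals.T)
    row_w = vals.sum(axis=1) / m
    col_w = vals.sum(axis=0) / m
    return 0.5 * (float(row_w @ n_rows_eff) + float(col_w @ n_cols_eff))


def variance_ratio(a: AbundanceMatrix, on: str = "abundance") -> float:
    """Schluter variance ratio V of the insect (higher) level across hollows.

    V = Var(T) / sum_i Var(a_i.) with T_j the per-hollow total and the
    variances taken across hollows with the population (1/n) denominator.
    V > 1 indicates positive aggregation of species, V < 1 disaggregation.
    Using sample variances would rescale numerator and denominator by the
    same factor and leave V unchanged.

    ``on="incidence"`` computes the ratio on presence/absence data instead
    of abundances (which variant the classic reports used is ambiguous).
    """
    if a.n_cols < 2:
        raise DegenerateNetworkError("variance ratio needs at least two hollows")
    vals = a.values.astype(float)
    if on == "incidence":
        vals = (vals > 0).astype(float)
    elif on != "abundance":
        raise ValueError(f"on must be 'abundance' or 'incidence', got {on!r}")
    totals = vals.sum(axis=0)
    denom = vals.var(axis=1).sum()
    if denom == 0:
        raise DegenerateNetworkError("all species have zero variance across hollows")
    return float(totals.var() / denom)


@dataclass(frozen=True)
class NetworkSummary:
    """Network attribute block: sizes plus the scalar descriptors."""

    s_rows: int
    s_cols: int
    links: int
    individuals: int
    links_per_species: float
    connectance: float
    linkage_density: float
    variance_ratio: float

    def as_dict(self) -> dict:
        return {
            "S_insects": self.s_rows,
            "S_hollows": self.s_cols,
            "L": self.links,
            "m": self.individuals,
            "L/S": self.links_per_species,
            "C": self.connectance,
            "LD": self.linkage_density,
            "V-ratio": self.variance_ratio,
        }


def summarize(a: AbundanceMatrix) -> NetworkSummary:
    _check_nondegenerate(a)
    return NetworkSummary(
        s_rows=a.n_rows,
        s_cols=a.n_cols,
        links=a.links,
        individuals=a.individuals,
        links_per_species=links_per_species(a),
        connectance=connectance(a),
        linkage_density=linkage_density(a),
        variance_ratio=variance_ratio(a),
    )
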