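"""Lipid panel quality control and rank-based standardization.

Serum lipidomic panels report left-censored concentrations: values below a
species' lower limit of detection (LOD) carry no quantitative information.
Species with too many censored cells are dropped (default: keep species with
strictly less than 20% of data points below the LOD), and every retained
species is mapped onto a common standard-normal score scale with Blom's
rank-based inverse-normal transformation

    z_i = Phi^{-1}((r_i - 3/8) / (n + 1/4)),

where r_i is the (average, in case of ties) rank of observation i among the n
subjects.  Because the transform depends on ranks only, it is invariant to any
strictly monotone rescaling of the raw concentrations — in particular to the
internal-standard quantitation scale of the assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LipidMatrix",
    "StandardizedLipidMatrix",
    "filter_by_lod",
    "handle_below_lod_values",
    "blom_transform",
    "standardize",
]

LOD_THRESHOLD_DEFAULT = 0.20
BELOW_LOD_POLICIES = ("rank_low", "half_min", "zero")


@dataclass
class LipidMatrix:
    """Subjects x species concentration matrix with censoring annotations.

    ``values`` is indexed by subject with one column per species;
    ``below_lod`` is a same-shape boolean mask; ``species_meta`` is indexed by
    species with at least a ``lipid_class`` column (TG, PC, PE-O, ...) and
    optionally a fatty-acid composition string.
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    species_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.values.shape != self.below_lod.shape:
            raise ValueError("values and below_lod shapes differ")
        if not self.values.columns.equals(self.below_lod.columns):
            raise ValueError("values and below_lod species differ")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate species identifiers")

    @property
    def species(self) -> pd.Index:
        return self.values.columns

    def subset(self, species) -> "LipidMatrix":
        meta = self.species_meta
        if not meta.empty:
            meta = meta.loc[meta.index.intersection(species)]
        return LipidMatrix(self.values[species].copy(), self.below_lod[species].copy(), meta)


@dataclass
class StandardizedLipidMatrix:
    """Retained species on the Blom standard-normal-score scale."""

    values: pd.DataFrame
    retained_species: list

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def filter_by_lod(matrix: LipidMatrix, threshold: float = LOD_THRESHOLD_DEFAULT) -> LipidMatrix:
    """Drop species with a below-LOD fraction of ``threshold`` or more.

    Retention is strict (< threshold), so at the default 0.20 a species with
    exactly 20% censored cells is removed.  Idempotent; subjects unchanged.
    """
    frac = matrix.below_lod.mean(axis=0)
    keep = matrix.species[(frac < threshold).to_numpy()]
    if len(keep) == 0:
        raise ValueError(
            f"no species retained at LOD threshold {threshold}; review the threshold or panel"
        )
    return matrix.subset(keep)


def handle_below_lod_values(matrix: LipidMatrix, policy: str = "rank_low") -> LipidMatrix:
    """Replace below-LOD cells of retained species ahead of ranking.

    Policies: ``rank_low`` (default) pushes censored cells below the column
    minimum so they share the lowest tied rank under the Blom transform;
    ``half_min`` imputes half the smallest observed value; ``zero`` imputes 0.
    """
    if policy not in BELOW_LOD_POLICIES:
        raise ValueError(f"unknown below-LOD policy {policy!r}; choose from {BELOW_LOD_POLICIES}")
    values = matrix.values.copy()
    mask = matrix.below_lod
    for col in values.columns:
        m = mask[col].to_numpy()
        if not m.any():
            continue
        observed = values.loc[~m, col]
        col_min = float(observed.min()) if len(observed) else 0.0
        if policy == "half_min":
            fill = col_min / 2.0
        elif policy == "zero":
            fill = 0.0
        else:  # rank_low: any common value strictly below the observed minimum
            fill = col_min - 1.0
        values.loc[m, col] = fill
    return LipidMatrix(values, mask.copy(), matrix.species_meta)


def blom_transform(column: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal scores of a 1-D sample.

    Ties receive their average rank and hence identical scores.  An
    all-constant column degenerates to all zeros (with a warning), matching
    the single-observation case z = Phi^{-1}(0.5) = 0.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("blom_transform expects a non-empty 1-D array")
    if np.isnan(x).any():
        raise ValueError("blom_transform input contains NaN")
    n = x.size
    if np.all(x == x[0]):
        if n > 1:
            warnings.warn("constant column: Blom scores degenerate to zeros", stacklevel=2)
        return np.zeros(n)
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 3.0 / 8.0) / (n + 0.25))


def standardize(matrix: LipidMatrix) -> StandardizedLipidMatrix:
    """Blom-transform every species column of an LOD-handled matrix."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-column constant warnings handled in bulk
        for col in matrix.values.columns:
            out[col] = blom_transform(matrix.values[col].to_numpy())
    values = pd.DataFrame(out, index=matrix.values.index)
    return StandardizedLipidMatrix(values=values, retained_species=list(values.columns))
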