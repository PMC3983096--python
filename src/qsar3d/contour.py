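"""Std*coeff contour grids: where in space the model says substitution helps.

For each field kind, every surviving descriptor column contributes the
product of its PLS coefficient and its column standard deviation at its
grid point (dropped columns contribute zero). Contouring that grid at the
80th percentile of the nonzero value distribution marks favourable regions
(where adding the probed property raises predicted activity) and at the
20th percentile unfavourable ones — the quantitative analogue of the
green/yellow and blue/red contour pictures of field-QSAR practice.

The percentile is the linear-interpolation percentile of the *signed*
nonzero std*coeff values; this rule is declared here and pinned by tests,
since contribution-level conventions differ between implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fields import DescriptorMatrix, FieldGrid, GridSpec
from .griddata import write_dx
from .pls import PLSModel

__all__ = ["ContourMap", "stdcoeff_field", "contour_levels", "export_grid"]


@dataclass(frozen=True)
class ContourMap:
    kind: str
    spec: GridSpec
    values: np.ndarray  # std*coeff per grid point; zeros at dropped columns
    favourable_level: float
    unfavourable_level: float
    favourable_points: tuple[int, ...]  # grid-point indices
    unfavourable_points: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.favourable_level < self.unfavourable_level:
            raise ValueError("favourable level below unfavourable level")
        if set(self.favourable_points) & set(self.unfavourable_points):
            raise ValueError("favourable and unfavourable point sets overlap")

    def as_grid(self) -> FieldGrid:
        return FieldGrid(spec=self.spec, kind=f"stdcoeff_{self.kind}",
                         values=self.values)


def stdcoeff_field(model: PLSModel, X: DescriptorMatrix, kind: str) -> np.ndarray:
    """Per-grid-point coefficient-times-stdev values for one field kind."""
    if kind not in X.calculator.kinds:
        raise ValueError(f"field kind {kind!r} not in descriptor matrix "
                         f"(has {X.calculator.kinds})")
    if model.coef.shape[0] != X.n_columns:
        raise ValueError("model does not match descriptor matrix columns")
    values = np.zeros(X.calculator.spec.n_points)
    cols = X.block_columns(kind)
    std = X.X[:, cols].std(axis=0, ddof=1)
    values[X.col_point[cols]] = model.coef[cols] * std
    return values


def contour_levels(values: np.ndarray, spec: GridSpec, kind: str = "",
                   favourable_pct: float = 80.0,
                   unfavourable_pct: float = 20.0) -> ContourMap:
    """Contour a std*coeff grid at the given contribution percentiles.

    Levels are percentiles of the signed nonzero value distribution.
    Favourable points sit at or above the favourable level; unfavourable
    points at or below the unfavourable level, with points reaching both
    levels (possible only when the levels coincide) counted as favourable.
    """
    values = np.asarray(values, dtype=float)
    nz = np.flatnonzero(values != 0.0)
    if nz.size == 0:
        raise ValueError("all std*coeff values are zero; nothing to contour")
    if not 0 <= unfavourable_pct <= favourable_pct <= 100:
        raise ValueError("need 0 <= unfavourable_pct <= favourable_pct <= 100")
    fav_level = float(np.percentile(values[nz], favourable_pct))
    unfav_level = float(np.percentile(values[nz], unfavourable_pct))
    fav = tuple(int(i) for i in nz[values[nz] >= fav_level])
    unfav = tuple(int(i) for i in nz[(values[nz] <= unfav_level)
                                     & (values[nz] < fav_level)])
    return ContourMap(kind=kind, spec=spec, values=values,
                      favourable_level=fav_level, unfavourable_level=unfav_level,
                      favourable_points=fav, unfavourable_points=unfav)


def export_grid(cmap: ContourMap, path: str | Path) -> None:
    """Write the std*coeff grid as an OpenDX scalar file."""
    write_dx(cmap.as_grid(), path, name=f"stdcoeff_{cmap.kind}")
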