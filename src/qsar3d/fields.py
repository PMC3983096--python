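"""Molecular interaction fields on a shared rectangular grid.

Two field families are computed for every aligned compound on one common
lattice:

* CoMFA fields — interaction energies of a probe atom (an sp3 carbon with a
  +1 charge) in kcal/mol: a Lennard-Jones steric term

  ``E_steric(q) = sum_i eps_ip [ (r*_ip / r_iq)^12 - 2 (r*_ip / r_iq)^6 ]``

  and a Coulomb electrostatic term

  ``E_elec(q) = sum_i 332.17 q_i q_p / (D(r_iq) r_iq)``

  with a distance-dependent dielectric ``D(r) = r`` by default. Both are
  truncated to +/-30 kcal/mol, which also absorbs the singularities at atom
  centres.

* CoMSIA similarity indices — Gaussian-attenuated, singularity-free indices

  ``A_q = - sum_i w_probe,k w_ik exp(-alpha r_iq^2)``

  for five atomic properties k: steric (w = vdW radius cubed),
  electrostatic (partial charge), hydrophobic (atom-typed logP
  contribution), H-bond donor and acceptor (1 on flagged atoms). The probe
  has radius 1 A and every property +1; the attenuation factor alpha
  defaults to 0.3.

Field values over all grid points and field kinds form the descriptor
matrix handed to PLS: one row per compound, one column per (grid point,
field kind), with low-variance columns dropped and optional block scaling
that equalises total variance across field blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import params
from .dataset import CompoundRecord
from .params import ProbeSpec, comfa_probe, comsia_probe

__all__ = [
    "GridSpec", "FieldGrid", "FieldCalculator", "DescriptorMatrix",
    "build_grid", "comfa_field", "comsia_field", "build_descriptor_matrix",
    "COMFA_KINDS", "COMSIA_KINDS",
]

COMFA_KINDS = ("comfa_steric", "comfa_electrostatic")
COMSIA_KINDS = ("comsia_steric", "comsia_electrostatic", "comsia_hydrophobic",
                "comsia_donor", "comsia_acceptor")

_FIELD_SETS = {"comfa": COMFA_KINDS, "comsia": COMSIA_KINDS,
               "both": COMFA_KINDS + COMSIA_KINDS}


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned rectangular lattice shared by all compounds."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be positive")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3); z varies fastest."""
        axes = [np.asarray(o) + self.spacing * np.arange(n)
                for o, n in zip(self.origin, self.dims)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass(frozen=True)
class FieldGrid:
    """Field values of one kind for one compound on a grid."""

    spec: GridSpec
    kind: str
    values: np.ndarray  # (n_points,)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.spec.n_points,):
            raise ValueError("values length does not match grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("field values must be finite")
        object.__setattr__(self, "values", v)

    def reshaped(self) -> np.ndarray:
        return self.values.reshape(self.spec.dims)


def build_grid(compounds: Sequence[CompoundRecord], spacing: float = 2.0,
               margin: float = 4.0) -> GridSpec:
    """Lattice covering the union bounding box of all compounds plus margin."""
    if not compounds:
        raise ValueError("need at least one compound")
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    coords = np.vstack([c.coords for c in compounds])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = tuple(int(np.floor((h - l) / spacing + 1e-9)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(float(x) for x in lo), spacing=float(spacing),
                    dims=dims)


def _distances(compound: CompoundRecord, spec: GridSpec) -> np.ndarray:
    """(n_points, n_atoms) probe-atom distance matrix."""
    pts = spec.points()
    ac = compound.coords
    diff = pts[:, None, :] - ac[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def comfa_field(compound: CompoundRecord, spec: GridSpec,
                probe: ProbeSpec | None = None, kind: str = "steric",
                dielectric: str = "distance", dielectric_constant: float = 1.0,
                truncation: float = params.COMFA_TRUNCATION) -> FieldGrid:
    """CoMFA probe interaction energy grid, truncated to +/-truncation kcal/mol.

    Grid points coincident with atoms are handled by the truncation, never
    by an exception: the Lennard-Jones term diverges to +inf and clamps to
    +truncation, the Coulomb term to sign(q_i q_p) * truncation.
    """
    probe = probe or comfa_probe()
    if probe.kind != "comfa":
        raise ValueError("comfa_field needs a CoMFA probe")
    if kind not in ("steric", "electrostatic"):
        raise ValueError(f"unknown CoMFA field kind {kind!r}")
    r = _distances(compound, spec)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if kind == "steric":
            rstar_p, eps_p = probe.radius, params.lj_params("C")[1]
            rstar_i = np.array([params.lj_params(a.element)[0] for a in compound.atoms])
            eps_i = np.array([params.lj_params(a.element)[1] for a in compound.atoms])
            eps_ip = np.sqrt(eps_i * eps_p)
            ratio = (rstar_i + rstar_p)[None, :] / r
            e = eps_ip[None, :] * (ratio ** 12 - 2.0 * ratio ** 6)
            e = np.where(np.isnan(e) | np.isposinf(e), np.inf, e)
        else:
            q_i = np.array([a.charge for a in compound.atoms])
            qq = params.COULOMB_CONSTANT * q_i[None, :] * probe.charge
            if dielectric == "distance":
                denom = r * r
            elif dielectric == "constant":
                denom = dielectric_constant * r
            else:
                raise ValueError(f"unknown dielectric model {dielectric!r}")
            e = qq / denom
            e = np.where(np.isnan(e), 0.0, e)  # zero charge at zero distance
    total = np.clip(e.sum(axis=1), -truncation, truncation)
    return FieldGrid(spec=spec, kind=f"comfa_{kind}", values=total)


_COMSIA_PROPS = {
    "steric": lambda a: a.radius ** 3,
    "electrostatic": lambda a: a.charge,
    "hydrophobic": lambda a: a.hydrophobicity,
    "donor": lambda a: 1.0 if a.donor else 0.0,
    "acceptor": lambda a: 1.0 if a.acceptor else 0.0,
}

_PROBE_WEIGHT = {"steric": "steric", "electrostatic": "charge",
                 "hydrophobic": "hydrophobic", "donor": "donor",
                 "acceptor": "acceptor"}


def comsia_field(compound: CompoundRecord, spec: GridSpec,
                 probe: ProbeSpec | None = None, prop: str = "steric",
                 alpha: float = params.COMSIA_ALPHA) -> FieldGrid:
    """Gaussian similarity-index grid A_q = -sum_i w_probe w_ik exp(-alpha r^2).

    Finite everywhere, including at atom centres (A_q -> -w_probe*w_ik at
    r = 0), so no truncation is ever applied.
    """
    probe = probe or comsia_probe()
    if probe.kind != "comsia":
        raise ValueError("comsia_field needs a CoMSIA probe")
    if prop not in _COMSIA_PROPS:
        raise ValueError(f"unknown CoMSIA property {prop!r}")
    if alpha <= 0:
        raise ValueError("attenuation factor alpha must be positive")
    w_probe = getattr(probe, _PROBE_WEIGHT[prop])
    w_ik = np.array([_COMSIA_PROPS[prop](a) for a in compound.atoms])
    r = _distances(compound, spec)
    a_q = -(w_probe * w_ik[None, :] * np.exp(-alpha * r * r)).sum(axis=1)
    return FieldGrid(spec=spec, kind=f"comsia_{prop}", values=a_q)


@dataclass(frozen=True)
class FieldCalculator:
    """Bundles the grid and all field-evaluation settings.

    Guarantees every compound is evaluated on the same lattice with the
    same probes, dielectric and attenuation factor — the precondition for a
    meaningful column-wise descriptor matrix.
    """

    spec: GridSpec
    kinds: tuple[str, ...]
    alpha: float = params.COMSIA_ALPHA
    dielectric: str = "distance"
    dielectric_constant: float = 1.0
    truncation: float = params.COMFA_TRUNCATION

    def field(self, compound: CompoundRecord, kind: str) -> FieldGrid:
        if kind in COMFA_KINDS:
            return comfa_field(compound, self.spec, kind=kind.split("_", 1)[1],
                               dielectric=self.dielectric,
                               dielectric_constant=self.dielectric_constant,
                               truncation=self.truncation)
        if kind in COMSIA_KINDS:
            return comsia_field(compound, self.spec, prop=kind.split("_", 1)[1],
                                alpha=self.alpha)
        raise ValueError(f"unknown field kind {kind!r}")

    def raw_matrix(self, compounds: Sequence[CompoundRecord]) -> np.ndarray:
        """(n_compounds, n_points * n_kinds) unfiltered descriptor block."""
        rows = []
        for c in compounds:
            rows.append(np.concatenate([self.field(c, k).values for k in self.kinds]))
        return np.array(rows)


@dataclass
class DescriptorMatrix:
    """Compounds x (grid point, field kind) descriptor block for PLS.

    Carries enough metadata (retained-column mask, block scale factors,
    focusing weights and the calculator itself) to featurise new compounds
    consistently via :meth:`transform`.
    """

    ids: list[str]
    X: np.ndarray  # (n, p) final values, filtered + scaled (+ focused)
    calculator: FieldCalculator
    col_kind: np.ndarray  # (p,) field kind per retained column
    col_point: np.ndarray  # (p,) grid-point index per retained column
    block_scale: dict[str, float]
    dropped: list[tuple[str, int, float]]  # (kind, point index, stdev)
    weights: np.ndarray = field(default=None)  # region-focusing weights

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.ones(self.X.shape[1])
        if self.X.shape != (len(self.ids), len(self.col_kind)):
            raise ValueError("descriptor matrix shape mismatch")

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def block_columns(self, kind: str) -> np.ndarray:
        return np.flatnonzero(self.col_kind == kind)

    def transform(self, compounds: Sequence[CompoundRecord]) -> np.ndarray:
        """Featurise new (aligned) compounds onto this matrix's columns."""
        raw = self.calculator.raw_matrix(compounds)
        n_pts = self.calculator.spec.n_points
        cols = np.array([self.calculator.kinds.index(k) * n_pts + p
                         for k, p in zip(self.col_kind, self.col_point)])
        scale = np.array([self.block_scale[k] for k in self.col_kind])
        return raw[:, cols] * scale * self.weights

    def subset(self, ids: Sequence[str]) -> "DescriptorMatrix":
        """Row subset in the given id order (columns untouched)."""
        index = {cid: i for i, cid in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return DescriptorMatrix(ids=list(ids), X=self.X[rows],
                                calculator=self.calculator,
                                col_kind=self.col_kind, col_point=self.col_point,
                                block_scale=self.block_scale, dropped=self.dropped,
                                weights=self.weights)

    def reweighted(self, weights: np.ndarray) -> "DescriptorMatrix":
        """Column-reweighted copy (used by region focusing)."""
        w = np.asarray(weights, dtype=float)
        if w.shape != (self.n_columns,):
            raise ValueError("weight length mismatch")
        return DescriptorMatrix(ids=list(self.ids), X=self.X * w,
                                calculator=self.calculator,
                                col_kind=self.col_kind, col_point=self.col_point,
                                block_scale=self.block_scale, dropped=self.dropped,
                                weights=self.weights * w)


def build_descriptor_matrix(compounds: Sequence[CompoundRecord],
                            spec: GridSpec,
                            fields: str | Sequence[str] = "both",
                            filter_sigma: dict[str, float] | None = None,
                            scaling: str = "block-standard",
                            alpha: float = params.COMSIA_ALPHA,
                            dielectric: str = "distance",
                            dielectric_constant: float = 1.0) -> DescriptorMatrix:
    """Assemble the PLS X block from field grids of all compounds.

    Parameters
    ----------
    fields : "comfa", "comsia", "both", or an explicit kind sequence.
    filter_sigma : per-kind minimum column standard deviation. Defaults to
        2.0 kcal/mol for CoMFA kinds and 0.0 for CoMSIA kinds; columns that
        are exactly constant are always dropped.
    scaling : "block-standard" rescales each field block to unit total
        variance; "none" leaves raw values.
    """
    kinds = _FIELD_SETS[fields] if isinstance(fields, str) else tuple(fields)
    for k in kinds:
        if k not in COMFA_KINDS + COMSIA_KINDS:
            raise ValueError(f"unknown field kind {k!r}")
    sigma = {k: (2.0 if k in COMFA_KINDS else 0.0) for k in kinds}
    sigma.update(filter_sigma or {})
    calc = FieldCalculator(spec=spec, kinds=kinds, alpha=alpha,
                           dielectric=dielectric,
                           dielectric_constant=dielectric_constant)
    raw = calc.raw_matrix(compounds)
    n_pts = spec.n_points
    all_kind = np.repeat(kinds, n_pts)
    all_point = np.tile(np.arange(n_pts), len(kinds))
    std = raw.std(axis=0, ddof=1) if raw.shape[0] > 1 else np.zeros(raw.shape[1])
    keep = (std >= np.array([sigma[k] for k in all_kind])) & (std > 0)
    dropped = [(k, int(p), float(s))
               for k, p, s in zip(all_kind[~keep], all_point[~keep], std[~keep])]
    if not keep.any():
        raise ValueError("all descriptor columns dropped; lower filter_sigma")
    X = raw[:, keep]
    col_kind, col_point = all_kind[keep], all_point[keep]
    block_scale = {k: 1.0 for k in kinds}
    if scaling == "block-standard":
        for k in kinds:
            cols = np.flatnonzero(col_kind == k)
            if cols.size:
                total_var = X[:, cols].var(axis=0, ddof=1).sum()
                if total_var > 0:
                    block_scale[k] = float(1.0 / np.sqrt(total_var))
                    X[:, cols] *= block_scale[k]
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    return DescriptorMatrix(ids=[c.id for c in compounds], X=X, calculator=calc,
                            col_kind=col_kind, col_point=col_point,
                            block_scale=block_scale, dropped=dropped)
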