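"""Loading structures and activities, pIC50 conversion, and train/test splits.

Structures arrive as SDF (V2000) or MOL2 files and are consumed as given —
no 2D->3D generation or conformer search happens here. On load every atom is
annotated with the full property set the field engine needs: a partial charge
(from the file or recomputed with the Gasteiger scheme), a van der Waals
radius from the packaged parameter table, an atom-typed hydrophobicity
contribution (Ghose-Crippen scheme via RDKit), and hydrogen-bond donor /
acceptor flags.

Donor/acceptor rules are deliberately simple: a donor is an N or O bearing
at least one hydrogen; an acceptor is an N or O that is not positively
charged. Activities are potencies on the pIC50 scale, ``-log10`` of the
molar IC50; tabulated IC50 values are taken to be in micromolar unless a
different unit is passed explicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

from .params import UnknownElementError, vdw_radius

__all__ = [
    "Atom",
    "CompoundRecord",
    "ActivityRecord",
    "SplitSpec",
    "read_compound_set",
    "write_compound_set",
    "pic50_from_ic50",
    "ic50_from_pic50",
    "read_activity_table",
    "make_split",
]

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


@dataclass(frozen=True)
class Atom:
    """One atom with the properties the field engine consumes."""

    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    charge: float  # partial charge, e
    radius: float  # vdW radius, Angstrom
    hydrophobicity: float  # Crippen logP contribution
    donor: bool
    acceptor: bool

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom coordinates must be 3 finite numbers, got {coords}")
        object.__setattr__(self, "coords", coords)
        if not math.isfinite(self.charge):
            raise ValueError("partial charge must be finite")
        if self.radius <= 0:
            raise ValueError("vdW radius must be positive")


@dataclass
class CompoundRecord:
    """One 3D structure with per-atom parameters plus its activity."""

    id: str
    atoms: list[Atom]
    activity: float | None = None
    role: str = "unassigned"  # train | test | unassigned
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"compound {self.id!r} has no atoms")
        if self.role not in ("train", "test", "unassigned"):
            raise ValueError(f"bad role {self.role!r}")

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        return np.array([a.coords for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "CompoundRecord":
        """Copy of this record with new coordinates (same atom order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        mol = None
        if self.mol is not None:
            mol = Chem.Mol(self.mol)
            if mol.GetNumConformers():
                conf = mol.GetConformer()
                for i, c in enumerate(coords):
                    conf.SetAtomPosition(i, tuple(float(x) for x in c))
        return CompoundRecord(self.id, atoms, self.activity, self.role, mol)


@dataclass(frozen=True)
class ActivityRecord:
    id: str
    pic50: float
    ic50: float | None = None  # micromolar
    role: str = "unassigned"

    def __post_init__(self) -> None:
        if not math.isfinite(self.pic50):
            raise ValueError(f"pIC50 for {self.id!r} is not finite")
        if self.ic50 is not None:
            expected = pic50_from_ic50(self.ic50)
            if abs(expected - self.pic50) > 5e-4:
                raise ValueError(
                    f"{self.id!r}: pIC50 {self.pic50} inconsistent with "
                    f"IC50 {self.ic50} uM (expected {expected:.4f})"
                )


@dataclass(frozen=True)
class SplitSpec:
    train: frozenset[str]
    test: frozenset[str]

    def __post_init__(self) -> None:
        if self.train & self.test:
            raise ValueError("train and test sets overlap")


def pic50_from_ic50(ic50: float, unit: str = "uM") -> float:
    """Convert an IC50 to pIC50 = -log10(molar IC50).

    Parameters
    ----------
    ic50 : float
        Half-maximal inhibitory concentration, strictly positive.
    unit : str
        One of M, mM, uM, nM, pM; default micromolar.
    """
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown IC50 unit {unit!r}")
    if not (ic50 > 0):
        raise ValueError(f"IC50 must be positive, got {ic50}")
    return -math.log10(ic50 * _UNIT_TO_MOLAR[unit])


def ic50_from_pic50(pic50: float, unit: str = "uM") -> float:
    """Inverse of :func:`pic50_from_ic50`."""
    return 10.0 ** (-pic50) / _UNIT_TO_MOLAR[unit]


def _annotate(mol: Chem.Mol, idx: int, name: str, charge_policy: str) -> CompoundRecord:
    if charge_policy == "recompute":
        AllChem.ComputeGasteigerCharges(mol)
        charges = [float(a.GetDoubleProp("_GasteigerCharge")) for a in mol.GetAtoms()]
    elif charge_policy == "from_file":
        charges = []
        for a in mol.GetAtoms():
            if a.HasProp("_TriposPartialCharge"):
                charges.append(float(a.GetProp("_TriposPartialCharge")))
            elif a.HasProp("PartialCharge"):
                charges.append(float(a.GetProp("PartialCharge")))
            else:
                raise ValueError(
                    f"record {idx} ({name!r}): no partial charges in file; "
                    "use charge_policy='recompute'"
                )
    else:
        raise ValueError(f"unknown charge_policy {charge_policy!r}")
    if not all(math.isfinite(c) for c in charges):
        raise ValueError(f"record {idx} ({name!r}): non-finite partial charge")

    contribs = rdMolDescriptors._CalcCrippenContribs(mol)
    conf = mol.GetConformer()
    atoms = []
    for a in mol.GetAtoms():
        el = a.GetSymbol()
        try:
            radius = vdw_radius(el)
        except UnknownElementError as e:
            raise ValueError(f"record {idx} ({name!r}): {e.args[0]}") from None
        is_no = el in ("N", "O")
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(
            element=el,
            coords=np.array([pos.x, pos.y, pos.z]),
            charge=charges[a.GetIdx()],
            radius=radius,
            hydrophobicity=contribs[a.GetIdx()][0],
            donor=is_no and a.GetTotalNumHs(includeNeighbors=True) >= 1,
            acceptor=is_no and a.GetFormalCharge() <= 0,
        ))
    return CompoundRecord(id=name, atoms=atoms, mol=mol)


def _iter_mol2_blocks(text: str) -> Iterable[str]:
    marker = "@<TRIPOS>MOLECULE"
    parts = text.split(marker)
    for p in parts[1:]:
        yield marker + p


def read_compound_set(path: str | Path,
                      charge_policy: str = "recompute") -> list[CompoundRecord]:
    """Read an SDF (V2000) or MOL2 file into :class:`CompoundRecord` objects.

    Every atom of every record comes back carrying a finite partial charge,
    a vdW radius, a hydrophobicity contribution and donor/acceptor flags.
    Unparseable records raise a :class:`ValueError` naming the record index.
    """
    path = Path(path)
    records: list[CompoundRecord] = []
    if path.suffix.lower() == ".mol2":
        blocks = list(_iter_mol2_blocks(path.read_text()))
        if not blocks:
            raise ValueError(f"{path}: no MOL2 records found")
        for idx, block in enumerate(blocks):
            mol = Chem.MolFromMol2Block(block, sanitize=True, removeHs=False)
            if mol is None:
                raise ValueError(f"record {idx}: unparseable MOL2 block in {path}")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else str(idx)
            records.append(_annotate(mol, idx, name or str(idx), charge_policy))
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        for idx, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"record {idx}: unparseable SDF record in {path}")
            try:
                Chem.SanitizeMol(mol)
            except Exception as e:  # noqa: BLE001 - rdkit raises many types
                raise ValueError(f"record {idx}: sanitization failed: {e}") from None
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else str(idx)
            records.append(_annotate(mol, idx, name or str(idx), charge_policy))
        if not records:
            raise ValueError(f"{path}: no SDF records found")
    return records


def write_compound_set(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Write records (with current coordinates) back to an SDF file."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for rec in records:
            if rec.mol is None:
                raise ValueError(f"compound {rec.id!r} carries no molecule object")
            mol = Chem.Mol(rec.mol)
            conf = mol.GetConformer()
            for i, a in enumerate(rec.atoms):
                conf.SetAtomPosition(i, tuple(float(x) for x in a.coords))
            mol.SetProp("_Name", rec.id)
            writer.write(mol)
    finally:
        writer.close()


def read_activity_table(path: str | Path, unit: str = "uM",
                        pic50_column: str = "pic50") -> list[ActivityRecord]:
    """Read a delimited activity table (columns: id, ic50_uM and/or pic50, role).

    When only an IC50 column is present, pIC50 is filled in by conversion.
    Duplicate ids and rows missing both activity columns are errors.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip() for c in df.columns]
    if "id" not in df.columns:
        raise ValueError(f"{path}: no 'id' column")
    ic_col = next((c for c in df.columns if c in ("ic50_uM", "ic50")), None)
    pc_col = pic50_column if pic50_column in df.columns else (
        "pic50" if "pic50" in df.columns else None)
    if ic_col is None and pc_col is None:
        raise ValueError(f"{path}: need an ic50 or pic50 column")
    ids = df["id"].astype(str).str.strip()
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate compound id(s): {sorted(set(dup))}")
    records = []
    for _, row in df.iterrows():
        ic50 = float(row[ic_col]) if ic_col and pd.notna(row[ic_col]) else None
        if pc_col is not None and pd.notna(row[pc_col]):
            pic50 = float(row[pc_col])
        elif ic50 is not None:
            pic50 = pic50_from_ic50(ic50, unit=unit)
        else:
            raise ValueError(f"{path}: row id={row['id']} has no activity value")
        role = str(row["role"]).strip() if "role" in df.columns and pd.notna(row.get("role")) else "unassigned"
        if unit != "uM" and ic50 is not None:
            # ActivityRecord stores IC50 in micromolar
            ic50 = ic50 * _UNIT_TO_MOLAR[unit] / _UNIT_TO_MOLAR["uM"]
        records.append(ActivityRecord(id=str(row["id"]).strip(), pic50=pic50,
                                      ic50=ic50, role=role))
    return records


def make_split(records: Sequence[ActivityRecord], test_ids: Iterable[str]) -> SplitSpec:
    """Partition records into train/test, enforcing the extremes-in-train rule.

    The most and least active compounds must stay in the training set so the
    model never extrapolates on held-out data. The activity spread of the
    full set is checked and a warning raised when it is below 3 log units.
    An empty test set is legal but makes external validation impossible.
    """
    test_ids = {str(t) for t in test_ids}
    all_ids = {r.id for r in records}
    unknown = test_ids - all_ids
    if unknown:
        raise ValueError(f"test ids not in activity table: {sorted(unknown)}")
    by_act = sorted(records, key=lambda r: r.pic50)
    lo, hi = by_act[0], by_act[-1]
    # ties count: every compound sharing the extreme activity stays in train
    for rec in records:
        if rec.id in test_ids and rec.pic50 in (hi.pic50, lo.pic50):
            label = "most" if rec.pic50 == hi.pic50 else "least"
            raise ValueError(
                f"{label}-active compound {rec.id!r} (pIC50 {rec.pic50}) "
                "must be in the training set"
            )
    spread = hi.pic50 - lo.pic50
    if spread < 3.0:
        warnings.warn(
            f"activity spread {spread:.2f} log units is below the 3-log-unit "
            "guideline for a reliable model", stacklevel=2)
    if not test_ids:
        warnings.warn("empty test set: external validation impossible", stacklevel=2)
    return SplitSpec(train=frozenset(all_ids - test_ids), test=frozenset(test_ids))
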