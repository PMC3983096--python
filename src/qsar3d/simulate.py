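"""Synthetic congeneric series with a planted field-activity relationship.

The modelled chemical series exists in the literature only as drawings, so
pipeline testing needs a generator that emulates its shape: one rigid
shared scaffold (a fused planar bicyclic, standing in for the
isoquinoline-1,3-dione core) carrying 0-3 variable substituents. Each
substituent is a single pseudo-atom — a sphere with a tunable element,
partial charge, hydrophobicity and donor/acceptor flags. This deliberate
idealisation keeps the mapping from substituent properties to grid-field
values exactly linear, so a planted linear activity model

``pIC50 = baseline + sum_sites sum_props coef[site, prop] * prop_value + noise``

is recoverable by the PLS pipeline and recovery is provable, not anecdotal.
Property values are the same quantities the CoMSIA fields see: vdW radius
cubed (steric), partial charge, hydrophobicity, donor/acceptor indicators.

Compounds are generated pre-aligned (every scaffold atom at identical
coordinates), activities span several log units by construction, and the
planted truth (feature matrix and coefficients) ships alongside the data
for parameter-recovery tests. The printed 81-compound actual/predicted
activity table of the original study is packaged as a fixture and exposed
by :func:`table2_fixture`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Geometry import Point3D

from .dataset import ActivityRecord, Atom, CompoundRecord, write_compound_set
from .params import vdw_radius

__all__ = ["Substituent", "SubstituentSite", "ScenarioSpec", "PlantedTruth",
           "generate_set", "write_scenario", "default_scenario",
           "probe_library", "table2_fixture", "SCAFFOLD_PATTERN"]

_BL = 1.4  # aromatic-like bond length, A
_X = 1.2124  # _BL * cos(30 deg)

# rigid fused-bicyclic scaffold, 10 atoms in the z = 0 plane
_SCAFFOLD_COORDS = np.array([
    (0.0, _BL / 2, 0.0), (0.0, -_BL / 2, 0.0),
    (_X, _BL, 0.0), (2 * _X, _BL / 2, 0.0), (2 * _X, -_BL / 2, 0.0),
    (_X, -_BL, 0.0),
    (-_X, _BL, 0.0), (-2 * _X, _BL / 2, 0.0), (-2 * _X, -_BL / 2, 0.0),
    (-_X, -_BL, 0.0),
])
_SCAFFOLD_BONDS = [(0, 1), (0, 2), (2, 3), (3, 4), (4, 5), (5, 1),
                   (0, 6), (6, 7), (7, 8), (8, 9), (9, 1)]

#: atom-index alignment pattern covering the whole scaffold
SCAFFOLD_PATTERN: tuple[int, ...] = tuple(range(10))

_PROPS = ("steric", "charge", "hydrophobic", "donor", "acceptor")


@dataclass(frozen=True)
class Substituent:
    """A single-sphere pseudo-substituent."""

    name: str
    element: str
    charge: float
    hydrophobicity: float
    donor: bool = False
    acceptor: bool = False

    def property_values(self) -> dict[str, float]:
        r = vdw_radius(self.element)
        return {"steric": r ** 3, "charge": self.charge,
                "hydrophobic": self.hydrophobicity,
                "donor": 1.0 if self.donor else 0.0,
                "acceptor": 1.0 if self.acceptor else 0.0}


@dataclass(frozen=True)
class SubstituentSite:
    """Attachment point on the scaffold plus outward growth direction."""

    scaffold_atom: int
    direction: tuple[float, float, float]
    bond_length: float = 1.5

    def position(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        return _SCAFFOLD_COORDS[self.scaffold_atom] + self.bond_length * d


_DEFAULT_VOCABULARY = (
    Substituent("methyl", "C", 0.00, 0.55),
    Substituent("hydroxyl", "O", -0.40, -0.40, donor=True, acceptor=True),
    Substituent("amine", "N", -0.30, -0.60, donor=True, acceptor=True),
    Substituent("fluoro", "F", -0.20, 0.20),
    Substituent("bromo", "Br", -0.10, 0.90),
    Substituent("thio", "S", 0.00, 0.60),
    Substituent("ammonium", "N", 0.50, -1.00, donor=True),
)

_DEFAULT_SITES = (
    SubstituentSite(3, (1.0, 0.5, 0.0)),   # R1, right ring upper edge
    SubstituentSite(7, (-1.0, 0.5, 0.0)),  # R2, left ring upper edge
    SubstituentSite(5, (0.5, -1.0, 0.0)),  # R3, right ring lower edge
)

# (site index, property) -> effect on pIC50 per unit property value
_DEFAULT_EFFECTS = {
    (0, "steric"): 0.30,       # bulk tolerated at R1 (per A^3)
    (1, "charge"): -2.00,      # electron density favoured at R2 (per e)
    (2, "hydrophobic"): 0.80,  # lipophilicity favoured at R3
    (2, "donor"): 0.40,        # H-bond donation favoured at R3
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything that defines one synthetic study: sizes, chemistry, truth."""

    n_compounds: int = 81
    n_test: int | None = None  # default: 15 when n allows, else ~a quarter
    sites: tuple[SubstituentSite, ...] = _DEFAULT_SITES
    vocabulary: tuple[Substituent, ...] = _DEFAULT_VOCABULARY
    effects: dict[tuple[int, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS))
    baseline: float = 5.6  # pIC50 of the unsubstituted scaffold
    p_unsubstituted: float = 0.25  # per-site probability of no substituent
    noise_sd: float = 0.2  # log units
    seed: int = 20240301

    def __post_init__(self) -> None:
        if self.n_compounds < 10:
            raise ValueError("need at least 10 compounds")
        if not self.vocabulary:
            raise ValueError("substituent vocabulary is empty")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not all(np.isfinite(list(self.effects.values()) or [0.0])):
            raise ValueError("planted effects must be finite")
        if self.n_test is None:
            object.__setattr__(self, "n_test",
                               min(15, self.n_compounds // 4))
        if not 0 <= self.n_test < self.n_compounds:
            raise ValueError("n_test must be < n_compounds")


@dataclass(frozen=True)
class PlantedTruth:
    """The generating model, kept for parameter-recovery tests."""

    feature_names: tuple[str, ...]  # "site{i}:{prop}"
    features: np.ndarray  # (n, k) property values per compound
    coef: np.ndarray  # (k,) planted effects, aligned with feature_names
    baseline: float
    noise_sd: float
    clean_activity: np.ndarray  # (n,) activity before noise

    def to_json(self) -> str:
        return json.dumps({
            "feature_names": list(self.feature_names),
            "features": self.features.tolist(),
            "coef": self.coef.tolist(),
            "baseline": self.baseline,
            "noise_sd": self.noise_sd,
            "clean_activity": self.clean_activity.tolist(),
        }, indent=1)


def default_scenario(**overrides) -> ScenarioSpec:
    """The shipped study conditions: 81 compounds, 15 held out, 3 sites."""
    return ScenarioSpec(**overrides)


def _build_mol(choices: Sequence[Substituent | None],
               sites: Sequence[SubstituentSite]) -> tuple[Chem.Mol, list[Atom]]:
    rw = Chem.RWMol()
    coords: list[np.ndarray] = []
    for xyz in _SCAFFOLD_COORDS:
        rw.AddAtom(Chem.Atom("C"))
        coords.append(np.asarray(xyz))
    for a, b in _SCAFFOLD_BONDS:
        rw.AddBond(a, b, Chem.BondType.SINGLE)
    atoms = [Atom(element="C", coords=c, charge=0.0, radius=vdw_radius("C"),
                  hydrophobicity=0.3, donor=False, acceptor=False)
             for c in coords]
    for site, sub in zip(sites, choices):
        if sub is None:
            continue
        idx = rw.AddAtom(Chem.Atom(sub.element))
        rw.AddBond(site.scaffold_atom, idx, Chem.BondType.SINGLE)
        pos = site.position()
        coords.append(pos)
        atoms.append(Atom(element=sub.element, coords=pos, charge=sub.charge,
                          radius=vdw_radius(sub.element),
                          hydrophobicity=sub.hydrophobicity,
                          donor=sub.donor, acceptor=sub.acceptor))
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, c in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*(float(x) for x in c)))
    mol.AddConformer(conf)
    return mol, atoms


def generate_set(spec: ScenarioSpec
                 ) -> tuple[list[CompoundRecord], list[ActivityRecord], PlantedTruth]:
    """Draw one synthetic study from the scenario.

    Returns pre-aligned compounds, their (noisy) activity records with
    train/test roles, and the planted truth. Deterministic for a fixed
    scenario (the seed is part of the spec).
    """
    rng = np.random.default_rng(spec.seed)
    n, n_sites = spec.n_compounds, len(spec.sites)
    feature_names = tuple(f"site{i}:{p}" for i in range(n_sites) for p in _PROPS)
    coef = np.array([spec.effects.get((i, p), 0.0)
                     for i in range(n_sites) for p in _PROPS])
    compounds: list[CompoundRecord] = []
    features = np.zeros((n, n_sites * len(_PROPS)))
    for j in range(n):
        choices: list[Substituent | None] = []
        for i in range(n_sites):
            if rng.random() < spec.p_unsubstituted:
                choices.append(None)
            else:
                choices.append(spec.vocabulary[rng.integers(len(spec.vocabulary))])
        mol, atoms = _build_mol(choices, spec.sites)
        cid = f"S{j + 1:03d}"
        mol.SetProp("_Name", cid)
        compounds.append(CompoundRecord(id=cid, atoms=atoms, mol=mol))
        for i, sub in enumerate(choices):
            if sub is not None:
                vals = sub.property_values()
                for k, p in enumerate(_PROPS):
                    features[j, i * len(_PROPS) + k] = vals[p]
    clean = spec.baseline + features @ coef
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    activity = clean + noise
    # held-out set drawn at random, keeping the extremes in training
    order = np.argsort(activity)
    protected = {int(order[0]), int(order[-1])}
    eligible = np.array([j for j in range(n) if j not in protected])
    test_idx = set(int(j) for j in
                   rng.choice(eligible, size=spec.n_test, replace=False)) \
        if spec.n_test else set()
    records = []
    for j, c in enumerate(compounds):
        role = "test" if j in test_idx else "train"
        c.activity = float(activity[j])
        c.role = role
        records.append(ActivityRecord(id=c.id, pic50=float(activity[j]), role=role))
    truth = PlantedTruth(feature_names=feature_names, features=features,
                         coef=coef, baseline=spec.baseline,
                         noise_sd=spec.noise_sd, clean_activity=clean)
    return compounds, records, truth


def write_scenario(spec: ScenarioSpec, directory: str | Path
                   ) -> tuple[Path, Path, Path]:
    """Materialise a scenario: SDF structures, activity table, truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    compounds, records, truth = generate_set(spec)
    sdf = directory / "compounds.sdf"
    tsv = directory / "activities.tsv"
    truth_path = directory / "truth.json"
    write_compound_set(compounds, sdf)
    with open(tsv, "w") as f:
        f.write("id\tpic50\trole\n")
        for r in records:
            f.write(f"{r.id}\t{r.pic50:.6f}\t{r.role}\n")
    truth_path.write_text(truth.to_json())
    return sdf, tsv, truth_path


def probe_library(spec: ScenarioSpec
                  ) -> tuple[CompoundRecord, list[CompoundRecord], np.ndarray]:
    """Bare scaffold plus every single-substituent probe compound.

    Returns the unsubstituted scaffold, one compound per (site, substituent)
    pair, and the planted activity effect of each probe relative to the bare
    scaffold. Predicting these probes with a fitted model and differencing
    against the predicted bare-scaffold activity yields the model's
    substituent-effect vector, directly comparable (e.g. by cosine
    similarity) with the planted one — the package's parameter-recovery
    measure.
    """
    bare_mol, bare_atoms = _build_mol([None] * len(spec.sites), spec.sites)
    bare_mol.SetProp("_Name", "bare")
    bare = CompoundRecord(id="bare", atoms=bare_atoms, mol=bare_mol)
    probes: list[CompoundRecord] = []
    effects: list[float] = []
    for s in range(len(spec.sites)):
        for sub in spec.vocabulary:
            choices: list[Substituent | None] = [None] * len(spec.sites)
            choices[s] = sub
            mol, atoms = _build_mol(choices, spec.sites)
            cid = f"probe_s{s}_{sub.name}"
            mol.SetProp("_Name", cid)
            probes.append(CompoundRecord(id=cid, atoms=atoms, mol=mol))
            vals = sub.property_values()
            effects.append(sum(spec.effects.get((s, p), 0.0) * vals[p]
                               for p in vals))
    return bare, probes, np.array(effects)


def table2_fixture() -> pd.DataFrame:
    """The packaged 81-compound actual/predicted pIC50 table.

    Columns: id, pic50_actual, pred_comfa, res_comfa, pred_comsia,
    res_comsia, role (66 train / 15 test). Values transcribed from the
    printed table; two residual entries are known to disagree with their
    own actual/predicted pair in the source, so downstream computation
    always recomputes residuals as predicted minus actual.
    """
    with resources.files("qsar3d.data").joinpath("table2.tsv").open() as f:
        df = pd.read_csv(f, sep="\t")
    df["id"] = df["id"].astype(str)
    return df
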