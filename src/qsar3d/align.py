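"""Rigid superposition of a congeneric series onto a template compound.

Field-based QSAR compares molecules point by point in space, so every
compound must first be superposed onto a common frame. The shared rigid
scaffold of the series (for the modelled series, the isoquinoline-1,3-dione
ring system) defines the correspondence; a least-squares (Kabsch) rigid
rotation + translation of the scaffold atoms then carries the whole
molecule. No flexible fitting is performed.

The substructure pattern is either a SMARTS string (matched with RDKit) or
an explicit atom-index list, in which case the same indices are taken in
template and target — the convention used by the synthetic-series generator,
whose scaffold atoms occupy identical positions in every record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .dataset import CompoundRecord

__all__ = ["SubstructureMap", "RigidTransform", "match_substructure",
           "superpose", "align_set"]


@dataclass(frozen=True)
class SubstructureMap:
    """Atom correspondence between template and target scaffolds."""

    pattern: str | tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]  # (template atom idx, target atom idx)

    def __post_init__(self) -> None:
        if len(self.pairs) < 3:
            raise ValueError("rigid superposition needs at least 3 atom pairs")


@dataclass(frozen=True)
class RigidTransform:
    """x -> x @ rotation + translation, a proper rigid motion."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd_after: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float))
        if self.rmsd_after < 0:
            raise ValueError("rmsd cannot be negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation + self.translation


def superpose(target_points: np.ndarray, template_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping *target_points* onto *template_points*.

    Kabsch algorithm: centroids removed, rotation from the SVD of the
    covariance with a reflection-correcting sign. Collinear or degenerate
    point sets (rotation about the line undetermined) are rejected.
    """
    X = np.asarray(target_points, dtype=float)
    Y = np.asarray(template_points, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValueError("need matching (n>=3, 3) coordinate arrays")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    # degenerate if the template scaffold is (near-)collinear
    sv = np.linalg.svd(Y0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    H = X0.T @ Y0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = yc - xc @ R
    rmsd = float(np.sqrt(np.mean(np.sum((X @ R + t - Y) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t, rmsd_after=rmsd)


def _smarts_matches(record: CompoundRecord, query: Chem.Mol) -> list[tuple[int, ...]]:
    if record.mol is None:
        raise ValueError(f"compound {record.id!r} carries no molecule object; "
                         "SMARTS matching needs one (use an atom-index pattern)")
    return [tuple(m) for m in record.mol.GetSubstructMatches(query, uniquify=True)]


def match_substructure(template: CompoundRecord, target: CompoundRecord,
                       pattern: str | Sequence[int]) -> SubstructureMap:
    """Find the scaffold atom correspondence between template and target.

    A SMARTS pattern must match the template exactly once. If the target
    matches more than once, the match giving the lowest post-superposition
    RMSD wins; exact ties resolve to the lexicographically smallest atom
    ordering (matches are enumerated in that order).
    """
    if not isinstance(pattern, str):
        idx = tuple(int(i) for i in pattern)
        for rec in (template, target):
            if max(idx) >= len(rec.atoms):
                raise ValueError(
                    f"pattern index {max(idx)} out of range for compound {rec.id!r}")
        return SubstructureMap(pattern=idx, pairs=tuple((i, i) for i in idx))

    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise ValueError(f"invalid SMARTS pattern {pattern!r}")
    tmpl_matches = _smarts_matches(template, query)
    if len(tmpl_matches) != 1:
        raise ValueError(
            f"pattern must match template {template.id!r} exactly once, "
            f"matched {len(tmpl_matches)} times")
    tgt_matches = _smarts_matches(target, query)
    if not tgt_matches:
        raise ValueError(f"compound {target.id!r} does not contain the scaffold")
    tmpl_idx = tmpl_matches[0]
    tmpl_pts = template.coords[list(tmpl_idx)]
    tgt_coords = target.coords
    best, best_rmsd = None, np.inf
    for m in tgt_matches:
        rmsd = superpose(tgt_coords[list(m)], tmpl_pts).rmsd_after
        if rmsd < best_rmsd - 1e-12:
            best, best_rmsd = m, rmsd
    return SubstructureMap(pattern=pattern,
                           pairs=tuple(zip(tmpl_idx, best)))


def align_set(compounds: Sequence[CompoundRecord], template_id: str,
              pattern: str | Sequence[int]) -> list[CompoundRecord]:
    """Superpose every compound onto the template via the shared scaffold.

    The template itself is returned unchanged. Compounds that fail to match
    are collected and reported together in one error.
    """
    by_id = {c.id: c for c in compounds}
    if template_id not in by_id:
        raise ValueError(f"template id {template_id!r} not in compound set")
    template = by_id[template_id]
    aligned: list[CompoundRecord] = []
    failures: list[str] = []
    for rec in compounds:
        if rec.id == template_id:
            aligned.append(rec)
            continue
        try:
            smap = match_substructure(template, rec, pattern)
            t_idx = [p[0] for p in smap.pairs]
            g_idx = [p[1] for p in smap.pairs]
            xform = superpose(rec.coords[g_idx], template.coords[t_idx])
            aligned.append(rec.with_coords(xform.apply(rec.coords)))
        except ValueError as e:
            failures.append(f"{rec.id}: {e}")
    if failures:
        raise ValueError("alignment failed for: " + "; ".join(failures))
    return aligned
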