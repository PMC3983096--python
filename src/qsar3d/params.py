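"""Per-element atom parameters used by the field engine.

One versioned table supplies everything a grid-field calculation needs per
atom: van der Waals radius, Lennard-Jones well parameters (Tripos-style
``r*``/``epsilon``), and the probe definitions. Hydrophobicity is atom-typed
(Ghose-Crippen contributions via RDKit) and therefore lives in
:mod:`qsar3d.dataset`, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

PARAMETER_TABLE_VERSION = "1.0"

# element -> (vdW radius [A], LJ r* [A], LJ epsilon [kcal/mol])
# Tripos-force-field-style values; r* is the single-atom minimum-energy radius
# so the pair minimum sits at r*_i + r*_p with eps_ip = sqrt(eps_i * eps_p).
_ELEMENTS: dict[str, tuple[float, float, float]] = {
    "H": (1.20, 1.50, 0.042),
    "C": (1.70, 1.70, 0.107),
    "N": (1.55, 1.55, 0.095),
    "O": (1.52, 1.52, 0.116),
    "F": (1.47, 1.47, 0.109),
    "P": (1.80, 1.80, 0.314),
    "S": (1.80, 1.80, 0.314),
    "Cl": (1.75, 1.75, 0.314),
    "Br": (1.85, 1.85, 0.434),
    "I": (1.98, 1.98, 0.623),
}

#: Coulomb conversion constant, kcal*A/(mol*e^2)
COULOMB_CONSTANT = 332.17

#: CoMFA field truncation, kcal/mol
COMFA_TRUNCATION = 30.0

#: CoMSIA Gaussian attenuation factor (dimensionless per A^2)
COMSIA_ALPHA = 0.3


class UnknownElementError(KeyError):
    """Raised when an element has no entry in the parameter table."""


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Angstrom for *element*."""
    try:
        return _ELEMENTS[element][0]
    except KeyError:
        raise UnknownElementError(f"no parameters for element {element!r}") from None


def lj_params(element: str) -> tuple[float, float]:
    """Lennard-Jones ``(r*, epsilon)`` for *element* (Angstrom, kcal/mol)."""
    try:
        _, rstar, eps = _ELEMENTS[element]
    except KeyError:
        raise UnknownElementError(f"no parameters for element {element!r}") from None
    return rstar, eps


def known_elements() -> frozenset[str]:
    return frozenset(_ELEMENTS)


@dataclass(frozen=True)
class ProbeSpec:
    """A probe atom evaluated at every grid point.

    The CoMFA probe is an sp3 carbon carrying a +1 charge; its steric
    parameters are the carbon Lennard-Jones entry. The CoMSIA probe has a
    1 A radius and every property set to +1.
    """

    kind: str  # "comfa" | "comsia"
    radius: float
    charge: float
    steric: float
    hydrophobic: float
    donor: float
    acceptor: float

    def __post_init__(self) -> None:
        if self.kind not in ("comfa", "comsia"):
            raise ValueError(f"unknown probe kind {self.kind!r}")


def comfa_probe() -> ProbeSpec:
    rstar, _ = lj_params("C")
    return ProbeSpec(kind="comfa", radius=rstar, charge=1.0, steric=1.0,
                     hydrophobic=0.0, donor=0.0, acceptor=0.0)


def comsia_probe() -> ProbeSpec:
    return ProbeSpec(kind="comsia", radius=1.0, charge=1.0, steric=1.0,
                     hydrophobic=1.0, donor=1.0, acceptor=1.0)
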