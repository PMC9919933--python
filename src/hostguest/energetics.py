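"""Binding energy, Hildebrand solubility parameter, pairwise nonbonded
energies, and charge-class hydrogen-bond typing.

Binding energy of a host-guest complex:

    E_binding = -E_inter = -(E_total - E_guest - E_host)   [kcal/mol]

with the convention that a positive E_binding means favourable association.
When per-frame energies are supplied, components are averaged over a
trailing window of frames (the tail of an equilibrated run).

Hildebrand solubility parameter:

    delta = sqrt(CED) = sqrt(dE / V) = sqrt((dH - R T) / V)

with the cohesive energy dE in cal/mol, the molar volume V in cm³/mol, and
delta in (cal/cm³)^1/2. Two materials are compatible when |delta_A -
delta_B| < 1.0, may be compatible up to 3.4, and are incompatible above 4.9;
the uncovered gap (3.4, 4.9] is reported as indeterminate rather than being
silently merged into a neighbour.

Hydrogen-bond types are enumerated from an atom-class table (acceptor oxygen
classes and donor-hydroxyl hydrogen classes with their partial charges):
every intermolecular acceptor x donor-H pairing is a type, labelled A, B,
C, ... with guest acceptors (paired with the host donor hydrogen) listed
before host acceptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .descriptors import RDFResult, radial_distribution
from .errors import DomainError, InvalidInputError
from .trajectory import Frame, Trajectory, minimum_image_displacement

__all__ = [
    "EnergyComponents",
    "CohesiveEnergyResult",
    "CompatibilityVerdict",
    "AtomClass",
    "AtomClassTable",
    "HBondTypeCatalogue",
    "NonbondedParams",
    "binding_energy",
    "binding_energy_from_table",
    "pairwise_energy",
    "solubility_parameter",
    "compatibility",
    "enumerate_hbond_types",
    "assign_hbond_type",
    "rdf_per_type",
]

COULOMB_CONSTANT = 332.0637  # kcal Å / (mol e²)
GAS_CONSTANT_CAL = 1.9872  # cal / (mol K)


@dataclass(frozen=True)
class EnergyComponents:
    """Total, guest and host energies with the derived binding energy."""

    e_total: float
    e_guest: float
    e_host: float

    @property
    def e_binding(self) -> float:
        return -(self.e_total - self.e_guest - self.e_host)


@dataclass(frozen=True)
class CohesiveEnergyResult:
    cohesive_energy: float  # cal/mol
    molar_volume: float  # cm³/mol
    ced: float  # cal/cm³
    delta: float  # (cal/cm³)^1/2
    heat_of_vaporization: float | None = None  # cal/mol, when the dH path was used
    temperature: float | None = None  # K


@dataclass(frozen=True)
class CompatibilityVerdict:
    delta_a: float
    delta_b: float
    difference: float
    category: str


@dataclass(frozen=True)
class AtomClass:
    """One charge class from the atom-class table."""

    label: str
    role: str  # "host" or "guest"
    charge: float  # e; negative for acceptors, positive for donor hydrogens
    kind: str  # "acceptor" or "donorH"

    def __post_init__(self):
        if self.kind not in ("acceptor", "donorH"):
            raise InvalidInputError(f"kind must be acceptor or donorH, got {self.kind!r}")
        if self.role not in ("host", "guest"):
            raise InvalidInputError(f"role must be host or guest, got {self.role!r}")
        if self.kind == "acceptor" and self.charge >= 0:
            raise InvalidInputError(f"acceptor class {self.label} must carry negative charge")
        if self.kind == "donorH" and self.charge <= 0:
            raise InvalidInputError(f"donor-H class {self.label} must carry positive charge")


@dataclass(frozen=True)
class AtomClassTable:
    entries: tuple[AtomClass, ...]

    def __post_init__(self):
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise InvalidInputError("atom-class labels must be unique")

    def of_kind(self, role: str, kind: str) -> list[AtomClass]:
        return [e for e in self.entries if e.role == role and e.kind == kind]


@dataclass(frozen=True)
class HBondTypeCatalogue:
    """Ordered (type label, acceptor class, donor-H class) triples."""

    entries: tuple[tuple[str, str, str], ...]

    def lookup(self, acceptor_class: str, donor_h_class: str) -> str | None:
        for label, acc, don in self.entries:
            if acc == acceptor_class and don == donor_h_class:
                return label
        return None


@dataclass(frozen=True)
class NonbondedParams:
    """Lennard-Jones + Coulomb parameters for toy pairwise-additive systems.

    ``lj`` maps element symbol to (epsilon kcal/mol, sigma Å); mixing is
    Lorentz-Berthelot. No tail corrections.
    """

    lj: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    cutoff: float = 12.0  # Å
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self):
        if self.cutoff <= 0:
            raise InvalidInputError("cutoff must be positive")
        for el, (eps, sig) in self.lj.items():
            if eps < 0 or sig <= 0:
                raise InvalidInputError(f"bad LJ parameters for {el}: {(eps, sig)}")


# ---------------------------------------------------------------------------
# binding energy


def binding_energy(e_total: float, e_guest: float, e_host: float) -> EnergyComponents:
    """E_binding = -(E_total - E_guest - E_host); positive favours binding."""
    for v in (e_total, e_guest, e_host):
        if not np.isfinite(v):
            raise InvalidInputError("energies must be finite")
    return EnergyComponents(e_total=e_total, e_guest=e_guest, e_host=e_host)


def binding_energy_from_table(
    energies: Mapping[str, np.ndarray], window: int = 5
) -> EnergyComponents:
    """Binding energy from per-frame component energies.

    Each component (keys ``total``, ``guest``, ``host``) is averaged over
    the trailing ``window`` frames before the binding energy is formed.
    """
    missing = {"total", "guest", "host"} - set(energies)
    if missing:
        raise InvalidInputError(f"energy table missing components: {sorted(missing)}")
    if window < 1:
        raise InvalidInputError("window must be >= 1")
    means = {k: float(np.asarray(energies[k], dtype=float)[-window:].mean())
             for k in ("total", "guest", "host")}
    return binding_energy(means["total"], means["guest"], means["host"])


# ---------------------------------------------------------------------------
# pairwise nonbonded energy


def _pair_energy_arrays(frame: Frame, params: NonbondedParams, idx: np.ndarray):
    coords = frame.coordinates[idx]
    charges = np.array([frame.atoms[i].partial_charge for i in idx])
    eps = np.empty(len(idx))
    sig = np.empty(len(idx))
    for n, i in enumerate(idx):
        e, s = params.lj.get(frame.atoms[i].element, (0.0, 1.0))
        eps[n], sig[n] = e, s
    return coords, charges, eps, sig


def _pairwise_sum(frame, params, idx_a, idx_b, exclude_self_pairs):
    """Sum of nonbonded pair energies between two index sets (vectorized)."""
    ca, qa, ea, sa = _pair_energy_arrays(frame, params, idx_a)
    cb, qb, eb, sb = _pair_energy_arrays(frame, params, idx_b)
    delta = minimum_image_displacement(ca[:, None, :], cb[None, :, :], frame.cell)
    r = np.sqrt(np.einsum("ijx,ijx->ij", delta, delta))
    if exclude_self_pairs:
        same = idx_a[:, None] == idx_b[None, :]
        r = np.where(same, np.inf, r)
    if np.any(r == 0):
        raise DomainError("coincident atoms (r = 0) in pairwise energy")
    within = r <= params.cutoff
    eps = np.sqrt(ea[:, None] * eb[None, :])  # Lorentz-Berthelot
    sig = (sa[:, None] + sb[None, :]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        sr6 = (sig / r) ** 6
        lj = 4.0 * eps * (sr6**2 - sr6)
        coul = params.coulomb_constant * qa[:, None] * qb[None, :] / r
        e = np.where(within, lj + coul, 0.0)
    return float(e.sum())


def pairwise_energy(
    frame: Frame, params: NonbondedParams, subset: np.ndarray | None = None
) -> float:
    """Total nonbonded energy of a subset (kcal/mol), unique pairs in cutoff.

    E = sum over pairs of 4 eps [(sigma/r)^12 - (sigma/r)^6]
        + k q_i q_j / r,  k = 332.0637 kcal Å / (mol e²),
    with minimum-image distances and Lorentz-Berthelot mixing.
    """
    idx = np.arange(frame.n_atoms) if subset is None else np.asarray(subset, dtype=int)
    if idx.size < 2:
        return 0.0
    return _pairwise_sum(frame, params, idx, idx, exclude_self_pairs=True) / 2.0


def cross_pair_energy(
    frame: Frame, params: NonbondedParams, group_a: np.ndarray, group_b: np.ndarray
) -> float:
    """Interaction energy between two disjoint groups (kcal/mol)."""
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if np.intersect1d(a, b).size:
        raise InvalidInputError("cross-pair groups must be disjoint")
    if a.size == 0 or b.size == 0:
        return 0.0
    return _pairwise_sum(frame, params, a, b, exclude_self_pairs=False)


# ---------------------------------------------------------------------------
# solubility parameter and compatibility


def solubility_parameter(
    cohesive_energy: float | None = None,
    molar_volume: float | None = None,
    heat_of_vaporization: float | None = None,
    temperature: float = 298.0,
) -> CohesiveEnergyResult:
    """Hildebrand solubility parameter delta = sqrt(dE / V).

    Supply either ``cohesive_energy`` (cal/mol) directly, or
    ``heat_of_vaporization`` (cal/mol) with ``temperature`` (K), in which
    case dE = dH - R T with R = 1.9872 cal/(mol K). ``molar_volume`` is in
    cm³/mol. Cohesive energy is positive by convention (E_isolated -
    E_bulk).
    """
    if molar_volume is None or molar_volume <= 0:
        raise DomainError("molar volume must be a positive cm³/mol value")
    dh = None
    if cohesive_energy is None:
        if heat_of_vaporization is None:
            raise InvalidInputError("supply cohesive_energy or heat_of_vaporization")
        dh = heat_of_vaporization
        cohesive_energy = heat_of_vaporization - GAS_CONSTANT_CAL * temperature
    if cohesive_energy < 0:
        raise DomainError(
            "cohesive energy must be non-negative; use the convention "
            "dE = E_isolated - E_bulk (positive for a cohesive material)"
        )
    ced = cohesive_energy / molar_volume
    return CohesiveEnergyResult(
        cohesive_energy=cohesive_energy,
        molar_volume=molar_volume,
        ced=ced,
        delta=float(np.sqrt(ced)),
        heat_of_vaporization=dh,
        temperature=temperature if dh is not None else None,
    )


def compatibility(delta_a: float, delta_b: float) -> CompatibilityVerdict:
    """Compatibility category from |delta_A - delta_B| in (cal/cm³)^1/2.

    < 1.0 compatible; [1.0, 3.4] may_be_compatible; (3.4, 4.9]
    indeterminate; > 4.9 incompatible. The boundary values 1.0 and 3.4 fall
    into may_be_compatible and 4.9 into indeterminate (the source rules use
    strict inequalities, leaving boundaries to this convention).
    """
    if not (np.isfinite(delta_a) and np.isfinite(delta_b)):
        raise InvalidInputError("solubility parameters must be finite")
    diff = abs(delta_a - delta_b)
    if diff < 1.0:
        category = "compatible"
    elif diff <= 3.4:
        category = "may_be_compatible"
    elif diff <= 4.9:
        category = "indeterminate"
    else:
        category = "incompatible"
    return CompatibilityVerdict(delta_a=delta_a, delta_b=delta_b,
                                difference=diff, category=category)


# ---------------------------------------------------------------------------
# hydrogen-bond typing


def _letter(i: int) -> str:
    # A, B, ..., Z, AA, AB, ... for catalogues beyond 26 entries
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def enumerate_hbond_types(table: AtomClassTable) -> HBondTypeCatalogue:
    """Enumerate intermolecular hydrogen-bond types from an atom-class table.

    Types are the cross-product of guest acceptors with host donor
    hydrogens, followed by host acceptors with guest donor hydrogens
    (intramolecular pairings are excluded by construction), labelled with
    consecutive letters from A. Acceptors keep table order; multiple donor
    classes on one side enumerate in table order as well.
    """
    pairs: list[tuple[str, str]] = []
    for acc in table.of_kind("guest", "acceptor"):
        for don in table.of_kind("host", "donorH"):
            pairs.append((acc.label, don.label))
    for acc in table.of_kind("host", "acceptor"):
        for don in table.of_kind("guest", "donorH"):
            pairs.append((acc.label, don.label))
    entries = tuple((_letter(i), acc, don) for i, (acc, don) in enumerate(pairs))
    return HBondTypeCatalogue(entries=entries)


def assign_hbond_type(record, frame: Frame, catalogue: HBondTypeCatalogue) -> str:
    """Type label for a detected hydrogen bond, or "untyped".

    Intramolecular records and records whose (acceptor class, hydrogen
    class) pairing is absent from the catalogue are "untyped".
    """
    if record.intra_or_inter == "intramolecular":
        return "untyped"
    acc = frame.atoms[record.acceptor].class_label
    don = frame.atoms[record.hydrogen].class_label
    if acc is None or don is None:
        raise InvalidInputError(
            "acceptor/hydrogen atoms must carry class labels for typing"
        )
    return catalogue.lookup(acc, don) or "untyped"


def rdf_per_type(
    traj: Trajectory,
    catalogue: HBondTypeCatalogue,
    dr: float = 0.1,
    r_max: float | None = None,
) -> dict[str, RDFResult]:
    """One acceptor-donor RDF per catalogue type (skips absent classes)."""
    frame0 = traj.frames[0]
    out: dict[str, RDFResult] = {}
    for label, acc_class, don_class in catalogue.entries:
        group_a = frame0.select(class_label=acc_class)
        group_b = frame0.select(class_label=don_class)
        if group_a.size == 0 or group_b.size == 0:
            continue
        out[label] = radial_distribution(traj, group_a, group_b, dr=dr, r_max=r_max)
    return out
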