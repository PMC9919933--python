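"""Synthetic-data generators with known ground truth.

Every generator is a pure function of its parameters and seed (one explicit
seeded NumPy generator per call, no global state), so fixtures are
bit-reproducible for the same library versions.

The generators emulate the inputs of a host-guest inclusion study:

* noisy A_L-type phase-solubility experiments with Beer-Lambert readout,
* Brownian and ideal-gas particle trajectories in periodic boxes,
* frames seeded with an exact number of hydrogen-bond geometries plus
  decoys that narrowly violate the distance or angle criterion,
* two-cluster toy systems with pairwise-additive nonbonded energies and an
  exactly known binding energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energetics import (
    EnergyComponents,
    NonbondedParams,
    cross_pair_energy,
    pairwise_energy,
)
from .errors import GenerationError, InvalidInputError
from .solubility import AbsorbanceSeries
from .trajectory import AtomRecord, Frame, PeriodicCell, Trajectory

__all__ = [
    "IsothermSpec",
    "SimulatedIsotherm",
    "BrownianSpec",
    "TwoClusterSystem",
    "simulate_isotherm",
    "brownian_trajectory",
    "ideal_gas_frames",
    "hbond_fixture",
    "two_cluster_system",
]


# ---------------------------------------------------------------------------
# phase-solubility isotherms


@dataclass(frozen=True)
class IsothermSpec:
    """Ground truth for a simulated 1:1 phase-solubility experiment.

    The implied dimensionless isotherm slope is K = Ks S0 / (1 + Ks S0),
    always < 1 for a 1:1 complex. ``noise_sd`` is the relative standard
    deviation of multiplicative (instrument-like) absorbance noise.
    """

    true_Ks: float  # M^-1
    true_S0: float  # M
    calibration_slope: float = 20.0  # AU per mM
    calibration_intercept: float = 0.05  # AU
    host_concentrations: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)  # mM
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.true_Ks < 0 or self.true_S0 <= 0:
            raise InvalidInputError("need Ks >= 0 and S0 > 0")
        if self.calibration_slope <= 0:
            raise InvalidInputError("calibration slope must be positive")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")

    @property
    def implied_slope(self) -> float:
        ks_s0 = self.true_Ks * self.true_S0
        return ks_s0 / (1.0 + ks_s0)


@dataclass(frozen=True)
class SimulatedIsotherm:
    spec: IsothermSpec
    calibration: AbsorbanceSeries
    host_concentrations: np.ndarray  # mM
    absorbances: np.ndarray  # AU, noisy


def simulate_isotherm(spec: IsothermSpec) -> SimulatedIsotherm:
    """Simulate a phase-solubility experiment under the 1:1 A_L model.

    Guest solubility at host concentration C is S(C) = S0 + K C (both mM);
    absorbance is A = m S + b times (1 + eps), eps ~ Normal(0, noise_sd).
    The calibration series is generated noiselessly from (m, b).
    """
    rng = np.random.default_rng(spec.seed)
    cal_conc = np.linspace(0.02, 0.09, 8)  # mM
    cal_abs = spec.calibration_slope * cal_conc + spec.calibration_intercept
    calibration = AbsorbanceSeries(concentrations=cal_conc, absorbances=cal_abs)
    host = np.asarray(spec.host_concentrations, dtype=float)
    s0_mM = spec.true_S0 / 1e-3
    solubility = s0_mM + spec.implied_slope * host  # mM
    absorb = spec.calibration_slope * solubility + spec.calibration_intercept
    absorb = absorb * (1.0 + rng.normal(0.0, spec.noise_sd, size=absorb.shape))
    return SimulatedIsotherm(spec=spec, calibration=calibration,
                             host_concentrations=host, absorbances=absorb)


# ---------------------------------------------------------------------------
# trajectories


@dataclass(frozen=True)
class BrownianSpec:
    n_particles: int = 100
    diffusion: float = 0.1  # Å²/ps
    dt: float = 1.0  # ps
    n_steps: int = 100
    box_edge: float = 100.0  # Å
    seed: int = 0

    def __post_init__(self):
        if min(self.n_particles, self.dt, self.n_steps, self.box_edge) <= 0:
            raise InvalidInputError("all Brownian spec fields must be positive")
        if self.diffusion < 0:
            raise InvalidInputError("diffusion coefficient must be non-negative")


def _particle_frames(coords: np.ndarray, cell: PeriodicCell, dt: float,
                     element: str = "X") -> Trajectory:
    n_atoms = coords.shape[1]
    atoms = [AtomRecord(index=i, element=element) for i in range(n_atoms)]
    frames = [Frame(atoms=atoms, coordinates=coords[t], cell=cell, time=t * dt)
              for t in range(coords.shape[0])]
    return Trajectory(frames=frames, timestep=dt)


def brownian_trajectory(spec: BrownianSpec) -> Trajectory:
    """Ideal Brownian motion: i.i.d. Gaussian steps, variance 2 D dt per axis.

    Coordinates are unwrapped (free diffusion); the periodic cell is
    metadata for volume-based analyses.
    """
    rng = np.random.default_rng(spec.seed)
    start = rng.uniform(0.0, spec.box_edge, size=(1, spec.n_particles, 3))
    steps = rng.normal(0.0, np.sqrt(2.0 * spec.diffusion * spec.dt),
                       size=(spec.n_steps, spec.n_particles, 3))
    coords = start + np.concatenate(
        [np.zeros((1, spec.n_particles, 3)), np.cumsum(steps, axis=0)])
    return _particle_frames(coords, PeriodicCell.cubic(spec.box_edge), spec.dt)


def ideal_gas_frames(n: int, box_edge: float, n_frames: int, seed: int = 0) -> Trajectory:
    """Uniform i.i.d. positions per frame in a periodic cubic box (g(r) = 1)."""
    if min(n, box_edge, n_frames) <= 0:
        raise InvalidInputError("n, box_edge and n_frames must be positive")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box_edge, size=(n_frames, n, 3))
    return _particle_frames(coords, PeriodicCell.cubic(box_edge), dt=1.0)


# ---------------------------------------------------------------------------
# hydrogen-bond fixtures

_GROUP_PITCH = 11.0  # Å; keeps distinct groups beyond any H-bond cutoff


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _orthobasis(u: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    a = _random_unit(rng)
    v1 = a - np.dot(a, u) * u
    while np.linalg.norm(v1) < 1e-8:
        a = _random_unit(rng)
        v1 = a - np.dot(a, u) * u
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(u, v1)
    return v1, v2


def _acceptor_position(donor, hydrogen, distance, angle_deg, rng):
    """Place an acceptor at the given H...A distance and D-H...A angle."""
    to_d = donor - hydrogen
    to_d /= np.linalg.norm(to_d)
    v1, v2 = _orthobasis(to_d, rng)
    theta = np.radians(angle_deg)
    phi = rng.uniform(0, 2 * np.pi)
    w = np.cos(theta) * to_d + np.sin(theta) * (np.cos(phi) * v1 + np.sin(phi) * v2)
    return hydrogen + distance * w


def hbond_fixture(
    k_bonds: int,
    decoys: int = 0,
    box_edge: float = 60.0,
    seed: int = 0,
    acceptor_class: str = "O1",
    donor_h_class: str = "H2",
    donor_o_class: str = "O7",
) -> tuple[Frame, list[tuple[int, int, int]]]:
    """Frame with exactly ``k_bonds`` O-H...O hydrogen-bond geometries.

    Each planted bond satisfies H...A in [1.8, 2.9] Å and D-H...A angle in
    [150, 180]°; acceptors sit on a guest molecule and donor hydroxyls on a
    host molecule, with the given class labels. ``decoys`` additional atoms
    narrowly violate either the distance or the angle criterion, or are
    isolated acceptors. Groups occupy disjoint grid cells at least 11 Å
    apart, so no accidental cross-group bond can form. Returns the frame and
    the ground-truth (donor, hydrogen, acceptor) index triples.
    """
    if k_bonds < 0 or decoys < 0:
        raise InvalidInputError("k_bonds and decoys must be non-negative")
    rng = np.random.default_rng(seed)
    n_div = int(box_edge // _GROUP_PITCH)
    # decoy groups hold 1-3 atoms; worst case every decoy is its own group
    if n_div**3 < k_bonds + decoys:
        raise GenerationError(
            f"box edge {box_edge} Å gives {n_div**3} placement cells; "
            f"need up to {k_bonds + decoys}"
        )
    pitch = box_edge / n_div
    cells = [(i, j, k) for i in range(n_div) for j in range(n_div) for k in range(n_div)]
    cells = [cells[i] for i in rng.permutation(len(cells))]
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    truth: list[tuple[int, int, int]] = []

    def add(element, mol_id, role, label, pos):
        atoms.append(AtomRecord(index=len(atoms), element=element,
                                molecule_id=mol_id, molecule_role=role,
                                class_label=label))
        coords.append(np.asarray(pos, dtype=float))
        return len(atoms) - 1

    cell_iter = iter(cells)

    def center():
        i, j, k = next(cell_iter)
        base = (np.array([i, j, k]) + 0.5) * pitch
        return base + rng.uniform(-1.0, 1.0, size=3)

    for _ in range(k_bonds):
        c = center()
        u = _random_unit(rng)
        donor_pos = c
        h_pos = c + 0.96 * u
        a_pos = _acceptor_position(donor_pos, h_pos,
                                   rng.uniform(1.8, 2.9), rng.uniform(150, 180), rng)
        d = add("O", 1, "host", donor_o_class, donor_pos)
        h = add("H", 1, "host", donor_h_class, h_pos)
        a = add("O", 0, "guest", acceptor_class, a_pos)
        truth.append((d, h, a))

    placed = 0
    kind = 0
    while placed < decoys:
        c = center()
        u = _random_unit(rng)
        if kind == 0:  # isolated acceptor: no hydrogen anywhere nearby
            add("O", 0, "guest", acceptor_class, c)
            placed += 1
        elif kind == 1 and decoys - placed >= 2:  # hydroxyl with no acceptor in range
            add("O", 1, "host", donor_o_class, c)
            add("H", 1, "host", donor_h_class, c + 0.96 * u)
            placed += 2
        elif decoys - placed >= 3:  # acceptor at a valid distance but bad angle
            donor_pos = c
            h_pos = c + 0.96 * u
            a_pos = _acceptor_position(donor_pos, h_pos, rng.uniform(1.9, 2.2),
                                       rng.uniform(60, 100), rng)
            add("O", 1, "host", donor_o_class, donor_pos)
            add("H", 1, "host", donor_h_class, h_pos)
            add("O", 0, "guest", acceptor_class, a_pos)
            placed += 3
        else:
            add("O", 0, "guest", acceptor_class, c)
            placed += 1
        kind = (kind + 1) % 3

    frame = Frame(atoms=atoms, coordinates=np.array(coords).reshape(len(atoms), 3),
                  cell=PeriodicCell.cubic(box_edge))
    return frame, truth


# ---------------------------------------------------------------------------
# two-cluster energy systems


@dataclass(frozen=True)
class TwoClusterSystem:
    frame: Frame
    components: EnergyComponents  # e_total, e_guest, e_host from direct summation
    cross_energy: float  # host-guest interaction, kcal/mol
    host_indices: np.ndarray
    guest_indices: np.ndarray


def two_cluster_system(
    n_host: int,
    n_guest: int,
    separation: float,
    params: NonbondedParams | None = None,
    seed: int = 0,
    charge_magnitude: float = 0.2,
    cluster_radius: float = 2.5,
) -> TwoClusterSystem:
    """Two rigid random atom clusters with exactly known component energies.

    Host atoms scatter around the origin and guest atoms around
    ``(separation, 0, 0)``; charges are uniform in ±charge_magnitude (scaling
    the magnitude scales every charge linearly). Component and cross
    energies come from direct pairwise summation, so under pairwise
    additivity E_total = E_host + E_guest + E_cross exactly.
    """
    if n_host <= 0 or n_guest <= 0:
        raise InvalidInputError("cluster sizes must be positive")
    if params is None:
        params = NonbondedParams(lj={"C": (0.1, 3.4)})
    rng = np.random.default_rng(seed)

    def cluster(n, origin):
        pts: list[np.ndarray] = []
        for _ in range(n):
            for _attempt in range(200):
                p = origin + rng.uniform(-cluster_radius, cluster_radius, size=3)
                if all(np.linalg.norm(p - q) > 0.8 for q in pts):
                    pts.append(p)
                    break
            else:
                raise GenerationError("could not place cluster atoms without overlap")
        return np.array(pts)

    host_xyz = cluster(n_host, np.zeros(3))
    guest_xyz = cluster(n_guest, np.array([separation, 0.0, 0.0]))
    unit_charges = rng.uniform(-1.0, 1.0, size=n_host + n_guest)
    charges = charge_magnitude * unit_charges
    atoms = []
    for i in range(n_host + n_guest):
        role = "host" if i < n_host else "guest"
        atoms.append(AtomRecord(index=i, element="C", partial_charge=float(charges[i]),
                                molecule_id=0 if role == "host" else 1,
                                molecule_role=role))
    frame = Frame(atoms=atoms, coordinates=np.vstack([host_xyz, guest_xyz]))
    host_idx = np.arange(n_host)
    guest_idx = np.arange(n_host, n_host + n_guest)
    e_host = pairwise_energy(frame, params, host_idx)
    e_guest = pairwise_energy(frame, params, guest_idx)
    cross = cross_pair_energy(frame, params, host_idx, guest_idx)
    components = EnergyComponents(e_total=e_host + e_guest + cross,
                                  e_guest=e_guest, e_host=e_host)
    return TwoClusterSystem(frame=frame, components=components, cross_energy=cross,
                            host_indices=host_idx, guest_indices=guest_idx)
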