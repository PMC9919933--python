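"""Trajectory descriptors: MSD, RDF, hydrogen-bond detection and concentration.

Mean square displacement
    MSD(t) = <|r_i(t) - r_i(0)|^2>, averaged over selected particles and,
    optionally, over all valid time origins (better statistics; the literal
    single-origin form uses frame 0 as r_i(0)). Requires unwrapped
    coordinates; the Einstein relation MSD = 6 D t gives the diffusion
    coefficient in 3-D.

Radial distribution function
    g(r) = dN / (N_ref * rho * 4 pi r^2 dr), the relative probability of
    finding a partner atom at distance r, computed from minimum-image pair
    distances, frame-averaged, and normalized so an ideal gas gives g -> 1.

Hydrogen bonds
    Geometric criterion: a hydrogen covalently attached to a donor atom
    (within 1.2 Å) counts as bonded to an acceptor when the H...A distance is
    at or below a cutoff and the D-H...A angle at the hydrogen is at or above
    a minimum. Peak positions classify interactions into bands: hydrogen
    bond (2.5-3.0 Å), strong van der Waals (3.0-5.0 Å), weak van der Waals
    (>= 5.0 Å). The molar H-bond concentration of a periodic cell is
    C_HBs = N_HBs / (N_A * V).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from .errors import DomainError, InvalidInputError
from .trajectory import Frame, PeriodicCell, Trajectory, minimum_image_displacement

__all__ = [
    "MSDResult",
    "RDFResult",
    "HBondCriteria",
    "HBondRecord",
    "HBondConcentration",
    "mean_square_displacement",
    "estimate_diffusion",
    "radial_distribution",
    "classify_interaction",
    "detect_hbonds",
    "hbond_concentration",
]

AVOGADRO = constants.Avogadro  # 6.02214076e23 mol^-1
A3_TO_CM3 = 1e-24

# D-H covalent assignment cutoff (Å): standard O-H bond length plus margin
COVALENT_DH_CUTOFF = 1.2


@dataclass(frozen=True)
class MSDResult:
    lag_times: np.ndarray  # ps
    msd: np.ndarray  # Å²
    selection: str = "all"
    n_origins: int = 1


@dataclass(frozen=True)
class RDFResult:
    bin_centers: np.ndarray  # Å
    g_of_r: np.ndarray
    bin_width: float  # Å
    mean_density: float  # atoms / Å³ (group_b)
    pair_counts: np.ndarray  # raw histogram, summed over frames


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    Defaults: H...A <= 3.0 Å (the upper edge of the RDF hydrogen-bond band)
    and D-H...A angle >= 120°, with oxygen as the only donor and acceptor
    element (the O-H...O bonds relevant to hydroxyl-rich hosts and guests).
    """

    max_h_acceptor_distance: float = 3.0  # Å
    min_dha_angle: float = 120.0  # degrees
    donor_elements: frozenset = frozenset({"O"})
    acceptor_elements: frozenset = frozenset({"O"})

    def __post_init__(self):
        if self.max_h_acceptor_distance <= 0:
            raise InvalidInputError("H...A cutoff must be positive")
        if not 0 <= self.min_dha_angle <= 180:
            raise InvalidInputError("angle must be in [0, 180] degrees")


@dataclass(frozen=True)
class HBondRecord:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # H...A, Å
    angle: float  # D-H...A, degrees
    frame: int = 0
    intra_or_inter: str = "intermolecular"


@dataclass(frozen=True)
class HBondConcentration:
    n_hbonds: float
    volume_cm3: float
    c_hbs: float  # mol / cm³


# ---------------------------------------------------------------------------
# MSD


def _msd_multiple_origins(pos: np.ndarray) -> np.ndarray:
    """FFT-based MSD averaged over all time origins.

    pos: (T, N, 3) unwrapped coordinates. Returns (T,) MSD averaged over
    particles and origins, using the standard decomposition
    MSD(m) = S1(m) - 2 S2(m) with S2 the positional autocorrelation.
    """
    T, N, _ = pos.shape
    nfft = 1 << (2 * T - 1).bit_length()
    f = np.fft.rfft(pos, n=nfft, axis=0)
    acf = np.fft.irfft(f * f.conj(), n=nfft, axis=0)[:T].real  # (T, N, 3)
    norm = (T - np.arange(T))[:, None]
    s2 = acf.sum(axis=2) / norm
    d = np.einsum("tnx,tnx->tn", pos, pos)  # |r(t)|² per particle
    q = 2.0 * d.sum(axis=0)
    s1 = np.empty((T, N))
    for m in range(T):
        if m > 0:
            q = q - d[m - 1] - d[T - m]
        s1[m] = q / (T - m)
    return (s1 - 2.0 * s2).mean(axis=1)


def mean_square_displacement(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    origin_scheme: str = "multiple",
) -> MSDResult:
    """MSD of the selected atoms versus lag time.

    ``selection`` is an index array (e.g. from ``Frame.select``); ``None``
    selects all atoms. ``origin_scheme`` is ``"multiple"`` (average over all
    time origins) or ``"single"`` (frame 0 is the origin, the literal
    definition). Coordinates must be unwrapped; a jump larger than half a
    cell edge between consecutive frames triggers a warning.
    """
    if traj.n_frames < 2:
        raise InvalidInputError("MSD needs at least 2 frames")
    pos = traj.coordinates
    if selection is not None:
        selection = np.asarray(selection, dtype=int)
        if selection.size == 0:
            raise InvalidInputError("empty atom selection")
        pos = pos[:, selection, :]
    cell = traj.frames[0].cell
    if cell.periodic:
        jumps = np.abs(np.diff(pos, axis=0)).max()
        if jumps > cell.min_edge / 2:
            warnings.warn(
                "frame-to-frame jump exceeds half the cell edge: coordinates "
                "look wrapped; MSD requires unwrapped coordinates",
                stacklevel=2,
            )
    times = traj.times
    lags = times - times[0]
    if origin_scheme == "single":
        disp = pos - pos[0]
        msd = np.einsum("tnx,tnx->t", disp, disp) / pos.shape[1]
        n_origins = 1
    elif origin_scheme == "multiple":
        msd = _msd_multiple_origins(pos)
        msd[0] = 0.0  # exact by definition; clears FFT round-off
        n_origins = traj.n_frames
    else:
        raise InvalidInputError(f"unknown origin_scheme {origin_scheme!r}")
    sel_desc = "all" if selection is None else f"{pos.shape[1]} atoms"
    return MSDResult(lag_times=lags, msd=np.maximum(msd, 0.0),
                     selection=sel_desc, n_origins=n_origins)


def estimate_diffusion(msd: MSDResult, fit_window: tuple[float, float]) -> float:
    """Diffusion coefficient D = slope/6 (Å²/ps) from an OLS fit of MSD(t).

    ``fit_window`` is the (min, max) lag-time range in ps, inclusive.
    """
    lo, hi = fit_window
    mask = (msd.lag_times >= lo) & (msd.lag_times <= hi)
    if mask.sum() < 2:
        raise InvalidInputError("fit window contains fewer than 2 MSD points")
    x, y = msd.lag_times[mask], msd.msd[mask]
    slope = np.polyfit(x, y, 1)[0]
    return slope / 6.0


# ---------------------------------------------------------------------------
# RDF


def radial_distribution(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    dr: float = 0.1,
    r_max: float | None = None,
) -> RDFResult:
    """Frame-averaged radial distribution function g(r) between two groups.

    Minimum-image pair distances are histogrammed into half-open bins
    [r, r + dr) and normalized by shell volume 4 pi r² dr, by the number of
    reference (group_a) atoms, by the number of frames, and by the mean
    number density of group_b, so that an ideal gas gives g(r) = 1.
    Self-pairs are excluded where the groups overlap.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        raise InvalidInputError("RDF groups must be non-empty")
    cell = traj.frames[0].cell
    if not cell.periodic:
        raise InvalidInputError("RDF requires a periodic cell")
    half_min_edge = cell.min_edge / 2
    if r_max is None:
        r_max = half_min_edge
    if r_max > half_min_edge + 1e-9:
        raise InvalidInputError(
            f"r_max={r_max} exceeds half the smallest cell edge ({half_min_edge})"
        )
    n_bins = int(np.ceil(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    counts = np.zeros(n_bins)
    rho = group_b.size / cell.volume
    if rho <= 0:
        raise DomainError("zero partner density")
    same = group_a.size == group_b.size and np.array_equal(np.sort(group_a), np.sort(group_b))
    for frame in traj.frames:
        a = frame.coordinates[group_a]
        b = frame.coordinates[group_b]
        delta = minimum_image_displacement(a[:, None, :], b[None, :, :], cell)
        dist = np.sqrt(np.einsum("ijx,ijx->ij", delta, delta))
        if same:
            np.fill_diagonal(dist, np.inf)
        else:
            shared = np.intersect1d(group_a, group_b)
            if shared.size:
                ia = {g: i for i, g in enumerate(group_a)}
                ib = {g: i for i, g in enumerate(group_b)}
                for g in shared:
                    dist[ia[g], ib[g]] = np.inf
        flat = dist[dist < r_max]
        counts += np.histogram(flat, bins=edges)[0]
    centers = edges[:-1] + dr / 2
    shell = 4.0 * np.pi * centers**2 * dr
    g = counts / (traj.n_frames * group_a.size * rho * shell)
    return RDFResult(bin_centers=centers, g_of_r=g, bin_width=dr,
                     mean_density=rho, pair_counts=counts)


_BANDS = ((2.5, 3.0, "hydrogen_bond"), (3.0, 5.0, "strong_vdw"))


def classify_interaction(peak_position: float) -> str:
    """Classify an RDF peak position into an interaction band.

    2.5-3.0 Å: hydrogen bond; 3.0-5.0 Å: strong van der Waals; >= 5.0 Å:
    weak van der Waals. Positions below 2.5 Å fall outside the defined bands
    and are reported as hydrogen bonds with a warning.
    """
    if peak_position <= 0:
        raise InvalidInputError("peak position must be positive")
    if peak_position < 2.5:
        warnings.warn(
            f"peak at {peak_position:.3g} Å is unusually short for a hydrogen bond",
            stacklevel=2,
        )
        return "hydrogen_bond"
    for lo, hi, label in _BANDS:
        if lo <= peak_position < hi:
            return label
    return "weak_vdw"


# ---------------------------------------------------------------------------
# hydrogen bonds


def detect_hbonds(
    frame: Frame, criteria: HBondCriteria = HBondCriteria(), frame_index: int = 0
) -> list[HBondRecord]:
    """Geometric hydrogen-bond detection in one frame.

    Hydrogens within 1.2 Å (minimum image) of a donor-element atom define
    D-H covalent pairs; each pair is tested against every acceptor-element
    atom (excluding the donor itself) for H...A distance <= cutoff and
    D-H...A angle >= minimum. Records are flagged intra- or intermolecular
    by comparing donor and acceptor molecule_ids.
    """
    elements = np.array([a.element for a in frame.atoms])
    mol_ids = np.array([a.molecule_id for a in frame.atoms])
    h_idx = np.nonzero(elements == "H")[0]
    d_idx = np.nonzero(np.isin(elements, sorted(criteria.donor_elements)))[0]
    a_idx = np.nonzero(np.isin(elements, sorted(criteria.acceptor_elements)))[0]
    if h_idx.size == 0 or d_idx.size == 0 or a_idx.size == 0:
        return []
    coords = frame.coordinates
    cell = frame.cell

    # covalent D-H assignment: nearest donor within the covalent cutoff
    dh = minimum_image_displacement(coords[h_idx][:, None, :], coords[d_idx][None, :, :], cell)
    dh_dist = np.sqrt(np.einsum("ijx,ijx->ij", dh, dh))
    records: list[HBondRecord] = []
    for i, h in enumerate(h_idx):
        j = np.argmin(dh_dist[i])
        if dh_dist[i, j] > COVALENT_DH_CUTOFF:
            continue
        donor = int(d_idx[j])
        ha = minimum_image_displacement(coords[h], coords[a_idx], cell)
        ha_dist = np.sqrt(np.einsum("ix,ix->i", ha, ha))
        hd = minimum_image_displacement(coords[h], coords[donor], cell)
        for k, acceptor in enumerate(a_idx):
            if acceptor == donor:
                continue
            if ha_dist[k] > criteria.max_h_acceptor_distance or ha_dist[k] == 0:
                continue
            cos_angle = np.dot(hd, ha[k]) / (np.linalg.norm(hd) * ha_dist[k])
            angle = float(np.degrees(np.arccos(np.clip(cos_angle, -1.0, 1.0))))
            if angle < criteria.min_dha_angle:
                continue
            kind = ("intramolecular" if mol_ids[donor] == mol_ids[acceptor]
                    else "intermolecular")
            records.append(HBondRecord(
                donor=donor, hydrogen=int(h), acceptor=int(acceptor),
                distance=float(ha_dist[k]), angle=angle,
                frame=frame_index, intra_or_inter=kind,
            ))
    return records


def hbond_count_over_frames(
    traj: Trajectory, criteria: HBondCriteria = HBondCriteria()
) -> tuple[np.ndarray, float, float]:
    """Per-frame H-bond counts plus their mean and standard deviation."""
    counts = np.array([
        len(detect_hbonds(f, criteria, frame_index=i))
        for i, f in enumerate(traj.frames)
    ])
    return counts, float(counts.mean()), float(counts.std())


def hbond_concentration(n_hbonds: float, cell: PeriodicCell) -> HBondConcentration:
    """Molar hydrogen-bond concentration C_HBs = N_HBs / (N_A V) in mol/cm³.

    The cell volume is converted from Å³ (1 Å³ = 1e-24 cm³). When the count
    comes from a trajectory, pass the per-frame mean rounded to the nearest
    integer.
    """
    if n_hbonds < 0:
        raise InvalidInputError("hydrogen-bond count must be non-negative")
    if not cell.periodic:
        raise DomainError("hydrogen-bond concentration needs a periodic cell volume")
    v_cm3 = cell.volume * A3_TO_CM3
    return HBondConcentration(
        n_hbonds=n_hbonds, volume_cm3=v_cm3, c_hbs=n_hbonds / (AVOGADRO * v_cm3)
    )
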