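import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rutin_calibration():
    """Fitted Beer-Lambert curve from the packaged rutin dilution series."""
    from hostguest.datasets import load_calibration_series
    from hostguest.solubility import fit_calibration

    return fit_calibration(load_calibration_series())


@pytest.fixture(scope="session")
def rutin_isotherms(rutin_calibration):
    """All three fitted cyclodextrin isotherms, keyed by system name."""
    from hostguest.datasets import load_isotherm_table
    from hostguest.solubility import build_isotherm

    out = {}
    for name, group in load_isotherm_table().groupby("system", sort=False):
        out[str(name)] = build_isotherm(
            group["host_conc_mM"].to_numpy(),
            group["absorbance"].to_numpy(),
            rutin_calibration,
        )
    return out


@pytest.fixture(scope="session")
def brownian_500():
    """The seeded 500-particle, 1000-step free-diffusion fixture (D = 0.1)."""
    from hostguest.synthetic import BrownianSpec, brownian_trajectory

    return brownian_trajectory(
        BrownianSpec(n_particles=500, diffusion=0.1, dt=1.0, n_steps=1000,
                     box_edge=100.0, seed=42)
    )


def ols_oracle(x, y):
    """Closed-form OLS slope/intercept/r² via the sigma formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy, syy = (x * x).sum(), (x * y).sum(), (y * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r_num = n * sxy - sx * sy
    r_den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    r2 = (r_num / r_den) ** 2 if r_den > 0 else 0.0
    return slope, intercept, r2


def brute_force_hbonds(frame, criteria):
    """Plain-loop geometric hydrogen-bond enumeration (O(N²) oracle)."""
    from hostguest.trajectory import minimum_image_displacement

    def dist(i, j):
        d = minimum_image_displacement(frame.coordinates[i], frame.coordinates[j],
                                       frame.cell)
        return np.linalg.norm(d), d

    bonds = set()
    n = frame.n_atoms
    for h in range(n):
        if frame.atoms[h].element != "H":
            continue
        donor, best = None, np.inf
        for d in range(n):
            if frame.atoms[d].element not in criteria.donor_elements:
                continue
            r, _ = dist(h, d)
            if r < best:
                donor, best = d, r
        if donor is None or best > 1.2:
            continue
        for a in range(n):
            if a == donor or frame.atoms[a].element not in criteria.acceptor_elements:
                continue
            r_ha, v_ha = dist(h, a)
            if r_ha == 0 or r_ha > criteria.max_h_acceptor_distance:
                continue
            _, v_hd = dist(h, donor)
            cosang = np.dot(v_hd, v_ha) / (np.linalg.norm(v_hd) * np.linalg.norm(v_ha))
            angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if angle >= criteria.min_dha_angle:
                bonds.add((donor, h, a))
    return bonds


def brute_force_pairwise(frame, params, indices):
    """Plain-loop nonbonded energy over unique pairs (oracle)."""
    from hostguest.trajectory import minimum_image_displacement

    total = 0.0
    idx = list(indices)
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            ai, aj = frame.atoms[idx[i]], frame.atoms[idx[j]]
            d = minimum_image_displacement(frame.coordinates[idx[i]],
                                           frame.coordinates[idx[j]], frame.cell)
            r = float(np.linalg.norm(d))
            if r > params.cutoff:
                continue
            ei, si = params.lj.get(ai.element, (0.0, 1.0))
            ej, sj = params.lj.get(aj.element, (0.0, 1.0))
            eps = np.sqrt(ei * ej)
            sig = (si + sj) / 2
            sr6 = (sig / r) ** 6
            total += 4 * eps * (sr6**2 - sr6)
            total += params.coulomb_constant * ai.partial_charge * aj.partial_charge / r
    return total
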