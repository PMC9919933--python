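"""Binding energy, nonbonded pairs, solubility parameters, H-bond typing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import brute_force_pairwise
from hostguest.datasets import load_atom_class_table, load_solubility_parameters
from hostguest.descriptors import HBondCriteria, classify_interaction, detect_hbonds
from hostguest.energetics import (
    AtomClass,
    AtomClassTable,
    NonbondedParams,
    assign_hbond_type,
    binding_energy,
    binding_energy_from_table,
    compatibility,
    cross_pair_energy,
    enumerate_hbond_types,
    pairwise_energy,
    rdf_per_type,
    solubility_parameter,
)
from hostguest.errors import DomainError, InvalidInputError
from hostguest.synthetic import hbond_fixture, two_cluster_system
from hostguest.trajectory import AtomRecord, Frame, PeriodicCell, Trajectory


class TestBindingEnergy:
    @pytest.mark.parametrize("e_total,e_guest,e_host,expected", [
        (-100.0, -30.0, -50.0, 20.0),
        (0.0, 0.0, 0.0, 0.0),
    ])
    def test_arithmetic(self, e_total, e_guest, e_host, expected):
        assert binding_energy(e_total, e_guest, e_host).e_binding == expected

    @given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
    def test_noninteracting_composition_is_zero(self, a, b):
        assert binding_energy(a + b, a, b).e_binding == pytest.approx(0.0, abs=1e-8)

    def test_equals_cross_pair_sum_on_toy_system(self):
        system = two_cluster_system(12, 9, separation=5.0, seed=7)
        c = system.components
        from_totals = binding_energy(c.e_total, c.e_guest, c.e_host).e_binding
        assert from_totals == pytest.approx(-system.cross_energy, rel=1e-10)

    def test_far_clusters_do_not_bind(self):
        system = two_cluster_system(5, 5, separation=100.0, seed=1)
        assert system.components.e_binding == 0.0

    def test_trailing_window_mean(self):
        energies = {
            "total": np.array([0.0, 0.0, -10.0, -10.0]),
            "guest": np.array([0.0, 0.0, -2.0, -4.0]),
            "host": np.array([0.0, 0.0, -4.0, -2.0]),
        }
        comp = binding_energy_from_table(energies, window=2)
        assert comp.e_total == -10.0
        assert comp.e_binding == pytest.approx(-(-10.0 - (-3.0) - (-3.0)))

    def test_missing_component_rejected(self):
        with pytest.raises(InvalidInputError):
            binding_energy_from_table({"total": np.zeros(3)})


class TestPairwiseEnergy:
    def test_lj_zero_crossing(self):
        params = NonbondedParams(lj={"Ar": (0.3, 3.0)})
        atoms = [AtomRecord(0, "Ar"), AtomRecord(1, "Ar")]
        frame = Frame(atoms, np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        assert pairwise_energy(frame, params) == pytest.approx(0.0, abs=1e-12)

    def test_coulomb_arithmetic(self):
        params = NonbondedParams(lj={})
        atoms = [AtomRecord(0, "X", partial_charge=1.0),
                 AtomRecord(1, "X", partial_charge=-1.0)]
        frame = Frame(atoms, np.array([[0.0, 0, 0], [3.320637, 0, 0]]))
        assert pairwise_energy(frame, params) == pytest.approx(-100.0, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        atoms = [AtomRecord(i, "C", partial_charge=float(rng.uniform(-0.5, 0.5)))
                 for i in range(n)]
        coords = rng.uniform(0, 12, size=(n, 3))
        frame = Frame(atoms, coords, cell=PeriodicCell.cubic(25.0))
        params = NonbondedParams(lj={"C": (0.1, 3.4)}, cutoff=8.0)
        ours = pairwise_energy(frame, params)
        oracle = brute_force_pairwise(frame, params, range(n))
        assert ours == pytest.approx(oracle, rel=1e-10)

    def test_coincident_atoms_rejected(self):
        atoms = [AtomRecord(0, "C"), AtomRecord(1, "C")]
        frame = Frame(atoms, np.zeros((2, 3)))
        with pytest.raises(DomainError):
            pairwise_energy(frame, NonbondedParams(lj={"C": (0.1, 3.4)}))

    def test_charge_scaling_is_bilinear(self):
        base = two_cluster_system(6, 6, 5.0, seed=3,
                                  params=NonbondedParams(lj={}), charge_magnitude=0.2)
        doubled = two_cluster_system(6, 6, 5.0, seed=3,
                                     params=NonbondedParams(lj={}), charge_magnitude=0.4)
        assert doubled.cross_energy == pytest.approx(4 * base.cross_energy, rel=1e-10)


class TestSolubilityParameter:
    def test_rutin_delta_from_ced(self):
        res = solubility_parameter(cohesive_energy=160.0225, molar_volume=1.0)
        assert res.delta == pytest.approx(12.650, abs=1e-3)

    def test_zero_energy(self):
        assert solubility_parameter(cohesive_energy=0.0, molar_volume=10.0).delta == 0.0

    def test_enthalpy_path(self):
        res = solubility_parameter(heat_of_vaporization=10_000.0, temperature=298.0,
                                   molar_volume=100.0)
        assert res.cohesive_energy == pytest.approx(10_000.0 - 1.9872 * 298.0)
        assert res.delta == pytest.approx(9.699, abs=1e-3)

    @given(st.floats(1.0, 1e6), st.floats(0.1, 1e4))
    def test_reconstructs_inputs(self, de, v):
        res = solubility_parameter(cohesive_energy=de, molar_volume=v)
        assert res.delta**2 * v == pytest.approx(de, rel=1e-9)

    @given(st.floats(1.0, 1e5), st.floats(1.0, 1e3), st.floats(1.1, 5.0))
    def test_monotonicity(self, de, v, f):
        base = solubility_parameter(cohesive_energy=de, molar_volume=v).delta
        assert solubility_parameter(cohesive_energy=de * f, molar_volume=v).delta > base
        assert solubility_parameter(cohesive_energy=de, molar_volume=v * f).delta < base

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            solubility_parameter(cohesive_energy=-5.0, molar_volume=10.0)
        with pytest.raises(DomainError):
            solubility_parameter(cohesive_energy=5.0, molar_volume=0.0)
        with pytest.raises(InvalidInputError):
            solubility_parameter(molar_volume=10.0)


class TestCompatibility:
    @pytest.mark.parametrize("da,db,diff,category", [
        (12.650, 12.422, 0.228, "compatible"),
        (12.650, 10.677, 1.973, "may_be_compatible"),
        (12.650, 9.658, 2.992, "may_be_compatible"),
        (10.0, 4.0, 6.0, "incompatible"),
        (5.0, 1.0, 4.0, "indeterminate"),
    ])
    def test_examples(self, da, db, diff, category):
        v = compatibility(da, db)
        assert v.difference == pytest.approx(diff, abs=1e-9)
        assert v.category == category

    @pytest.mark.parametrize("diff,category", [
        (1.0, "may_be_compatible"), (3.4, "may_be_compatible"),
        (4.9, "indeterminate"), (0.999999, "compatible"), (4.900001, "incompatible"),
    ])
    def test_boundaries_deterministic(self, diff, category):
        assert compatibility(diff, 0.0).category == category

    @given(st.floats(0, 50), st.floats(0, 50))
    def test_partitions_and_symmetric(self, a, b):
        v = compatibility(a, b)
        assert v.category in {"compatible", "may_be_compatible",
                              "indeterminate", "incompatible"}
        assert v.category == compatibility(b, a).category

    def test_all_packaged_pairs(self):
        deltas = load_solubility_parameters()
        for host in ("beta-CD", "HP-beta-CD", "DM-beta-CD"):
            v = compatibility(deltas["rutin"], deltas[host])
            assert v.category in ("compatible", "may_be_compatible")


class TestTypeEnumeration:
    def test_packaged_table_yields_eight_types(self):
        catalogue = enumerate_hbond_types(load_atom_class_table())
        assert catalogue.entries == (
            ("A", "O1", "H2"), ("B", "O2", "H2"), ("C", "O3", "H2"),
            ("D", "O4", "H2"), ("E", "O5", "H2"), ("F", "O6", "H2"),
            ("G", "O7", "H1"), ("H", "O8", "H1"),
        )

    def test_one_sided_catalogue(self):
        table = AtomClassTable(entries=(
            AtomClass("O1", "guest", -0.5, "acceptor"),
            AtomClass("O2", "guest", -0.4, "acceptor"),
            AtomClass("H2", "host", 0.4, "donorH"),
        ))
        catalogue = enumerate_hbond_types(table)
        assert catalogue.entries == (("A", "O1", "H2"), ("B", "O2", "H2"))

    def test_empty_table(self):
        assert enumerate_hbond_types(AtomClassTable(entries=())).entries == ()

    @given(st.integers(0, 6), st.integers(0, 3), st.integers(0, 2), st.integers(0, 2))
    def test_count_formula(self, ga, ha, gd, hd):
        entries = []
        for i in range(ga):
            entries.append(AtomClass(f"GA{i}", "guest", -0.3, "acceptor"))
        for i in range(ha):
            entries.append(AtomClass(f"HA{i}", "host", -0.3, "acceptor"))
        for i in range(gd):
            entries.append(AtomClass(f"GD{i}", "guest", 0.3, "donorH"))
        for i in range(hd):
            entries.append(AtomClass(f"HD{i}", "host", 0.3, "donorH"))
        catalogue = enumerate_hbond_types(AtomClassTable(entries=tuple(entries)))
        assert len(catalogue.entries) == ga * hd + ha * gd

    def test_charge_sign_conventions_enforced(self):
        with pytest.raises(InvalidInputError):
            AtomClass("O1", "guest", 0.2, "acceptor")
        with pytest.raises(InvalidInputError):
            AtomClass("H1", "guest", -0.2, "donorH")


class TestTypeAssignment:
    def test_planted_o1_h2_bonds_are_type_a(self):
        frame, truth = hbond_fixture(4, decoys=6, box_edge=56.0, seed=9)
        catalogue = enumerate_hbond_types(load_atom_class_table())
        records = detect_hbonds(frame)
        assert records
        for rec in records:
            assert assign_hbond_type(rec, frame, catalogue) == "A"

    def test_intramolecular_untyped(self):
        frame, _ = hbond_fixture(1, box_edge=45.0, seed=0)
        (rec,) = detect_hbonds(frame)
        fake = type(rec)(donor=rec.donor, hydrogen=rec.hydrogen, acceptor=rec.acceptor,
                         distance=rec.distance, angle=rec.angle, frame=0,
                         intra_or_inter="intramolecular")
        catalogue = enumerate_hbond_types(load_atom_class_table())
        assert assign_hbond_type(fake, frame, catalogue) == "untyped"

    def test_unknown_class_untyped(self):
        frame, _ = hbond_fixture(1, box_edge=45.0, seed=1, acceptor_class="O6",
                                 donor_h_class="H1", donor_o_class="O1")
        # guest donor H1 with guest acceptor O6 never appears in the catalogue
        (rec,) = detect_hbonds(frame)
        catalogue = enumerate_hbond_types(load_atom_class_table())
        assert assign_hbond_type(rec, frame, catalogue) == "untyped"


class TestPerTypeRDF:
    def test_constructed_contact_peaks_in_its_band(self):
        frame, _ = hbond_fixture(1, box_edge=45.0, seed=4)
        catalogue = enumerate_hbond_types(load_atom_class_table())
        curves = rdf_per_type(Trajectory(frames=[frame]), catalogue, dr=0.1)
        assert set(curves) == {"A"}
        rdf = curves["A"]
        peak_r = rdf.bin_centers[int(np.argmax(rdf.g_of_r))]
        # planted H...A distances lie in [1.8, 2.9] Å
        assert 1.8 - 0.1 <= peak_r <= 2.9 + 0.1

    def test_empty_catalogue_empty_map(self):
        frame, _ = hbond_fixture(1, box_edge=45.0, seed=4)
        from hostguest.energetics import HBondTypeCatalogue
        assert rdf_per_type(Trajectory(frames=[frame]),
                            HBondTypeCatalogue(entries=())) == {}

    def test_known_distances_per_type(self):
        # two planted contact types at distinct constructed distances
        frame_a, truth_a = hbond_fixture(3, box_edge=45.0, seed=12,
                                         acceptor_class="O2")
        catalogue = enumerate_hbond_types(load_atom_class_table())
        curves = rdf_per_type(Trajectory(frames=[frame_a]), catalogue, dr=0.05)
        assert set(curves) == {"B"}
        peak_r = curves["B"].bin_centers[int(np.argmax(curves["B"].g_of_r))]
        dists = [np.linalg.norm(frame_a.coordinates[h] - frame_a.coordinates[a])
                 for _, h, a in truth_a]
        assert min(dists) - 0.05 <= peak_r <= max(dists) + 0.05
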