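"""Spot values and edge cases for every descriptor family."""

import math

import pytest

from topodesc import Calculator, MissingReason, from_smiles, is_missing, read_molecules
from topodesc.synthetic import GraphRecipe, generate


def value(family, mol, name):
    return Calculator(family)(mol)[name]


def skeleton(kind, n, seed=0):
    return generate(GraphRecipe(kind=kind, n=n, seed=seed))


class TestAtomCount:
    def test_ethanol(self, ethanol):
        res = Calculator("AtomCount")(ethanol)
        assert res["nAtom"] == 9
        assert res["nHeavyAtom"] == 3
        assert res["nC"] == 2
        assert res["nO"] == 1
        assert res["nH"] == 6

    def test_benzene(self, benzene):
        res = Calculator("AtomCount")(benzene)
        assert res["nC"] == 6
        assert res["nH"] == 6
        assert res["nX"] == 0

    def test_chlorobenzene_halogens(self):
        res = Calculator("AtomCount")(from_smiles("c1ccccc1Cl"))
        assert res["nCl"] == 1
        assert res["nX"] == 1

    def test_spiro_and_bridgehead(self):
        spiro = Calculator("AtomCount")(from_smiles("C1CCC2(CC1)CCCC2"))
        assert spiro["nSpiro"] == 1
        assert spiro["nBridgehead"] == 0
        norbornane = Calculator("AtomCount")(from_smiles("C1CC2CCC1C2"))
        assert norbornane["nBridgehead"] == 2
        assert norbornane["nSpiro"] == 0

    def test_counts_additive_over_fragments(self):
        mol = read_molecules("CC.CC", format="smiles")[0]
        res = Calculator("AtomCount")(mol)
        assert res["nC"] == 4
        assert res["nHeavyAtom"] == 4


class TestZagreb:
    def test_methylbutane(self, methylbutane):
        res = Calculator("ZagrebIndex")(methylbutane)
        assert res["Zagreb1"] == 16
        assert res["Zagreb2"] == 14
        assert res["mZagreb2"] == pytest.approx(4.0 / 3.0, abs=1e-15)

    def test_single_atom(self):
        res = Calculator("ZagrebIndex")(from_smiles("C"))
        assert res["Zagreb1"] == 0
        assert res["Zagreb2"] == 0

    def test_additive_over_fragments(self):
        one = Calculator("ZagrebIndex")(from_smiles("CCC"))
        two = Calculator("ZagrebIndex")(read_molecules("CCC.CCC", format="smiles")[0])
        assert two["Zagreb1"] == 2 * one["Zagreb1"]
        assert two["Zagreb2"] == 2 * one["Zagreb2"]


class TestWiener:
    def test_methylbutane(self, methylbutane):
        res = Calculator("WienerIndex")(methylbutane)
        assert res["WPath"] == 18
        assert res["WPol"] == 2

    def test_cyclohexane(self, cyclohexane):
        assert value("WienerIndex", cyclohexane, "WPath") == 27

    def test_two_atoms(self):
        res = Calculator("WienerIndex")(from_smiles("CC"))
        assert res["WPath"] == 1
        assert res["WPol"] == 0


class TestBalabanJ:
    def test_cyclohexane_exactly_two(self, cyclohexane):
        assert value("BalabanJ", cyclohexane, "BalabanJ") == pytest.approx(2.0, abs=1e-12)

    def test_butane(self):
        # distance row sums (6,4,4,6); J = 3 * (2/sqrt(24) + 1/4)
        j = value("BalabanJ", from_smiles("CCCC"), "BalabanJ")
        assert j == pytest.approx(1.9747, abs=1e-4)

    def test_two_atoms_forced_value(self):
        assert value("BalabanJ", from_smiles("CC"), "BalabanJ") == pytest.approx(1.0)

    def test_single_atom_missing(self):
        v = value("BalabanJ", from_smiles("C"), "BalabanJ")
        assert is_missing(v) and v.reason is MissingReason.empty_graph


class TestChi:
    def test_propane_path1_simple(self):
        v = value("Chi", from_smiles("CCC"), "Xp-1d")
        assert v == pytest.approx(math.sqrt(2.0), abs=1e-12)

    def test_isobutane_path0_simple(self, isobutane):
        v = value("Chi", isobutane, "Xp-0d")
        assert v == pytest.approx(3.0 + 3.0 ** -0.5, abs=1e-12)

    def test_acyclic_chain_class_zero(self, methylbutane):
        res = Calculator("Chi")(methylbutane)
        for order in range(3, 8):
            assert res[f"Xch-{order}d"] == 0.0

    def test_averaged_with_no_subgraphs_missing(self):
        # ethane has no order-2 paths: averaged variant divides by zero
        res = Calculator("Chi")(from_smiles("CC"))
        v = res["AXp-2d"]
        assert is_missing(v) and v.reason is MissingReason.divide_by_zero
        assert res["Xp-2d"] == 0.0

    def test_valence_delta_oxygen(self, ethanol):
        # ethanol deltas: C(1), C(2), O(1); valence deltas: 1, 2, 5
        v = value("Chi", ethanol, "Xp-0dv")
        assert v == pytest.approx(1.0 + 2 ** -0.5 + 5 ** -0.5, abs=1e-12)


class TestKappa:
    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_linear_chain_kappa1_equals_atom_count(self, n):
        assert value("KappaShapeIndex", skeleton("path", n), "Kier1") == pytest.approx(n)

    def test_pentane_kappa2(self):
        assert value("KappaShapeIndex", from_smiles("CCCCC"), "Kier2") == pytest.approx(4.0)

    def test_cyclohexane_kappa1(self, cyclohexane):
        assert value("KappaShapeIndex", cyclohexane, "Kier1") == pytest.approx(6 * 25 / 36)

    def test_too_small_missing(self):
        res = Calculator("KappaShapeIndex")(from_smiles("CC"))
        assert all(is_missing(v) for v in res)


class TestEccentricConnectivity:
    def test_cyclohexane(self, cyclohexane):
        assert value("EccentricConnectivityIndex", cyclohexane, "ECIndex") == 36

    def test_methylbutane(self, methylbutane):
        assert value("EccentricConnectivityIndex", methylbutane, "ECIndex") == 19

    def test_two_atoms(self):
        assert value("EccentricConnectivityIndex", from_smiles("CC"), "ECIndex") == 2


class TestRingCount:
    def test_benzene(self, benzene):
        res = Calculator("RingCount")(benzene)
        assert res["n6Ring"] == 1
        assert sum(res.values()) == 1

    def test_naphthalene_two_six_rings(self):
        res = Calculator("RingCount")(from_smiles("c1ccc2ccccc2c1"))
        assert res["n6Ring"] == 2

    def test_acyclic_all_zero(self):
        res = Calculator("RingCount")(from_smiles("CCCCCC"))
        assert all(v == 0 for v in res)


class TestFramework:
    def test_benzene_full_framework(self, benzene):
        assert value("Framework", benzene, "fMF") == 1.0

    def test_hexane_pruned_to_nothing(self):
        assert value("Framework", from_smiles("CCCCCC"), "fMF") == 0.0

    def test_toluene(self):
        assert value("Framework", from_smiles("Cc1ccccc1"), "fMF") == pytest.approx(6 / 7)


class TestMolecularId:
    def test_single_atom(self):
        assert value("MolecularId", from_smiles("C"), "MID") == pytest.approx(1.0)

    def test_ethane(self):
        assert value("MolecularId", from_smiles("CC"), "MID") == pytest.approx(3.0)

    def test_subset_sums_bounded_by_total(self, ethanol):
        res = Calculator("MolecularId")(ethanol)
        assert res["MID_C"] + res["MID_O"] == pytest.approx(res["MID"])
        assert res["MID_N"] == 0.0
        assert res["AMID"] == pytest.approx(res["MID"] / 3.0)


class TestABC:
    def test_cyclohexane(self, cyclohexane):
        assert value("ABCIndex", cyclohexane, "ABC") == pytest.approx(6 * math.sqrt(0.5))

    def test_two_atoms_forced_zero(self):
        assert value("ABCIndex", from_smiles("CC"), "ABC") == 0.0

    def test_path3(self):
        assert value("ABCIndex", from_smiles("CCC"), "ABC") == pytest.approx(math.sqrt(2.0))

    def test_abcgg_cyclohexane(self, cyclohexane):
        # each bond splits the remaining atoms evenly: n_u = n_v = 3
        assert value("ABCIndex", cyclohexane, "ABCGG") == pytest.approx(6 * 2 / 3)


class TestDetourFamily:
    def test_detour_index_values(self, cyclopentane, cyclohexane):
        assert value("DetourMatrix", cyclopentane, "DetourIndex") == 35
        assert value("DetourMatrix", cyclohexane, "DetourIndex") == 63

    def test_tree_equals_distance_family(self, methylbutane):
        det = Calculator("DetourMatrix")(methylbutane)
        dist = Calculator("DistanceMatrix")(methylbutane)
        for agg in ("SpAbs", "SpMax", "LogEE", "VE1", "VR1"):
            assert det[f"{agg}_Dt"] == pytest.approx(dist[f"{agg}_D"], rel=1e-12)

    def test_disconnected_missing(self):
        mol = read_molecules("CC.CC", format="smiles")[0]
        res = Calculator("DetourMatrix")(mol)
        assert all(is_missing(v) for v in res)
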