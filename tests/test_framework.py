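"""Descriptor/Calculator framework: registry, caching, missing values,
arithmetic, result views and parallel mapping."""

import math
import pickle

import numpy as np
import pytest

from topodesc import (
    Calculator,
    MissingReason,
    MissingValue,
    from_smiles,
    is_missing,
    preset,
    read_molecules,
)


class TestRegistry:
    def test_wiener_preset_two_entries(self):
        calc = Calculator("WienerIndex")
        assert calc.descriptor_names == ["WPath", "WPol"]

    def test_chi_preset_56_entries(self):
        assert len(Calculator("Chi")) == 56

    def test_duplicate_registration_rejected(self):
        calc = Calculator("WienerIndex")
        with pytest.raises(ValueError, match="duplicate"):
            calc.register("WienerIndex")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            preset("Autocorrelation")

    def test_registration_order_preserved(self):
        calc = Calculator()
        calc.register("ZagrebIndex").register("WienerIndex")
        assert calc.descriptor_names == [
            "Zagreb1", "Zagreb2", "mZagreb1", "mZagreb2", "WPath", "WPol",
        ]

    def test_ring_count_extension(self):
        assert len(preset("RingCount")) == 10
        extended = preset("RingCount", max_n=16)
        assert len(extended) == 14
        assert extended[-1].name == "n16Ring"


class TestCalculate:
    def test_result_length_equals_registered(self, ethanol):
        calc = Calculator("all")
        res = calc(ethanol)
        assert len(res) == len(calc)
        assert res.names == tuple(calc.descriptor_names)

    def test_single_atom_wiener(self):
        res = Calculator("WienerIndex")(from_smiles("C"))
        assert res["WPath"] == 0
        assert res["WPol"] == 0

    def test_disconnected_balaban_missing(self):
        mol = read_molecules("CC.CC", format="smiles")[0]
        res = Calculator("BalabanJ")(mol)
        v = res["BalabanJ"]
        assert is_missing(v)
        assert v.reason is MissingReason.disconnected

    def test_zagreb_methylbutane(self, methylbutane):
        res = Calculator("ZagrebIndex")(methylbutane)
        assert res["Zagreb1"] == 16
        assert res["Zagreb2"] == 14

    def test_no_exception_escapes(self):
        from topodesc.core import Descriptor

        class Bomb(Descriptor):
            family = "Test"
            name = "Bomb"

            def compute(self, mol, ctx):
                raise RuntimeError("boom")

        res = Calculator([Bomb()])(from_smiles("CC"))
        v = res["Bomb"]
        assert is_missing(v)
        assert v.reason is MissingReason.dependency_failure

    def test_strict_mode_raises(self):
        mol = read_molecules("CC.CC", format="smiles")[0]
        with pytest.raises(RuntimeError, match="disconnected"):
            Calculator("BalabanJ", strict=True)(mol)

    def test_cache_transparency(self, cyclohexane, methylbutane):
        on = Calculator("all", use_cache=True)
        off = Calculator("all", use_cache=False)
        for mol in (cyclohexane, methylbutane):
            a, b = on(mol), off(mol)
            for (na, va), (nb, vb) in zip(a.items(), b.items()):
                assert na == nb
                if is_missing(va):
                    assert is_missing(vb) and va.reason == vb.reason
                else:
                    assert va == vb, na


class TestResultViews:
    @pytest.fixture()
    def mixed_result(self):
        mol = read_molecules("CC.CC", format="smiles")[0]
        return Calculator(["ZagrebIndex", "BalabanJ"])(mol)

    def test_fill_missing(self, mixed_result):
        filled = mixed_result.fill_missing(-999.0)
        assert len(filled) == 5
        assert filled["BalabanJ"] == -999.0

    def test_fill_missing_default_nan(self, mixed_result):
        assert math.isnan(mixed_result.fill_missing()["BalabanJ"])

    def test_drop_missing(self, mixed_result):
        dropped = mixed_result.drop_missing()
        assert len(dropped) == 4
        assert "BalabanJ" not in dropped.names

    def test_drop_without_missing_is_identity(self, ethanol):
        res = Calculator("ZagrebIndex")(ethanol)
        assert res.drop_missing().asdict() == res.asdict()

    def test_asdict_preserves_order(self, mixed_result):
        assert list(mixed_result.asdict()) == list(mixed_result.names)


class TestArithmetic:
    def test_product_term(self, methylbutane):
        z1, z2 = preset("ZagrebIndex")[:2]
        prod = z1 * z2
        res = Calculator([prod])(methylbutane)
        assert res[prod.name] == 224

    def test_self_cancellation(self, ethanol, cyclohexane):
        z1 = preset("ZagrebIndex")[0]
        diff = z1 - z1
        for mol in (ethanol, cyclohexane):
            assert Calculator([diff])(mol)[diff.name] == 0.0

    def test_missing_operand_propagates(self):
        j = preset("BalabanJ")[0]
        z1 = preset("ZagrebIndex")[0]
        combo = j / z1
        mol = read_molecules("CC.CC", format="smiles")[0]
        v = Calculator([combo])(mol)[combo.name]
        assert is_missing(v)
        assert v.reason is MissingReason.dependency_failure

    def test_division_by_zero(self, ethanol):
        z1 = preset("ZagrebIndex")[0]
        combo = z1 / (z1 - z1)
        v = Calculator([combo])(ethanol)[combo.name]
        assert is_missing(v)
        assert v.reason is MissingReason.divide_by_zero

    def test_constants_and_negation(self, ethanol):
        z1 = preset("ZagrebIndex")[0]
        calc = Calculator([2 * z1, -z1, z1 ** 2])
        res = calc(ethanol)
        base = Calculator([z1])(ethanol)[z1.name]
        assert res[(2 * z1).name] == 2 * base
        assert res[(-z1).name] == -base
        assert res[(z1 ** 2).name] == base ** 2


class TestParallelMap:
    SMILES = ["CCO", "c1ccccc1", "CC(C)CC", "C1CCCCC1", "CCCCCC",
              "CC(=O)O", "c1ccc2ccccc2c1", "CC(C)(C)C", "C1CCC1", "CCN"]

    def test_parallel_matches_serial(self):
        mols = [from_smiles(s) for s in self.SMILES]
        calc = Calculator(["WienerIndex", "ZagrebIndex", "Chi"])
        serial = calc.map(mols, processes=1)
        for p in (2, 3, 4):
            par = calc.map(mols, processes=p)
            for a, b in zip(serial, par):
                assert a.asdict() == b.asdict()

    def test_empty_batch(self):
        assert Calculator("WienerIndex").map([]) == []

    def test_bad_record_contained(self):
        mols = read_molecules("CCO\nC1CC bad\nCCC", format="smiles")
        calc = Calculator("ZagrebIndex")
        out = calc.map(mols, processes=2)
        assert len(out) == 3
        assert not out[0].missing() and not out[2].missing()
        assert all(
            is_missing(v) and v.reason is MissingReason.parse_failure
            for v in out[1]
        )

    def test_calculator_picklable(self):
        calc = Calculator("all")
        _ = calc.registered
        clone = pickle.loads(pickle.dumps(calc))
        assert clone.descriptor_names == calc.descriptor_names


class TestSklearnSurface:
    def test_transform_shape_and_names(self):
        mols = [from_smiles(s) for s in ("CCO", "CCC")]
        calc = Calculator(["WienerIndex", "ZagrebIndex"])
        X = calc.fit(mols).transform(mols)
        assert X.shape == (2, 6)
        assert list(calc.get_feature_names_out()) == calc.descriptor_names

    def test_missing_encoded_as_nan(self):
        mols = read_molecules("CC.CC\nCCO", format="smiles")
        X = Calculator("BalabanJ").fit(mols).transform(mols)
        assert np.isnan(X[0, 0]) and np.isfinite(X[1, 0])

    def test_pipeline_composition(self):
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        mols = [from_smiles(s) for s in ("CCO", "CCC", "CCCC", "CC(C)C")]
        pipe = make_pipeline(Calculator("ZagrebIndex"), StandardScaler())
        out = pipe.fit_transform(mols)
        assert out.shape == (4, 4)

    def test_get_set_params_roundtrip(self):
        calc = Calculator("ZagrebIndex", n_jobs=2)
        params = calc.get_params()
        assert params["n_jobs"] == 2
        calc.set_params(n_jobs=1)
        assert calc.n_jobs == 1
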