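"""Diet-composition arithmetic: normalization, energy correction, probit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtri

from ursatroph.diet import (ConfigurationError, DietDataset,
                            InvalidComposition, default_categories,
                            energy_contribution, normalize_frequencies,
                            probit_compress, probit_decompress,
                            read_diet_table, write_diet_table)


class TestNormalizeFrequencies:
    @pytest.mark.parametrize("counts,expected", [
        ({"berries": 4}, {"berries": 1.0}),
        ({"a": 2, "b": 2}, {"a": 0.5, "b": 0.5}),
        ({"a": 3, "b": 1, "c": 4}, {"a": 0.375, "b": 0.125, "c": 0.5}),
    ])
    def test_examples(self, counts, expected):
        out = normalize_frequencies(counts)
        assert out.to_dict() == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidComposition):
            normalize_frequencies({"a": 0.0, "b": 0.0})

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=25).filter(
        lambda xs: sum(xs) > 0))
    def test_closure(self, xs):
        out = normalize_frequencies({f"c{i}": x for i, x in enumerate(xs)})
        assert abs(out.sum() - 1.0) < 1e-9
        assert (out[pd.Series(xs, index=out.index) == 0] == 0).all()


class TestEnergyContribution:
    def _cats(self, rows):
        return pd.DataFrame(rows, columns=["category", "trophic_class", "c_D",
                                           "c_E"]).set_index("category")

    def test_identity_factors_preserve_volumes(self):
        cats = self._cats([("a", "animal_vertebrate", 1, 1),
                           ("b", "plant", 1, 1)])
        ec = energy_contribution({"a": 0.5, "b": 0.5}, cats)
        assert ec.E.to_dict() == pytest.approx({"a": 0.5, "b": 0.5})
        assert ec.P == pytest.approx(0.5)

    def test_meat_grass_example(self):
        cats = self._cats([("meat", "animal_vertebrate", 0.9, 2.0),
                           ("grass", "plant", 0.3, 1.0)])
        ec = energy_contribution({"meat": 0.5, "grass": 0.5}, cats)
        assert ec.E["meat"] == pytest.approx(0.857143, abs=1e-6)
        assert ec.E["grass"] == pytest.approx(0.142857, abs=1e-6)
        assert ec.P == pytest.approx(0.857143, abs=1e-6)

    def test_absent_prey_gives_zero_share(self):
        cats = self._cats([("meat", "animal_vertebrate", 0.9, 2.0),
                           ("grass", "plant", 0.3, 1.0)])
        assert energy_contribution({"meat": 0.0, "grass": 1.0}, cats).P == 0.0

    def test_missing_factor_names_category(self):
        cats = self._cats([("meat", "animal_vertebrate", 0.9, 2.0)])
        with pytest.raises(ConfigurationError, match="grass"):
            energy_contribution({"meat": 0.5, "grass": 0.5}, cats)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.1, 10.0))
    def test_uniform_rescaling_invariance(self, k):
        base = self._cats([("a", "animal_invertebrate", 0.8, 1.2),
                           ("b", "plant", 0.4, 0.7),
                           ("c", "fungi", 0.5, 0.6)])
        scaled = base.copy()
        scaled["c_D"] = scaled["c_D"] * k
        v = {"a": 0.2, "b": 0.5, "c": 0.3}
        np.testing.assert_allclose(energy_contribution(v, base).E,
                                   energy_contribution(v, scaled).E,
                                   atol=1e-12)

    def test_relabeling_within_class_preserves_P(self):
        cats = self._cats([("a", "animal_vertebrate", 0.9, 1.5),
                           ("b", "animal_vertebrate", 0.9, 1.5),
                           ("p", "plant", 0.4, 0.8)])
        v1 = {"a": 0.3, "b": 0.1, "p": 0.6}
        v2 = {"a": 0.1, "b": 0.3, "p": 0.6}
        assert energy_contribution(v1, cats).P == \
            pytest.approx(energy_contribution(v2, cats).P)


class TestProbitCompression:
    def test_half_maps_to_zero(self):
        for n in (2, 50, 210):
            assert probit_compress(0.5, n) == pytest.approx(0.0, abs=1e-12)

    def test_zero_at_n210(self):
        # probit(0.5/210), the compressed image of P = 0
        assert probit_compress(0.0, 210) == pytest.approx(ndtri(0.5 / 210))
        assert probit_compress(0.0, 210) == pytest.approx(-2.82, abs=0.01)

    def test_large_n_limit(self):
        assert probit_compress(0.3, 10 ** 8) == pytest.approx(ndtri(0.3),
                                                              abs=1e-5)

    def test_monotone_and_open_interval(self):
        p = np.linspace(0, 1, 101)
        y = probit_compress(p, 210)
        assert np.all(np.diff(y) > 0)
        assert np.all(np.isfinite(y))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            probit_compress(1.2, 210)
        with pytest.raises(ValueError):
            probit_compress(0.5, 1)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0, 1), st.integers(2, 10 ** 6))
    def test_round_trip(self, p, n):
        assert probit_decompress(probit_compress(p, n), n) == \
            pytest.approx(p, abs=1e-12)


def _toy_rows(dataset_id, v_missing=False, f_scale=1.0):
    rows = []
    comp = [("fruits_fleshy", 0.5, 0.6), ("mammals_large", 0.3, 0.3),
            ("graminoids", 0.2, 0.1)]
    for cat, f, v in comp:
        rows.append({
            "dataset_id": dataset_id, "study_id": "s1",
            "species": "Ursus arctos", "lat": 45.0, "lon": 7.0,
            "sample_type": "scat", "n_samples": 50, "category": cat,
            "F": f * f_scale, "V": ("" if v_missing else v),
            "npp": 0.4, "gsl": 8, "co_occurrence": "none"})
    return rows


class TestDietTableIO:
    def test_round_trip(self, tmp_path, categories):
        path = tmp_path / "diet.csv"
        pd.DataFrame(_toy_rows("d1") + _toy_rows("d2") +
                     _toy_rows("d3")).to_csv(path, index=False)
        datasets = read_diet_table(path)
        assert len(datasets) == 3
        assert not datasets[0].needs_imputation
        out = tmp_path / "again.csv"
        write_diet_table(datasets, out)
        assert len(read_diet_table(out)) == 3

    def test_bad_sum_is_validation_error(self, tmp_path):
        path = tmp_path / "diet.csv"
        pd.DataFrame(_toy_rows("d1", f_scale=0.8)).to_csv(path, index=False)
        with pytest.raises(InvalidComposition, match="row"):
            read_diet_table(path)

    def test_blank_volumes_flag_imputation(self, tmp_path):
        path = tmp_path / "diet.csv"
        pd.DataFrame(_toy_rows("d1", v_missing=True)).to_csv(path, index=False)
        (ds,) = read_diet_table(path)
        assert ds.needs_imputation

    def test_workbook_reader_maps_columns(self, tmp_path):
        pytest.importorskip("openpyxl")
        from ursatroph.diet import read_diet_workbook

        df = pd.DataFrame(_toy_rows("d1")).rename(columns={"F": "RFO"})
        xlsx = tmp_path / "deposited.xlsx"
        df.to_excel(xlsx, index=False)
        (ds,) = read_diet_workbook(xlsx, column_map={"RFO": "F"})
        assert ds.dataset_id == "d1"


def test_dataset_invariants_enforced():
    items = pd.DataFrame({"F": [0.6, 0.6], "V": [np.nan, np.nan]},
                         index=pd.Index(["a", "b"], name="category"))
    with pytest.raises(InvalidComposition):
        DietDataset(dataset_id="x", study_id="s", species="Ursus arctos",
                    lat=0, lon=0, sample_type="scat", n_samples=5,
                    items=items, npp=0.5, gsl=6, co_occurrence="none")


def test_default_category_scheme_is_complete(categories):
    assert len(categories) == 20
    assert (categories[["c_D", "c_E"]] > 0).all().all()
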