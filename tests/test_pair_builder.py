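import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specsim.chemstruct import SimilarityMatrix
from specsim.pair_builder import (
    BiasedSamplerConfig,
    FilterCriteria,
    biased_bin_edges,
    enumerate_pairs,
    pair_passes_filter,
    pairs_to_frame,
    read_epochs_hdf,
    read_test_pairs_parquet,
    sample_epochs,
    uniform_bin_edges,
    write_epochs_hdf,
    write_test_pairs_parquet,
)

from conftest import make_spectrum


def spec(sid, key, ce=20.0, adduct="[M+H]+", prec=500.0, ion="ESI", analyzer="Orbitrap"):
    return make_spectrum(
        sid, precursor_mz=prec, adduct=adduct, collision_energy=ce,
        ionization_method=ion, mass_analyzer=analyzer, structure_ref=key,
    )


def identity_matrix(keys):
    n = len(keys)
    v = np.eye(n) * 0.0 + np.full((n, n), 0.5)
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix(structure_ids=list(keys), values=v)


class TestPairFilter:
    def test_identical_metadata_passes(self):
        a, b = spec("a", "K1"), spec("b", "K2")
        ok, reason = pair_passes_filter(a, b, FilterCriteria())
        assert ok and reason is None

    @pytest.mark.parametrize("ce_b,expected", [(25.0, False), (24.9, True)])
    def test_ce_difference_strictly_below_5(self, ce_b, expected):
        # difference of exactly 5 eV fails; 4.9 passes
        a, b = spec("a", "K1", ce=20.0), spec("b", "K2", ce=ce_b)
        ok, _ = pair_passes_filter(a, b, FilterCriteria())
        assert ok is expected

    def test_missing_ce_skips_criterion_unless_strict(self):
        a, b = spec("a", "K1", ce=None), spec("b", "K2", ce=35.0)
        assert pair_passes_filter(a, b, FilterCriteria())[0]
        ok, reason = pair_passes_filter(a, b, FilterCriteria(ce_required=True))
        assert not ok and reason == "collision_energy_missing"

    def test_adduct_mismatch(self):
        a, b = spec("a", "K1"), spec("b", "K2", adduct="[M+Na]+")
        ok, reason = pair_passes_filter(a, b, FilterCriteria())
        assert not ok and reason == "adduct"

    @pytest.mark.parametrize("prec_b,expected", [(700.0, False), (699.9, True)])
    def test_precursor_difference_strictly_below_200(self, prec_b, expected):
        a, b = spec("a", "K1", prec=500.0), spec("b", "K2", prec=prec_b)
        assert pair_passes_filter(a, b, FilterCriteria())[0] is expected

    def test_missing_required_field_fails(self):
        a, b = spec("a", "K1", analyzer=None), spec("b", "K2")
        ok, reason = pair_passes_filter(a, b, FilterCriteria())
        assert not ok and reason == "analyzer_missing"


class TestEnumeratePairs:
    def test_ordered_count_n_times_n_minus_1(self):
        spectra = [spec(f"s{i}", f"K{i}") for i in range(3)]
        m = identity_matrix([f"K{i}" for i in range(3)])
        pairs = list(enumerate_pairs(spectra, m))
        assert len(pairs) == 6

    def test_unordered_half(self):
        spectra = [spec(f"s{i}", f"K{i}") for i in range(3)]
        m = identity_matrix([f"K{i}" for i in range(3)])
        pairs = list(enumerate_pairs(spectra, m, ordered=False))
        assert len(pairs) == 3
        assert all(p.spectrum_id_a < p.spectrum_id_b for p in pairs)

    def test_filtered_matches_brute_force_recount(self):
        spectra = [
            spec("s0", "K0"),
            spec("s1", "K1", adduct="[M+Na]+"),  # adduct mismatch vs others
            spec("s2", "K2", ce=26.0),           # CE too far from 20
            spec("s3", "K3"),
        ]
        m = identity_matrix([f"K{i}" for i in range(4)])
        crit = FilterCriteria()
        got = list(enumerate_pairs(spectra, m, crit))
        expected = sum(
            1
            for a, b in itertools.permutations(spectra, 2)
            if pair_passes_filter(a, b, crit)[0]
        )
        assert len(got) == expected

    def test_filtered_subset_of_all_pairs(self):
        spectra = [spec(f"s{i}", f"K{i}", ce=float(20 + 3 * i)) for i in range(5)]
        m = identity_matrix([f"K{i}" for i in range(5)])
        allp = {(p.spectrum_id_a, p.spectrum_id_b) for p in enumerate_pairs(spectra, m)}
        filt = {
            (p.spectrum_id_a, p.spectrum_id_b)
            for p in enumerate_pairs(spectra, m, FilterCriteria())
        }
        strict = {
            (p.spectrum_id_a, p.spectrum_id_b)
            for p in enumerate_pairs(spectra, m, FilterCriteria(ce_required=True))
        }
        assert strict <= filt <= allp

    def test_spectrum_without_structure_excluded(self):
        spectra = [spec("s0", "K0"), spec("s1", None)]
        m = identity_matrix(["K0"])
        assert list(enumerate_pairs(spectra, m)) == []

    def test_same_structure_pair_has_target_one(self):
        spectra = [spec("s0", "K0"), spec("s1", "K0")]
        m = identity_matrix(["K0"])
        pairs = list(enumerate_pairs(spectra, m))
        assert len(pairs) == 2
        assert all(p.target_similarity == 1.0 for p in pairs)


class TestBinEdges:
    def test_midpoint_closed_form(self):
        cfg = BiasedSamplerConfig(n_bins=20, edge_exponent=0.3)
        edges = biased_bin_edges(cfg)
        assert edges[10] == pytest.approx(0.5**0.3)
        assert edges[10] == pytest.approx(0.8122523963562356)
        assert edges[0] == 0.0 and edges[-1] == 1.0

    def test_exponent_one_is_uniform(self):
        cfg = BiasedSamplerConfig(n_bins=10, edge_exponent=1.0)
        assert np.allclose(biased_bin_edges(cfg), uniform_bin_edges(10))

    @settings(max_examples=30, deadline=None)
    @given(
        n_bins=st.integers(2, 50),
        exponent=st.floats(0.05, 1.0, allow_nan=False),
    )
    def test_strictly_increasing(self, n_bins, exponent):
        cfg = BiasedSamplerConfig(n_bins=n_bins, edge_exponent=exponent)
        edges = biased_bin_edges(cfg)
        assert np.all(np.diff(edges) > 0)


def uniform_pair_frame(n, n_keys=20, seed=0):
    rng = np.random.default_rng(seed)
    keys = [f"K{i:02d}" for i in range(n_keys)]
    return pd.DataFrame(
        {
            "spectrum_id_a": [f"a{i}" for i in range(n)],
            "spectrum_id_b": [f"b{i}" for i in range(n)],
            "inchikey14_a": rng.choice(keys, n),
            "inchikey14_b": rng.choice(keys, n),
            "target_similarity": rng.uniform(0, 1, n),
            "mean_tt_similarity": np.nan,
        }
    )


class TestSampleEpochs:
    def test_coverage_pass_only(self):
        df = uniform_pair_frame(500, n_keys=30, seed=2)
        keys = sorted(set(df["inchikey14_a"]) | set(df["inchikey14_b"]))
        cfg = BiasedSamplerConfig(pairs_per_epoch=len(keys), n_epochs=1, seed=0)
        [epoch] = sample_epochs(df, cfg, mode="biased20")
        assert len(epoch) == len(keys)
        covered = set(epoch["inchikey14_a"]) | set(epoch["inchikey14_b"])
        assert set(keys) <= covered

    def test_every_key_covered_each_epoch(self):
        df = uniform_pair_frame(2000, n_keys=15, seed=3)
        cfg = BiasedSamplerConfig(pairs_per_epoch=300, n_epochs=3, seed=1)
        for epoch in sample_epochs(df, cfg, mode="uniform10"):
            covered = set(epoch["inchikey14_a"]) | set(epoch["inchikey14_b"])
            keys = set(df["inchikey14_a"]) | set(df["inchikey14_b"])
            assert keys <= covered

    def test_biased_half_above_warped_midpoint(self):
        df = uniform_pair_frame(50_000, seed=4)
        cfg = BiasedSamplerConfig(pairs_per_epoch=20_000, n_epochs=1, seed=5)
        [epoch] = sample_epochs(df, cfg, mode="biased20")
        frac = (epoch["target_similarity"] > 0.5**0.3).mean()
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_uniform_tail_above_081(self):
        df = uniform_pair_frame(50_000, seed=4)
        cfg = BiasedSamplerConfig(pairs_per_epoch=20_000, n_epochs=1, seed=5)
        [epoch] = sample_epochs(df, cfg, mode="uniform10")
        frac = (epoch["target_similarity"] > 0.81).mean()
        assert frac == pytest.approx(0.19, abs=0.03)

    def test_seeded_determinism(self):
        df = uniform_pair_frame(1000, seed=6)
        cfg = BiasedSamplerConfig(pairs_per_epoch=200, n_epochs=2, seed=7)
        a = sample_epochs(df, cfg, mode="biased20")
        b = sample_epochs(df, cfg, mode="biased20")
        for ea, eb in zip(a, b):
            pd.testing.assert_frame_equal(ea, eb)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            sample_epochs(uniform_pair_frame(10), BiasedSamplerConfig(), mode="nope")


class TestPersistence:
    def test_epochs_hdf_roundtrip(self, tmp_path):
        df = uniform_pair_frame(50, seed=8)
        cfg = BiasedSamplerConfig(pairs_per_epoch=10, n_epochs=2, seed=9)
        epochs = sample_epochs(df, cfg, mode="uniform10")
        p = tmp_path / "epochs.h5"
        write_epochs_hdf(epochs, p)
        back = read_epochs_hdf(p)
        assert len(back) == 2
        for orig, rt in zip(epochs, back):
            pd.testing.assert_frame_equal(orig[rt.columns], rt)

    def test_zero_epochs_error(self, tmp_path):
        with pytest.raises(ValueError):
            write_epochs_hdf([], tmp_path / "x.h5")

    def test_refuses_existing_path(self, tmp_path):
        df = uniform_pair_frame(20, seed=1)
        p = tmp_path / "pairs.parquet"
        write_test_pairs_parquet(df, p)
        with pytest.raises(FileExistsError):
            write_test_pairs_parquet(df, p)
        write_test_pairs_parquet(df, p, overwrite=True)

    def test_parquet_roundtrip(self, tmp_path):
        df = uniform_pair_frame(20, seed=1)
        p = tmp_path / "pairs.parquet"
        write_test_pairs_parquet(df, p)
        back = read_test_pairs_parquet(p)
        pd.testing.assert_frame_equal(df[back.columns], back)
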