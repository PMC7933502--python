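import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import upper_triangle_pairs
from fmsc.core import (
    Connectome,
    FmscError,
    METRIC_NAMES,
    Parcellation,
    devectorize_upper_triangle,
    flat_index_to_pair,
    n_edge_features,
    pair_to_flat_index,
    read_connectome,
    read_morphometry,
    read_timeseries,
    vectorize_upper_triangle,
    write_connectome,
)


def random_correlation_like(rng, m):
    a = rng.uniform(-1, 1, size=(m, m))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestParcellation:
    def test_default_has_34_regions_from_17_networks_times_2_hemispheres(self):
        p = Parcellation.yeo17_two_hemisphere()
        assert len(p) == 34
        assert len(set(p.network_name)) == 17
        assert p.hemisphere.count("L") == p.hemisphere.count("R") == 17

    def test_rejects_duplicates_and_short_parcellations(self):
        with pytest.raises(FmscError):
            Parcellation(("a", "a"), ("L", "R"), ("x", "x"))
        with pytest.raises(FmscError):
            Parcellation(("a",), ("L",), ("x",))


class TestUpperTriangle:
    def test_feature_dimension_is_m_choose_2(self):
        assert n_edge_features(34) == 561
        rng = np.random.default_rng(0)
        for m in (2, 3, 10, 34):
            c = random_correlation_like(rng, m)
            assert vectorize_upper_triangle(c).shape == (m * (m - 1) // 2,)

    def test_single_off_diagonal(self):
        v = vectorize_upper_triangle(np.array([[1.0, 0.3], [0.3, 1.0]]))
        assert v.tolist() == [0.3]

    def test_row_major_ordering_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for m in (3, 5, 8):
            c = random_correlation_like(rng, m)
            v = vectorize_upper_triangle(c)
            expected = [c[i, j] for i, j in upper_triangle_pairs(m)]
            assert v.tolist() == expected

    def test_flat_index_pair_bijection_all_sizes(self):
        for m in range(2, 41):
            pairs = upper_triangle_pairs(m)
            for k, (i, j) in enumerate(pairs):
                assert flat_index_to_pair(k, m) == (i, j)
                assert pair_to_flat_index(i, j, m) == k

    def test_known_endpoints_for_34_regions(self):
        assert flat_index_to_pair(0, 34) == (0, 1)
        assert flat_index_to_pair(560, 34) == (32, 33)

    def test_out_of_range_and_asymmetric_inputs_rejected(self):
        with pytest.raises(FmscError):
            flat_index_to_pair(3, 3)
        with pytest.raises(FmscError):
            flat_index_to_pair(-1, 3)
        with pytest.raises(FmscError):
            vectorize_upper_triangle(np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(FmscError):
            vectorize_upper_triangle(np.zeros((2, 3)))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=2, max_value=40), st.integers(min_value=0, max_value=2**31))
    def test_vectorize_devectorize_identity(self, m, seed):
        rng = np.random.default_rng(seed)
        c = random_correlation_like(rng, m)
        v = vectorize_upper_triangle(c)
        assert np.array_equal(devectorize_upper_triangle(v, m), c)


class TestConnectomeInvariants:
    def test_rejects_asymmetry_bad_diagonal_and_out_of_range(self, rng):
        m = random_correlation_like(rng, 4)
        bad = m.copy()
        bad[0, 1] += 1e-6
        with pytest.raises(FmscError):
            Connectome(bad, tuple("abcd"), "FCN")
        bad = m.copy()
        bad[0, 0] = 0.5
        with pytest.raises(FmscError):
            Connectome(bad, tuple("abcd"), "MSN")
        bad = m.copy()
        bad[0, 1] = bad[1, 0] = 1.5
        with pytest.raises(FmscError):
            Connectome(bad, tuple("abcd"), "MSN")

    def test_adjacency_must_be_binary_with_zero_diagonal(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        with pytest.raises(FmscError):
            Connectome(a, tuple("abc"), "adjacency")
        a[0, 1] = a[1, 0] = 1.0
        Connectome(a, tuple("abc"), "adjacency")  # valid

    def test_rejects_nonfinite_values(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(FmscError):
            Connectome(m, tuple("abc"), "FCN")


class TestFileIO:
    def test_morphometry_roundtrip_and_reordering(self, tmp_path, parc34, rng):
        values = rng.normal(10, 2, size=(34, 8))
        df = pd.DataFrame(values, columns=list(METRIC_NAMES))
        df.insert(0, "region_id", list(parc34.region_ids))
        # shuffle rows: reader must restore parcellation order
        shuffled = df.sample(frac=1.0, random_state=0)
        path = tmp_path / "sub.csv"
        shuffled.to_csv(path, index=False)
        table = read_morphometry(path, parc34)
        assert table.values.shape == (34, 8)
        np.testing.assert_allclose(table.values, values)

    def test_missing_region_and_unknown_column_are_named(self, tmp_path, parc34, rng):
        df = pd.DataFrame(rng.normal(size=(34, 8)), columns=list(METRIC_NAMES))
        df.insert(0, "region_id", list(parc34.region_ids))
        dropped = df[df["region_id"] != "Limbic B (R)"]
        p = tmp_path / "missing.csv"
        dropped.to_csv(p, index=False)
        with pytest.raises(FmscError, match="Limbic B"):
            read_morphometry(p, parc34)
        bad = df.rename(columns={"FI": "foo"})
        p2 = tmp_path / "badcol.csv"
        bad.to_csv(p2, index=False)
        with pytest.raises(FmscError, match="foo"):
            read_morphometry(p2, parc34)

    def test_non_numeric_cell_error_names_location(self, tmp_path, parc34, rng):
        df = pd.DataFrame(rng.normal(size=(34, 8)), columns=list(METRIC_NAMES))
        df.insert(0, "region_id", list(parc34.region_ids))
        df.loc[3, "GMV"] = "oops"
        p = tmp_path / "badcell.csv"
        df.to_csv(p, index=False)
        with pytest.raises(FmscError, match="GMV"):
            read_morphometry(p, parc34)

    def test_timeseries_reader_aligns_to_parcellation(self, tmp_path, parc34, rng):
        values = rng.standard_normal((34, 20))
        df = pd.DataFrame(values, columns=[f"t{t}" for t in range(20)])
        df.insert(0, "region_id", list(parc34.region_ids))
        p = tmp_path / "ts.csv"
        df.to_csv(p, index=False)
        ts = read_timeseries(p, parc34)
        np.testing.assert_allclose(ts.values, values)

    def test_connectome_tsv_roundtrip_is_bitwise(self, tmp_path, rng):
        c = Connectome(
            random_correlation_like(rng, 34),
            Parcellation.yeo17_two_hemisphere().region_ids,
            "MSN",
        )
        p = tmp_path / "c.tsv"
        write_connectome(p, c)
        back = read_connectome(p)
        assert back.kind == "MSN"
        assert back.region_ids == c.region_ids
        assert np.array_equal(back.matrix, c.matrix)

    def test_connectome_read_rejects_label_mismatch(self, tmp_path, rng, parc34):
        c = Connectome(random_correlation_like(rng, 4), tuple("abcd"), "FCN")
        p = tmp_path / "c.tsv"
        write_connectome(p, c)
        with pytest.raises(FmscError, match="parcellation"):
            read_connectome(p, parcellation=parc34)
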