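import numpy as np
import pandas as pd
import pytest

from adniche.abundance import (
    AsvTable,
    alpha_diversity,
    anosim,
    bray_curtis_matrix,
    rarefy,
    read_count_table,
    to_relative,
    weight_to_absolute,
    write_count_table,
)
from adniche.errors import (
    EmptyTableError,
    FormatError,
    InvalidGroupingError,
    InvalidInputError,
    MissingMetadataError,
    UndefinedPairError,
)
from oracles import anosim_exhaustive_p


class TestIO:
    def test_round_trip(self, small_table, tmp_path):
        path = tmp_path / "counts.tsv"
        write_count_table(small_table, path)
        back = read_count_table(path)
        pd.testing.assert_frame_equal(back.data, small_table.data)
        # canonical formatting is byte-stable
        path2 = tmp_path / "again.tsv"
        write_count_table(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    @pytest.mark.parametrize(
        "body,fragment",
        [
            ("taxon_id\ts1\ts2\nt1\t3.5\t1\n", "line 2"),  # non-integer cell
            ("taxon_id\ts1\ts2\nt1\t1\t2\nt1\t3\t4\n", "duplicate taxon"),
            ("taxon_id\ts1\ts2\nt1\t1\n", "expected 3 fields"),  # ragged
            ("taxon_id\ts1\ts1\nt1\t1\t2\n", "duplicate sample"),
        ],
    )
    def test_format_errors_name_the_line(self, tmp_path, body, fragment):
        path = tmp_path / "bad.tsv"
        path.write_text(body)
        with pytest.raises(FormatError, match=fragment):
            read_count_table(path)


class TestRarefy:
    def test_depth_equals_total_is_identity(self, small_table):
        out = rarefy(small_table, depth=100, seed=1)
        pd.testing.assert_frame_equal(out.data, small_table.data)
        assert out.mode == "rarefied"

    def test_depth_one(self, small_table):
        out = rarefy(small_table, depth=1, seed=1)
        assert (out.data.sum(axis=0) == 1).all()
        assert ((out.data != 0).sum(axis=0) == 1).all()

    def test_column_sums_and_no_count_increase(self, small_table):
        out = rarefy(small_table, depth=50, seed=3)
        assert (out.data.sum(axis=0) == 50).all()
        assert (out.data.to_numpy() <= small_table.data.to_numpy()).all()

    def test_underdepth_samples_dropped(self, small_table):
        bigger = small_table.data.copy()
        bigger["tiny"] = [1, 0, 0, 0]
        out = rarefy(AsvTable(bigger, mode="raw"), depth=50, seed=0)
        assert "tiny" not in out.samples
        with pytest.raises(EmptyTableError):
            rarefy(small_table, depth=10**6, seed=0)

    def test_seed_determinism(self, small_table):
        a = rarefy(small_table, depth=50, seed=42)
        b = rarefy(small_table, depth=50, seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_hypergeometric_mean(self):
        """Mean rarefied count over many seeds matches depth * proportion."""
        counts = pd.DataFrame({"s": [300, 100, 600]}, index=["a", "b", "c"])
        table = AsvTable(counts, mode="raw")
        depth = 200
        draws = np.array(
            [rarefy(table, depth, seed=s).data["s"].to_numpy() for s in range(1000)]
        )
        total = 1000.0
        p = counts["s"] / total
        expect = depth * p.to_numpy()
        # multivariate hypergeometric variance for each component
        var = depth * p * (1 - p) * (total - depth) / (total - 1)
        se = np.sqrt(var.to_numpy() / draws.shape[0])
        assert (np.abs(draws.mean(axis=0) - expect) <= 3 * se + 1e-9).all()


class TestAbsolute:
    def test_proportional_scaling(self):
        table = AsvTable(pd.DataFrame({"s": [30, 70]}, index=["a", "b"]), mode="raw")
        rare = rarefy(table, 100, seed=0)
        out = weight_to_absolute(rare, {"s": 1e6})
        assert out.data["s"].tolist() == pytest.approx([3e5, 7e5])

    def test_column_sums_equal_copies(self, small_table):
        rare = rarefy(small_table, 50, seed=0)
        copies = {s: 10 ** (6 + i) for i, s in enumerate(rare.samples)}
        out = weight_to_absolute(rare, copies)
        for s in out.samples:
            assert out.data[s].sum() == pytest.approx(copies[s])

    def test_zero_copies_gives_zero_column(self, small_table):
        rare = rarefy(small_table, 50, seed=0)
        copies = {s: 0.0 for s in rare.samples}
        out = weight_to_absolute(rare, copies)
        assert (out.data.to_numpy() == 0).all()

    def test_missing_copies_error(self, small_table):
        rare = rarefy(small_table, 50, seed=0)
        with pytest.raises(MissingMetadataError):
            weight_to_absolute(rare, {"s1": 1.0})

    def test_requires_rarefied_mode(self, small_table):
        with pytest.raises(InvalidInputError):
            weight_to_absolute(small_table, {s: 1.0 for s in small_table.samples})


class TestAlphaDiversity:
    def test_uniform_community(self):
        s, j = alpha_diversity([10, 10, 10, 10])
        assert s == 4 and j == pytest.approx(1.0)

    def test_hand_value(self):
        s, j = alpha_diversity([5, 5, 10])
        p = np.array([0.25, 0.25, 0.5])
        expected = -(p * np.log(p)).sum() / np.log(3)
        assert s == 3 and j == pytest.approx(expected)
        assert j == pytest.approx(0.946, abs=5e-4)

    def test_single_taxon_missing_evenness(self):
        s, j = alpha_diversity([7, 0, 0])
        assert s == 1 and np.isnan(j)

    def test_matches_skbio(self):
        import skbio.diversity.alpha as ska

        vec = np.array([5, 1, 12, 0, 30, 2])
        s, j = alpha_diversity(vec)
        assert j == pytest.approx(float(ska.pielou_e(vec)))

    def test_all_zero_error(self):
        with pytest.raises(InvalidInputError):
            alpha_diversity([0, 0])


class TestBrayCurtis:
    def _abs(self, df):
        return AsvTable(df.astype(float), mode="absolute")

    def test_examples(self):
        df = pd.DataFrame({"x": [2.0, 2.0], "y": [1.0, 3.0], "z": [2.0, 2.0]},
                          index=["a", "b"])
        bc = bray_curtis_matrix(self._abs(df))
        assert bc.loc["x", "y"] == pytest.approx(0.25)
        assert bc.loc["x", "z"] == 0.0

    def test_disjoint_is_one(self):
        df = pd.DataFrame({"x": [5.0, 0.0], "y": [0.0, 7.0]}, index=["a", "b"])
        bc = bray_curtis_matrix(self._abs(df))
        assert bc.loc["x", "y"] == pytest.approx(1.0)

    def test_metric_properties(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.random((6, 5)) * 100, columns=list("vwxyz"))
        bc = bray_curtis_matrix(self._abs(df)).to_numpy()
        assert np.allclose(bc, bc.T)
        assert np.allclose(np.diag(bc), 0.0)
        assert ((bc >= 0) & (bc <= 1)).all()

    def test_two_all_zero_samples_error(self):
        df = pd.DataFrame({"x": [0.0, 0.0], "y": [0.0, 0.0], "z": [1.0, 2.0]},
                          index=["a", "b"])
        with pytest.raises(UndefinedPairError):
            bray_curtis_matrix(self._abs(df))


class TestAnosim:
    def _separated(self):
        # two tight groups far apart: all between > all within
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.95, 0.85],
                [0.9, 0.95, 0.0, 0.12],
                [0.8, 0.85, 0.12, 0.0],
            ]
        )
        return d, ["g1", "g1", "g2", "g2"]

    def test_maximal_separation_r_is_one(self):
        d, g = self._separated()
        res = anosim(d, g, n_perm=99, seed=0)
        assert res.r_statistic == pytest.approx(1.0)

    def test_all_equal_distances_r_zero(self):
        d = np.ones((4, 4)) - np.eye(4)
        res = anosim(d, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert res.r_statistic == pytest.approx(0.0)

    def test_p_matches_exhaustive_enumeration(self):
        d, g = self._separated()
        _, p_exact = anosim_exhaustive_p(d, g)
        res = anosim(d, g, n_perm=999, seed=7)
        assert p_exact == pytest.approx(1 / 3)
        assert abs(res.p_value - p_exact) < 0.05

    def test_r_matches_skbio(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (4, 2)), rng.normal(2, 1, (4, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        g = ["a"] * 4 + ["b"] * 4
        ours = anosim(d, g, n_perm=99, seed=0)
        theirs = skbio_anosim(SkbioDM(d), g, permutations=0)
        assert ours.r_statistic == pytest.approx(theirs["test statistic"])

    def test_rank_invariance_under_monotone_transform(self):
        d, g = self._separated()
        res1 = anosim(d, g, n_perm=199, seed=1)
        res2 = anosim(np.sqrt(d), g, n_perm=199, seed=1)
        assert res1.r_statistic == pytest.approx(res2.r_statistic)
        assert res1.p_value == res2.p_value

    def test_singleton_group_error(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(InvalidGroupingError):
            anosim(d, ["a", "a", "b"], n_perm=99)


def test_relative_mode_sums_to_100(small_table):
    rel = to_relative(small_table)
    assert np.allclose(rel.data.sum(axis=0), 100.0)


def test_duplicate_ids_rejected():
    df = pd.DataFrame([[1, 2], [3, 4]], index=["a", "a"], columns=["s1", "s2"])
    with pytest.raises(InvalidInputError):
        AsvTable(df, mode="raw")
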