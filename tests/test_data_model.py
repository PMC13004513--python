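import numpy as np
import pytest

from survflow import (
    ColumnSchema,
    StratificationRule,
    SurvivalDataset,
    read_dataset,
    stratify,
    write_dataset,
)
from survflow.errors import (
    DegenerateFeatureError,
    EmptyGroupError,
    ParseError,
    SchemaError,
)

from conftest import make_dataset


def _write(tmp_path, text, name="d.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadDataset:
    def test_well_formed_tsv_round_trip(self, tmp_path):
        p = _write(
            tmp_path,
            "id\ttime\tevent\tx1\n"
            "a\t1.5\t1\t0.2\nb\t2\t0\t-1\nc\t3\t1\t0.5\nd\t4.5\t0\t2\ne\t5\t1\t0\n",
        )
        schema = ColumnSchema("time", "event", ("x1",), id_col="id")
        ds = read_dataset(p, schema)
        assert ds.n == 5 and ds.p == 1
        assert ds.n_events == 3
        assert list(ds.subject_ids) == ["a", "b", "c", "d", "e"]

    def test_event_aliases(self, tmp_path):
        p = _write(tmp_path, "time\tevent\n1\tyes\n2\tdead\n3\talive\n4\tno\n")
        ds = read_dataset(p, {"time_col": "time", "event_col": "event"})
        assert list(ds.event) == [1, 1, 0, 0]

    def test_aliases_disabled_rejects_words(self, tmp_path):
        p = _write(tmp_path, "time\tevent\n1\tyes\n")
        with pytest.raises(ParseError):
            read_dataset(p, {"time_col": "time", "event_col": "event"}, event_aliases=False)

    def test_negative_time_cites_row(self, tmp_path):
        p = _write(tmp_path, "time\tevent\n1\t1\n-2\t0\n")
        with pytest.raises(ParseError, match="row 1"):
            read_dataset(p, {"time_col": "time", "event_col": "event"})

    def test_missing_column_named(self, tmp_path):
        p = _write(tmp_path, "time\tevent\n1\t1\n")
        with pytest.raises(SchemaError, match="x9"):
            read_dataset(p, ColumnSchema("time", "event", ("x9",)))

    def test_missing_values_rejected_unless_dropped(self, tmp_path):
        p = _write(tmp_path, "time\tevent\n1\t1\n\t0\n3\t1\n")
        with pytest.raises(ParseError):
            read_dataset(p, {"time_col": "time", "event_col": "event"})
        with pytest.warns(UserWarning, match="dropped 1"):
            ds = read_dataset(
                p, {"time_col": "time", "event_col": "event"}, drop_missing=True
            )
        assert ds.n == 2

    def test_csv_delimiter_autodetect(self, tmp_path):
        p = _write(tmp_path, "time,event\n1,1\n2,0\n", name="d.csv")
        assert read_dataset(p, {"time_col": "time", "event_col": "event"}).n == 2


class TestWriteDataset:
    @pytest.mark.parametrize("with_groups", [False, True])
    def test_round_trip_exact(self, tmp_path, rng, with_groups):
        n = 30
        ds = make_dataset(
            rng.exponential(7, n),
            rng.integers(0, 2, n),
            rng.standard_normal((n, 3)),
            groups=rng.choice(["A", "B"], n) if with_groups else None,
        )
        path = tmp_path / "out.tsv"
        write_dataset(ds, path)
        from survflow.data import dataset_schema

        back = read_dataset(path, dataset_schema(ds))
        np.testing.assert_array_equal(back.time, ds.time)
        np.testing.assert_array_equal(back.event, ds.event)
        np.testing.assert_array_equal(back.covariates, ds.covariates)
        assert back.feature_names == ds.feature_names
        if with_groups:
            assert list(back.groups) == list(ds.groups)

    def test_zero_feature_dataset(self, tmp_path):
        ds = make_dataset([1, 2, 3], [1, 0, 1])
        path = tmp_path / "out.tsv"
        write_dataset(ds, path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["id", "time", "event"]


class TestInvariants:
    def test_event_values_strict(self):
        with pytest.raises(ParseError):
            make_dataset([1, 2], [1, 2])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(SchemaError):
            SurvivalDataset(
                np.array(["a", "a"]), np.array([1.0, 2.0]), np.array([1, 0]),
                np.zeros((2, 0)), (),
            )

    def test_feature_name_count_must_match(self):
        with pytest.raises(SchemaError):
            make_dataset([1, 2], [1, 0], np.zeros((2, 2)), feature_names=("x",))


class TestStratify:
    def test_explicit_cutoff_convention(self):
        ds = make_dataset(
            [1, 2, 3, 4], [1, 1, 1, 1], np.array([10.0, 35.0, 40.0, 20.0]),
            feature_names=("tumor_size",),
        )
        rule = StratificationRule(
            "tumor_size", mode="explicit_cutoff", cutoff=35, label_low="<35", label_high=">=35"
        )
        out = stratify(ds, rule)
        assert list(out.groups) == ["<35", ">=35", ">=35", "<35"]
        assert ds.groups is None  # original unmodified

    def test_median_split_even_distinct_is_half_half(self, rng):
        n = 40
        x = rng.permutation(np.arange(n, dtype=float))
        ds = make_dataset(rng.exponential(5, n), np.ones(n, int), x)
        out = stratify(ds, StratificationRule("x1"))
        counts = [(out.groups == g).sum() for g in ("low", "high")]
        assert counts == [n // 2, n // 2]

    def test_median_tie_handling(self):
        # ties at the median go to the high group (>= convention)
        ds = make_dataset([1, 2, 3, 4], [1, 1, 1, 1], np.array([1.0, 2.0, 2.0, 3.0]))
        out = stratify(ds, StratificationRule("x1"))
        assert list(out.groups) == ["low", "high", "high", "high"]

    def test_quantile_mode_tertiles(self):
        ds = make_dataset(
            np.arange(1, 10, dtype=float), np.ones(9, int),
            np.arange(9, dtype=float),
        )
        out = stratify(ds, StratificationRule("x1", mode="quantile", quantile_count=3))
        labels, counts = np.unique(list(out.groups), return_counts=True)
        assert len(labels) == 3 and counts.tolist() == [3, 3, 3]

    def test_constant_feature_degenerate(self):
        ds = make_dataset([1, 2], [1, 1], np.array([5.0, 5.0]))
        with pytest.raises(DegenerateFeatureError):
            stratify(ds, StratificationRule("x1"))

    def test_out_of_range_cutoff_empty_group(self):
        ds = make_dataset([1, 2], [1, 1], np.array([1.0, 2.0]))
        with pytest.raises(EmptyGroupError):
            stratify(ds, StratificationRule("x1", mode="explicit_cutoff", cutoff=99.0))

    def test_stratify_changes_only_groups(self, rng):
        n = 25
        ds = make_dataset(rng.exponential(3, n), rng.integers(0, 2, n), rng.standard_normal(n))
        out = stratify(ds, StratificationRule("x1"))
        np.testing.assert_array_equal(out.time, ds.time)
        np.testing.assert_array_equal(out.event, ds.event)
        np.testing.assert_array_equal(out.covariates, ds.covariates)
        assert out.n == ds.n
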