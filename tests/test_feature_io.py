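import numpy as np
import pandas as pd
import pytest

from ploidymapper.feature_io import (
    FeatureIOError,
    FeatureTable,
    LabelImage,
    NucleusRecord,
    read_assignments,
    read_feature_table,
    read_label_image,
    write_assignments,
    write_feature_table,
    write_label_image,
)
from ploidymapper.ploidy_assign import ComponentClassMap, classify

from conftest import make_table


def _write_csv(path, df):
    df.to_csv(path, index=False)
    return path


class TestReadFeatureTable:
    def test_ilastik_versioned_intensity_column(self, tmp_path):
        # "Total Intensity_0" must resolve automatically, with no mapping
        path = _write_csv(
            tmp_path / "t.csv",
            pd.DataFrame(
                {
                    "object_id": [1, 2],
                    "Total Intensity_0": [123.5, 456.25],
                    "Size in pixels": [10, 20],
                }
            ),
        )
        table = read_feature_table(path)
        assert [r.total_intensity for r in table.records] == [123.5, 456.25]

    def test_unversioned_intensity_column(self, tmp_path):
        path = _write_csv(
            tmp_path / "t.csv",
            pd.DataFrame(
                {"object_id": [7], "Total Intensity": [9.0], "Size in pixels": [3]}
            ),
        )
        table = read_feature_table(path)
        assert table.records[0].total_intensity == 9.0
        assert table.records[0].object_id == 7

    def test_empty_file_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("object_id,Total Intensity,Size in pixels\n")
        table = read_feature_table(path)
        assert len(table) == 0

    def test_user_labels_with_predicted_class_fallback(self, tmp_path):
        path = _write_csv(
            tmp_path / "t.csv",
            pd.DataFrame(
                {
                    "object_id": [1],
                    "Total Intensity": [1.0],
                    "Size in pixels": [1],
                    "Predicted Class": ["guard_cell"],
                }
            ),
        )
        assert read_feature_table(path).records[0].user_label == "guard_cell"
        path2 = _write_csv(
            tmp_path / "t2.csv",
            pd.DataFrame(
                {
                    "object_id": [1],
                    "Total Intensity": [1.0],
                    "Size in pixels": [1],
                    "User Labels": ["nucleus"],
                    "Predicted Class": ["guard_cell"],
                }
            ),
        )
        # "User Labels" wins over the fallback
        assert read_feature_table(path2).records[0].user_label == "nucleus"

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = _write_csv(
            tmp_path / "t.csv",
            pd.DataFrame({"object_id": [1], "Size in pixels": [4]}),
        )
        with pytest.raises(FeatureIOError, match="total_intensity"):
            read_feature_table(path)

    def test_non_numeric_intensity_names_row(self, tmp_path):
        path = _write_csv(
            tmp_path / "t.csv",
            pd.DataFrame(
                {
                    "object_id": [1, 2],
                    "Total Intensity": ["3.0", "oops"],
                    "Size in pixels": [1, 1],
                }
            ),
        )
        with pytest.raises(FeatureIOError, match="row 1"):
            read_feature_table(path)

    def test_rows_without_object_id_rejected(self, tmp_path):
        path = _write_csv(
            tmp_path / "t.csv",
            pd.DataFrame(
                {
                    "object_id": [1, None, 3],
                    "Total Intensity": [1.0, 2.0, 3.0],
                    "Size in pixels": [1, 1, 1],
                }
            ),
        )
        table = read_feature_table(path)
        assert [r.object_id for r in table.records] == [1, 3]

    def test_column_order_insensitive(self, tmp_path):
        cols = {
            "Size in pixels": [5],
            "Total Intensity": [50.0],
            "object_id": [1],
        }
        a = _write_csv(tmp_path / "a.csv", pd.DataFrame(cols))
        b = _write_csv(
            tmp_path / "b.csv",
            pd.DataFrame(cols)[["object_id", "Total Intensity", "Size in pixels"]],
        )
        ra, rb = read_feature_table(a).records[0], read_feature_table(b).records[0]
        assert ra == rb

    def test_explicit_dialect_override(self, tmp_path):
        path = _write_csv(
            tmp_path / "t.csv",
            pd.DataFrame({"id": [1], "sum_I": [5.5], "npx": [2]}),
        )
        table = read_feature_table(
            path,
            dialect={"object_id": "id", "total_intensity": "sum_I", "size": "npx"},
        )
        assert table.records[0].total_intensity == 5.5

    def test_centroid_columns_set_dimensionality(self, tmp_path):
        path = _write_csv(
            tmp_path / "t.csv",
            pd.DataFrame(
                {
                    "object_id": [1],
                    "Total Intensity": [1.0],
                    "Size in pixels": [1],
                    "Center of the object_0": [3.0],
                    "Center of the object_1": [4.0],
                    "Center of the object_2": [5.0],
                }
            ),
        )
        table = read_feature_table(path)
        assert table.dimensionality == 3
        assert table.records[0].centroid == (3.0, 4.0, 5.0)

    def test_duplicate_object_id_rejected(self, tmp_path):
        path = _write_csv(
            tmp_path / "t.csv",
            pd.DataFrame(
                {
                    "object_id": [1, 1],
                    "Total Intensity": [1.0, 2.0],
                    "Size in pixels": [1, 1],
                }
            ),
        )
        with pytest.raises(FeatureIOError, match="duplicate"):
            read_feature_table(path)


class TestFeatureTableRoundTrip:
    def test_write_read_round_trip_field_for_field(self, tmp_path):
        rng = np.random.default_rng(42)
        rows = []
        for i in range(5):
            intensity = float(rng.uniform(10, 1e6))
            size = float(rng.integers(5, 500))
            rows.append(
                {
                    "object_id": i + 1,
                    "total_intensity": intensity,
                    "size": size,
                    "mean_intensity": intensity / size,
                    "variance_of_intensity": float(rng.uniform(0, 100)),
                    "user_label": "nucleus",
                    "group": "g1",
                }
            )
        table = make_table(rows)
        path = tmp_path / "rt.csv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        assert len(back) == 5
        for orig, re_read in zip(table.records, back.records):
            assert re_read.object_id == orig.object_id
            assert re_read.total_intensity == pytest.approx(
                orig.total_intensity, rel=1e-14
            )
            assert re_read.size == pytest.approx(orig.size, rel=1e-14)
            assert re_read.variance_of_intensity == pytest.approx(
                orig.variance_of_intensity, rel=1e-14
            )
            assert re_read.user_label == orig.user_label
            assert re_read.group == orig.group

    def test_empty_table_round_trip(self, tmp_path):
        path = tmp_path / "e.csv"
        write_feature_table(FeatureTable(), path)
        assert len(read_feature_table(path)) == 0


class TestLabelImage:
    def test_zero_tiff(self, tmp_path):
        img = LabelImage(array=np.zeros((8, 8), dtype=np.uint16))
        path = tmp_path / "z.tif"
        write_label_image(img, path)
        back = read_label_image(path)
        assert back.labels.size == 0
        assert back.array.dtype == np.uint16

    def test_hdf5_round_trip(self, tmp_path):
        arr = np.zeros((4, 6), dtype=np.uint16)
        arr[0, 0] = 1
        arr[1, 1] = 2
        arr[2, 2] = 7
        path = tmp_path / "l.h5"
        write_label_image(LabelImage(array=arr), path)
        back = read_label_image(path)
        np.testing.assert_array_equal(back.array, arr)
        assert set(back.labels) == {1, 2, 7}

    def test_dtype_boundary_preserved(self, tmp_path):
        arr = np.full((3, 3), 65535, dtype=np.uint16)
        path = tmp_path / "m.tif"
        write_label_image(LabelImage(array=arr), path)
        assert read_label_image(path).array.max() == 65535

    def test_float_raster_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "f.tif"
        tifffile.imwrite(path, np.zeros((3, 3), dtype=np.float32))
        with pytest.raises(FeatureIOError, match="object predictions"):
            read_label_image(path)

    def test_3d_round_trip(self, tmp_path):
        arr = np.arange(24, dtype=np.uint16).reshape(2, 3, 4)
        path = tmp_path / "v.tif"
        write_label_image(LabelImage(array=arr), path)
        np.testing.assert_array_equal(read_label_image(path).array, arr)


def _two_class_map():
    return ComponentClassMap(
        order=np.array([0, 1]),
        class_for_component={0: "2C", 1: "4C"},
        ladder=["2C", "4C"],
    )


class TestWriteAssignments:
    def test_filtered_rows_marked(self, tmp_path):
        table = make_table([{}, {}, {}])
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        assignment = classify(P, _two_class_map())
        path = tmp_path / "a.csv"
        write_assignments(table, assignment, path, index_map=[0, 2])
        df = read_assignments(path)
        assert len(df) == 3
        assert df.loc[1, "ploidy_class"] == "filtered"
        assert pd.isna(df.loc[1, "posterior_0"])
        assert df.loc[0, "ploidy_class"] == "2C"
        assert df.loc[2, "ploidy_class"] == "4C"

    def test_round_trip_reproduces_class_counts(self, tmp_path):
        rng = np.random.default_rng(7)
        n = 20
        raw = rng.uniform(0.05, 1.0, size=(n, 2))
        P = raw / raw.sum(axis=1, keepdims=True)
        table = make_table([{} for _ in range(n)])
        assignment = classify(P, _two_class_map())
        path = tmp_path / "a.csv"
        write_assignments(table, assignment, path)
        df = read_assignments(path)
        for name in ("2C", "4C"):
            assert (df["ploidy_class"] == name).sum() == int(
                np.sum(assignment.class_name == name)
            )

    def test_posteriors_round_trip_precision(self, tmp_path):
        P = np.array([[0.123456789012345, 0.876543210987655]])
        table = make_table([{}])
        assignment = classify(P, _two_class_map())
        path = tmp_path / "a.csv"
        write_assignments(table, assignment, path)
        df = read_assignments(path)
        assert df.loc[0, "posterior_0"] == pytest.approx(P[0, 0], rel=1e-14)

    def test_zero_record_table(self, tmp_path):
        table = make_table([{}])
        P = np.array([[1.0, 0.0]])
        assignment = classify(P, _two_class_map())
        path = tmp_path / "a.csv"
        with pytest.raises(FeatureIOError, match="length"):
            write_assignments(make_table([{}, {}]), assignment, path)
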