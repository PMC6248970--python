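import numpy as np
import pytest

from radadapt import FeatureTable, InputError, RunConfig, VolumeROI, \
    read_feature_table, read_volume_roi, registry_names, write_feature_table
from radadapt.data_io import write_volume_nifti


def make_table(n=5, p=3, names=None, seed=0):
    rng = np.random.default_rng(seed)
    names = names or [f"glcm_energy_{j},0,0" for j in range(p)]
    labels = np.array(["adaptive", "non-adaptive"] * n, dtype=object)[:n]
    return FeatureTable(
        feature_names=names,
        X=rng.normal(size=(n, len(names))),
        labels=labels,
        patient_ids=[f"P{i}" for i in range(n)],
        class_values=("adaptive", "non-adaptive"),
    )


class TestVolumeROI:
    def test_roundtrip_nifti(self, tmp_path):
        vol = np.arange(64, dtype=float).reshape(4, 4, 4)
        mask = np.zeros((4, 4, 4))
        mask[1:3, 1:3, 1:3] = 1
        write_volume_nifti(vol, tmp_path / "v.nii.gz")
        write_volume_nifti(mask, tmp_path / "m.nii.gz")
        roi = read_volume_roi(str(tmp_path / "v.nii.gz"), str(tmp_path / "m.nii.gz"))
        assert roi.n_roi_voxels == 8
        np.testing.assert_allclose(roi.volume, vol)

    def test_roundtrip_nrrd(self, tmp_path):
        import SimpleITK as sitk

        vol = np.arange(60, dtype=float).reshape(3, 4, 5)
        mask = (vol % 7 == 0).astype(np.uint8)
        for arr, name in ((vol, "v.nrrd"), (mask, "m.nrrd")):
            sitk.WriteImage(sitk.GetImageFromArray(arr.transpose(2, 1, 0)),
                            str(tmp_path / name))
        roi = read_volume_roi(str(tmp_path / "v.nrrd"), str(tmp_path / "m.nrrd"))
        assert roi.volume.shape == (3, 4, 5)
        np.testing.assert_allclose(roi.volume, vol)
        assert roi.n_roi_voxels == int(mask.sum())

    def test_mask_values_coerced_to_binary(self):
        vol = np.zeros((3, 3, 3))
        mask = np.zeros((3, 3, 3))
        mask[0, 0, 0], mask[1, 1, 1] = 2.0, 7.5
        roi = VolumeROI("x", vol, mask)
        assert roi.n_roi_voxels == 2

    def test_dimension_mismatch_names_both_shapes(self, tmp_path):
        write_volume_nifti(np.zeros((4, 4, 4)), tmp_path / "v.nii.gz")
        write_volume_nifti(np.ones((4, 4, 3)), tmp_path / "m.nii.gz")
        with pytest.raises(InputError, match=r"\(4, 4, 4\).*\(4, 4, 3\)"):
            read_volume_roi(str(tmp_path / "v.nii.gz"), str(tmp_path / "m.nii.gz"))

    @pytest.mark.parametrize("n_fg", [0, 1])
    def test_empty_or_single_voxel_roi_rejected(self, n_fg):
        mask = np.zeros((4, 4, 4))
        mask.flat[:n_fg] = 1
        with pytest.raises(InputError, match="at least 2 foreground"):
            VolumeROI("x", np.zeros((4, 4, 4)), mask)


class TestFeatureTableIO:
    @pytest.mark.parametrize("ext", ["arff", "csv"])
    def test_write_read_roundtrip(self, tmp_path, ext):
        table = make_table(n=7, p=4)
        path = tmp_path / f"t.{ext}"
        write_feature_table(table, str(path))
        back = read_feature_table(str(path))
        assert back.feature_names == table.feature_names
        np.testing.assert_allclose(back.X, table.X, atol=1e-9)
        assert list(back.labels) == list(table.labels)

    def test_full_registry_arff_attribute_count(self, tmp_path):
        """A 251-column table serializes to 252 ARFF attributes (features + class)."""
        names = registry_names()
        table = make_table(n=4, names=names)
        path = tmp_path / "full.arff"
        write_feature_table(table, str(path))
        # independent text parse
        n_attr = sum(1 for line in open(path) if line.lower().startswith("@attribute"))
        assert n_attr == 252

    def test_arff_cross_checked_against_scipy_reader(self, tmp_path):
        from scipy.io import arff as scipy_arff

        table = make_table(n=6, p=3, names=["f1", "f2", "f3"])
        path = tmp_path / "x.arff"
        write_feature_table(table, str(path))
        data, meta = scipy_arff.loadarff(str(path))
        for j, name in enumerate(table.feature_names):
            np.testing.assert_allclose(np.array([row[j] for row in data]),
                                       table.X[:, j], atol=1e-9)
        labels = [row[-1].decode() for row in data]
        assert labels == [str(v) for v in table.labels]

    def test_arff_missing_and_nominal_coding(self, tmp_path):
        path = tmp_path / "n.arff"
        path.write_text(
            "@relation t\n"
            "@attribute sem_age numeric\n"
            "@attribute sem_histology {adenocarcinoma,squamous}\n"
            "@attribute class {adaptive,non-adaptive}\n"
            "@data\n"
            "71,squamous,adaptive\n"
            "?,adenocarcinoma,non-adaptive\n"
        )
        t = read_feature_table(str(path))
        assert t.nominal_codings["sem_histology"] == {"adenocarcinoma": 0, "squamous": 1}
        assert np.isnan(t.X[1, 0]) and t.X[0, 1] == 1.0

    def test_three_class_values_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("f1,class\n1,a\n2,b\n3,c\n")
        with pytest.raises(InputError, match="2 distinct values"):
            read_feature_table(str(path))

    def test_nonnumeric_radiomic_value_rejected(self, tmp_path):
        path = tmp_path / "bad.arff"
        path.write_text("@relation t\n@attribute glcm_energy numeric\n"
                        "@attribute class {a,b}\n@data\nfoo,a\n1.0,b\n")
        with pytest.raises(InputError, match="non-numeric"):
            read_feature_table(str(path))

    def test_empty_feature_list_rejected_on_write(self, tmp_path):
        with pytest.raises(InputError):
            t = make_table(n=4, p=2)
            t.feature_names, t.X = [], np.empty((4, 0))
            write_feature_table(t, str(tmp_path / "e.arff"))

    def test_missing_value_in_radiomic_column_rejected(self):
        with pytest.raises(InputError, match="missing values"):
            FeatureTable(
                feature_names=["glcm_energy_1,0,0"],
                X=np.array([[np.nan], [1.0]]),
                labels=np.array(["adaptive", "non-adaptive"], dtype=object),
                patient_ids=["a", "b"],
            )


class TestRunConfig:
    @pytest.mark.parametrize("kwargs", [
        {"selection_threshold": 0.0},
        {"selection_threshold": 1.5},
        {"bootstrap_replicates": 1},
        {"prevalence": 0.0},
        {"quantization_levels": 1},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(InputError):
            RunConfig(**kwargs)
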