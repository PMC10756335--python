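"""Response binarization, omics normalization and image standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from cdrlearn.exceptions import ValidationError
from cdrlearn.preprocess import (
    OmicsMatrix,
    binarize_response,
    build_response_table,
    fill_missing,
    gaussian_normalize,
    log_tpm_transform,
    preprocess_image,
)


class TestBinarizeResponse:
    @pytest.mark.parametrize(
        "ic50, threshold, expected",
        [
            (566.28, 32.0, 0),  # far above the screening maximum -> resistant
            (32.0, 32.0, 1),  # the comparison is inclusive
            (0.0, 32.0, 1),
            (31.999, 32.0, 1),
            (32.001, 32.0, 0),
        ],
    )
    def test_threshold_semantics(self, ic50, threshold, expected):
        assert binarize_response(ic50, threshold) == expected

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_invalid_ic50_rejected(self, bad):
        with pytest.raises(ValidationError):
            binarize_response(bad, 32.0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValidationError):
            binarize_response(1.0, 0.0)

    @settings(deadline=None)
    @given(
        ic50_lo=st.floats(0, 1e6, allow_nan=False),
        delta=st.floats(0, 1e6, allow_nan=False),
        threshold=st.floats(1e-6, 1e6, allow_nan=False),
    )
    def test_monotone_nonincreasing_in_ic50(self, ic50_lo, delta, threshold):
        assert binarize_response(ic50_lo, threshold) >= binarize_response(
            ic50_lo + delta, threshold
        )

    def test_scale_invariance_raw_vs_ln(self):
        df = pd.DataFrame(
            {
                "cell_line": ["a", "a", "b"],
                "drug": ["d1", "d2", "d1"],
                "ic50": [10.0, 50.0, 32.0],
                "max_screening_conc": [32.0, 32.0, 32.0],
            }
        )
        raw = build_response_table(df, ic50_scale="raw")
        ln = build_response_table(df, ic50_scale="ln")
        assert list(raw.records["label"]) == list(ln.records["label"])


class TestResponseTable:
    def make_df(self):
        return pd.DataFrame(
            {
                "cell_line": ["a", "a", "b", "c"],
                "drug": ["d1", "d2", "d1", "d2"],
                "ic50": [1.0, 100.0, 32.0, 5.0],
                "max_screening_conc": [32.0, 32.0, 32.0, 32.0],
            }
        )

    def test_label_counts_partition_records(self):
        table = build_response_table(self.make_df())
        A = table.label_matrix
        assert np.nansum(A == 1) + np.nansum(A == 0) == len(table.records)

    def test_missing_pairs_are_nan(self):
        table = build_response_table(self.make_df())
        A = table.label_matrix
        assert np.isnan(A).sum() == A.size - len(table.records)

    def test_duplicate_pair_rejected(self):
        df = self.make_df()
        df.loc[4] = ["a", "d1", 2.0, 32.0]
        with pytest.raises(ValidationError, match="duplicate"):
            build_response_table(df)

    def test_error_names_offending_record(self):
        df = self.make_df()
        df.loc[1, "ic50"] = -5.0
        with pytest.raises(ValidationError, match="d2"):
            build_response_table(df)


class TestLogTpm:
    def test_known_values(self):
        out = log_tpm_transform(np.array([[0.0, 1.0, 7.0]]))
        np.testing.assert_allclose(out, [[0.0, 1.0, 3.0]])

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            log_tpm_transform(np.array([[-0.1]]))

    def test_shape_preserved(self):
        x = np.abs(np.random.default_rng(0).standard_normal((5, 7)))
        assert log_tpm_transform(x).shape == x.shape


class TestGaussianNormalize:
    def test_hand_computed_column(self):
        out = gaussian_normalize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_constant_column_maps_to_zero(self):
        out = gaussian_normalize(np.array([[5.0], [5.0], [5.0]]))
        np.testing.assert_allclose(out, 0.0)

    def test_columns_centered_and_scaled(self):
        x = np.random.default_rng(1).standard_normal((50, 8)) * 3.0 + 2.0
        out = gaussian_normalize(x)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-6)

    def test_idempotent(self):
        x = np.random.default_rng(2).standard_normal((20, 4))
        once = gaussian_normalize(x)
        np.testing.assert_allclose(gaussian_normalize(once), once, atol=1e-6)

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError, match="fill_missing"):
            gaussian_normalize(np.array([[1.0], [np.nan]]))


class TestFillMissing:
    def test_zero_fill(self):
        x = np.array([[1.0, np.nan], [np.nan, 4.0]])
        np.testing.assert_array_equal(fill_missing(x), [[1.0, 0.0], [0.0, 4.0]])

    def test_observed_entries_bit_exact(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((10, 10))
        mask = rng.random((10, 10)) < 0.3
        x_holes = np.where(mask, np.nan, x)
        filled = fill_missing(x_holes)
        assert (filled[~mask] == x[~mask]).all()

    def test_all_missing_column(self):
        x = np.full((4, 1), np.nan)
        np.testing.assert_array_equal(fill_missing(x), np.zeros((4, 1)))


class TestOmicsMatrixChain:
    def test_state_tracking(self):
        m = OmicsMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]), ["g1", "g2"], ["a", "b"])
        out = m.log_tpm().fill_missing().standardize()
        assert out.state == "standardized"
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-9)

    def test_id_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            OmicsMatrix(np.zeros((2, 2)), ["g1"], ["a", "b"])


class TestPreprocessImage:
    def test_resize_to_224(self):
        rng = np.random.default_rng(4)
        big = (rng.random((448, 448, 3)) * 255).astype(np.uint8)
        out = preprocess_image(big)
        assert out.shape == (224, 224, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_identity_for_already_224_uint8(self):
        rng = np.random.default_rng(5)
        img = (rng.random((224, 224, 3)) * 255).astype(np.uint8)
        np.testing.assert_allclose(preprocess_image(img), img / 255.0)

    def test_uniform_white_maps_to_ones(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        np.testing.assert_allclose(preprocess_image(img), 1.0)

    def test_grayscale_replicated(self):
        img = (np.linspace(0, 255, 224 * 224).reshape(224, 224)).astype(np.uint8)
        out = preprocess_image(img)
        np.testing.assert_array_equal(out[..., 0], out[..., 1])
        np.testing.assert_array_equal(out[..., 0], out[..., 2])

    def test_file_roundtrip_and_bad_file(self, tmp_path):
        img = (np.random.default_rng(6).random((100, 80, 3)) * 255).astype(np.uint8)
        p = tmp_path / "cell.png"
        Image.fromarray(img).save(p)
        out = preprocess_image(p)
        assert out.shape == (224, 224, 3)
        bad = tmp_path / "broken.png"
        bad.write_bytes(b"not an image")
        with pytest.raises(ValidationError, match="broken.png"):
            preprocess_image(bad)
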