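import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cxplaque.spectral import (CollinearSpectraError, GridMismatchError,
                               ReferenceSpectraSet,
                               extract_reference_spectra, linear_unmix)
from cxplaque.stacks import LambdaStack, default_bin_centers

from oracles import nnls_reference


def stack_from_abundances(abund, refs, voxel_size=(8.2, 0.25, 0.25)):
    return LambdaStack(abund @ refs.matrix, refs.bin_centers, voxel_size)


class TestReferenceSpectraSet:
    def test_rows_normalized_to_unit_sum(self, refs):
        assert np.allclose(refs.matrix.sum(axis=1), 1.0)

    def test_collinear_pair_named(self, refs):
        m = refs.matrix.copy()
        m[1] = m[0]
        with pytest.raises(CollinearSpectraError, match="AMCA|Alexa488"):
            ReferenceSpectraSet(refs.fluorophores, m, refs.bin_centers)

    def test_csv_round_trip(self, refs, tmp_path):
        p = tmp_path / "refs.csv"
        refs.to_csv(p)
        back = ReferenceSpectraSet.from_csv(p)
        assert back.fluorophores == refs.fluorophores
        np.testing.assert_allclose(back.matrix, refs.matrix, atol=1e-12)
        np.testing.assert_allclose(back.bin_centers, refs.bin_centers, atol=1e-4)

    def test_condition_number_reported(self, refs):
        assert 1.0 < refs.condition_number < 1e3


class TestExtractReferenceSpectra:
    def test_scaled_uniform_roi_recovers_fingerprint(self, refs):
        # voxels all equal to 3x a fingerprint -> exact fingerprint back
        k = 3
        data = np.tile(3.0 * refs.matrix[k], (1, 4, 4, 1))
        stack = LambdaStack(data, refs.bin_centers)
        roi = np.zeros((1, 4, 4), dtype=bool)
        roi[0, :2, :2] = True
        out = extract_reference_spectra(stack, {"Cy3": roi})
        np.testing.assert_allclose(out.matrix[0], refs.matrix[k], atol=1e-12)

    def test_two_dye_stack_recovers_both_fingerprints(self, refs):
        abund = np.zeros((1, 4, 4, 6))
        abund[0, :2, :, 1] = 7.0          # Alexa488 region
        abund[0, 2:, :, 4] = 2.5          # Alexa594 region
        stack = stack_from_abundances(abund, refs)
        rois = {"Alexa488": abund[..., 1] > 0, "Alexa594": abund[..., 4] > 0}
        out = extract_reference_spectra(stack, rois)
        np.testing.assert_allclose(out.matrix[0], refs.matrix[1], atol=1e-9)
        np.testing.assert_allclose(out.matrix[1], refs.matrix[4], atol=1e-9)

    def test_single_voxel_roi_is_that_voxel_normalized(self, refs):
        data = np.zeros((1, 2, 2, 32))
        data[0, 0, 0] = np.linspace(1, 4, 32)
        stack = LambdaStack(data, refs.bin_centers)
        roi = np.zeros((1, 2, 2), dtype=bool)
        roi[0, 0, 0] = True
        out = extract_reference_spectra(stack, {"x": roi})
        np.testing.assert_allclose(out.matrix[0],
                                   data[0, 0, 0] / data[0, 0, 0].sum(), atol=1e-12)

    def test_empty_roi_rejected(self, refs):
        stack = LambdaStack(np.ones((1, 2, 2, 32)), refs.bin_centers)
        with pytest.raises(ValueError, match="empty"):
            extract_reference_spectra(stack, {"x": np.zeros((1, 2, 2), dtype=bool)})


class TestLinearUnmix:
    def test_single_source_voxel(self, refs):
        abund = np.zeros((1, 1, 1, 6))
        abund[..., 3] = 5.0               # 5 x Cy3 fingerprint
        stack = stack_from_abundances(abund, refs)
        out = linear_unmix(stack, refs)
        np.testing.assert_allclose(out.abundances, abund, atol=1e-9)
        assert out.residual.max() < 1e-12

    def test_zero_voxel_gives_zero_abundance_zero_residual(self, refs):
        stack = LambdaStack(np.zeros((1, 2, 2, 32)), refs.bin_centers)
        out = linear_unmix(stack, refs)
        assert np.all(out.abundances == 0)
        assert np.all(out.residual == 0)

    def test_noiseless_round_trip_many_random_mixtures(self, refs, rng):
        abund = rng.uniform(0, 10, size=(10, 10, 10, 6))
        stack = stack_from_abundances(abund, refs)
        out = linear_unmix(stack, refs)
        rel = np.abs(out.abundances - abund) / np.maximum(abund, 1e-9)
        assert rel.max() < 1e-6

    def test_nonnegative_matches_independent_bounded_solver(self, refs, rng):
        # noisy spectra force active constraints; compare to lsq_linear
        abund = rng.uniform(0, 5, size=(64, 6))
        spectra = abund @ refs.matrix + rng.normal(0, 0.3, size=(64, 32))
        spectra = np.clip(spectra, 0, None)
        stack = LambdaStack(spectra.reshape(1, 8, 8, 32), refs.bin_centers)
        out = linear_unmix(stack, refs)
        got = out.abundances.reshape(64, 6)
        want = np.stack([nnls_reference(refs.matrix.T, s) for s in spectra])
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_unconstrained_residual_not_above_nonnegative(self, refs, rng):
        spectra = np.clip(rng.normal(1, 1, size=(32, 32)), 0, None)
        stack = LambdaStack(spectra.reshape(1, 4, 8, 32), refs.bin_centers)
        r_free = linear_unmix(stack, refs, nonnegative=False).residual
        r_nn = linear_unmix(stack, refs, nonnegative=True).residual
        assert np.all(r_free <= r_nn + 1e-12)
        # and any solution beats the trivial all-zero one
        norm = np.sqrt(np.mean(spectra ** 2, axis=1)).reshape(r_nn.shape)
        assert np.all(r_nn <= norm + 1e-12)

    def test_permuting_fluorophores_permutes_channels(self, refs, rng):
        abund = rng.uniform(0, 3, size=(1, 4, 4, 6))
        stack = stack_from_abundances(abund, refs)
        perm = ("Cy3", "AMCA", "Cy5", "Alexa532", "Alexa488", "Alexa594")
        out1 = linear_unmix(stack, refs)
        out2 = linear_unmix(stack, refs.reorder(perm))
        for i, f in enumerate(perm):
            np.testing.assert_allclose(out2.abundances[..., i],
                                       out1.channel(f), atol=1e-9)

    def test_grid_mismatch_rejected(self, refs):
        stack = LambdaStack(np.zeros((1, 1, 1, 16)), default_bin_centers(16))
        with pytest.raises(GridMismatchError):
            linear_unmix(stack, refs)

    def test_background_column_absorbs_flat_pedestal(self, refs):
        abund = np.zeros((1, 2, 2, 6))
        abund[0, 0, 0, 3] = 8.0
        stack = LambdaStack(abund @ refs.matrix + 2.0, refs.bin_centers)
        out = linear_unmix(stack, refs, background_column=True)
        assert out.fluorophores[-1] == "background"
        np.testing.assert_allclose(out.channel("Cy3")[0, 0, 0], 8.0, atol=1e-6)
        np.testing.assert_allclose(out.channel("Cy3")[0, 1, 1], 0.0, atol=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(min_value=0.0, max_value=50.0))
    def test_linearity_in_scale(self, refs, scale):
        abund = np.full((1, 2, 2, 6), 1.5)
        base = stack_from_abundances(abund, refs)
        scaled = LambdaStack(base.data * scale, refs.bin_centers)
        out = linear_unmix(scaled, refs)
        np.testing.assert_allclose(out.abundances, scale * abund, atol=1e-7 * (1 + scale))
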