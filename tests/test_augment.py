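"""The five experiment-mimicking augmentation procedures."""

import numpy as np
import pytest

from msfingerprint import (
    AugmentationPlan,
    DatasetTensor,
    MassGrid,
    RawRun,
    ScanRecord,
    TimeGrid,
    alter_intensity,
    augment_dataset,
    augment_sample,
    bin_scan,
    gradient_shrink,
    gradient_stretch,
    grid_run,
    mass_shift,
    stretch_rt,
)
from msfingerprint.augment import _segment_schedule

from conftest import make_sample, oracle_linear_resample


def peak_sample(n_points=100, n_bins=5, peaks=((40, 2, 100.0),), seg_grids=False):
    """A sample with triangular peaks at given (rt_index, mz_index, height)."""
    tg = TimeGrid(t_start=0.0, t_step=0.1, n_points=n_points)
    mg = MassGrid(mz_first=100, n_bins=n_bins)
    m = np.zeros((n_points, n_bins))
    for rt_i, mz_i, h in peaks:
        m[rt_i - 1 : rt_i + 2, mz_i] = (h / 2, h, h / 2)
    return make_sample(m, tg, mg)


class TestStretchRt:
    def test_zero_offset_is_identity(self):
        s = peak_sample()
        np.testing.assert_allclose(stretch_rt(s, 0).matrix, s.matrix)

    def test_constant_chromatogram_stays_constant(self):
        s = peak_sample()
        s.matrix[:] = 7.0
        out = stretch_rt(s, +20).matrix
        np.testing.assert_allclose(out, 7.0)
        out = stretch_rt(s, -20).matrix
        np.testing.assert_allclose(out[:80], 7.0)  # un-padded region
        np.testing.assert_allclose(out[80:], 0.0)  # zero-padded tail

    @pytest.mark.parametrize("k", [30, -30, 7])
    def test_matches_bruteforce_resample_oracle(self, k):
        s = peak_sample(peaks=((40, 2, 100.0), (70, 1, 50.0)))
        out = stretch_rt(s, k).matrix
        n = s.matrix.shape[0]
        for col in range(s.matrix.shape[1]):
            want = oracle_linear_resample(s.matrix[:, col], n + k)
            want = want[:n] if k >= 0 else np.concatenate([want, np.zeros(-k)])
            np.testing.assert_allclose(out[:, col], want, rtol=1e-9, atol=1e-12)

    def test_apex_moves_by_the_resampling_ratio(self):
        s = peak_sample(n_points=300, peaks=((200, 2, 100.0),))
        out = stretch_rt(s, +30).matrix
        apex = out[:, 2].argmax()
        assert apex == pytest.approx(200 * (300 + 30 - 1) / (300 - 1), abs=1.5)

    def test_offset_larger_than_axis_rejected(self):
        with pytest.raises(ValueError):
            stretch_rt(peak_sample(), 100)

    def test_metadata_and_provenance(self):
        v = stretch_rt(peak_sample(), 10)
        assert v.parent_id == "s" and v.label == "roots"
        assert "stretch_rt" in v.provenance


class TestGradientProcedures:
    def test_default_grid_splits_into_15_segments_of_50(self):
        plan = AugmentationPlan()
        tg = TimeGrid()
        assert tg.n_points // plan.segment_len == 15
        schedule = _segment_schedule(15, plan.segment_insert_range)
        assert schedule[0] == 1 and schedule[-1] == 7
        assert all(b >= a for a, b in zip(schedule, schedule[1:]))

    def test_all_zero_sample_stays_zero(self):
        s = peak_sample()
        s.matrix[:] = 0.0
        assert gradient_stretch(s).matrix.sum() == 0.0
        assert gradient_shrink(s).matrix.sum() == 0.0

    def test_late_peak_displaced_more_than_early_peak(self):
        s = peak_sample(n_points=100, peaks=((15, 1, 100.0), (85, 3, 100.0)))
        plan = AugmentationPlan(segment_len=20)  # 5 segments on 100 points
        out = gradient_stretch(s, plan).matrix
        early_shift = out[:, 1].argmax() - 15
        late_shift = out[:, 3].argmax() - 85
        assert late_shift > early_shift >= 0

    def test_matches_segmentwise_resample_oracle(self):
        s = peak_sample(n_points=100, peaks=((15, 1, 100.0), (85, 3, 100.0)))
        plan = AugmentationPlan(segment_len=20)
        schedule = _segment_schedule(5, plan.segment_insert_range)
        for op, sign in ((gradient_stretch, +1), (gradient_shrink, -1)):
            out = op(s, plan).matrix
            for col in range(s.matrix.shape[1]):
                pieces = [
                    oracle_linear_resample(
                        s.matrix[seg * 20 : (seg + 1) * 20, col],
                        20 + sign * schedule[seg],
                    )
                    for seg in range(5)
                ]
                want = np.concatenate(pieces)
                want = (
                    want[:100]
                    if len(want) >= 100
                    else np.concatenate([want, np.zeros(100 - len(want))])
                )
                np.testing.assert_allclose(out[:, col], want, rtol=1e-9, atol=1e-12)

    def test_indivisible_segment_length_rejected(self):
        with pytest.raises(ValueError):
            gradient_stretch(peak_sample(n_points=100), AugmentationPlan(segment_len=30))


class TestMassShift:
    def _run(self):
        scans = [
            ScanRecord(rt=1.0, mz=[100.0, 650.0, 1200.0], intensity=[10.0, 20.0, 30.0]),
            ScanRecord(rt=2.0, mz=[400.0], intensity=[5.0]),
        ]
        return RawRun(sample_id="m", specimen_id="m", replicate=1, label="fruits", scans=scans)

    def test_linear_ramp_anchored_at_scan_range(self):
        out = mass_shift(self._run(), 0.1, 0.6, +1)
        np.testing.assert_allclose(
            out.scans[0].mz, [100.1, 650.35, 1200.6]  # 0.35 = ramp midpoint
        )
        out = mass_shift(self._run(), 0.1, 0.6, -1)
        np.testing.assert_allclose(out.scans[0].mz, [99.9, 649.65, 1199.4])

    def test_intensities_untouched(self):
        out = mass_shift(self._run(), 0.2, 1.0, +1)
        for a, b in zip(self._run().scans, out.scans):
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_small_shift_conserves_regridded_totals(self):
        """Shifts below the residual window width only move bin assignments."""
        mg = MassGrid()
        run = self._run()
        for scan_before, scan_after in zip(
            run.scans, mass_shift(run, 0.1, 0.6, +1).scans
        ):
            assert bin_scan(scan_after, mg).sum() == pytest.approx(
                bin_scan(scan_before, mg).sum()
            )

    def test_inverted_deltas_rejected(self):
        with pytest.raises(ValueError):
            mass_shift(self._run(), 0.6, 0.1, +1)


class TestAlterIntensity:
    def test_scaling_examples(self):
        s = peak_sample()
        s.matrix[10, 2] = 100.0
        assert alter_intensity(s, 1.05).matrix[10, 2] == pytest.approx(105.0)
        np.testing.assert_array_equal(alter_intensity(s, 1.0).matrix, s.matrix)
        assert alter_intensity(s, 0.95).matrix.sum() == pytest.approx(0.95 * s.matrix.sum())

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            alter_intensity(peak_sample(), 0.0)


class TestPlanAndDataset:
    def test_default_plan_multiplier_is_14(self):
        assert AugmentationPlan().expected_multiplier == 14

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            AugmentationPlan(stretch_offsets=(0, 10))
        with pytest.raises(ValueError):
            AugmentationPlan(intensity_factors=(1.0, -0.5))
        with pytest.raises(ValueError):
            AugmentationPlan(mass_shift_variants=((0.6, 0.1, 1),))

    def _run_and_sample(self):
        tg = TimeGrid(t_start=0.0, t_step=0.1, n_points=100)
        mg = MassGrid(mz_first=100, n_bins=8)
        scans = [
            ScanRecord(rt=t, mz=[101.2, 104.5], intensity=[5.0 + t, 3.0])
            for t in np.arange(0.0, 10.0, 0.5)
        ]
        run = RawRun(sample_id="a", specimen_id="spA", replicate=1, label="roots", scans=scans)
        sample = grid_run(run, tg, mg)
        return run, sample

    def test_one_original_yields_15_total(self):
        run, sample = self._run_and_sample()
        plan = AugmentationPlan(segment_len=20)
        tensor = augment_dataset([run], DatasetTensor([sample]), plan)
        assert len(tensor) == 15
        augmented = [s for s in tensor if s.parent_id is not None]
        assert len(augmented) == plan.expected_multiplier == 14
        for v in augmented:
            assert v.label == sample.label
            assert v.specimen_id == sample.specimen_id
            assert v.time_grid == sample.time_grid and v.mass_grid == sample.mass_grid
            assert v.provenance

    def test_empty_input_yields_empty_output(self):
        assert len(augment_dataset([], DatasetTensor([]), AugmentationPlan())) == 0

    def test_missing_raw_run_rejected(self):
        _, sample = self._run_and_sample()
        with pytest.raises(ValueError, match="no raw run"):
            augment_dataset([], DatasetTensor([sample]), AugmentationPlan(segment_len=20))

    def test_intensity_commutes_with_stretching(self):
        _, sample = self._run_and_sample()
        a = alter_intensity(stretch_rt(sample, 10), 1.05).matrix
        b = stretch_rt(alter_intensity(sample, 1.05), 10).matrix
        np.testing.assert_allclose(a, b, atol=1e-9)
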