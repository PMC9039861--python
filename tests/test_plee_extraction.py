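import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import EXAMPLE_RETAINED_PL, make_recording
from _oracles import brute_force_median_plee, median_by_sort, tukey_retained

from plee import (
    BreathModelParams,
    EmptyWindowError,
    ExtractionConfig,
    NoEndExpirationError,
    NoPlateauError,
    batch_process,
    driving_pressure,
    export_project,
    filter_end_expiratory,
    filter_plateau,
    median_plee,
    parse_crf,
    simulate_recording,
    trim_to_experiment,
    tukey_remove_outliers,
)


class TestTrim:
    def test_datastart_zero_is_identity(self, example_rec):
        assert len(trim_to_experiment(example_rec, 0.0)) == len(example_rec)

    def test_trim_example_excerpt(self, example_rec):
        # hand count: 7 printed stamps are >= 0.02 s (0.0234375 ... 0.046875)
        assert len(trim_to_experiment(example_rec, 0.02)) == 7

    def test_datastart_beyond_recording(self, example_rec):
        with pytest.raises(EmptyWindowError):
            trim_to_experiment(example_rec, 1.0)

    def test_optional_dataend(self, example_rec):
        rec = trim_to_experiment(example_rec, 0.0, dataend=0.02)
        assert len(rec) == 6
        assert rec.time[-1] <= 0.02


class TestEndExpiratoryFilter:
    def test_window_bounds_inclusive(self):
        cfg = ExtractionConfig(set_peep=15.0)
        assert cfg.paw_window == (14.0, 16.0)
        rec = make_recording(
            paw=[14.0, 16.0, 16.0 + 1e-9, 13.999, 15.0],
            flow=[0, 10.0, 0, 0, -10.0],
            pl=[1, 2, 3, 4, 5],
        )
        kept = filter_end_expiratory(rec, cfg)
        assert kept.pl.tolist() == [1, 2, 5]  # both bounds of both windows kept

    def test_example_excerpt_at_peep_6(self, example_rec):
        kept = filter_end_expiratory(example_rec, ExtractionConfig(set_peep=6.0))
        assert len(kept) == 12  # the all-zero first row fails the Paw window
        assert kept.pl.tolist() == EXAMPLE_RETAINED_PL

    def test_constant_high_flow_fails(self):
        rec = make_recording(paw=[5.0] * 4, flow=[30.0] * 4, pl=[0.0] * 4)
        with pytest.raises(NoEndExpirationError):
            filter_end_expiratory(rec, ExtractionConfig(set_peep=5.0))


class TestTukey:
    def test_constant_input_unchanged(self):
        kept, removed = tukey_remove_outliers([5.0, 5.0, 5.0, 5.0])
        assert kept.tolist() == [5.0] * 4
        assert removed == 0

    def test_single_outlier(self):
        # interpolated quartiles of {1..4,100}: Q1=2, Q3=4, upper fence 7
        kept, removed = tukey_remove_outliers([1.0, 2.0, 3.0, 4.0, 100.0])
        assert kept.tolist() == [1.0, 2.0, 3.0, 4.0]
        assert removed == 1

    def test_order_preserved(self):
        kept, _ = tukey_remove_outliers([3.0, 1.0, 100.0, 2.0])
        assert kept.tolist() == [3.0, 1.0, 2.0]

    @given(
        st.lists(st.floats(-50, 50, allow_nan=False, width=32), min_size=1, max_size=60),
        st.floats(0.5, 3.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_fence_oracle(self, values, k):
        kept, removed = tukey_remove_outliers(values, k=k)
        expected = tukey_retained(values, k=k)
        assert kept.tolist() == expected
        assert removed == len(values) - len(expected)

    def test_hinges_variant(self):
        # hinges of {1,2,3,4,100}: lower half {1,2,3} -> 2, upper {3,4,100} -> 4
        kept, removed = tukey_remove_outliers(
            [1.0, 2.0, 3.0, 4.0, 100.0], quartile_method="hinges"
        )
        assert kept.tolist() == [1.0, 2.0, 3.0, 4.0]
        assert removed == 1


class TestMedianPlee:
    def test_example_excerpt_median(self, example_rec):
        res = median_plee(example_rec, 0.0, ExtractionConfig(set_peep=6.0))
        expected = median_by_sort(tukey_retained(EXAMPLE_RETAINED_PL))
        assert res.median_plee == expected == 6.3
        assert res.n_total == 13
        assert res.n_endexp == 12
        assert res.n_outliers_removed == 0
        assert res.pl_source == "exported"

    def test_constant_recording(self):
        rec = make_recording(paw=[5.0] * 8, flow=[0.0] * 8, pl=[2.5] * 8)
        res = median_plee(rec, 0.0, ExtractionConfig(set_peep=5.0))
        assert res.median_plee == 2.5

    def test_audit_counts_monotone(self, short_sim):
        _, rec, _ = short_sim
        res = median_plee(rec, 5.0, ExtractionConfig(set_peep=10.0))
        assert res.n_total >= res.n_after_trim >= res.n_endexp >= res.n_retained >= 1

    def test_median_within_retained_range(self, short_sim):
        _, rec, _ = short_sim
        res = median_plee(rec, 0.0, ExtractionConfig(set_peep=10.0))
        kept = filter_end_expiratory(trim_to_experiment(rec, 0.0),
                                     ExtractionConfig(set_peep=10.0))
        assert kept.pl.min() <= res.median_plee <= kept.pl.max()

    def test_order_invariance(self, short_sim):
        _, rec, _ = short_sim
        cfg = ExtractionConfig(set_peep=10.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(rec))
        shuffled = rec.subset(perm)  # time channel stays attached to its samples
        a = median_plee(rec, 3.0, cfg)
        b = median_plee(shuffled, 3.0, cfg)
        assert a.median_plee == b.median_plee
        assert a.n_endexp == b.n_endexp

    def test_pl_derived_from_paw_and_pes_when_absent(self, short_sim):
        _, rec, _ = short_sim
        import dataclasses

        bare = dataclasses.replace(rec, pl=None)
        res = median_plee(bare, 0.0, ExtractionConfig(set_peep=10.0))
        ref = median_plee(rec, 0.0, ExtractionConfig(set_peep=10.0))
        assert res.pl_source == "derived"
        assert res.median_plee == pytest.approx(ref.median_plee, abs=1e-12)

    def test_rounding_convention(self):
        rec = make_recording(paw=[5.0] * 4, flow=[0.0] * 4, pl=[2.55, 2.55, 2.61, 2.61])
        res = median_plee(rec, 0.0, ExtractionConfig(set_peep=5.0))
        assert res.median_plee == pytest.approx(2.58)
        assert res.median_plee_rounded == 2.6

    def test_artifact_robustness(self):
        # <= 5% of samples shifted by >> 10 x IQR must not move the median
        rng = np.random.default_rng(4)
        n = 2000
        pl = rng.normal(2.0, 0.3, n)
        clean = make_recording(paw=[5.0] * n, flow=[0.0] * n, pl=pl.copy())
        cfg = ExtractionConfig(set_peep=5.0)
        ref = median_plee(clean, 0.0, cfg).median_plee
        pl2 = pl.copy()
        idx = rng.choice(n, size=n // 20, replace=False)
        pl2[idx] += 15.0  # ~50 x IQR of the clean distribution
        dirty = make_recording(paw=[5.0] * n, flow=[0.0] * n, pl=pl2)
        res = median_plee(dirty, 0.0, cfg)
        assert res.n_outliers_removed >= len(idx)
        assert abs(res.median_plee - ref) <= 0.2


class TestBruteForceEquivalence:
    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_random_recordings_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 1000))
        rec = make_recording(
            paw=rng.uniform(3.0, 7.0, n),
            flow=rng.uniform(-15.0, 15.0, n),
            pl=rng.uniform(-5.0, 10.0, n),
        )
        datastart = float(rng.uniform(0, n / 512.0))
        cfg = ExtractionConfig(set_peep=5.0)
        expected = brute_force_median_plee(
            rec.time, rec.flow, rec.paw, rec.pl, datastart, 5.0
        )
        try:
            got = median_plee(rec, datastart, cfg).median_plee
        except EmptyWindowError:
            got = "empty-window"
        except NoEndExpirationError:
            got = "no-end-expiration"
        assert got == expected


class TestPlateauAndDrivingPressure:
    def test_plateau_bound_strict(self):
        rec = make_recording(paw=[7.0, 12.0], flow=[0.0, 3.0], pl=[1.0, 2.0])
        kept = filter_plateau(rec, ExtractionConfig(set_peep=5.0))
        assert kept.pl.tolist() == [2.0]  # paw == peep+offset excluded

    def test_pure_expiration_has_no_plateau(self):
        rec = make_recording(paw=[5.1] * 6, flow=[0.0] * 6, pl=[0.0] * 6)
        with pytest.raises(NoPlateauError):
            filter_plateau(rec, ExtractionConfig(set_peep=5.0))

    def test_delta_is_exact_difference(self):
        paw = [5.0] * 6 + [12.0] * 6
        flow = [0.0] * 12
        pl = [2.0] * 6 + [8.0] * 6
        rec = make_recording(paw=paw, flow=flow, pl=pl)
        res = driving_pressure(rec, 0.0, ExtractionConfig(set_peep=5.0))
        assert res.median_plplat == 8.0
        assert res.median_plee == 2.0
        assert res.delta_pl == 6.0

    def test_single_compartment_identity(self):
        # with an end-inspiratory hold, the plateau-to-end-expiration
        # difference equals lung elastance x tidal volume
        params = BreathModelParams(
            set_peep=5.0, pause_fraction=0.1, cardiac_amplitude=0.0,
            noise_sd=0.0, duration_s=60.0,
        )
        rec, _ = simulate_recording(params)
        res = driving_pressure(rec, 0.0, ExtractionConfig(set_peep=5.0))
        expected = params.e_lung * params.tidal_volume_ml / 1000.0
        assert res.delta_pl == pytest.approx(expected, abs=0.3)


class TestBatch:
    def test_grid_shape_and_failure_rows(self, tmp_path):
        base = BreathModelParams(duration_s=30.0, cardiac_amplitude=0.0, noise_sd=0.0)
        export = export_project(
            tmp_path, n_participants=2, peep_levels=(10.0, 5.0),
            base_params=base, seed=3, lead_in_s=5.0,
        )
        # add a CRF row with no matching folder: must fail loudly, not drop
        crf_text = export.crf_path.read_text() + "Ghost,0\n"
        export.crf_path.write_text(crf_text)
        res = batch_process(tmp_path, parse_crf(export.crf_path), [10.0, 5.0])
        assert len(res) == 6  # 3 CRF rows x 2 levels, CRF-order x level-order
        ghost = res[res.id == "Ghost"]
        assert ghost.medianPLee.isna().all()
        assert ghost.error.str.contains("signals.txt").all()
        good = res[res.id != "Ghost"]
        assert good.medianPLee.notna().all()

    def test_empty_peep_levels(self, tmp_path):
        base = BreathModelParams(duration_s=30.0, noise_sd=0.0, cardiac_amplitude=0.0)
        export = export_project(
            tmp_path, n_participants=1, peep_levels=(5.0,), base_params=base, seed=1,
            lead_in_s=0.0,
        )
        res = batch_process(tmp_path, parse_crf(export.crf_path), [])
        assert len(res) == 0
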