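"""Trace extraction, derandomization, response measures and PSTHs."""

import numpy as np
import pytest

from calstack import RoiSet, StackHeader, open_stack
from calstack.baseline import NoBaselineError, assign_blank_frames
from calstack.responses import (
    derandomize,
    extract_region_responses,
    extract_region_traces,
    psth,
)
from calstack.synthetic import SimConfig, generate_and_open

from conftest import write_raw_blocks


def stack_from(tmp_path, data, **hdr):
    base = dict(
        n_rows=data.shape[0], n_cols=data.shape[1],
        n_channels=data.shape[3], dtype="u8",
        frames_per_file=[data.shape[2]],
    )
    base.update(hdr)
    h = StackHeader(**base)
    paths = write_raw_blocks(tmp_path, data.astype(np.uint8),
                             h.frames_per_file)
    h.to_json(str(tmp_path / "h.json"))
    return open_stack(paths, str(tmp_path / "h.json"))


class TestExtractTraces:
    def test_constant_stack(self, tmp_path):
        data = np.full((6, 6, 8, 1), 42, dtype=np.uint8)
        st = stack_from(tmp_path, data)
        tr = extract_region_traces(st, RoiSet((6, 6), [[0, 1, 7]]))
        assert np.allclose(tr.values, 42.0)

    def test_single_pixel_roi_equals_pixel_trace(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 256, size=(6, 6, 10, 2), dtype=np.uint8)
        st = stack_from(tmp_path, data)
        tr = extract_region_traces(st, RoiSet((6, 6), [[13]]))  # pixel (2, 1)
        assert np.allclose(tr.values[0, :, 0], data[2, 1, :, 0])
        assert np.allclose(tr.values[0, :, 1], data[2, 1, :, 1])

    def test_matches_eager_brute_force(self, tmp_path):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 256, size=(8, 8, 12, 1), dtype=np.uint8)
        st = stack_from(tmp_path, data)
        regions = [rng.choice(64, size=5, replace=False) for _ in range(3)]
        tr = extract_region_traces(st, RoiSet((8, 8), regions))
        flat = data.reshape(64, 12, 1).astype(float)
        for k, reg in enumerate(regions):
            assert np.allclose(tr.values[k, :, 0],
                               flat[np.sort(reg), :, 0].mean(axis=0))

    def test_empty_roiset_rejected(self, tmp_path):
        st = stack_from(tmp_path, np.zeros((4, 4, 4, 1), dtype=np.uint8))
        with pytest.raises(ValueError):
            extract_region_traces(st, RoiSet((4, 4), []))

    def test_linearity_of_mean_measure(self, tmp_path):
        """Raw-scale mean extraction is linear in pixel values."""
        rng = np.random.default_rng(2)
        a = rng.integers(0, 100, size=(6, 6, 8, 1), dtype=np.uint8)
        b = rng.integers(0, 100, size=(6, 6, 8, 1), dtype=np.uint8)
        rois = RoiSet((6, 6), [np.arange(6), np.arange(20, 30)])
        ta = extract_region_traces(stack_from(tmp_path / "a", a), rois).values
        (tmp_path / "b").mkdir()
        tb = extract_region_traces(stack_from(tmp_path / "b", b), rois).values
        (tmp_path / "ab").mkdir()
        tab = extract_region_traces(
            stack_from(tmp_path / "ab", a + b), rois
        ).values
        assert np.allclose(tab, ta + tb)


@pytest.fixture(autouse=True)
def _mkdirs(tmp_path):
    (tmp_path / "a").mkdir(exist_ok=True)
    yield


class TestDerandomize:
    def test_hand_derived_two_blocks(self, tmp_path):
        """Block orders [3,1,2] and [2,3,1]: stimulus 1's trials are block 1
        presentation 2 and block 2 presentation 3."""
        data = np.zeros((4, 4, 60, 1), dtype=np.uint8)
        st = stack_from(
            tmp_path, data, frames_per_file=[30, 30],
            t_frame_duration=0.5,
            sequence_ids_per_block=[[3, 1, 2], [2, 3, 1]],
            stimulus_durations=[5.0, 5.0, 5.0],
        )
        tm = derandomize(st.frame_stimulus_info(), st.timeline)
        assert tm.presentation_of_trial[(1, 0)] == 1  # 2nd presentation
        assert tm.presentation_of_trial[(1, 1)] == 5  # 6th overall
        assert tm.n_trials(1) == 2

    def test_identity_order_single_trial(self, tmp_path):
        data = np.zeros((4, 4, 20, 1), dtype=np.uint8)
        st = stack_from(
            tmp_path, data, t_frame_duration=0.5, frames_per_file=[20],
            sequence_ids_per_block=[[1, 2]], stimulus_durations=[5.0, 5.0],
        )
        tm = derandomize(st.frame_stimulus_info(), st.timeline)
        assert np.array_equal(tm.frames(1, 0), np.arange(10))
        assert np.array_equal(tm.frames(2, 0), np.arange(10, 20))

    def test_bijective_against_brute_force_over_seeds(self, tmp_path):
        """50 seeded random block orders: grouping equals a per-stimulus
        brute-force scan and the mapping is injective."""
        rng = np.random.default_rng(0)
        for trial in range(50):
            n_stim = int(rng.integers(2, 6))
            orders = [list(rng.permutation(n_stim) + 1) for _ in range(2)]
            sub = tmp_path / f"t{trial}"
            sub.mkdir()
            per_block = int(np.ceil(n_stim * 2.0 / 0.5))
            data = np.zeros((2, 2, 2 * per_block, 1), dtype=np.uint8)
            st = stack_from(
                sub, data, frames_per_file=[per_block, per_block],
                t_frame_duration=0.5, sequence_ids_per_block=orders,
                stimulus_durations=[2.0] * n_stim,
            )
            fi = st.frame_stimulus_info()
            tm = derandomize(fi, st.timeline)
            allf = tm.all_mapped_frames()
            assert len(allf) == len(np.unique(allf))
            sid_arr = st.timeline.presentation_stim_id
            for sid in tm.stim_ids:
                pres = np.flatnonzero(sid_arr == sid)
                assert tm.n_trials(sid) == len(pres)
                for t_i, p in enumerate(pres):
                    expect = fi.loc[
                        fi["presentation_index"] == p + 1, "frame"
                    ].to_numpy()
                    assert np.array_equal(tm.frames(sid, t_i), expect)


@pytest.fixture(scope="module")
def tuned(tmp_path_factory):
    out = tmp_path_factory.mktemp("resp")
    cfg = SimConfig(
        n_rows=48, n_cols=48, n_channels=1, n_blocks=3, n_stimuli=4,
        stimulus_duration=1.0, blank_time=0.5, n_cells=3, cell_radius=3,
        frame_rate=8.0, amplitudes=1.0, noise_sd=0.0, seed=1,
        orders=[[], [3, 1, 4, 2], [2, 4, 1, 3]],
    )
    stack, gt = generate_and_open(cfg, str(out))
    from calstack.baseline import define_black_region

    define_black_region(stack, gt.black_region)
    assign_blank_frames(stack, np.arange(gt.frames_per_block[0]),
                        (0, stack.n_frames))
    rois = RoiSet((48, 48), gt.cell_masks((48, 48)))
    return stack, gt, rois


class TestExtractResponses:
    def test_shape_and_stim_ids(self, tuned):
        stack, gt, rois = tuned
        m = extract_region_responses(stack, rois)
        assert m.responses.shape == (3, 4, 2)
        assert m.stim_ids == [1, 2, 3, 4]

    def test_peak_dff_matches_ground_truth(self, tuned):
        """Noiseless planted transients: peak dF/F0 equals the planted
        value within quantization."""
        stack, gt, rois = tuned
        m = extract_region_responses(stack, rois, measure="peak", scale="dff")
        ideal = np.asarray(gt.ideal_peak_dff)
        sid_arr = np.asarray(gt.presentation_stim_id)
        quant = 2.0 / 60.0  # one dtype step against F0 = 60, both F and F0
        for s_idx, sid in enumerate(m.stim_ids):
            for t_i, p in enumerate(np.flatnonzero(sid_arr == sid)):
                assert np.allclose(
                    m.responses[:, s_idx, t_i], ideal[:, p], atol=quant
                )

    def test_use_window_excludes_early_transient(self, tmp_path):
        """A transient confined to the first 0.3 s yields ~0 mean response
        when the use window is [0.5, 1.0] s."""
        cfg = SimConfig(
            n_rows=32, n_cols=32, n_channels=1, n_blocks=2, n_stimuli=2,
            stimulus_duration=1.0, blank_time=1.0, n_cells=2, cell_radius=3,
            frame_rate=10.0, amplitudes=1.0, tau=0.08, noise_sd=0.0, seed=2,
            use_times=[[0.5, 1.0], [0.5, 1.0]],
            orders=[[], [1, 2]],
        )
        stack, gt = generate_and_open(cfg, str(tmp_path))
        from calstack.baseline import define_black_region

        define_black_region(stack, gt.black_region)
        assign_blank_frames(stack, np.arange(gt.frames_per_block[0]),
                            (0, stack.n_frames))
        rois = RoiSet((32, 32), gt.cell_masks((32, 32)))
        m = extract_region_responses(stack, rois, measure="mean", scale="dff")
        assert np.nanmax(np.abs(m.responses)) < 0.05

    def test_dff_requires_baseline(self, tuned, tmp_path):
        stack, gt, rois = tuned
        bare, _ = generate_and_open(
            SimConfig(n_rows=32, n_cols=32, n_channels=1, n_blocks=1,
                      n_stimuli=2, stimulus_duration=1.0, blank_time=0.5,
                      n_cells=1, cell_radius=3, frame_rate=8.0, seed=4),
            str(tmp_path),
        )
        with pytest.raises(NoBaselineError):
            extract_region_responses(
                bare, RoiSet((32, 32), [[0, 1]]), scale="dff"
            )

    def test_ratio_measure_on_two_channels(self, tmp_path):
        """Constant channels a=60, b=30 (black 10): ratio = 50/20 = 2.5."""
        data = np.zeros((4, 4, 20, 2), dtype=np.uint8)
        data[:, :, :, 0] = 60
        data[:, :, :, 1] = 30
        st = stack_from(
            tmp_path, data, t_frame_duration=0.5,
            sequence_ids_per_block=[[1]], stimulus_durations=[5.0],
        )
        st.set_black_trace(np.full(20, 10.0))
        m = extract_region_responses(
            st, RoiSet((4, 4), [[0, 5]]), measure="ratio"
        )
        assert np.allclose(m.responses[0, 0, 0], 2.5)

    def test_fret_like_transient_ratio_peak(self, tmp_path):
        """Opposite-gain transient on two channels: the peak of the ratio
        trace equals the analytic (1 + g e^-t/tau) / (1 - g e^-t/tau)."""
        n, f0, g, tau, dt = 16, 100.0, 0.2, 0.6, 0.25
        t = np.arange(n) * dt
        decay = g * np.exp(-t / tau)
        data = np.zeros((4, 4, n, 2))
        data[:, :, :, 0] = f0 * (1 + decay)
        data[:, :, :, 1] = f0 * (1 - decay)
        data = np.rint(data).astype(np.uint8)
        st = stack_from(
            tmp_path, data, t_frame_duration=dt,
            sequence_ids_per_block=[[1]], stimulus_durations=[n * dt],
        )
        from calstack.responses import extract_region_traces as ert

        tr = ert(st, RoiSet((4, 4), [[0]]))
        from calstack.baseline import ratio

        peak = np.nanmax(ratio(tr.values[0, :, 0], tr.values[0, :, 1]))
        expect = (1 + g) / (1 - g)
        assert peak == pytest.approx(expect, abs=2.0 / (f0 * (1 - g)))


class TestPsth:
    def test_identical_trials_equal_any_trial(self, tmp_path):
        rng = np.random.default_rng(5)
        block = rng.integers(0, 256, size=(4, 4, 10, 1), dtype=np.uint8)
        data = np.concatenate([block, block], axis=2)  # two identical blocks
        st = stack_from(
            tmp_path, data, frames_per_file=[10, 10], t_frame_duration=1.0,
            sequence_ids_per_block=[[1, 2], [1, 2]],
            stimulus_durations=[5.0, 5.0],
        )
        rois = RoiSet((4, 4), [[0, 3, 9]])
        m = extract_region_responses(st, rois)
        tr = extract_region_traces(st, rois)
        tm = m.trial_map
        for sid, trace in psth(m).items():
            single = tr.values[:, tm.frames(sid, 0)[: trace.shape[1]], 0]
            assert np.allclose(trace, single)

    def test_truncation_to_min_trial_length(self, tmp_path):
        data = np.zeros((4, 4, 33, 1), dtype=np.uint8)
        st = stack_from(
            tmp_path, data, frames_per_file=[17, 16], t_frame_duration=1.0,
            sequence_ids_per_block=[[1], [1]], stimulus_durations=[16.0],
        )
        m = extract_region_responses(st, RoiSet((4, 4), [[0]]))
        # trial 1 catches 16 frames, trial 2 also 16 -> craft different:
        assert psth(m)[1].shape[1] == min(
            len(m.trial_map.frames(1, 0)), len(m.trial_map.frames(1, 1))
        )

    def test_equals_stacked_mean_oracle(self, tuned):
        stack, gt, rois = tuned
        m = extract_region_responses(stack, rois)
        tr = extract_region_traces(stack, rois)
        tm = m.trial_map
        for sid, trace in psth(m).items():
            n = trace.shape[1]
            stacked = np.stack(
                [tr.values[:, tm.frames(sid, t)[:n], 0]
                 for t in range(tm.n_trials(sid))]
            )
            assert np.allclose(trace, stacked.mean(axis=0))
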