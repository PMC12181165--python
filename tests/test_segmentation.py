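"""Background modeling, thresholding and contour filtering."""

import numpy as np
import pytest

from nematrack.errors import ParameterError
from nematrack.segmentation import (
    BackgroundModel,
    build_background,
    filter_edge_touching,
    filter_min_size,
    find_contours,
    preprocess_frame,
    segment_frame,
)
from nematrack.video_io import FrameSequence


def constant_seq(value=180, n=4):
    return FrameSequence(np.full((n, 20, 20), value, dtype=np.uint8), 7.5)


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 < radius**2


class TestBackground:
    def test_constant_sequence_reference_is_that_constant(self):
        bg = build_background(constant_seq(180))
        assert np.all(bg.reference == 180)

    def test_moving_worm_absent_from_reference(self, two_worm_rendered):
        seq, _ = two_worm_rendered
        bg = build_background(seq)
        scene = 200  # generator substrate intensity
        assert np.abs(bg.reference.astype(int) - scene).mean() < 2

    def test_oversized_stride_degenerates_to_first_frame(self):
        frames = np.stack(
            [np.full((8, 8), 50, np.uint8), np.full((8, 8), 200, np.uint8)]
        )
        bg = build_background(FrameSequence(frames, 7.5), sample_stride=10)
        assert np.all(bg.reference == 50)

    def test_stride_below_one_rejected(self):
        with pytest.raises(ParameterError):
            build_background(constant_seq(), 0)


class TestPreprocess:
    def test_frame_identical_to_reference_gives_empty_mask(self):
        bg = BackgroundModel(np.full((20, 20), 180, np.uint8))
        mask = preprocess_frame(np.full((20, 20), 180, np.uint8), bg)
        assert not mask.any()

    def test_dimension_mismatch_rejected(self):
        bg = BackgroundModel(np.full((20, 20), 180, np.uint8))
        with pytest.raises(ParameterError):
            preprocess_frame(np.zeros((10, 10), np.uint8), bg)

    def test_worm_mask_recovers_ground_truth_pixels(self, two_worm_rendered):
        """Foreground pixel count within 15% of the rendered body pixels."""
        seq, truth = two_worm_rendered
        bg = build_background(seq)
        for f in (0, 20, 39):
            mask = preprocess_frame(seq.frames[f], bg)
            gt = truth.table.query(f"frame == {f}")["pixels"].sum()
            assert mask.sum() == pytest.approx(gt, rel=0.15)

    def test_salt_noise_removed_by_opening(self):
        bg = BackgroundModel(np.full((40, 40), 200, np.uint8))
        frame = np.full((40, 40), 200, np.uint8)
        frame[disc_mask((40, 40), (20, 20), 6)] = 60  # a real object
        rng = np.random.default_rng(1)
        salt = rng.choice(40 * 40, size=15, replace=False)
        flat = frame.reshape(-1)
        for idx in salt:
            if not disc_mask((40, 40), (20, 20), 9).reshape(-1)[idx]:
                flat[idx] = 60  # isolated dark pixels
        mask = preprocess_frame(frame, bg)
        labels_on = np.argwhere(mask)
        # every surviving pixel belongs to the disc, not to the salt
        assert len(labels_on) > 0
        assert np.all((labels_on - 20) ** 2 @ np.ones(2) < 9**2)

    def test_static_debris_never_becomes_foreground(self):
        """A dark patch present in every frame is removed as an artifact."""
        frames = np.full((6, 40, 40), 200, np.uint8)
        frames[:, 5:12, 5:12] = 60  # static debris in all frames
        worm = disc_mask((40, 40), (28, 28), 5)
        frames[3][worm] = 60  # a worm visits frame 3 only
        seq = FrameSequence(frames, 7.5)
        bg = build_background(seq)
        mask = preprocess_frame(seq.frames[3], bg)
        assert not mask[5:12, 5:12].any()
        assert mask[worm].mean() > 0.8


class TestContours:
    def test_two_disjoint_discs_two_observations(self):
        mask = disc_mask((40, 60), (15, 15), 6) | disc_mask((40, 60), (25, 45), 6)
        assert len(find_contours(mask, 0)) == 2

    def test_empty_mask_no_observations(self):
        assert find_contours(np.zeros((10, 10), bool), 0) == []

    def test_rectangle_area_by_construction(self):
        mask = np.zeros((30, 40), bool)
        mask[5:15, 10:30] = True  # 10 x 20
        (obs,) = find_contours(mask, 2)
        assert obs.area_px == 200
        assert obs.frame_index == 2
        assert obs.bbox == (10, 5, 30, 15)

    def test_mask_pixel_count_equals_area(self, two_worm_rendered):
        seq, _ = two_worm_rendered
        bg = build_background(seq)
        for obs in segment_frame(seq.frames[10], bg, 10, 100):
            assert obs.mask.sum() == obs.area_px


class TestFilters:
    def areas(self, obs):
        return [o.area_px for o in obs]

    def make(self, areas):
        out = []
        for a in areas:
            side = int(np.ceil(np.sqrt(a)))
            mask = np.zeros((side, side + 1), bool)
            mask.reshape(-1)[:a] = True
            out.append(
                find_contours(np.pad(mask, 2), 0)[0]
            )
        for o, a in zip(out, areas):
            assert o.area_px == a
        return out

    def test_min_size_threshold_is_inclusive(self):
        obs = self.make([50, 200, 500])
        assert self.areas(filter_min_size(obs, 100)) == [200, 500]
        assert self.areas(filter_min_size(obs, 0)) == [50, 200, 500]
        assert self.areas(filter_min_size(obs, 200)) == [200, 500]

    def test_edge_touching_removed(self):
        inner = disc_mask((40, 40), (20, 20), 6)
        clipped = disc_mask((40, 40), (20, 0), 6)
        obs = find_contours(inner | clipped, 0)
        kept = filter_edge_touching(obs, 40, 40)
        assert len(obs) == 2 and len(kept) == 1
        assert kept[0].bbox[0] > 0

    def test_filters_idempotent_and_commute(self, two_worm_rendered):
        seq, _ = two_worm_rendered
        bg = build_background(seq)
        obs = find_contours(preprocess_frame(seq.frames[5], bg), 5)
        a = filter_edge_touching(filter_min_size(obs, 100), seq.width, seq.height)
        b = filter_min_size(filter_edge_touching(obs, seq.width, seq.height), 100)
        assert [o.bbox for o in a] == [o.bbox for o in b]
        assert [o.bbox for o in filter_min_size(a, 100)] == [o.bbox for o in a]

    def test_border_crossing_worm_absent_only_in_those_frames(self):
        """A worm scripted to exit the frame is filtered exactly while out."""
        from nematrack.synthetic import SceneSpec, WormSpec, render_scene

        # body along x, drifting toward the top border (perpendicular to
        # its axis, so each pixel is only briefly covered and the
        # background stays clean)
        spec = WormSpec(
            length_um=500,
            width_um=50,
            drift_um_s=(0.0, -120.0),
            freq_hz=0.0,
            kappa0_per_um=0.0,
            init_pos_um=(500.0, 200.0),
            heading_rad=0.0,
        )
        scene = SceneSpec(
            worms=[spec], width_px=200, height_px=200, frame_rate=7.5, n_frames=20, seed=9
        )
        seq, truth = render_scene(scene)
        bg = build_background(seq)
        border_frames = set(truth.flags(0, "border"))
        assert border_frames  # scene really does reach the border
        rows = truth.worm_rows(0).set_index("frame")
        for f in range(seq.n_frames):
            n = len(segment_frame(seq.frames[f], bg, f, 100))
            in_frame = rows.loc[f, "pixels"] > 0
            expected = 1 if (in_frame and f not in border_frames) else 0
            assert n == expected, f"frame {f}"


def test_observation_count_matches_worm_count(two_worm_rendered, cfg):
    """On clean scenes, one observation per simulated worm per frame."""
    seq, truth = two_worm_rendered
    bg = build_background(seq)
    for f in range(0, seq.n_frames, 7):
        assert len(segment_frame(seq.frames[f], bg, f, cfg.min_size_px)) == 2
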