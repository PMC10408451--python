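import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inrfqa import (
    ConfigurationError,
    INRFParams,
    InvalidInputError,
    ShapeMismatchError,
    VideoSequence,
    inrf_iqa,
    inrf_vqa,
    plan_alignment,
    read_video,
    scale_params,
)
from inrfqa._exceptions import InvalidParameterError
from inrfqa.synth import (
    DistortionSpec,
    apply_distortion,
    make_image,
    make_video,
    save_frames,
    write_y4m,
)

# ---------------------------------------------------------------------------
# scale_params
# ---------------------------------------------------------------------------


def test_scale_factor_2k():
    scaled = scale_params(frame_width=1920, base_width=512)
    assert scaled.scale_factor == 3.75
    assert scaled.sigma_w == 25.0 * 3.75
    assert scaled.lam == 3.0  # unchanged


def test_scale_identity():
    base = INRFParams()
    scaled = scale_params(base, frame_width=512)
    assert scaled.scale_factor == 1.0
    assert (scaled.sigma_m, scaled.sigma_w, scaled.sigma_g) == (
        base.sigma_m,
        base.sigma_w,
        base.sigma_g,
    )


def test_scale_1280():
    scaled = scale_params(frame_width=1280, base_width=512)
    assert scaled.scale_factor == 2.5
    assert scaled.sigma_w == 62.5


def test_scale_invalid_widths():
    with pytest.raises(InvalidParameterError):
        scale_params(frame_width=0)
    with pytest.raises(InvalidParameterError):
        scale_params(frame_width=100, base_width=0)


# ---------------------------------------------------------------------------
# plan_alignment
# ---------------------------------------------------------------------------


def test_plan_drop_2to1():
    plan = plan_alignment(120, 60, "drop_reference")
    assert plan.ref_indices == tuple(range(0, 120, 2))
    assert plan.dist_indices == tuple(range(60))


def test_plan_equal_counts():
    for strategy in ("drop_reference", "duplicate_distorted"):
        plan = plan_alignment(4, 4, strategy)
        assert plan.ref_indices == (0, 1, 2, 3)
        assert plan.dist_indices == (0, 1, 2, 3)


def test_plan_duplicate_4to1():
    plan = plan_alignment(120, 30, "duplicate_distorted")
    assert plan.ref_indices == tuple(range(120))
    expected = tuple(i * 30 // 120 for i in range(120))
    assert plan.dist_indices == expected
    # each distorted index repeated exactly 4 times
    assert all(plan.dist_indices.count(k) == 4 for k in range(30))


def test_plan_upsampling_direction_rejected():
    with pytest.raises(InvalidInputError):
        plan_alignment(30, 120, "drop_reference")


def test_plan_unknown_strategy():
    with pytest.raises(InvalidParameterError):
        plan_alignment(10, 5, "interpolate")


@given(
    n_dist=st.integers(1, 40),
    mult=st.integers(1, 5),
    extra=st.integers(0, 7),
    strategy=st.sampled_from(["drop_reference", "duplicate_distorted"]),
)
@settings(max_examples=60, deadline=None)
def test_plan_properties(n_dist, mult, extra, strategy):
    n_ref = n_dist * mult + extra
    plan = plan_alignment(n_ref, n_dist, strategy)
    assert len(plan.ref_indices) == len(plan.dist_indices)
    assert all(0 <= i < n_ref for i in plan.ref_indices)
    assert all(0 <= j < n_dist for j in plan.dist_indices)
    assert list(plan.ref_indices) == sorted(plan.ref_indices)
    assert list(plan.dist_indices) == sorted(plan.dist_indices)
    if strategy == "drop_reference":
        assert plan.dist_indices == tuple(range(n_dist))
    else:
        assert plan.ref_indices == tuple(range(n_ref))


# ---------------------------------------------------------------------------
# inrf_vqa
# ---------------------------------------------------------------------------


@pytest.fixture
def base_frame():
    return make_image("filtered_noise", size=32, seed=5)


def test_vqa_identity(base_frame):
    video = make_video(base_frame, n_frames=4, motion="pan")
    assert inrf_vqa(video, video).value == 0.0


def test_vqa_constant_frames_equals_iqa(base_frame):
    dist_frame = apply_distortion(
        base_frame, DistortionSpec("gaussian_noise", 0.05, seed=1)
    )
    ref = make_video(base_frame, n_frames=3, motion="static")
    dist = make_video(dist_frame, n_frames=3, motion="static")
    result = inrf_vqa(ref, dist)
    expected = inrf_iqa(base_frame, dist_frame, result.params)
    assert result.value == pytest.approx(expected, abs=0)


def test_vqa_pooled_is_mean_and_bounded(base_frame):
    ref = make_video(base_frame, n_frames=8, motion="pan")
    noisy_frames = [
        apply_distortion(f, DistortionSpec("gaussian_noise", 0.03, seed=i))
        for i, f in enumerate(ref.frames[::2])
    ]
    dist = VideoSequence(frames=noisy_frames, fps=ref.fps / 2)
    result = inrf_vqa(ref, dist, strategy="drop_reference")
    assert result.value == pytest.approx(np.mean(result.per_frame), abs=1e-15)
    assert min(result.per_frame) <= result.value <= max(result.per_frame)


def test_vqa_per_frame_recomputation(base_frame):
    """Score equals the hand-computed mean over the aligned pairs."""
    ref = make_video(base_frame, n_frames=8, motion="pan")
    dist_frames = [
        apply_distortion(ref.frames[2 * i], DistortionSpec("gaussian_noise", 0.04, seed=i))
        for i in range(4)
    ]
    dist = VideoSequence(frames=dist_frames, fps=15.0)
    result = inrf_vqa(ref, dist, strategy="drop_reference")
    assert result.plan.ref_indices == (0, 2, 4, 6)
    by_hand = np.mean(
        [
            inrf_iqa(ref.frames[2 * i], dist_frames[i], result.params)
            for i in range(4)
        ]
    )
    assert result.value == pytest.approx(by_hand, abs=1e-12)


def test_vqa_strategies_agree_on_equal_counts(base_frame):
    ref = make_video(base_frame, n_frames=4, motion="pan")
    dist_frames = [
        apply_distortion(f, DistortionSpec("gaussian_blur", 1.0, seed=0))
        for f in ref.frames
    ]
    dist = VideoSequence(frames=dist_frames, fps=ref.fps)
    a = inrf_vqa(ref, dist, strategy="drop_reference")
    b = inrf_vqa(ref, dist, strategy="duplicate_distorted")
    assert a.value == b.value


def test_vqa_scale_identity_at_512():
    frame = np.tile(make_image("filtered_noise", size=32, seed=2), (1, 16))  # 32x512
    noisy = apply_distortion(frame, DistortionSpec("gaussian_noise", 0.05, seed=3))
    ref = VideoSequence(frames=[frame], fps=30.0)
    dist = VideoSequence(frames=[noisy], fps=30.0)
    result = inrf_vqa(ref, dist)
    assert result.params.scale_factor == 1.0
    assert result.value == inrf_iqa(frame, noisy)


def test_vqa_frame_permutation_invariance(base_frame):
    ref = make_video(base_frame, n_frames=4, motion="pan")
    dist_frames = [
        apply_distortion(f, DistortionSpec("gaussian_noise", 0.04, seed=7))
        for f in ref.frames
    ]
    perm = [2, 0, 3, 1]
    a = inrf_vqa(ref, VideoSequence(dist_frames, fps=30.0))
    b = inrf_vqa(
        VideoSequence([ref.frames[i] for i in perm], fps=30.0),
        VideoSequence([dist_frames[i] for i in perm], fps=30.0),
    )
    assert a.value == pytest.approx(b.value, abs=1e-15)


def test_vqa_resolution_mismatch(base_frame):
    ref = make_video(base_frame, n_frames=2)
    dist = make_video(base_frame[:, :-2], n_frames=2)
    with pytest.raises(ShapeMismatchError):
        inrf_vqa(ref, dist)


def test_video_sequence_validation():
    with pytest.raises(InvalidInputError):
        VideoSequence(frames=[], fps=30.0)
    with pytest.raises(ShapeMismatchError):
        VideoSequence(frames=[np.zeros((4, 4)), np.zeros((4, 5))], fps=30.0)


# ---------------------------------------------------------------------------
# read_video
# ---------------------------------------------------------------------------


def test_read_frame_directory(tmp_path):
    video = make_video(make_image("disk", size=16, seed=0), n_frames=3, motion="pan")
    save_frames(video, tmp_path)
    loaded = read_video(tmp_path, fps=30.0)
    assert len(loaded) == 3
    assert loaded.width == 16
    # name order == temporal order; PNG round trip is 8-bit exact
    for orig, back in zip(video.frames, loaded.frames):
        assert np.array_equal(np.asarray(back), np.round(orig * 255).astype(np.uint8))


def test_read_y4m_roundtrip(tmp_path):
    video = make_video(make_image("sinusoid", size=16, seed=1), n_frames=2, fps=24.0)
    path = tmp_path / "clip.y4m"
    write_y4m(video, path)
    loaded = read_video(path)
    assert len(loaded) == 2
    assert (loaded.height, loaded.width) == (16, 16)
    assert loaded.fps == 24.0
    # quantization to 8 bits only
    assert np.abs(loaded.frames[0] - video.frames[0]).max() <= 1 / 255 + 1e-12


def test_read_raw_yuv420_with_sidecar(tmp_path):
    w, h, n = 8, 6, 3
    rng = np.random.default_rng(0)
    planes = []
    for _ in range(n):
        y = rng.integers(0, 256, size=(h, w), dtype=np.uint8)
        u = np.full((h // 2, w // 2), 128, dtype=np.uint8)
        planes.append(y.tobytes() + u.tobytes() + u.tobytes())
    path = tmp_path / "clip.yuv"
    path.write_bytes(b"".join(planes))
    (tmp_path / "clip.yuv.json").write_text(
        json.dumps({"width": w, "height": h, "fps": 25, "pix_fmt": "yuv420p"})
    )
    loaded = read_video(path)
    assert len(loaded) == n  # exactly W*H*1.5*N bytes -> N frames
    assert (loaded.height, loaded.width) == (h, w)
    assert loaded.fps == 25.0


def test_read_raw_yuv_missing_geometry(tmp_path):
    path = tmp_path / "clip.yuv"
    path.write_bytes(b"\x00" * 96)
    with pytest.raises(ConfigurationError):
        read_video(path)
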