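"""Contrast floor subtraction, shift/speed estimation, volume stitching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mmfscope as m
from mmfscope import PhantomSpec, make_drift_record, make_scene


def test_floor_subtract_removes_lowest_percentile_mean():
    """On a 100-pixel frame whose single lowest pixel is 7, fraction 0.01
    subtracts exactly 7 everywhere (clamped at zero)."""
    data = np.full((10, 10), 20.0)
    data[3, 4] = 7.0
    out = m.floor_subtract(data, 0.01)
    assert np.isclose(out[0, 0], 13.0)
    assert out[3, 4] == 0.0


def test_floor_subtract_constant_frame_zeroes():
    assert np.all(m.floor_subtract(np.full((6, 7), 3.3), 0.01) == 0)


def test_floor_subtract_fraction_validation():
    with pytest.raises(ValueError):
        m.floor_subtract(np.ones((4, 4)), 0.0)
    with pytest.raises(ValueError):
        m.floor_subtract(np.ones((4, 4)), 1.0)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.01, 0.5))
def test_floor_subtract_matches_sorting_oracle(seed, fraction):
    """Partition-based implementation equals the brute-force
    sort-and-average oracle exactly."""
    rng = np.random.default_rng(seed)
    data = rng.random((13, 11)) * 50
    k = int(np.ceil(fraction * data.size))
    oracle = np.clip(data - np.sort(data.ravel())[:k].mean(), 0, None)
    assert np.array_equal(m.floor_subtract(data, fraction), oracle)


@pytest.fixture(scope="module")
def textured_frame():
    rng = np.random.default_rng(5)
    base = rng.random((120, 40))
    from scipy.ndimage import gaussian_filter
    return gaussian_filter(base, 2.0)


def test_shift_integer_translation(textured_frame):
    a = textured_frame[10:90]
    b = textured_frame[13:93]  # scene advanced 3 rows past the probe
    assert abs(m.estimate_shift(a, b) - 3.0) <= 0.1


def test_shift_zero_translation(textured_frame):
    a = textured_frame[10:90]
    assert m.estimate_shift(a, a) == 0.0


def test_shift_subpixel_translation(textured_frame):
    """Band-limited 2.5-row translation recovered to ±0.25 rows."""
    from scipy.ndimage import fourier_shift
    a = textured_frame[20:84]
    shifted = np.fft.ifftn(
        fourier_shift(np.fft.fftn(textured_frame), (-2.5, 0))).real
    b = shifted[20:84]
    assert abs(m.estimate_shift(a, b) - 2.5) <= 0.25


def test_shift_flat_overlap_rejected():
    with pytest.raises(ValueError, match="flat"):
        m.estimate_shift(np.ones((40, 10)), np.ones((40, 10)))


@pytest.fixture(scope="module")
def drift_setup():
    scene = make_scene(PhantomSpec(
        kind="neurons", seed=2,
        params={"shape": (2, 200, 40), "voxel_size": (2.5, 1.0, 1.0),
                "n_somata": 12}))
    iz = int(np.argmax(scene.density.sum(axis=(1, 2))))
    plan = m.ScanPlan(mode="raster", field_of_view=(40.0, 40.0),
                      pixel_pitch=1.0, plane_offsets=(iz * 2.5,))
    return scene, iz, plan


def test_speed_estimate_on_integer_drift(drift_setup):
    """3 px/frame phantom drift recovered within 0.1 px/frame."""
    scene, _, plan = drift_setup
    record = make_drift_record(scene, speed=0.9, plan=plan,
                               frame_rate=0.3, n_stacks=15)
    assert abs(m.estimate_speed(record) - 3.0) <= 0.1


def test_speed_zero_drift(drift_setup):
    scene, _, plan = drift_setup
    record = make_drift_record(scene, speed=0.0, plan=plan,
                               frame_rate=0.3, n_stacks=4)
    # speed 0 means identical stacks; shift is exactly zero
    assert m.estimate_speed(record) == 0.0


def test_speed_invariant_to_intensity_scaling(drift_setup):
    scene, _, plan = drift_setup
    record = make_drift_record(scene, speed=0.9, plan=plan,
                               frame_rate=0.3, n_stacks=10)
    scaled_stacks = []
    for st_ in record.stacks:
        frames = [m.Frame(data=f.data * 7.5, plan=f.plan, plane_z=f.plane_z,
                          timestamp=f.timestamp) for f in st_.frames]
        scaled_stacks.append(m.ZStack(frames=frames))
    scaled = m.ScanRecord(stacks=scaled_stacks, frame_rate=record.frame_rate)
    assert np.isclose(m.estimate_speed(scaled), m.estimate_speed(record))


def test_stitch_recovers_static_scene(drift_setup):
    """Noiseless integer-speed record stitches back to the ground-truth
    scene with sub-percent RMSE."""
    scene, iz, plan = drift_setup
    record = make_drift_record(scene, speed=0.9, plan=plan,
                               frame_rate=0.3, n_stacks=15)
    vol = m.stitch(record, 3.0)
    g = vol.volume.shape[1]
    gt = scene.density[iz][:g, :40]
    rmse = np.sqrt(np.mean((vol.volume[0] - gt) ** 2))
    assert rmse / (gt.max() - gt.min()) < 0.02


def test_stitch_averages_overlap_pixels():
    plan = m.ScanPlan(mode="raster", field_of_view=(4, 4), pixel_pitch=1.0,
                      plane_offsets=(0.0,))
    f1 = m.Frame(data=np.full((4, 4), 2.0), plan=plan, plane_z=0.0)
    f2 = m.Frame(data=np.full((4, 4), 4.0), plan=plan, plane_z=0.0)
    record = m.ScanRecord(stacks=[m.ZStack(frames=[f1]), m.ZStack(frames=[f2])],
                          frame_rate=1.0)
    vol = m.stitch(record, 2.0)
    overlap = vol.sample_count[0] == 2
    assert np.all(vol.volume[0][overlap] == 3.0)


def test_stitch_sample_count_matches_geometry(drift_setup):
    """Steady-region overlap equals ceil(frame_height / speed)."""
    scene, _, plan = drift_setup
    record = make_drift_record(scene, speed=1.2, plan=plan,
                               frame_rate=0.3, n_stacks=30)
    speed = 4.0
    vol = m.stitch(record, speed)
    mid = vol.sample_count[0, 60:80, :]
    assert np.all(mid == int(np.ceil(40 / speed)))


def test_stitch_speed_validation(drift_setup):
    scene, _, plan = drift_setup
    record = make_drift_record(scene, speed=0.9, plan=plan,
                               frame_rate=0.3, n_stacks=4)
    with pytest.raises(ValueError):
        m.stitch(record, 0.0)


def test_identical_uniform_frames_stitch_to_constant_axis():
    """A record of identical frames, each uniform along the insertion
    axis, stitches to a volume constant along that axis."""
    plan = m.ScanPlan(mode="raster", field_of_view=(8, 6), pixel_pitch=1.0,
                      plane_offsets=(0.0,))
    rng = np.random.default_rng(3)
    img = np.tile(rng.random(6), (8, 1))
    stacks = [m.ZStack(frames=[m.Frame(data=img.copy(), plan=plan, plane_z=0.0)])
              for _ in range(5)]
    record = m.ScanRecord(stacks=stacks, frame_rate=1.0)
    vol = m.stitch(record, 3.0)
    assert np.allclose(vol.volume[0], vol.volume[0][:1, :])


def test_end_to_end_drift_recovery(drift_setup):
    """Floor-subtract → speed estimate → stitch recovers the phantom:
    speed within 5%, stitched volume NCC > 0.95 against ground truth."""
    scene, iz, plan = drift_setup
    record = make_drift_record(scene, speed=1.0, plan=plan,
                               frame_rate=0.3, n_stacks=20)
    cleaned = m.ScanRecord(
        stacks=[m.ZStack(frames=[m.floor_subtract(f, 0.01) for f in s.frames])
                for s in record.stacks],
        frame_rate=record.frame_rate)
    speed = m.estimate_speed(cleaned)
    true_speed = 1.0 / 0.3 / 1.0  # µm/s / Hz / (µm/px)
    assert abs(speed - true_speed) / true_speed < 0.05
    vol = m.stitch(cleaned, speed)
    g = vol.volume.shape[1]
    gt = scene.density[iz][:g, :40]
    a = gt.ravel() - gt.mean()
    b = vol.volume[0].ravel() - vol.volume[0].mean()
    ncc = (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
    assert ncc > 0.95
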