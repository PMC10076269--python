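"""Scan engine: raster frames, z-stacks, line scans, ROI traces."""

import numpy as np
import pytest

import mmfscope as m


def _point_scene(grid_pitch=0.25, half_extent=2.5, z=0.0):
    n = int(round(2 * half_extent / grid_pitch)) + 1
    density = np.zeros((1, n, n))
    density[0, n // 2, n // 2] = 1.0
    return m.Scene(density=density, voxel_size=(1.0, grid_pitch, grid_pitch),
                   origin=(z, -half_extent, -half_extent))


@pytest.fixture(scope="module")
def raster_plan(small_fiber):
    pitch = small_fiber.grid.pitch
    return m.ScanPlan(mode="raster", field_of_view=(4.8, 4.8),
                      pixel_pitch=pitch, plane_offsets=(0.0,))


def test_empty_scene_gives_zero_frame(small_fiber, raster_plan):
    scene = m.Scene(density=np.zeros((1, 8, 8)), voxel_size=(1, 0.5, 0.5),
                    origin=(0, -2, -2))
    frame = m.scan_frame(small_fiber.tm, small_fiber.op, scene, raster_plan)
    assert np.all(frame.data == 0)


def test_point_emitter_reproduces_focus_footprint(small_fiber, raster_plan):
    """Imaging a sub-resolution bead traces out the excitation PSF:
    frame FWHM within 15% of the focus-intensity FWHM."""
    scene = _point_scene()
    frame = m.scan_frame(small_fiber.tm, small_fiber.op, scene, raster_plan)
    img = frame.data
    out, _ = m.synthesize_focus(small_fiber.tm, small_fiber.op,
                                small_fiber.grid.index_of(0.0, 0.0))
    psf = np.abs(out) ** 2

    def fwhm(profile, pitch):
        prof = profile - profile.min()
        peak = prof.max()
        i0 = int(np.argmax(prof))
        # interpolated half-max crossings either side of the peak
        left = np.interp(0.5 * peak, prof[:i0 + 1], np.arange(i0 + 1))
        right_seg = prof[i0:][::-1]
        right = len(prof) - 1 - np.interp(0.5 * peak, right_seg,
                                          np.arange(len(right_seg)))
        return (right - left) * pitch

    iy, ix = np.unravel_index(np.argmax(img), img.shape)
    w_frame = fwhm(img[iy, :], raster_plan.pixel_pitch)
    jy, jx = np.unravel_index(np.argmax(psf), psf.shape)
    w_psf = fwhm(psf[jy, :], small_fiber.grid.pitch)
    assert abs(w_frame - w_psf) / w_psf < 0.15


def test_noiseless_imaging_linear_in_density(small_fiber, raster_plan, rng):
    shape = (2, 10, 10)
    kw = dict(voxel_size=(1.0, 0.5, 0.5), origin=(0.0, -2.5, -2.5))
    s1 = m.Scene(density=rng.random(shape), **kw)
    s2 = m.Scene(density=rng.random(shape), **kw)
    s12 = m.Scene(density=s1.density + s2.density, **kw)
    f1 = m.scan_frame(small_fiber.tm, small_fiber.op, s1, raster_plan).data
    f2 = m.scan_frame(small_fiber.tm, small_fiber.op, s2, raster_plan).data
    f12 = m.scan_frame(small_fiber.tm, small_fiber.op, s12, raster_plan).data
    assert np.allclose(f12, f1 + f2, rtol=1e-9, atol=1e-12)
    f2x = m.scan_frame(small_fiber.tm, small_fiber.op,
                       m.Scene(density=2 * s1.density, **kw), raster_plan).data
    assert np.allclose(f2x, 2 * f1, rtol=1e-9)


def test_point_signal_independent_of_lateral_position(small_fiber, raster_plan):
    """Total collected signal is uniform across the central 80% FOV."""
    totals = []
    for (y0, x0) in [(0.0, 0.0), (1.2, 0.0), (0.0, -1.2), (0.9, 0.9)]:
        scene = _point_scene()
        scene = m.Scene(density=scene.density, voxel_size=scene.voxel_size,
                        origin=(0.0, -2.5 + y0, -2.5 + x0))
        frame = m.scan_frame(small_fiber.tm, small_fiber.op, scene, raster_plan)
        totals.append(frame.data.sum())
    totals = np.array(totals)
    assert totals.std() / totals.mean() < 0.10


def test_zstack_shape_and_plane_selection(small_fiber):
    offsets = (0.0, 2.5, 5.0)
    ladder = [small_fiber.tm] + [
        m.refocus_tm(small_fiber.tm, m.RefocusSpec(z=z)) for z in offsets[1:]
    ]
    plan = m.ScanPlan(mode="raster", field_of_view=(3.0, 3.0),
                      pixel_pitch=small_fiber.grid.pitch,
                      plane_offsets=offsets)
    scene = _point_scene(z=2.5)
    stack = m.scan_zstack(ladder, small_fiber.op, scene, plan)
    arr = stack.as_array()
    assert arr.shape[0] == len(offsets)
    assert stack.plane_offsets == list(offsets)
    # emitter at z = 2.5 µm is brightest in the matching plane
    assert int(np.argmax(arr.max(axis=(1, 2)))) == 1


def test_zstack_missing_plane_names_offset(small_fiber):
    plan = m.ScanPlan(mode="raster", field_of_view=(3.0, 3.0),
                      pixel_pitch=0.3, plane_offsets=(0.0, 2.5))
    scene = _point_scene()
    with pytest.raises(KeyError, match="2.5"):
        m.scan_zstack(small_fiber.tm, small_fiber.op, scene, plan)


def test_zstack_plane_order_irrelevant(small_fiber):
    offsets = (0.0, 2.5)
    ladder = [small_fiber.tm, m.refocus_tm(small_fiber.tm, m.RefocusSpec(z=2.5))]
    scene = _point_scene()
    kw = dict(field_of_view=(3.0, 3.0), pixel_pitch=small_fiber.grid.pitch)
    s1 = m.scan_zstack(ladder, small_fiber.op, scene,
                       m.ScanPlan(mode="raster", plane_offsets=offsets, **kw))
    s2 = m.scan_zstack(ladder, small_fiber.op, scene,
                       m.ScanPlan(mode="raster", plane_offsets=offsets[::-1], **kw))
    assert np.array_equal(s1.as_array(), s2.as_array())


def _line_plan(grid, n_points=17, rate=100.0):
    ys = np.linspace(-2.4, 2.4, n_points)
    traj = np.stack([ys, np.zeros(n_points)], axis=1)
    return m.ScanPlan(mode="line", field_of_view=(4.8, 4.8),
                      pixel_pitch=grid.pitch, plane_offsets=(0.0,),
                      rate=rate, trajectory=traj)


def test_static_scene_gives_identical_columns(small_fiber):
    plan = _line_plan(small_fiber.grid)
    scene = _point_scene()
    k = m.scan_line(small_fiber.tm, small_fiber.op, scene, plan, n_sweeps=6)
    assert np.allclose(k.data, k.data[:, :1])
    assert k.line_rate == plan.rate


def test_translating_scene_streak_slope(small_fiber):
    """A scene moving at v µm/s produces streaks of slope
    v / (line_rate · pixel_pitch) px per line."""
    plan = _line_plan(small_fiber.grid, n_points=17, rate=100.0)
    scene = _point_scene()
    v = 3.0  # µm/s along the scanned line
    k = m.scan_line(small_fiber.tm, small_fiber.op, scene, plan, n_sweeps=20,
                    drift_velocity=(0.0, v, 0.0))
    pos = np.argmax(k.data, axis=0).astype(float)
    slope = np.polyfit(np.arange(k.data.shape[1]), pos, 1)[0]
    expected = v / (plan.rate * k.pixel_pitch)
    assert abs(slope - expected) / expected < 0.2


def test_empty_trajectory_rejected():
    with pytest.raises(ValueError, match="trajectory"):
        m.ScanPlan(mode="line", trajectory=np.zeros((0, 2)))


def test_roi_traces_background_subtraction():
    rng = np.random.default_rng(0)
    n_sweeps = 50
    bg = m.Kymograph(data=np.full((8, n_sweeps), 2.0) , line_rate=60.0,
                     pixel_pitch=0.5)
    roi_same = m.Kymograph(data=np.full((8, n_sweeps), 2.0), line_rate=60.0,
                           pixel_pitch=0.5)
    transient = np.full((8, n_sweeps), 2.0)
    peak_at = 17
    t = np.arange(n_sweeps, dtype=float)
    pulse = np.where(t >= peak_at, np.exp(-(t - peak_at) / 5.0), 0.0)
    transient += pulse[np.newaxis, :]
    roi_t = m.Kymograph(data=transient, line_rate=60.0, pixel_pitch=0.5)
    third = m.Kymograph(data=np.full((8, n_sweeps), 5.0), line_rate=60.0,
                        pixel_pitch=0.5)
    traces = m.roi_traces([roi_same, roi_t, third, bg], background_index=3)
    assert traces.shape == (3, n_sweeps)
    assert np.allclose(traces[0], 0.0)
    assert int(np.argmax(traces[1])) == peak_at
    assert np.allclose(traces[2], 3.0)


def test_roi_traces_sweep_mismatch():
    a = m.Kymograph(data=np.zeros((4, 10)), line_rate=60, pixel_pitch=0.5)
    b = m.Kymograph(data=np.zeros((4, 12)), line_rate=60, pixel_pitch=0.5)
    with pytest.raises(ValueError, match="mismatch"):
        m.roi_traces([a, b], background_index=1)
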