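"""Synthetic pattern generation and microscope forward model."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

import tilestats as ts
from tilestats.simulate import DEFAULT_WF_FIELD, bin_points

FIELD = DEFAULT_WF_FIELD  # 256 x 256 px at 40 nm


def test_random_pattern_points_inside_field_and_csr():
    """CSR draws: correct count, inside the field, quadrat counts consistent
    with a homogeneous Poisson process at the 1% level."""
    pat = ts.generate_pattern(ts.PatternSpec(kind="random", n_points=500), FIELD, seed=3)
    assert pat.n_points == 500
    assert np.all(pat.points >= 0)
    assert np.all(pat.points[:, 0] < FIELD.width_nm)
    assert np.all(pat.points[:, 1] < FIELD.height_nm)
    # independent quadrat-count chi-square check (8x8 quadrats)
    k = 8
    ix = np.floor(pat.points[:, 0] / FIELD.width_nm * k).astype(int)
    iy = np.floor(pat.points[:, 1] / FIELD.height_nm * k).astype(int)
    counts = np.bincount(iy * k + ix, minlength=k * k)
    expected = 500 / (k * k)
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p = stats.chi2.sf(chi2, k * k - 1)
    assert p > 0.01


def test_clustered_points_stay_within_disc():
    spec = ts.PatternSpec(kind="clustered", n_points=400, cluster_diameter_nm=240.0)
    pat = ts.generate_pattern(spec, FIELD, seed=4)
    centers = np.asarray(pat.metadata["cluster_centers"])
    d = np.linalg.norm(pat.points - centers[pat.cluster_ids], axis=1)
    assert np.all(d <= 120.0 + 1e-9)


def test_regular_lattice_equal_nearest_neighbours():
    spec = ts.PatternSpec(kind="regular", n_points=16 * 16, jitter_nm=0.0)
    pat = ts.generate_pattern(spec, FIELD, seed=0)
    tree = cKDTree(pat.points)
    nn = tree.query(pat.points, k=2)[0][:, 1]
    assert np.allclose(nn, nn[0], rtol=1e-9)


def test_polar_density_increases_along_axis():
    spec = ts.PatternSpec(kind="polar", n_points=4000)
    pat = ts.generate_pattern(spec, FIELD, seed=5)
    bands = np.floor(pat.points[:, 1] / FIELD.height_nm * 4).astype(int)
    counts = np.bincount(bands, minlength=4)
    assert np.all(np.diff(counts) > 0)  # ramp along +y by default


def test_pattern_determinism_and_errors():
    spec = ts.PatternSpec(kind="random", n_points=50)
    a = ts.generate_pattern(spec, FIELD, seed=9)
    b = ts.generate_pattern(spec, FIELD, seed=9)
    assert np.array_equal(a.points, b.points)
    with pytest.raises(ValueError, match="empty pattern"):
        ts.generate_pattern(ts.PatternSpec(kind="random", n_points=0), FIELD, 0)
    with pytest.raises(ValueError, match="larger than field extent"):
        ts.generate_pattern(
            ts.PatternSpec(
                kind="clustered", n_points=10, cluster_diameter_nm=1e6
            ),
            FIELD,
            0,
        )


def test_clark_evans_index_near_unity_over_replicates():
    """Nearest-neighbour Clark-Evans index (periodic boundaries) ~ 1 for CSR."""
    ratios = []
    for seed in range(50):
        pat = ts.generate_pattern(
            ts.PatternSpec(kind="random", n_points=500), FIELD, seed=seed
        )
        box = [FIELD.width_nm, FIELD.height_nm]
        tree = cKDTree(pat.points, boxsize=box)
        nn = tree.query(pat.points, k=2)[0][:, 1]
        rho = 500 / (FIELD.width_nm * FIELD.height_nm)
        ratios.append(np.mean(nn) / (0.5 / np.sqrt(rho)))
    assert 0.95 <= np.mean(ratios) <= 1.05


def test_rendering_conserves_expected_signal():
    """Noise off: total flux equals n_points * photons_per_emitter."""
    pat = ts.generate_pattern(ts.PatternSpec(kind="random", n_points=137), FIELD, 2)
    cfg = ts.SimulationConfig(noise=False, background_mean=0.0)
    img = ts.render_microscope_image(pat, cfg)
    total = img.pixels.sum()
    assert abs(total - 137 * cfg.photons_per_emitter) / total < 1e-6


def test_empty_pattern_renders_pure_background():
    pat = ts.PointPattern(
        points=np.empty((0, 2)),
        brightness=np.empty(0),
        field=FIELD,
        spec=ts.PatternSpec(kind="random", n_points=0),
        seed=0,
    )
    cfg = ts.SimulationConfig(background_mean=10.0, background_sigma=2.0, seed=1)
    img = ts.render_microscope_image(pat, cfg)
    n = img.pixels.size
    assert abs(img.pixels.mean() - 10.0) < 3 * 2.0 / np.sqrt(n)
    assert abs(img.pixels.std() - 2.0) < 3 * 2.0 / np.sqrt(2 * n)


def test_single_point_psf_fwhm_recovered_by_gaussian_fit():
    """Least-squares Gaussian fit to an isolated noise-free spot recovers the
    configured FWHM within 5%."""
    spec = ts.PatternSpec(kind="random", n_points=1)
    pt = np.array([[128.5 * 40.0, 128.5 * 40.0]])
    pat = ts.PointPattern(points=pt, brightness=np.ones(1), field=FIELD, spec=spec, seed=0)
    cfg = ts.SimulationConfig(resolution_fwhm_nm=200.0, noise=False, background_mean=0.0)
    img = ts.render_microscope_image(pat, cfg)
    yy, xx = np.mgrid[0:256, 0:256].astype(float)

    def gauss(coords, amp, x0, y0, sigma):
        x, y = coords
        return amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2))

    popt, _ = curve_fit(
        gauss,
        (xx.ravel(), yy.ravel()),
        img.pixels.ravel(),
        p0=(img.pixels.max(), 128, 128, 2.0),
    )
    fwhm_nm = popt[3] * 2 * np.sqrt(2 * np.log(2)) * 40.0
    assert abs(fwhm_nm - 200.0) / 200.0 < 0.05


def test_resolved_pair_shows_two_maxima():
    from skimage.feature import peak_local_max

    spec = ts.PatternSpec(kind="random", n_points=2)
    pts = np.array([[4000.0, 5120.0], [5000.0, 5120.0]])  # 5 x FWHM apart
    pat = ts.PointPattern(points=pts, brightness=np.ones(2), field=FIELD, spec=spec, seed=0)
    img = ts.render_microscope_image(
        pat, ts.SimulationConfig(resolution_fwhm_nm=200.0, noise=False, background_mean=0.0)
    )
    peaks = peak_local_max(img.pixels, threshold_abs=img.pixels.max() * 0.1)
    assert len(peaks) == 2


def test_render_determinism_and_undersampling_guard():
    pat = ts.generate_pattern(ts.PatternSpec(kind="random", n_points=20), FIELD, 1)
    cfg = ts.SimulationConfig(seed=5)
    a = ts.render_microscope_image(pat, cfg)
    b = ts.render_microscope_image(pat, cfg)
    assert np.array_equal(a.pixels, b.pixels)
    with pytest.raises(ValueError, match="undersampled"):
        ts.render_microscope_image(pat, ts.SimulationConfig(resolution_fwhm_nm=10.0))


def test_split_field_halves_and_counts():
    field = ts.FieldGeometry(512, 512, 40.0)
    pat = ts.generate_split_field(1600, field, cluster_diameter_nm=240.0, seed=11)
    assert pat.n_points == 1600
    meta = pat.metadata
    n_up = meta["n_upper"]
    # binomial split: within 5 sigma of half
    assert abs(n_up - 800) < 5 * np.sqrt(1600 * 0.25)
    boundary = meta["boundary_row_nm"]
    assert np.all(pat.points[:n_up, 1] < boundary)
    assert np.all(pat.points[n_up:, 1] >= boundary)
    # lower-half points satisfy the cluster-diameter constraint
    lower_ids = pat.cluster_ids[n_up:]
    lower_pts = pat.points[n_up:]
    for cid in np.unique(lower_ids):
        grp = lower_pts[lower_ids == cid]
        if len(grp) > 1:
            d = np.linalg.norm(grp[:, None] - grp[None, :], axis=-1)
            assert d.max() <= 240.0 + 1e-9


def test_brightness_marks_scale_rendered_flux():
    spec = ts.PatternSpec(kind="random", n_points=2)
    pts = np.array([[2000.0, 5120.0], [8000.0, 5120.0]])
    pat = ts.PointPattern(
        points=pts, brightness=np.array([1.0, 3.0]), field=FIELD, spec=spec, seed=0
    )
    raster = bin_points(pat)
    assert raster.sum() == 4.0
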