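import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from phenomap import hyper as H
from phenomap.rgb import PlantMask


def make_cube(bands_by_nm: dict, shape=(2, 2)):
    """Cube with one plane per given wavelength (constant or array)."""
    wl = sorted(bands_by_nm)
    planes = np.stack(
        [np.broadcast_to(np.asarray(bands_by_nm[w], dtype=float), shape) for w in wl]
    )
    return H.HyperCube(planes.astype(float), np.array(wl, dtype=float))


RATIO_WLS = [546.0, 705.0, 750.0, 1056.0, 1151.0, 1700.0]


class TestBandLookup:
    def test_default_grid_endpoints_and_red_edge(self):
        wl = H.default_wavelength_grid()
        cube = H.HyperCube(np.zeros((243, 1, 1)), wl)
        assert H.band_for_wavelength(cube, 546) == 0
        assert H.band_for_wavelength(cube, 1700) == 242
        assert H.band_for_wavelength(cube, 705) == 33

    def test_tie_breaks_toward_lower_index(self):
        cube = H.HyperCube(np.zeros((3, 1, 1)), np.array([100.0, 200.0, 300.0]))
        assert H.band_for_wavelength(cube, 150) == 0

    def test_out_of_range_rejected(self):
        cube = H.HyperCube(np.zeros((2, 1, 1)), np.array([546.0, 1700.0]))
        with pytest.raises(ValueError):
            H.band_for_wavelength(cube, 500)


class TestCubeIO:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        cube = H.HyperCube(
            rng.integers(0, 256, size=(5, 8, 6), dtype=np.uint8).astype(np.uint8),
            np.array([600.0, 700.0, 800.0, 900.0, 1000.0]),
        )
        H.write_cube(cube, tmp_path / "day")
        back = H.read_cube(tmp_path / "day")
        assert np.array_equal(back.planes, cube.planes)
        assert np.array_equal(back.wavelengths_nm, cube.wavelengths_nm)

    def test_missing_band_is_reported(self, tmp_path):
        cube = H.HyperCube(
            np.zeros((3, 4, 4), dtype=np.uint8), np.array([600.0, 700.0, 800.0])
        )
        H.write_cube(cube, tmp_path / "day")
        import shutil

        shutil.rmtree(tmp_path / "day" / "700")
        with pytest.raises(ValueError, match="700"):
            H.read_cube(tmp_path / "day", wavelengths_nm=[600, 700, 800])

    def test_three_channel_grayscale_collapsed(self, tmp_path):
        import imageio.v3 as iio

        for wl, val in ((600, 10), (700, 20)):
            d = tmp_path / "day" / str(wl)
            d.mkdir(parents=True)
            plane = np.full((4, 4, 3), val, dtype=np.uint8)
            iio.imwrite(d / "band.png", plane)
        cube = H.read_cube(tmp_path / "day")
        assert cube.planes.shape == (2, 4, 4)
        assert cube.planes[1, 0, 0] == 20


class TestNdviSegmentation:
    def test_hand_values(self):
        cube = make_cube({w: 0.0 for w in RATIO_WLS} | {750.0: 0.5, 705.0: 0.2})
        assert H.ndvi(cube)[0, 0] == pytest.approx(0.3 / 0.7)
        assert H.segment_plant_ndvi(cube).mask.all()

    def test_equal_bands_are_background(self):
        cube = make_cube({w: 0.4 for w in RATIO_WLS})
        assert H.ndvi(cube)[0, 0] == 0.0
        assert H.segment_plant_ndvi(cube).is_na

    def test_antisymmetric_index_is_background(self):
        cube = make_cube({w: 0.0 for w in RATIO_WLS} | {750.0: 0.2, 705.0: 0.5})
        assert H.ndvi(cube)[0, 0] == pytest.approx(-0.3 / 0.7)
        assert H.segment_plant_ndvi(cube).is_na

    @settings(max_examples=50, deadline=None)
    @given(
        arrays(np.float64, (6, 4, 4),
               elements=st.floats(0, 1e6, allow_nan=False))
    )
    def test_bounded_for_nonnegative_intensities(self, planes):
        cube = H.HyperCube(planes, np.array(RATIO_WLS))
        v = H.ndvi(cube)
        assert (v >= -1).all() and (v <= 1).all()

    @settings(max_examples=50, deadline=None)
    @given(
        arrays(np.float64, (6, 3, 3),
               elements=st.floats(0, 255, allow_nan=False))
    )
    def test_partition_property(self, planes):
        cube = H.HyperCube(planes, np.array(RATIO_WLS))
        plant = H.segment_plant_ndvi(cube)
        stem, leaf = H.segment_stem(cube, plant)
        assert np.array_equal(stem.mask | leaf.mask, plant.mask)
        assert not (stem.mask & leaf.mask).any()


class TestStemSegmentation:
    def plant_cube(self, r1056, r1151):
        return make_cube(
            {546.0: 0.1, 705.0: 0.1, 750.0: 0.9, 1056.0: r1056, 1151.0: r1151,
             1700.0: 0.1}
        )

    def test_ratio_above_threshold_is_stem(self):
        cube = self.plant_cube(1.3, 1.0)
        plant = H.segment_plant_ndvi(cube)
        stem, leaf = H.segment_stem(cube, plant)
        assert stem.mask.all() and leaf.is_na

    def test_equal_reflectance_is_leaf(self):
        cube = self.plant_cube(0.5, 0.5)
        plant = H.segment_plant_ndvi(cube)
        stem, leaf = H.segment_stem(cube, plant)
        assert stem.is_na and leaf.mask.all()

    def test_partition_on_random_cubes(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            cube = H.HyperCube(rng.random((6, 12, 12)), np.array(RATIO_WLS))
            plant = H.segment_plant_ndvi(cube)
            stem, leaf = H.segment_stem(cube, plant)
            assert np.array_equal(stem.mask | leaf.mask, plant.mask)
            assert not (stem.mask & leaf.mask).any()


class TestNormalization:
    def test_hand_division(self):
        planes = np.array([[[3.0, 2.0], [2.0, 2.0]]])  # 1 band, plant at (0,0)
        cube = H.HyperCube(
            np.repeat(planes, 2, axis=0), np.array([700.0, 800.0])
        )
        mask = PlantMask(np.array([[True, False], [False, False]]))
        norm = H.normalize_cube(cube, mask)
        assert norm.planes[0, 0, 0] == pytest.approx(1.5)
        assert norm.planes[0, 0, 1] == 2.0  # background untouched
        assert norm.normalized

    def test_plant_equal_to_background_maps_to_one(self):
        planes = np.full((2, 3, 3), 7.0)
        cube = H.HyperCube(planes, np.array([700.0, 800.0]))
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        norm = H.normalize_cube(cube, PlantMask(mask))
        assert norm.planes[0, 1, 1] == pytest.approx(1.0)

    def test_global_illumination_scalar_cancels(self):
        rng = np.random.default_rng(5)
        planes = rng.random((4, 6, 6)) + 0.5
        wl = np.array([600.0, 700.0, 800.0, 900.0])
        mask = PlantMask(rng.random((6, 6)) < 0.3)
        a = H.normalize_cube(H.HyperCube(planes, wl), mask)
        b = H.normalize_cube(H.HyperCube(planes * 3.7, wl), mask)
        assert np.allclose(
            a.planes[:, mask.mask], b.planes[:, mask.mask], rtol=1e-12
        )

    def test_zero_background_band_is_an_error(self):
        planes = np.stack([np.ones((2, 2)), np.zeros((2, 2))])
        cube = H.HyperCube(planes, np.array([700.0, 800.0]))
        mask = PlantMask(np.array([[True, False], [False, False]]))
        with pytest.raises(ValueError, match="800"):
            H.normalize_cube(cube, mask)


class TestPcaFalseColor:
    def test_minmax_fixture(self):
        assert np.allclose(H.minmax_rescale(np.array([2.0, 4.0, 6.0])), [0, 0.5, 1])

    def test_constant_spectra_render_black(self):
        planes = np.ones((4, 5, 5))
        cube = H.HyperCube(planes, np.array([600.0, 700.0, 800.0, 900.0]))
        mask = PlantMask(np.ones((5, 5), dtype=bool))
        images, _ = H.pca_false_color([cube], [mask])
        assert images[0].sum() == 0

    def test_two_cluster_cube_separated_on_red_channel(self):
        # stem-like and leaf-like template spectra; PC1 must be the
        # between-cluster axis and is checked against a direct
        # eigen-decomposition of the pixel covariance.
        rng = np.random.default_rng(11)
        wl = np.linspace(546, 1700, 8)
        leaf = np.linspace(0.4, 0.5, 8)
        stem = np.linspace(0.7, 0.3, 8)
        labels = rng.random((6, 6)) < 0.5
        planes = np.where(labels[None], stem[:, None, None], leaf[:, None, None])
        cube = H.HyperCube(planes, wl)
        mask = PlantMask(np.ones((6, 6), dtype=bool))
        images, pca = H.pca_false_color([cube], [mask])
        red = images[0][..., 0].astype(float)
        assert abs(red[labels].mean() - red[~labels].mean()) > 100
        # oracle: leading eigenvector of the covariance of pooled pixels
        X = planes.reshape(8, -1).T
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        lead = evecs[:, -1]
        assert abs(np.dot(lead, pca.components_[0])) == pytest.approx(1.0)

    def test_channels_are_8bit_and_nonplant_black(self):
        rng = np.random.default_rng(13)
        cube = H.HyperCube(rng.random((5, 7, 7)), np.linspace(600, 1000, 5))
        mask = PlantMask(rng.random((7, 7)) < 0.5)
        images, _ = H.pca_false_color([cube], [mask])
        img = images[0]
        assert img.dtype == np.uint8
        assert (img[~mask.mask] == 0).all()

    def test_lossless_reconstruction_with_all_components(self):
        rng = np.random.default_rng(17)
        X = rng.random((10, 4))
        from sklearn.decomposition import PCA

        p = PCA(n_components=4)
        scores = p.fit_transform(X)
        assert np.allclose(scores @ p.components_ + p.mean_, X)


class TestMeanSpectrum:
    def test_uniform_and_two_pixel_mean(self):
        planes = np.zeros((2, 1, 2))
        planes[0] = [[1.0, 3.0]]
        planes[1] = [[5.0, 5.0]]
        cube = H.HyperCube(planes, np.array([700.0, 800.0]))
        s = H.mean_spectrum(cube, PlantMask(np.ones((1, 2), dtype=bool)))
        assert np.allclose(s.mean_intensity, [2.0, 5.0])
        assert s.n_pixels == 2

    def test_empty_mask_rejected(self):
        cube = H.HyperCube(np.ones((2, 2, 2)), np.array([700.0, 800.0]))
        with pytest.raises(ValueError):
            H.mean_spectrum(cube, PlantMask(np.zeros((2, 2), dtype=bool)))

    def test_phantom_stem_brighter_at_1056_than_1151(self, exp_small):
        from phenomap.hyper import band_for_wavelength

        plant = exp_small.plants[0]
        cube, truth = exp_small.render_hypercube(plant, exp_small.config.n_days)
        s = H.mean_spectrum(cube, PlantMask(truth.stem_mask), "stem")
        i1056 = band_for_wavelength(cube, 1056)
        i1151 = band_for_wavelength(cube, 1151)
        assert s.mean_intensity[i1056] > s.mean_intensity[i1151]
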