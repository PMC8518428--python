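import numpy as np
import pytest

from livernav.bodynav import (BodyNavExtractor, BodyNavParams,
                              FeatureExtractionError, extract_features,
                              find_coronal_plane, localize_spine, origin_point,
                              segment_body)
from livernav.geometry import Plane
from livernav.phantom import PhantomSpec, generate_phantom
from livernav.volume import Volume


def _angle_deg(n1, n2):
    n1 = np.asarray(n1, float) / np.linalg.norm(n1)
    n2 = np.asarray(n2, float) / np.linalg.norm(n2)
    return np.degrees(np.arccos(np.clip(abs(n1 @ n2), 0.0, 1.0)))


@pytest.fixture(scope="module")
def posed_phantom():
    spec = PhantomSpec(shape=(32, 64, 96), spacing_mm=4.0, yaw_deg=6.0,
                       lateral_shift_mm=-7.0, organ_scale=1.8, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="module")
def features(posed_phantom):
    vol, _ = posed_phantom
    return extract_features(vol)


class TestParams:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            BodyNavParams(TB=400.0)

    def test_scalar_ss_broadcasts(self):
        p = BodyNavParams(SS=50.0)
        assert p.SS == (50.0, 50.0)

    def test_scaled_copies_one_parameter(self):
        p = BodyNavParams()
        q = p.scaled("DSA", 2.0)
        assert q.DSA == pytest.approx(2 * p.DSA)
        assert q.TB == p.TB and p.DSA == 30.0

    def test_scaled_may_violate_ordering(self):
        # sensitivity scans must be able to run out-of-order thresholds
        q = BodyNavParams().scaled("TB", 0.25)
        assert q.TB == pytest.approx(-75.0)

    def test_scaled_unknown_parameter(self):
        with pytest.raises(ValueError, match="unknown"):
            BodyNavParams().scaled("working_spacing_mm", 2.0)


class TestStages:
    def test_body_mask_matches_truth(self, posed_phantom):
        vol, truth = posed_phantom
        body = segment_body(vol)
        t = truth.body_mask.bool
        inter = np.count_nonzero(body.bool & t)
        dice = 2 * inter / (body.bool.sum() + t.sum())
        assert dice > 0.97

    def test_body_mask_is_solid(self, posed_phantom):
        vol, truth = posed_phantom
        body = segment_body(vol)
        # lungs are below TB but must be filled as interior cavities
        assert np.count_nonzero(truth.lung_mask.bool & ~body.bool) == 0

    def test_no_body_raises_stage_error(self):
        air = Volume(np.full((16, 16, 16), -1000.0), (4.0, 4.0, 4.0))
        with pytest.raises(FeatureExtractionError, match="segment_body"):
            segment_body(air)

    def test_spine_centroid_near_truth(self, posed_phantom):
        vol, truth = posed_phantom
        _, centroid = localize_spine(vol)
        idx = np.argwhere(truth.spine_mask.bool)
        true_c = (np.asarray(truth.spine_mask.origin_mm)
                  + idx.mean(axis=0) * np.asarray(truth.spine_mask.spacing_mm))
        # in-plane agreement within ~2 voxels
        assert np.linalg.norm(centroid[1:] - true_c[1:]) < 8.0

    def test_no_bone_raises_stage_error(self):
        soft = Volume(np.full((16, 16, 16), 30.0), (4.0, 4.0, 4.0))
        with pytest.raises(FeatureExtractionError, match="localize_spine"):
            localize_spine(soft)

    def test_coronal_plane_perpendicular_and_oriented(self, posed_phantom, features):
        sag, cor = features.sagittal_plane, features.coronal_plane
        assert abs(np.dot(sag.normal, cor.normal)) < 1e-9
        assert cor.normal[0] == pytest.approx(0.0, abs=1e-12)

    def test_coronal_degenerate_orientation(self):
        sag = Plane(point_mm=(0, 0, 0), normal=(0, 0, 1))
        with pytest.raises(FeatureExtractionError, match="coronal"):
            find_coronal_plane(sag, (0.0, 10.0, 0.0), (0.0, 10.0, 5.0))


class TestRecovery:
    def test_sagittal_plane_recovered(self, posed_phantom, features):
        _, truth = posed_phantom
        assert _angle_deg(features.sagittal_plane.normal,
                          truth.sagittal_plane.normal) < 2.0
        off = features.sagittal_plane.signed_distance(
            np.asarray(truth.sagittal_plane.point_mm, float))
        assert abs(off) < 2.0

    def test_coronal_plane_recovered(self, posed_phantom, features):
        vol, truth = posed_phantom
        off = features.coronal_plane.signed_distance(
            np.asarray(truth.coronal_plane.point_mm, float))
        assert abs(off) < 2 * 4.0  # two working voxels

    def test_diaphragm_level_recovered(self, posed_phantom, features):
        vol, truth = posed_phantom
        err_slices = abs(features.diaphragm_z_mm - truth.diaphragm_z_mm) / vol.spacing_mm[0]
        assert err_slices < 2.0


class TestFeatures:
    def test_channels_shape_and_order(self, posed_phantom, features):
        vol, _ = posed_phantom
        ch = features.channels
        assert ch.shape == (4, *vol.shape)
        assert np.isfinite(ch).all()

    def test_plane_sdfs_are_exact_affine_fields(self, posed_phantom, features):
        vol, _ = posed_phantom
        zz, yy, xx = np.meshgrid(*[
            o + np.arange(n) * s
            for o, n, s in zip(vol.origin_mm, vol.shape, vol.spacing_mm)
        ], indexing="ij")
        pts = np.stack([zz, yy, xx], axis=-1)
        expected = features.sagittal_plane.signed_distance(pts.reshape(-1, 3))
        np.testing.assert_allclose(
            features.sdf_sagittal.ravel(), expected, atol=1e-9)

    def test_surface_sdf_sign_convention(self, posed_phantom, features):
        _, truth = posed_phantom
        centroid = tuple(np.argwhere(truth.body_mask.bool).mean(axis=0)
                         .round().astype(int))
        # negative deep inside the body, positive out at the air corner
        assert features.sdf_surface[centroid] < 0
        assert features.sdf_surface[0, 0, 0] > 0

    def test_deterministic(self, posed_phantom, features):
        vol, _ = posed_phantom
        again = extract_features(vol)
        np.testing.assert_array_equal(features.channels, again.channels)

    def test_origin_point_on_all_planes(self, features):
        o = origin_point(features)
        for pl in features.planes:
            assert abs(pl.signed_distance(o)) < 1e-6


class TestEstimator:
    def test_transform_single_and_list(self, posed_phantom):
        vol, _ = posed_phantom
        ext = BodyNavExtractor().fit()
        single = ext.transform(vol)
        batch = ext.transform([vol])
        assert ext.n_features_out_ == 4
        np.testing.assert_array_equal(single.channels, batch[0].channels)

    def test_get_set_params_roundtrip(self):
        ext = BodyNavExtractor(TB=-250.0)
        params = ext.get_params()
        assert params["TB"] == -250.0
        ext.set_params(DSA=40.0)
        assert ext._params().DSA == 40.0
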