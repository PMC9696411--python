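"""Landmark detectors: CoordConv channels, head shapes, loss oracle,
decoding, and the translation-equivariance probe."""

import numpy as np
import pytest

from spinemark import (
    FrameTransform,
    LandmarkNetConfig,
    build_landmarknet,
    coord_channels,
    decode_landmarks,
    landmark_loss,
)
from spinemark import nn

TINY_LUMBAR = LandmarkNetConfig(kind="lumbar", base_channels=2, depth=2, seed=0)
TINY_SACRUM = LandmarkNetConfig(kind="sacrum", base_channels=2, depth=2, seed=0)


class TestCoordChannels:
    def test_corners_exact(self):
        cc = coord_channels(256, 256)
        assert cc.shape == (2, 256, 256)
        assert cc[0, 0, 0] == -1 and cc[1, 0, 0] == -1
        assert cc[0, -1, -1] == 1 and cc[1, -1, -1] == 1

    def test_center_pixel_of_odd_grid_is_zero(self):
        cc = coord_channels(3, 3)
        assert cc[0, 1, 1] == 0 and cc[1, 1, 1] == 0

    def test_linear_spacing(self):
        cc = coord_channels(256, 256)
        steps = np.diff(cc[0, 0])
        assert np.allclose(steps, 2 / 255, atol=1e-6)

    def test_input_independent_constants(self):
        assert np.array_equal(coord_channels(64, 32), coord_channels(64, 32))

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            coord_channels(1, 64)


class TestBuild:
    @pytest.mark.parametrize("cfg,channels", [(TINY_LUMBAR, 5), (TINY_SACRUM, 3)])
    def test_forward_shapes(self, cfg, channels):
        model = build_landmarknet(cfg)
        out = model.forward(np.zeros((1, 1, 256, 256), dtype=np.float32))
        assert out.v.shape == (1, 256, 256, channels)
        assert np.isfinite(out.v).all()
        cm, paf = model.predict(np.zeros((1, 1, 256, 256), dtype=np.float32))
        assert cm.shape == (1, channels - 1, 256, 256)
        assert paf.shape == (1, 256, 256)

    def test_kind_config_template(self):
        """Lumbar and sacrum nets differ only in the output head size."""
        assert TINY_LUMBAR.out_channels == 5 and TINY_LUMBAR.n_cm == 4
        assert TINY_SACRUM.out_channels == 3 and TINY_SACRUM.n_cm == 2
        assert TINY_LUMBAR.paf_weight == 0.001 and TINY_SACRUM.paf_weight == 0.01

    def test_paf_head_costs_one_output_channel(self):
        """The PAF output shares the whole trunk: the only PAF-specific
        parameters are one extra column of the final 1x1 head (plus its
        bias), so lumbar (5 out) vs a 4-channel head differ by exactly
        cin + 1 parameters."""
        model = build_landmarknet(TINY_LUMBAR)
        head = model.head
        assert head.kernel == 1
        assert head.w.v.shape[3] == TINY_LUMBAR.n_cm + 1
        per_channel = head.w.v.shape[2] * head.kernel**2 + 1
        # every non-head parameter is independent of the PAF channel
        trunk = model.n_params() - sum(p.v.size for p in head.params())
        with_paf = trunk + (TINY_LUMBAR.n_cm + 1) * per_channel + 2 * head.w.v.shape[2]
        without_paf = trunk + TINY_LUMBAR.n_cm * per_channel + 2 * head.w.v.shape[2]
        assert with_paf - without_paf == per_channel
        assert model.n_params() == with_paf

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            LandmarkNetConfig(kind="thoracic")
        with pytest.raises(ValueError):
            LandmarkNetConfig(coordconv_stages=5, depth=3)
        with pytest.raises(ValueError):
            LandmarkNetConfig(alpha=0.0)


def _interior_shift_residual(cfg, shift, rng):
    """Max interior difference between shifted-input output and
    output-shifted, for a random-weight net (norm disabled so border
    statistics cannot leak into the interior)."""
    model = build_landmarknet(cfg)
    x = rng.normal(size=(1, 1, 256, 256)).astype(np.float32)
    xs = np.roll(x, (shift, shift), axis=(2, 3))
    out = model.forward(x).v
    out_s = model.forward(xs).v
    expected = np.roll(out, (shift, shift), axis=(1, 2))
    m = 64  # margin larger than the total receptive field effects
    return np.abs(out_s[:, m:-m, m:-m] - expected[:, m:-m, m:-m]).max()


class TestShiftEquivarianceProbe:
    def test_plain_conv_net_is_shift_equivariant(self, rng):
        cfg = LandmarkNetConfig(
            kind="lumbar", base_channels=2, depth=2, coordconv_stages=0, norm="none", seed=3
        )
        assert _interior_shift_residual(cfg, 8, rng) < 1e-4

    def test_coordconv_breaks_equivariance(self, rng):
        cfg = LandmarkNetConfig(
            kind="lumbar", base_channels=2, depth=2, coordconv_stages=2, norm="none", seed=3
        )
        assert _interior_shift_residual(cfg, 8, rng) > 1e-3


class TestLandmarkLoss:
    def test_zero_at_exact(self, rng):
        cm = rng.random((4, 256, 256))
        paf = rng.random((256, 256))
        assert landmark_loss(cm, paf, cm, paf, TINY_LUMBAR) == pytest.approx(0.0)

    def test_alpha_weighting_of_paf_error(self, rng):
        cm = rng.random((4, 64, 64))
        paf_gt = np.zeros((64, 64))
        paf_pred = np.zeros((64, 64))
        paf_pred[10:20, 10:20] = 2.0  # squared error E = 100 * 4
        cfg = LandmarkNetConfig(kind="lumbar", base_channels=2, depth=2)
        got = landmark_loss(cm, paf_pred, cm, paf_gt, cfg)
        assert got == pytest.approx(0.001 * 400.0)

    def test_beta_weighting_for_sacrum(self, rng):
        cm = rng.random((2, 64, 64))
        paf_gt = np.zeros((64, 64))
        paf_pred = np.ones((64, 64))
        got = landmark_loss(cm, paf_pred, cm, paf_gt, TINY_SACRUM)
        assert got == pytest.approx(0.01 * 64 * 64)

    def test_matches_bruteforce_oracle(self, rng):
        cm_gt = rng.random((4, 32, 32))
        cm_pred = rng.random((4, 32, 32))
        paf_gt = rng.random((32, 32))
        paf_pred = rng.random((32, 32))
        expected = ((cm_pred - cm_gt) ** 2).sum() / 4 + 0.001 * ((paf_pred - paf_gt) ** 2).sum()
        got = landmark_loss(cm_pred, paf_pred, cm_gt, paf_gt, TINY_LUMBAR)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            landmark_loss(
                rng.random((2, 32, 32)),
                rng.random((32, 32)),
                rng.random((2, 32, 32)),
                rng.random((32, 32)),
                TINY_LUMBAR,
            )


class TestDecodeLandmarks:
    def test_ground_truth_stack_round_trip(self):
        from spinemark import gaussian_map

        pts = np.array([[60.0, 70.0], [180.0, 72.0], [58.0, 170.0], [182.0, 168.0]])
        stack = gaussian_map(pts, 5.0, (256, 256)).maps
        t = FrameTransform(0.5, (100.0, 200.0), "crop", "padded")
        decoded = decode_landmarks(stack, t)
        assert np.abs(decoded - t.apply(pts)).max() < 0.51

    def test_constant_channel_centroid_fallback(self):
        stack = np.ones((2, 256, 256))
        t = FrameTransform(1.0, (0.0, 0.0), "crop", "padded")
        with pytest.warns(UserWarning, match="constant"):
            decoded = decode_landmarks(stack, t)
        assert np.allclose(decoded, 127.5)

    def test_row_major_tie_break(self):
        stack = np.zeros((1, 16, 16))
        stack[0, 3, 9] = 1.0
        stack[0, 12, 2] = 1.0
        t = FrameTransform(1.0, (0.0, 0.0), "crop", "padded")
        assert tuple(decode_landmarks(stack, t)[0]) == (9.0, 3.0)
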