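import numpy as np
import pytest
from scipy.ndimage import correlate
from scipy.stats import spearmanr

from textcam import explain as ex
from textcam.nn import functional as F
from textcam.nn.autograd import Tensor
from textcam.nn.layers import Conv2d, Linear, Module
from textcam.preprocess import format_grid

rng = np.random.default_rng(2024)


class ToyCam(Module):
    """Two-conv toy classifier small enough for finite-difference oracles."""

    stage_names = ("conv1", "conv2")

    def __init__(self, in_ch=2, mid=3, out_ch=4, classes=2, seed=0):
        super().__init__()
        r = np.random.default_rng(seed)
        self.conv1 = Conv2d(in_ch, mid, 3, padding=1, rng=r)
        self.conv2 = Conv2d(mid, out_ch, 3, padding=1, rng=r)
        self.fc = Linear(out_ch, classes, rng=r)
        self._captured = {}

    def forward(self, x, capture=()):
        self._captured = {}
        a = F.relu(self.conv1(x))
        if "conv1" in capture:
            self._captured["conv1"] = a
        b = F.relu(self.conv2(a))
        if "conv2" in capture:
            self._captured["conv2"] = b
        return self.fc(F.global_avg_pool2d(b))

    def captured(self, name):
        return self._captured[name]


def _oracle_logit(model: ToyCam, activation: np.ndarray, class_id: int) -> float:
    """Independent float64 re-implementation of the toy model's tail
    (conv2 -> relu -> gap -> fc) as a function of the conv1 activation."""
    w2 = model.conv2.weight.data.astype(np.float64)
    out_ch = w2.shape[0]
    h, w = activation.shape[1:]
    conv = np.zeros((out_ch, h, w))
    for f in range(out_ch):
        for c in range(activation.shape[0]):
            conv[f] += correlate(activation[c].astype(np.float64), w2[f, c],
                                 mode="constant", cval=0.0)
    conv = np.maximum(conv, 0.0)
    pooled = conv.mean(axis=(1, 2))
    fc_w = model.fc.weight.data.astype(np.float64)
    fc_b = model.fc.bias.data.astype(np.float64)
    return float(fc_w[class_id] @ pooled + fc_b[class_id])


def _fd_alpha_and_map(model: ToyCam, x: np.ndarray, class_id: int, eps=1e-4):
    """Finite-difference d(logit)/d(conv1 activation), in float64."""
    model.eval()
    model.forward(Tensor(x[None]), capture=["conv1"])
    act = model.captured("conv1").data[0].astype(np.float64)
    grad = np.zeros_like(act)
    it = np.nditer(act, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        plus, minus = act.copy(), act.copy()
        plus[idx] += eps
        minus[idx] -= eps
        grad[idx] = (
            _oracle_logit(model, plus, class_id) - _oracle_logit(model, minus, class_id)
        ) / (2 * eps)
    alpha = grad.mean(axis=(1, 2))
    raw = np.maximum((alpha[:, None, None] * act).sum(axis=0), 0.0)
    return act, alpha, raw


class TestGradCamOracle:
    def test_alpha_matches_finite_differences(self):
        model = ToyCam(seed=5)
        x = rng.standard_normal((2, 5, 5)).astype(np.float32)
        cam = ex.compute_gradcam(model, x, class_id=1,
                                 cfg=ex.CamConfig(target_layer="conv1"))
        _, alpha_fd, raw_fd = _fd_alpha_and_map(model, x, class_id=1)
        np.testing.assert_allclose(cam.alpha, alpha_fd, rtol=1e-4, atol=1e-7)
        np.testing.assert_allclose(cam.raw, raw_fd, rtol=1e-4, atol=1e-7)

    def test_single_channel_unit_conv_recovers_activation(self):
        """One 1x1 conv and a positive linear score: the CAM is the min-max
        rescaled activation map itself."""
        model = ToyCam(in_ch=1, mid=1, out_ch=1, classes=2, seed=0)
        model.conv1.weight.data[...] = 1.0  # identity 3x3? no - set 1x1 equivalent
        model.conv1.weight.data[...] = 0.0
        model.conv1.weight.data[0, 0, 1, 1] = 1.0  # centre tap: identity conv
        model.conv2.weight.data[...] = 0.0
        model.conv2.weight.data[0, 0, 1, 1] = 1.0
        model.fc.weight.data[...] = np.array([[2.0], [-2.0]])
        model.fc.bias.data[...] = 0.0
        x = np.abs(rng.standard_normal((1, 6, 6))).astype(np.float32) + 0.1
        cam = ex.compute_gradcam(model, x, class_id=0,
                                 cfg=ex.CamConfig(target_layer="conv1"))
        expected = (x[0] - x[0].min()) / (x[0].max() - x[0].min())
        np.testing.assert_allclose(cam.grid_scores, expected, atol=1e-5)

    def test_negative_weight_relu_clamps_to_zero(self):
        model = ToyCam(in_ch=1, mid=1, out_ch=1, classes=2, seed=0)
        model.conv1.weight.data[...] = 0.0
        model.conv1.weight.data[0, 0, 1, 1] = 1.0
        model.conv2.weight.data[...] = 0.0
        model.conv2.weight.data[0, 0, 1, 1] = 1.0
        model.fc.weight.data[...] = np.array([[2.0], [-2.0]])
        x = np.abs(rng.standard_normal((1, 6, 6))).astype(np.float32) + 0.1
        cam = ex.compute_gradcam(model, x, class_id=1,
                                 cfg=ex.CamConfig(target_layer="conv1"))
        assert not cam.raw.any()
        assert not cam.grid_scores.any()

    def test_constant_logit_gives_zero_map(self):
        model = ToyCam(seed=3)
        model.fc.weight.data[...] = 0.0  # logits independent of activations
        x = rng.standard_normal((2, 5, 5)).astype(np.float32)
        cam = ex.compute_gradcam(model, x, class_id=0,
                                 cfg=ex.CamConfig(target_layer="conv1"))
        assert not cam.grid_scores.any()

    def test_invariants_on_random_inputs(self):
        model = ToyCam(seed=7)
        for i in range(100):
            x = rng.standard_normal((2, 5, 5)).astype(np.float32)
            cam = ex.compute_gradcam(model, x, class_id=i % 2,
                                     cfg=ex.CamConfig(target_layer="conv1"))
            assert (cam.raw >= 0).all()
            assert (cam.grid_scores >= 0).all() and (cam.grid_scores <= 1).all()
            if cam.raw.any():
                assert cam.grid_scores.min() == pytest.approx(0.0, abs=1e-12)
                assert cam.grid_scores.max() == pytest.approx(1.0, abs=1e-12)

    def test_class_sensitivity_disjoint_evidence(self):
        """Two classes reading disjoint channels: each CAM peaks inside its
        own class's evidence region."""
        model = ToyCam(in_ch=2, mid=2, out_ch=2, classes=2, seed=0)
        model.conv1.weight.data[...] = 0.0
        model.conv1.weight.data[0, 0, 1, 1] = 1.0  # channel 0 passthrough
        model.conv1.weight.data[1, 1, 1, 1] = 1.0  # channel 1 passthrough
        model.conv2.weight.data[...] = 0.0
        model.conv2.weight.data[0, 0, 1, 1] = 1.0
        model.conv2.weight.data[1, 1, 1, 1] = 1.0
        model.fc.weight.data[...] = np.array([[1.0, 0.0], [0.0, 1.0]])
        model.fc.bias.data[...] = 0.0
        x = np.zeros((2, 6, 6), dtype=np.float32)
        x[0, 1, 1] = 3.0  # evidence for class 0, top-left
        x[1, 4, 4] = 3.0  # evidence for class 1, bottom-right
        cam0 = ex.compute_gradcam(model, x, class_id=0,
                                  cfg=ex.CamConfig(target_layer="conv1"))
        cam1 = ex.compute_gradcam(model, x, class_id=1,
                                  cfg=ex.CamConfig(target_layer="conv1"))
        assert np.unravel_index(cam0.grid_scores.argmax(), (6, 6)) == (1, 1)
        assert np.unravel_index(cam1.grid_scores.argmax(), (6, 6)) == (4, 4)

    def test_predicted_class_is_default(self):
        model = ToyCam(seed=9)
        x = rng.standard_normal((2, 5, 5)).astype(np.float32)
        logits = model.forward(Tensor(x[None])).data[0]
        cam = ex.compute_gradcam(model, x, cfg=ex.CamConfig(target_layer="conv1"))
        assert cam.target_class == int(logits.argmax())

    def test_invalid_class_and_layer(self):
        model = ToyCam(seed=9)
        x = rng.standard_normal((2, 5, 5)).astype(np.float32)
        with pytest.raises(ValueError):
            ex.compute_gradcam(model, x, class_id=10,
                               cfg=ex.CamConfig(target_layer="conv1"))
        with pytest.raises(KeyError):
            ex.compute_gradcam(model, x, cfg=ex.CamConfig(target_layer="nope"))


class TestAttributeTokens:
    def _cam(self, scores):
        scores = np.asarray(scores, dtype=np.float64)
        return ex.ClassActivationMap(raw=scores, grid_scores=scores,
                                     target_class=0, alpha=np.zeros(1))

    def test_uniform_scores(self):
        grid = format_grid(["a", "b", "c", "d"], 2, 2)
        attr = ex.attribute_tokens(self._cam(np.ones((2, 2))), grid)
        assert all(e.score == 1.0 for e in attr.entries)
        assert [e.token for e in attr.entries] == ["a", "b", "c", "d"]

    def test_all_pad_grid(self):
        grid = format_grid([], 2, 2)
        attr = ex.attribute_tokens(self._cam(np.ones((2, 2))), grid)
        assert all(e.is_pad for e in attr.entries)

    def test_single_hot(self):
        grid = format_grid(["a", "b", "c", "d"], 2, 2)
        scores = np.zeros((2, 2))
        scores[1, 0] = 1.0
        attr = ex.attribute_tokens(self._cam(scores), grid)
        hot = [e for e in attr.entries if e.score == 1.0]
        assert len(hot) == 1 and hot[0].token == "c" and (hot[0].row, hot[0].col) == (1, 0)

    def test_shape_mismatch(self):
        grid = format_grid(["a"], 2, 2)
        with pytest.raises(ValueError):
            ex.attribute_tokens(self._cam(np.ones((3, 3))), grid)


class TestRenderHeatmap:
    def _read_gray(self, path):
        import matplotlib.image as mpimg

        img = mpimg.imread(str(path))
        return img[..., 0]

    def test_all_zero_cam_uniform_dark(self, tmp_path):
        cam = ex.ClassActivationMap(raw=np.zeros((4, 4)), grid_scores=np.zeros((4, 4)),
                                    target_class=0, alpha=np.zeros(1))
        path = tmp_path / "zero.png"
        ex.render_heatmap(cam, path, upscale=4)
        gray = self._read_gray(path)
        assert gray.max() == gray.min() == 0.0

    def test_intensity_monotone_in_score(self, tmp_path):
        scores = np.array([[0.0, 0.3], [0.6, 1.0]])
        cam = ex.ClassActivationMap(raw=scores, grid_scores=scores,
                                    target_class=0, alpha=np.zeros(1))
        path = tmp_path / "mono.png"
        ex.render_heatmap(cam, path, upscale=3)
        gray = self._read_gray(path)
        vals = [gray[1, 1], gray[1, 4], gray[4, 1], gray[4, 4]]
        assert vals == sorted(vals)
        assert vals[0] < vals[-1]

    def test_raster_dimensions(self, tmp_path):
        scores = np.random.default_rng(0).random((25, 25))
        cam = ex.ClassActivationMap(raw=scores, grid_scores=scores,
                                    target_class=0, alpha=np.zeros(1))
        path = tmp_path / "dim.png"
        ex.render_heatmap(cam, path, upscale=2)
        assert self._read_gray(path).shape == (50, 50)


class TestRenderHighlight:
    def _attr(self, tokens, scores, height=2, width=2):
        grid = format_grid(tokens, height, width)
        s = np.asarray(scores, dtype=np.float64).reshape(height, width)
        cam = ex.ClassActivationMap(raw=s, grid_scores=s, target_class=0,
                                    alpha=np.zeros(1))
        return ex.attribute_tokens(cam, grid)

    def test_threshold_zero_highlights_all(self):
        attr = self._attr(["a", "b", "c"], [0.1, 0.5, 0.9, 0.0])
        html = ex.render_highlight(attr, threshold=0.0)
        assert html.count("<mark") == 3

    def test_threshold_above_one_highlights_none(self):
        attr = self._attr(["a", "b", "c"], [0.1, 0.5, 0.9, 0.0])
        html = ex.render_highlight(attr, threshold=1.5)
        assert "<mark" not in html

    def test_pads_omitted_and_order_preserved(self):
        attr = self._attr(["x", "y"], [1.0, 0.0, 0.0, 0.0])
        html = ex.render_highlight(attr, threshold=2.0)
        assert "#" not in html.split("<body>")[1]
        body = html.split("<p>")[1]
        assert body.index("x") < body.index("y")

    def test_tokens_html_escaped(self):
        attr = self._attr(["<script>"], [1.0, 0, 0, 0])
        html = ex.render_highlight(attr, threshold=0.0)
        assert "<script>" not in html and "&lt;script&gt;" in html

    def test_quantile_threshold(self):
        attr = self._attr(["a", "b", "c", "d"], [0.1, 0.2, 0.8, 0.9])
        html = ex.render_highlight(attr, quantile=0.75)
        assert html.count("<mark") == 1


def test_default_target_layer_prefers_deepest_localizing_stage(e2e_run):
    layer = ex.default_target_layer(e2e_run.model, (16, 25, 25))
    # for 25x25 inputs the deepest stage with >= 4x4 extent is layer2 (4x4)
    assert layer == "layer2"


def test_weight_randomization_sanity(e2e_run):
    """CAMs of the trained model decorrelate when the head is re-randomized."""
    import copy

    model = e2e_run.model
    randomized = copy.deepcopy(model)
    r = np.random.default_rng(999)
    randomized.fc.weight.data[...] = r.normal(0, 0.5, randomized.fc.weight.data.shape)
    randomized.fc.bias.data[...] = r.normal(0, 0.5, randomized.fc.bias.data.shape)
    cfg = ex.CamConfig(target_layer="layer1")
    corrs = []
    for i in range(12):
        x = e2e_run.x_val[i]
        c1 = ex.compute_gradcam(model, x, class_id=int(e2e_run.y_val[i]), cfg=cfg)
        c2 = ex.compute_gradcam(randomized, x, class_id=int(e2e_run.y_val[i]), cfg=cfg)
        rho = spearmanr(c1.grid_scores.ravel(), c2.grid_scores.ravel()).statistic
        if np.isnan(rho):  # a constant map has no rank ordering
            rho = 0.0
        corrs.append(rho)
    assert float(np.mean(corrs)) < 0.5


def test_attribution_json_round_trip(tmp_path):
    grid = format_grid(["a", "b"], 2, 2)
    scores = np.array([[1.0, 0.5], [0.0, 0.0]])
    cam = ex.ClassActivationMap(raw=scores, grid_scores=scores, target_class=0,
                                alpha=np.zeros(1))
    attr = ex.attribute_tokens(cam, grid)
    path = tmp_path / "attr.json"
    ex.attribution_to_json(attr, path)
    import json

    data = json.loads(path.read_text())
    assert len(data) == 4
    assert data[0] == {"token": "a", "row": 0, "col": 0, "score": 1.0, "is_pad": False}
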