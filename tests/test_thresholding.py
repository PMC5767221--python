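"""Threshold methods against independent brute-force oracles.

The oracles re-derive each criterion naively (python loops over histogram
bins or window pixels) and never share code with the implementations.
"""

import numpy as np
import pytest

from ratioimg.core_io import ImageStack, Region
from ratioimg.thresholding import (
    ThresholdConfig,
    apply_mask,
    disk_footprint,
    li_fixed_point,
    make_mask_stack,
    threshold_chastagnier,
    threshold_constant,
    threshold_li,
    threshold_median_roi,
    threshold_otsu,
    threshold_phansalkar,
)

N_BINS = 256


# ---------------------------------------------------------------------------
# oracles


def _bin_index(values, lo, hi, n_bins=N_BINS):
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.digitize(values, edges[1:-1], right=False)
    return idx, (edges[:-1] + edges[1:]) / 2.0


def otsu_oracle(frame, n_bins=N_BINS):
    """Exhaustive within-class-variance minimization, naive per-bin loops."""
    vals = frame.ravel()
    idx, centers = _bin_index(vals, vals.min(), vals.max(), n_bins)
    best_crit, best_k = np.inf, None
    for k in range(n_bins - 1):
        below = centers[idx[idx <= k]]
        above = centers[idx[idx > k]]
        if below.size == 0 or above.size == 0:
            continue
        within = below.size * below.var() + above.size * above.var()
        if within < best_crit:
            best_crit, best_k = within, k
    return centers[best_k]


def li_oracle(frame, n_bins=N_BINS):
    """Exhaustive cross-entropy minimization from the raw values, per bin."""
    vals = frame.ravel().astype(float)
    idx, centers = _bin_index(vals, vals.min(), vals.max(), n_bins)
    best_crit, best_k = np.inf, None
    for k in range(n_bins - 1):
        below = vals[idx <= k]
        above = vals[idx > k]
        if below.size == 0 or above.size == 0:
            continue
        mu0, mu1 = below.mean(), above.mean()
        if mu0 <= 0 or mu1 <= 0:
            continue
        crit = -(below.sum() * np.log(mu0) + above.sum() * np.log(mu1))
        if crit < best_crit:
            best_crit, best_k = crit, k
    return centers[best_k]


def phansalkar_oracle(frame, radius, k, r, p, q):
    """Literal windowed-formula evaluation with explicit window enumeration."""
    frame = np.asarray(frame, dtype=float)
    vmax = frame.max()
    if vmax <= 0:
        return np.zeros(frame.shape, dtype=np.uint8)
    img = frame / vmax
    padded = np.pad(img, radius, mode="symmetric")
    fp = disk_footprint(radius)
    h, w = img.shape
    mask = np.zeros((h, w), dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            window = padded[y : y + 2 * radius + 1, x : x + 2 * radius + 1][fp]
            mu = window.mean()
            sd = window.std()
            t = mu * (1.0 + p * np.exp(-q * mu) + k * (sd / r - 1.0))
            mask[y, x] = 1 if img[y, x] > t else 0
    return mask


def _neuron_frame(rng, one_px_neurite=True):
    """Bright soma + thin dim neurite + noise (the composite's target case)."""
    from skimage.draw import disk, line

    frame = np.zeros((128, 128))
    labels = np.zeros((128, 128), dtype=int)
    rr, cc = disk((64, 64), 12, shape=frame.shape)
    frame[rr, cc] = 1000.0
    labels[rr, cc] = 1
    rr, cc = line(64, 76, 64, 120)
    frame[rr, cc] = 60.0
    labels[rr, cc] = 2
    if not one_px_neurite:
        frame[rr + 1, cc] = 60.0
        labels[rr + 1, cc] = 2
    frame = frame + rng.normal(0, 5.0, frame.shape)
    return np.clip(frame, 0, None), labels


# ---------------------------------------------------------------------------
# global thresholds


class TestConstant:
    def test_all_below(self):
        stack = ImageStack(np.full((2, 4, 4), 3.0))
        assert threshold_constant(stack, 5.0).frames.sum() == 0

    def test_strict_greater(self):
        stack = ImageStack(np.array([[[1.0, 5.0], [10.0, 20.0]]]))
        np.testing.assert_array_equal(
            threshold_constant(stack, 5.0).frames[0], [[0, 0], [1, 1]]
        )

    def test_zero_threshold(self, rng):
        frames = np.round(rng.random((2, 8, 8)) * 3)
        mask = threshold_constant(ImageStack(frames), 0.0)
        np.testing.assert_array_equal(mask.frames, (frames > 0).astype(np.uint8))


class TestMedianRoi:
    region = Region("ref", "rectangle", [(0, 0), (3, 3)], role="threshold-reference")

    def test_median_of_region(self):
        frame = np.zeros((8, 8))
        frame[:3, :3] = np.arange(1, 10).reshape(3, 3)
        mask = threshold_median_roi(ImageStack(frame[None]), self.region)
        # threshold 5: region pixels 6..9 survive
        assert mask.frames[0][:3, :3].sum() == 4

    def test_scaling_tracks_intensity(self, rng):
        frame = rng.random((16, 16)) * 100
        stack = ImageStack(np.stack([frame, 2.0 * frame]))
        region = Region("ref", "rectangle", [(2, 2), (10, 10)], role="threshold-reference")
        mask = threshold_median_roi(stack, region)
        np.testing.assert_array_equal(mask.frames[0], mask.frames[1])

    def test_uniform_region_fully_removed(self):
        frame = np.full((8, 8), 7.0)
        frame[5, 5] = 9.0
        mask = threshold_median_roi(ImageStack(frame[None]), self.region)
        assert mask.frames[0][:3, :3].sum() == 0  # strict >
        assert mask.frames[0][5, 5] == 1


class TestOtsu:
    def test_bimodal_two_values(self):
        frame = np.concatenate([np.full(32, 10.0), np.full(32, 200.0)]).reshape(8, 8)
        thr, mask = threshold_otsu(frame)
        assert 10.0 < thr < 200.0
        assert mask.sum() == 32
        np.testing.assert_array_equal(mask, (frame == 200.0).astype(np.uint8))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        frame = rng.integers(0, 256, size=(64, 64)).astype(float) ** 1.3
        thr, _ = threshold_otsu(frame)
        assert thr == pytest.approx(otsu_oracle(frame), abs=1e-9)

    def test_gaussian_mixture_misclassification(self):
        rng = np.random.default_rng(7)
        labels = rng.random((64, 64)) < 0.5
        frame = np.where(labels, rng.normal(180, 10, (64, 64)), rng.normal(30, 10, (64, 64)))
        _, mask = threshold_otsu(frame)
        assert (mask.astype(bool) != labels).mean() < 0.01

    def test_constant_frame_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            _, mask = threshold_otsu(np.full((8, 8), 5.0))
        assert mask.sum() == 0
        assert "constant" in caplog.text


class TestLi:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        frame = rng.gamma(2.0, 30.0, size=(64, 64))
        thr, _ = threshold_li(frame)
        assert thr == pytest.approx(li_oracle(frame), abs=1e-9)

    def test_two_values_separated(self):
        frame = np.concatenate([np.full(40, 5.0), np.full(24, 80.0)]).reshape(8, 8)
        thr, mask = threshold_li(frame)
        assert 5.0 < thr < 80.0
        np.testing.assert_array_equal(mask, (frame == 80.0).astype(np.uint8))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            threshold_li(np.array([[-1.0, 2.0]]))

    @pytest.mark.parametrize("seed", range(3))
    def test_fixed_point_converges(self, seed):
        rng = np.random.default_rng(seed)
        frame = rng.gamma(2.0, 30.0, size=(64, 64))
        _, n_iter = li_fixed_point(frame)
        assert n_iter < 100

    def test_constant_frame_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            _, mask = threshold_li(np.zeros((4, 4)))
        assert mask.sum() == 0


class TestPhansalkar:
    def test_constant_window_closed_form(self):
        # plateau at normalized 0.5 (max pixel far away sets the scale)
        frame = np.full((40, 40), 50.0)
        frame[0, 0] = 100.0
        k, r, p, q = 0.25, 0.5, 2.0, 10.0
        mask = threshold_phansalkar(frame, radius=5, k=k, r=r, p=p, q=q)
        m = 0.5
        t = m * (1.0 + p * np.exp(-q * m) + k * (0.0 / r - 1.0))
        assert (m > t) == bool(mask[20, 20])
        assert mask[20, 20] == 1  # 0.5 > 0.3817...

    @pytest.mark.parametrize("radius", [3, 5])
    def test_matches_windowed_oracle(self, radius, rng):
        frame = rng.random((16, 16)) * 200
        mask = threshold_phansalkar(frame, radius=radius)
        oracle = phansalkar_oracle(frame, radius, 0.25, 0.5, 2.0, 10.0)
        np.testing.assert_array_equal(mask, oracle)

    def test_all_zero_frame(self):
        assert threshold_phansalkar(np.zeros((8, 8))).sum() == 0


class TestChastagnier:
    def test_superset_of_otsu(self, rng):
        for _ in range(10):
            frame = rng.gamma(2.0, 50.0, size=(32, 32))
            mask = threshold_chastagnier(frame)
            _, otsu = threshold_otsu(frame)
            assert np.all(mask >= otsu)

    def test_binary_and_value_preserving(self, rng):
        frame, _ = _neuron_frame(rng)
        mask = threshold_chastagnier(frame)
        assert set(np.unique(mask)) <= {0, 1}
        masked = mask * frame
        keep = mask == 1
        np.testing.assert_array_equal(masked[keep], frame[keep])
        assert (masked[~keep] == 0).all()

    def test_neurite_recall_beats_otsu(self, rng):
        frame, labels = _neuron_frame(rng, one_px_neurite=True)
        mask = threshold_chastagnier(frame)
        _, otsu = threshold_otsu(frame)
        neurite = labels == 2
        assert mask[neurite].mean() > otsu[neurite].mean()

    def test_constant_frame_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            mask = threshold_chastagnier(np.full((16, 16), 3.0))
        assert mask.sum() == 0

    def test_sigma_order_enforced(self):
        with pytest.raises(ValueError, match="sigma_low"):
            threshold_chastagnier(np.zeros((8, 8)), sigma_low=5.0, sigma_high=2.0)


class TestApplyMask:
    def test_identity_and_annihilation(self, rng):
        frames = rng.random((2, 8, 8))
        stack = ImageStack(frames)
        from ratioimg.core_io import MaskStack

        ones = MaskStack(np.ones_like(frames, dtype=np.uint8))
        zeros = MaskStack(np.zeros_like(frames, dtype=np.uint8))
        np.testing.assert_array_equal(apply_mask(stack, ones).frames, frames)
        np.testing.assert_array_equal(apply_mask(stack, zeros).frames, 0.0)

    def test_mixed_mask_bit_identical_where_kept(self, rng):
        frames = rng.random((1, 8, 8))
        from ratioimg.core_io import MaskStack

        m = MaskStack((rng.random((1, 8, 8)) > 0.5).astype(np.uint8))
        out = apply_mask(ImageStack(frames), m)
        keep = m.frames == 1
        np.testing.assert_array_equal(out.frames[keep], frames[keep])


class TestMakeMaskStack:
    def test_constant_dispatch(self, rng):
        frames = rng.random((3, 8, 8)) * 10
        stack = ImageStack(frames)
        cfg = ThresholdConfig(method="constant", constant_value=5.0)
        np.testing.assert_array_equal(
            make_mask_stack(stack, cfg).frames, threshold_constant(stack, 5.0).frames
        )

    def test_per_frame_adaptation_on_decay(self, rng):
        frame, labels = _neuron_frame(rng, one_px_neurite=False)
        stack = ImageStack(np.stack([frame, frame / 2.0]))
        chast = make_mask_stack(stack, ThresholdConfig(method="chastagnier"))
        soma = labels == 1
        # per-frame composite retains the soma in both frames
        assert chast.frames[0][soma].mean() > 0.95
        assert chast.frames[1][soma].mean() > 0.95
        # constant threshold fixed from frame 0's Otsu loses frame 1's dim structures
        thr0, _ = threshold_otsu(stack.frames[0])
        const = make_mask_stack(stack, ThresholdConfig(method="constant", constant_value=thr0))
        neurite = labels == 2
        assert chast.frames[1][neurite].sum() > const.frames[1][neurite].sum()

    def test_mask_count_monotone_for_constant_on_decay(self, rng):
        frame, _ = _neuron_frame(rng, one_px_neurite=False)
        stack = ImageStack(np.stack([frame * (0.8**t) for t in range(5)]))
        const = make_mask_stack(stack, ThresholdConfig(method="constant", constant_value=50.0))
        counts = [const.frames[t].sum() for t in range(5)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_method(self):
        with pytest.raises(ValueError, match="unknown threshold method"):
            ThresholdConfig(method="huang")

    def test_median_roi_requires_region(self):
        with pytest.raises(ValueError, match="reference_region"):
            ThresholdConfig(method="median_roi")
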