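import numpy as np
import pytest
from skimage.draw import disk as sk_disk

from haemorasis import synthetic, wbc
from haemorasis.io_core import Tile
from haemorasis.wbc import (
    DIHEDRAL,
    IDENTITY_ONLY,
    DegenerateCellError,
    PostprocessParams,
    postprocess,
    segment_nucleus,
    segment_probabilities,
    train_segmenter,
)


class _ConstantBackend:
    """Equivariant toy backend: probability = scaled grayscale."""

    input_size = None

    def predict_proba_map(self, pixels):
        return pixels.mean(axis=2) / 255.0


class _NoisyBackend:
    def __init__(self, rng):
        self.rng = rng

    input_size = None

    def predict_proba_map(self, pixels):
        base = pixels.mean(axis=2) / 255.0
        return np.clip(base + self.rng.normal(0, 0.1, size=base.shape), 0, 1)


def _tile(arr):
    return Tile(pixels=arr)


class TestTTA:
    def test_identity_only_equals_plain(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
        backend = _ConstantBackend()
        plain = segment_probabilities(backend, _tile(arr))
        tta = segment_probabilities(backend, _tile(arr), tta=True,
                                    transforms=IDENTITY_ONLY)
        np.testing.assert_array_equal(plain, tta)

    def test_equivariant_backend_symmetric_input(self):
        """On a 4-fold symmetric input with a pointwise backend, dihedral TTA
        equals the single pass."""
        quarter = np.random.default_rng(1).integers(0, 255, (16, 16, 3))
        arr = np.zeros((32, 32, 3), dtype=np.uint8)
        sym = np.minimum(quarter, quarter[::-1])      # vertical symmetry
        sym = np.minimum(sym, sym[:, ::-1])           # horizontal symmetry
        sym = np.minimum(sym, sym.transpose(1, 0, 2))  # diagonal symmetry
        arr[:16, :16] = sym
        arr[16:, :16] = sym[::-1]
        arr[:16, 16:] = sym[:, ::-1]
        arr[16:, 16:] = sym[::-1, ::-1]
        backend = _ConstantBackend()
        plain = segment_probabilities(backend, _tile(arr))
        tta = segment_probabilities(backend, _tile(arr), tta=True)
        np.testing.assert_allclose(plain, tta, atol=1e-12)

    def test_tta_reduces_variance_of_noisy_backend(self):
        rng = np.random.default_rng(2)
        arr = rng.integers(0, 255, (24, 24, 3)).astype(np.uint8)
        single, averaged = [], []
        backend = _NoisyBackend(rng)
        for _ in range(100):
            single.append(segment_probabilities(backend, _tile(arr)))
            averaged.append(segment_probabilities(backend, _tile(arr), tta=True))
        var_single = np.stack(single).var(axis=0).mean()
        var_tta = np.stack(averaged).var(axis=0).mean()
        assert var_tta <= var_single

    def test_group_averaged_predictor_is_fixed_point(self):
        """TTA applied to an already dihedral-averaged predictor changes
        nothing."""
        rng = np.random.default_rng(3)
        arr = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)

        class Averaged:
            input_size = None

            def predict_proba_map(self, pixels):
                inner = _ConstantBackend()
                acc = None
                for fwd, inv in DIHEDRAL:
                    p = inv(inner.predict_proba_map(np.ascontiguousarray(fwd(pixels))))
                    acc = p if acc is None else acc + p
                return acc / len(DIHEDRAL)

        backend = Averaged()
        plain = segment_probabilities(backend, _tile(arr))
        tta = segment_probabilities(backend, _tile(arr), tta=True)
        np.testing.assert_allclose(plain, tta, atol=1e-12)


class TestPostprocess:
    def test_all_zero_map(self):
        assert postprocess(np.zeros((64, 64))) == []

    def test_single_disc_identity(self):
        prob = np.zeros((100, 100))
        rr, cc = sk_disk((50, 50), 25)
        prob[rr, cc] = 0.9
        instances = postprocess(prob, PostprocessParams(min_area=500, max_area=10000))
        assert len(instances) == 1
        assert instances[0].sum() == (prob >= 0.5).sum()

    def test_area_gate(self):
        prob = np.zeros((100, 100))
        rr, cc = sk_disk((30, 30), 5)   # area ~78, below the gate
        prob[rr, cc] = 1.0
        rr, cc = sk_disk((70, 70), 20)  # area ~1250, inside the gate
        prob[rr, cc] = 1.0
        instances = postprocess(prob, PostprocessParams(min_area=300, max_area=15000))
        assert len(instances) == 1

    def test_hole_fill(self):
        prob = np.zeros((80, 80))
        rr, cc = sk_disk((40, 40), 20)
        prob[rr, cc] = 1.0
        rr, cc = sk_disk((40, 40), 8)
        prob[rr, cc] = 0.0  # hollow center
        instances = postprocess(prob, PostprocessParams(min_area=300, max_area=15000))
        assert len(instances) == 1
        assert instances[0][40, 40]  # hole filled

    def test_dumbbell_split_when_enabled(self):
        prob = np.zeros((120, 200))
        rr, cc = sk_disk((60, 55), 28)
        prob[rr, cc] = 1.0
        rr, cc = sk_disk((60, 145), 28)
        prob[rr, cc] = 1.0
        prob[59:62, 55:146] = 1.0  # thin bridge
        merged = postprocess(prob, PostprocessParams(min_area=300, max_area=20000,
                                                     split_touching=False))
        assert len(merged) == 1
        split = postprocess(prob, PostprocessParams(min_area=300, max_area=20000,
                                                    split_touching=True))
        assert len(split) == 2

    def test_instances_disjoint_and_within_gate(self):
        rng = np.random.default_rng(4)
        prob = rng.random((128, 128))
        params = PostprocessParams(min_area=20, max_area=2000)
        instances = postprocess(prob, params)
        total = np.zeros((128, 128), dtype=int)
        for inst in instances:
            total += inst.astype(int)
            assert params.min_area <= inst.sum() <= params.max_area
        assert total.max() <= 1


class TestNucleus:
    def _two_tone_cell(self, invert=False):
        scene = synthetic.TileScene(
            shape=(96, 96), noise_sigma=0.0,
            wbc_specs=[synthetic.WBCSpec(center=(48, 48), radius=25, n_lobes=1)],
        )
        tile, gt = synthetic.render_tile(scene, seed=0)
        pixels = tile.pixels
        if invert:
            pixels = (255 - pixels).astype(np.uint8)
        return pixels, gt.masks_of(synthetic.CLASS_WBC)[0], gt.nucleus_mask

    def test_two_tone_cell_recovers_nucleus(self):
        pixels, cell, true_nuc = self._two_tone_cell()
        nuc = segment_nucleus(pixels, cell)
        disagreement = (nuc ^ true_nuc)[cell].sum() / cell.sum()
        assert disagreement <= 0.02

    def test_inverted_contrast_returns_darker_region(self):
        """On an inverted image the darker cluster is the cytoplasm — the
        documented low-contrast failure mode."""
        pixels, cell, true_nuc = self._two_tone_cell(invert=True)
        nuc = segment_nucleus(pixels, cell)
        overlap = (nuc & true_nuc).sum() / true_nuc.sum()
        assert overlap < 0.1  # picked the complement

    def test_nucleus_darker_than_rest_always(self, wbc_training_set):
        tiles, masks = wbc_training_set
        gray = lambda p: p.astype(float).mean(axis=2)
        for tile, cell in zip(tiles[:8], masks[:8]):
            if not cell.any():
                continue
            nuc = segment_nucleus(tile.pixels, cell)
            rest = cell & ~nuc
            if nuc.any() and rest.any():
                g = gray(tile.pixels)
                assert g[nuc].mean() < g[rest].mean()

    def test_nucleus_subset_of_cell(self):
        pixels, cell, _ = self._two_tone_cell()
        nuc = segment_nucleus(pixels, cell)
        assert not (nuc & ~cell).any()

    def test_constant_cell_rejected(self):
        pixels = np.full((40, 40, 3), 100, dtype=np.uint8)
        cell = np.zeros((40, 40), bool)
        cell[10:30, 10:30] = True
        with pytest.raises(DegenerateCellError):
            segment_nucleus(pixels, cell)


class TestTrainSegmenter:
    def test_heldout_iou(self, wbc_training_set, trained_segmenter):
        tiles, masks = wbc_training_set
        ious = []
        for tile, mask in zip(tiles[40:], masks[40:]):
            prob = segment_probabilities(trained_segmenter, tile, tta=True)
            pred = np.zeros_like(mask)
            for inst in postprocess(prob, PostprocessParams(min_area=200,
                                                            max_area=15000)):
                pred |= inst
            ious.append((pred & mask).sum() / max((pred | mask).sum(), 1))
        assert np.mean(ious) >= 0.7

    def test_loss_decreases(self, trained_segmenter):
        hist = trained_segmenter.loss_history_
        assert hist[-1] < hist[0]

    def test_zero_epochs_is_initialization(self, wbc_training_set):
        tiles, masks = wbc_training_set
        model = train_segmenter(tiles[:5], masks[:5], epochs=0, seed=0)
        assert np.all(model.weights == 0)
        prob = segment_probabilities(model, tiles[0])
        np.testing.assert_allclose(prob, 0.5)

    def test_same_seed_identical(self, wbc_training_set):
        tiles, masks = wbc_training_set
        m1 = train_segmenter(tiles[:10], masks[:10], epochs=3, seed=7)
        m2 = train_segmenter(tiles[:10], masks[:10], epochs=3, seed=7)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert m1.bias == m2.bias

    def test_empty_annotations_rejected(self):
        with pytest.raises(ValueError):
            train_segmenter([], [], epochs=1, seed=0)
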