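"""Shared fixtures: expensive synthetic benchmarks are session-scoped so the
unit suite and the end-to-end checks reuse one computation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from haemorasis import mil, qc, rbc, synthetic, wbc


@pytest.fixture(scope="session")
def planted_bags():
    """Well-separated planted cohort: 60 slides x 200 cells, d=10, K_true=4."""
    design = synthetic.default_bag_design(
        d=10, k_true=4, n_slides_per_condition=12,
        cells_per_slide=(200, 200), seed=11,
    )
    bags, assignments = synthetic.simulate_bags(design)
    return design, bags, assignments


@pytest.fixture(scope="session")
def mil_recovery(planted_bags):
    """5-fold CV of the morphotype model (K=10) plus stability selection."""
    design, bags, _ = planted_bags
    cv = mil.crossvalidate(bags, k=10, objectives=list(mil.TASKS),
                           folds=5, seed=1)
    report = mil.stability_select(cv.fold_models, threshold=0.8,
                                  reference_fold=cv.best_fold)
    return design, bags, cv, report


@pytest.fixture(scope="session")
def qc_benchmark():
    """200 labeled tiles (good vs blank/dense/blurred) and a trained QC model."""
    tiles, labels = synthetic.qc_benchmark(seed=3, n_good=100, n_poor=100)
    model = qc.train_qc(tiles, labels, seed=3)
    return tiles, labels, model


@pytest.fixture(scope="session")
def rbc_filter_benchmark():
    """Candidates from disc+clump scenes with ground-truth labels and a
    trained gradient-boosted filter."""
    feats, labels = [], []
    for s in range(40):
        scene = synthetic.clumped_scene(seed=100 + s)
        tile, gt = synthetic.render_tile(scene, seed=100 + s)
        cands = rbc.detect_rbc_candidates(tile)
        y = rbc.label_candidates(cands, gt.masks_of(synthetic.CLASS_RBC))
        feats.append(rbc.candidate_features(tile, cands))
        labels.append(y)
    X = pd.concat(feats, ignore_index=True)
    y = np.concatenate(labels)
    model = rbc.train_rbc_filter(X, y, seed=11)
    return X, y, model


@pytest.fixture(scope="session")
def wbc_training_set():
    """50 small synthetic tiles with white-cell ground truth masks."""
    tiles, masks = [], []
    for i in range(50):
        scene = synthetic.random_scene(
            seed=500 + i, shape=(128, 128), n_rbc=5, n_wbc=1,
            n_platelet=2, wbc_radius=20, rbc_radius=11,
        )
        tile, gt = synthetic.render_tile(scene, seed=500 + i)
        mask = np.zeros((128, 128), dtype=bool)
        for m in gt.masks_of(synthetic.CLASS_WBC):
            mask |= m
        tiles.append(tile)
        masks.append(mask)
    return tiles, masks


@pytest.fixture(scope="session")
def trained_segmenter(wbc_training_set):
    tiles, masks = wbc_training_set
    model = wbc.train_segmenter(tiles[:40], masks[:40], epochs=20, seed=5)
    return model
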