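"""Unit, property and cross-library tests for consensus and agreement."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from judicam import agreement
from judicam.cam_algorithms import SaliencyMap
from judicam.strategies import JuxtaposedEvidence
from judicam.synthetic_data import simulate_raters

# ---------------------------------------------------------------- STAPLE


def _toy_truth():
    truth = np.zeros((32, 32), dtype=bool)
    truth[8:20, 10:26] = True
    return truth


def test_staple_unanimous_raters_return_their_mask():
    truth = _toy_truth()
    result = agreement.staple([truth, truth, truth])
    assert np.array_equal(result.consensus_mask, truth)
    assert result.converged


def test_staple_all_empty_masks_give_empty_consensus():
    empty = np.zeros((8, 8), dtype=bool)
    result = agreement.staple([empty, empty])
    assert not result.consensus_mask.any()


def test_staple_requires_two_raters():
    with pytest.raises(ValueError):
        agreement.staple([_toy_truth()])


def test_staple_is_invariant_under_rater_reordering():
    truth = _toy_truth()
    raters = simulate_raters(truth, n_raters=5, sens=0.85, spec=0.95, smooth_radius=0, seed=4)
    a = agreement.staple(raters.masks)
    b = agreement.staple(raters.masks[::-1])
    assert np.array_equal(a.consensus_mask, b.consensus_mask)
    assert np.allclose(a.sensitivities, b.sensitivities[::-1])


def test_staple_outvotes_one_bad_rater():
    truth = _toy_truth()
    good = simulate_raters(truth, n_raters=4, sens=0.95, spec=0.98, smooth_radius=0, seed=9).masks
    bad = ~truth  # adversarial rater
    result = agreement.staple(good + [bad])
    inter = (result.consensus_mask & truth).sum()
    dice = 2.0 * inter / (result.consensus_mask.sum() + truth.sum())
    assert dice > 0.9
    assert result.sensitivities[-1] < 0.5  # the bad rater is identified


def test_staple_matches_simpleitk_consensus():
    sitk = pytest.importorskip("SimpleITK")
    truth = _toy_truth()
    raters = simulate_raters(truth, n_raters=5, sens=0.9, spec=0.96, smooth_radius=0, seed=13)
    ours = agreement.staple(raters.masks)
    images = [sitk.GetImageFromArray(m.astype(np.uint8)) for m in raters.masks]
    prob = sitk.GetArrayFromImage(sitk.STAPLE(images, 1.0))
    theirs = prob >= 0.5
    overlap = (ours.consensus_mask == theirs).mean()
    assert overlap > 0.99  # same consensus up to edge-pixel prior differences


# ---------------------------------------------------------------- kappas


def test_fleiss_kappa_matches_statsmodels():
    statsmodels = pytest.importorskip("statsmodels.stats.inter_rater")
    rng = np.random.default_rng(3)
    masks = [rng.uniform(size=(16, 16)) < 0.4 for _ in range(4)]
    table = np.stack([np.stack(masks).sum(axis=0).ravel()], axis=1)
    table = np.concatenate([4 - table, table], axis=1)
    expected = statsmodels.fleiss_kappa(table)
    assert abs(agreement.fleiss_kappa(masks) - expected) < 1e-10


def test_kappas_are_one_on_unanimous_mixed_data():
    mask = _toy_truth()
    assert agreement.fleiss_kappa([mask, mask, mask]) == pytest.approx(1.0)
    assert agreement.cohen_kappa(mask, mask) == pytest.approx(1.0)


def test_cohen_kappa_is_minus_one_for_balanced_complement():
    mask = np.array([True] * 50 + [False] * 50)
    assert agreement.cohen_kappa(mask, ~mask) == pytest.approx(-1.0)


def test_kappas_reject_degenerate_inputs():
    ones = np.ones((4, 4), dtype=bool)
    with pytest.raises(ValueError):
        agreement.fleiss_kappa([ones, ones])
    with pytest.raises(ValueError):
        agreement.fleiss_kappa([ones])
    with pytest.raises(ValueError):
        agreement.cohen_kappa(ones, ones)


# ------------------------------------------------------- masks & overlap


def test_binarize_map_uses_strict_mean_plus_std_threshold():
    values = np.zeros((10, 10))
    values[0, 0] = 1.0
    mask = agreement.binarize_map(values)
    # mu = 0.01, sigma = sqrt(0.01*0.99^2 + 0.99*0.01^2) ~ 0.0995
    assert mask[0, 0] and mask.sum() == 1
    constant = np.full((5, 5), 0.7)
    assert not agreement.binarize_map(constant).any()  # strict > keeps it empty
    smap = SaliencyMap(values=values)
    assert np.array_equal(agreement.binarize_map(smap), mask)


def test_iou_and_iogt_edge_cases():
    empty = np.zeros((4, 4), dtype=bool)
    full = np.ones((4, 4), dtype=bool)
    assert agreement.iou(empty, empty) == 0.0
    assert agreement.iou(full, full) == 1.0
    with pytest.raises(ValueError):
        agreement.iogt(full, empty)
    with pytest.raises(ValueError):
        agreement.iou(full, np.ones((3, 4), dtype=bool))


@settings(max_examples=50, deadline=None)
@given(arrays(bool, (6, 6)))
def test_fill_holes_is_idempotent_and_superset(mask):
    filled = agreement.fill_holes(mask)
    assert np.array_equal(agreement.fill_holes(filled), filled)
    assert (filled | mask).sum() == filled.sum()  # superset of the input


def test_fill_holes_closes_an_interior_hole():
    ring = np.zeros((7, 7), dtype=bool)
    ring[1:6, 1:6] = True
    ring[3, 3] = False
    assert agreement.fill_holes(ring)[3, 3]


def _bundle(values_by_slot, image_id):
    maps = {
        (p, l): SaliencyMap(values=v, polarity=p, level=l, algorithm="test")
        for (p, l), v in values_by_slot.items()
    }
    return JuxtaposedEvidence(maps=maps, approach="single", image_id=image_id)


def test_overlap_study_perfect_maps_score_one():
    gt = np.zeros((16, 16), dtype=bool)
    gt[4:9, 5:12] = True
    perfect = gt.astype(float)
    slots = {(p, l): perfect for p in ("positive", "negative") for l in ("AM3", "AM4")}
    report = agreement.overlap_study([_bundle(slots, "img0")], {"img0": gt})
    for _, row in report.rows.iterrows():
        assert row["IoU"] == pytest.approx(1.0)
        assert row["IoGT"] == pytest.approx(1.0)


def test_overlap_study_rejects_missing_ground_truth():
    gt = np.zeros((8, 8), dtype=bool)
    gt[2, 2] = True
    slots = {(p, l): gt.astype(float) for p in ("positive", "negative") for l in ("AM3", "AM4")}
    with pytest.raises(ValueError):
        agreement.overlap_study([_bundle(slots, "unknown")], {"img0": gt})
    with pytest.raises(ValueError):
        agreement.overlap_study([], {})
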