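"""Template matching, candidate features and detection metrics (unit level)."""

import numpy as np
import pandas as pd
import pytest

from cochleamap import detect as det
from cochleamap.linearize import LinearizedVolume, SpiralModel


def _linv_from_array(data):
    """Wrap a (s, r, v) array as a LinearizedVolume with a straight spiral."""
    ns = data.shape[0]
    s = np.arange(ns, dtype=float)
    curve = np.stack([s, np.zeros(ns), np.zeros(ns)], axis=1)
    spiral = SpiralModel(
        curve=curve,
        s=s,
        tangent=np.tile([1.0, 0, 0], (ns, 1)),
        radial=np.tile([0, 1.0, 0], (ns, 1)),
        vertical=np.tile([0, 0, 1.0], (ns, 1)),
    )
    return LinearizedVolume(
        data.astype(np.float32), spiral, (0.0, float(data.shape[1])), (0.0, float(data.shape[2]))
    )


def _blob(shape, centers, amp=1000.0, sigma=2.0):
    s, r, v = np.indices(shape, dtype=np.float32)
    out = np.zeros(shape, dtype=np.float32)
    for c in centers:
        out += amp * np.exp(
            -((s - c[0]) ** 2 + (r - c[1]) ** 2 + (v - c[2]) ** 2) / (2 * sigma**2)
        )
    return out


def test_template_matches_own_copy_with_correlation_one():
    templ = _blob((11, 11, 11), [(5, 5, 5)])
    data = np.zeros((60, 30, 30), dtype=np.float32)
    data[20:31, 10:21, 8:19] = templ
    linv = _linv_from_array(data)
    corr, peaks = det.match_template_volume(linv, templ, threshold=0.5)
    idx = np.unravel_index(np.argmax(corr), corr.shape)
    assert corr.max() == pytest.approx(1.0, abs=1e-4)
    assert idx == (25, 15, 13)


def test_template_against_negative_is_anticorrelated():
    templ = _blob((11, 11, 11), [(5, 5, 5)])
    data = np.zeros((40, 30, 30), dtype=np.float32)
    data[10:21, 10:21, 10:21] = -templ
    linv = _linv_from_array(data)
    corr, _ = det.match_template_volume(linv, templ, threshold=0.99)
    assert corr.min() == pytest.approx(-1.0, abs=1e-4)


def test_flat_template_rejected():
    linv = _linv_from_array(np.random.default_rng(0).normal(0, 1, (30, 20, 20)))
    with pytest.raises(ValueError):
        det.match_template_volume(linv, np.ones((5, 5, 5)), 0.3)


def test_adjacent_peak_pixels_form_one_candidate():
    corr = np.zeros((30, 20, 20), dtype=np.float32)
    peaks = np.zeros_like(corr, dtype=bool)
    corr[10, 10, 10] = corr[10, 11, 10] = 0.8
    peaks[10, 10, 10] = peaks[10, 11, 10] = True
    linv = _linv_from_array(np.ones((30, 20, 20)))
    cands = det.form_candidates(corr, peaks, linv)
    assert len(cands) == 1
    assert cands.df.area.iloc[0] == 2


def test_isolated_peak_candidate_has_area_one_and_sentinels():
    corr = np.zeros((30, 20, 20), dtype=np.float32)
    peaks = np.zeros_like(corr, dtype=bool)
    corr[15, 10, 10] = 0.9
    peaks[15, 10, 10] = True
    linv = _linv_from_array(np.ones((30, 20, 20)))
    cands = det.form_candidates(corr, peaks, linv)
    assert len(cands) == 1
    assert cands.df.area.iloc[0] == 1
    assert cands.df.nn_area.iloc[0] == 0.0  # lone-candidate sentinel


def test_sector_features_place_neighbors_by_angle():
    df = pd.DataFrame(
        {
            "s": [50.0, 60.0, 50.0],
            "r": [10.0, 10.0, 18.0],
            "v": [0.0, 0.0, 0.0],
        }
    )
    for col in det.STAGE1_FEATURES:
        if col not in df:
            df[col] = 1.0
    linv = _linv_from_array(np.ones((100, 30, 10)))
    cands = det.CandidateSet(df, linv=linv)
    det.add_sector_features(cands, np.array([0.5, 0.7, 0.9]))
    row0 = cands.df.iloc[0]
    # neighbor 1 is at ds=+10, dr=0 -> angle 90 deg from the r axis -> sector 1
    assert row0["sec1_score"] == pytest.approx(0.7)
    # neighbor 2 is at ds=0, dr=+8 -> angle 0 -> sector 0
    assert row0["sec0_score"] == pytest.approx(0.9)
    # empty sectors carry the sentinel
    assert row0["sec3_score"] == -1.0


def test_chain_linking_enforces_min_spacing():
    df = pd.DataFrame(
        {
            "s": [0.0, 5.0, 10.0, 20.0, 30.0],
            "score": [0.9, 0.95, 0.9, 0.9, 0.9],
        }
    )
    chain = det._chain_ihc(df, min_spacing=6.0)
    s = chain.s.to_numpy()
    assert np.all(np.diff(s) > 6.0)
    # total score is maximized: dropping the 5.0 candidate keeps 4 cells
    np.testing.assert_array_equal(s, [0.0, 10.0, 20.0, 30.0])


def test_gap_at_exactly_1_5x_average_not_flagged():
    class AlwaysYes:
        def predict(self, crops):
            return np.ones(len(crops), dtype=int)

    linv = _linv_from_array(np.zeros((200, 30, 10)))
    # spacings 10, 5, 15, 10 -> average exactly 10; the 15 um gap sits
    # exactly at 1.5x the average and must NOT be flagged (strict >)
    acc = pd.DataFrame({"s": [0.0, 10.0, 15.0, 30.0, 40.0], "r": 10.0, "v": 5.0, "row": 1})
    models = type("M", (), {"gap_classifier": AlwaysYes()})()
    pool = pd.DataFrame({"s": [22.5], "r": [10.0], "v": [5.0], "max_corr": [0.5]})
    out = det.recover_gap_cells(linv, models, acc, pool)
    assert len(out) == 0


def test_gap_beyond_threshold_recovers_pool_peak():
    class AlwaysYes:
        def predict(self, crops):
            return np.ones(len(crops), dtype=int)

    linv = _linv_from_array(np.zeros((200, 30, 10)))
    acc = pd.DataFrame(
        {"s": [10.0, 20.0, 30.0, 52.0, 62.0, 72.0], "r": 10.0, "v": 5.0, "row": 1}
    )
    models = type("M", (), {"gap_classifier": AlwaysYes()})()
    pool = pd.DataFrame({"s": [41.0], "r": [10.0], "v": [5.0], "max_corr": [0.6]})
    out = det.recover_gap_cells(linv, models, acc, pool)
    assert len(out) == 1
    assert out.iloc[0].provenance == "gap_recovered"
    assert out.iloc[0].s == 41.0


def test_true_loss_gap_not_recovered_when_classifier_negative():
    class AlwaysNo:
        def predict(self, crops):
            return np.zeros(len(crops), dtype=int)

    linv = _linv_from_array(np.zeros((200, 30, 10)))
    acc = pd.DataFrame(
        {"s": [10.0, 20.0, 30.0, 52.0, 62.0, 72.0], "r": 10.0, "v": 5.0, "row": 1}
    )
    models = type("M", (), {"gap_classifier": AlwaysNo()})()
    pool = pd.DataFrame({"s": [41.0], "r": [10.0], "v": [5.0], "max_corr": [0.6]})
    out = det.recover_gap_cells(linv, models, acc, pool)
    assert len(out) == 0


def test_watershed_separates_two_blobs():
    data = _blob((60, 30, 20), [(20, 15, 10), (45, 15, 10)], sigma=2.5)
    linv = _linv_from_array(data)
    cells = det.watershed_baseline(linv)
    assert len(cells) == 2


def test_watershed_touching_blobs_at_least_two():
    data = _blob((60, 30, 20), [(28, 15, 10), (34, 15, 10)], sigma=2.5)
    linv = _linv_from_array(data)
    cells = det.watershed_baseline(linv)
    assert len(cells) >= 2


def test_evaluate_detection_perfect_and_empty():
    truth = np.random.default_rng(0).uniform(0, 100, (20, 3))
    m = det.evaluate_detection(truth, truth)
    assert m["recover_rate"] == 1.0 and m["accuracy_rate"] == 1.0
    m = det.evaluate_detection(np.zeros((0, 3)), truth)
    assert m["recover_rate"] == 0.0 and m["undetected_n"] == 20


def test_evaluate_detection_hand_enumerated_case():
    truth = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0], [40, 0, 0]], float)
    detected = np.array(
        [[0.5, 0, 0], [10.5, 0, 0], [20.5, 0, 0], [30.5, 0, 0], [70, 0, 0]], float
    )  # 4 matches, 1 miss, 1 extra
    m = det.evaluate_detection(detected, truth)
    assert (m["detected_n"], m["undetected_n"], m["erroneous_n"]) == (4, 1, 1)
    assert m["recover_rate"] == pytest.approx(0.8)
    assert m["accuracy_rate"] == pytest.approx(0.8)


def test_evaluate_detection_permutation_invariant():
    rng = np.random.default_rng(1)
    truth = rng.uniform(0, 200, (30, 3))
    detected = truth[:25] + rng.normal(0, 1, (25, 3))
    m1 = det.evaluate_detection(detected, truth)
    m2 = det.evaluate_detection(detected[::-1], truth[rng.permutation(30)])
    assert m1 == m2


def test_greedy_matching_is_one_to_one():
    truth = np.array([[0, 0, 0]], float)
    detected = np.array([[1, 0, 0], [2, 0, 0]], float)  # both within tolerance
    m = det.evaluate_detection(detected, truth)
    assert m["detected_n"] == 1 and m["erroneous_n"] == 1
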