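"""Template matching plus staged machine-learning detection of hair cells.

The straightened volume is scanned with a self-built cell template
(normalized cross-correlation); connected groups of correlation peaks
become *cell candidates* carrying geometric, intensity and neighborhood
features.  Candidates are filtered by a gradient-boosted tree ensemble
(stage 1, noise reduction), then by a bagged-tree ensemble with expanded
predictors including the stage-1 scores of adjacent candidates in six
60-degree sectors and a resized intensity crop (stage 2, cell
detection).  IHCs are chained into a single row (> 6 um spacing); OHC
candidates are sorted into three rows by a convolutional classifier, and
suspicious within-row gaps (> 1.5x the average spacing) are re-examined
by a second convolutional classifier that can recover missed cells from
the original correlation peaks.  A classic 3D-watershed segmentation is
included as the benchmark baseline.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import match_template, peak_local_max
from skimage.segmentation import watershed
from skimage.transform import resize
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier

from .cnn import TinyConvNet
from .linearize import LinearizedVolume

__all__ = [
    "CandidateSet",
    "DetectorModels",
    "build_template",
    "match_template_volume",
    "form_candidates",
    "train_models",
    "detect_ihc",
    "detect_ohc",
    "recover_gap_cells",
    "detect_cells",
    "watershed_baseline",
    "evaluate_detection",
]

STAGE1_FEATURES = [
    "area", "s", "r", "v", "max_corr", "max_int",
    "nn_area", "nn_s", "nn_r", "nn_v", "nn_max_corr", "nn_max_int",
    "nn_ds", "nn_dr", "nn_dv",
]
N_SECTORS = 6
SECTOR_RADIUS = 40.0       # um; candidates farther than this are "absent"
CROP_H, CROP_W = 69, 39    # row/gap classifier crop (r across rows, s along)
CROP2_W = 21               # stage-2 intensity crop width (s)


def _robust_threshold(data: np.ndarray, k: float = 6.0) -> float:
    sample = data[::2, ::2, ::2].astype(np.float64)
    med = np.median(sample)
    mad = np.median(np.abs(sample - med))
    # floor keeps the threshold above a perfectly flat background (MAD 0)
    floor = max(1.4826 * mad, 1e-3 * (float(sample.max()) - med), 0.5)
    return float(med + k * floor)


def build_template(linv: LinearizedVolume, size: int = 9, top_n: int = 100) -> np.ndarray:
    """Average cell template from the sample's own brightest maxima.

    Crops of ``size``^3 voxels are collected around the ``top_n``
    highest-intensity regional maxima of the straightened volume and
    averaged; the result is mean-subtracted.
    """
    data = linv.data
    thr = _robust_threshold(data)
    maxima = (data == ndimage.maximum_filter(data, size=3)) & (data >= thr)
    pos = np.argwhere(maxima)
    if len(pos) == 0:
        raise ValueError("no intensity maxima found for template construction")
    vals = data[tuple(pos.T)]
    pos = pos[np.argsort(vals)[::-1][:top_n]]
    h = size // 2
    acc = np.zeros((size, size, size), dtype=np.float64)
    count = 0
    for p in pos:
        sl = tuple(slice(c - h, c + h + 1) for c in p)
        if any(s.start < 0 or s.stop > n for s, n in zip(sl, data.shape)):
            continue
        acc += data[sl]
        count += 1
    if count == 0:
        raise ValueError("all template crops fell outside the volume")
    templ = acc / count
    templ -= templ.mean()
    if templ.std() == 0:
        raise ValueError("flat (zero-variance) template")
    return templ.astype(np.float32)


def match_template_volume(
    linv: LinearizedVolume, template: np.ndarray, threshold: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of the template over the volume.

    Returns (correlation volume in [-1, 1], boolean peak mask of
    suprathreshold regional maxima).
    """
    if template.std() == 0:
        raise ValueError("flat (zero-variance) template")
    if any(t >= s for t, s in zip(template.shape, linv.data.shape)):
        raise ValueError("template must be smaller than the volume")
    corr = match_template(linv.data.astype(np.float32), template, pad_input=True)
    peaks = (corr == ndimage.maximum_filter(corr, size=3)) & (corr >= threshold)
    return corr, peaks


@dataclass
class CandidateSet:
    """Cell candidates with geometric, intensity and neighborhood features."""

    df: pd.DataFrame                       # one row per candidate
    crops161: np.ndarray | None = None     # (n, 161) resized intensity crops
    linv: LinearizedVolume | None = field(default=None, repr=False)
    corr: np.ndarray | None = field(default=None, repr=False)
    _crops_done: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.df)


def form_candidates(
    corr: np.ndarray,
    peaks: np.ndarray,
    linv: LinearizedVolume,
    r_window: tuple[float, float] | None = None,
) -> CandidateSet:
    """Group suprathreshold correlation-peak voxels into candidates.

    Adjacent peak voxels (26-connectivity) form one connected group; the
    group's correlation-weighted barycenter, pixel area, maximum
    correlation and maximum image intensity are recorded together with
    the same features of the nearest neighboring group and its relative
    position.  ``r_window`` optionally restricts candidates to a radial
    band (um, in slab coordinates).
    """
    labels, n = ndimage.label(peaks, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return CandidateSet(pd.DataFrame(columns=STAGE1_FEATURES), linv=linv, corr=corr)
    idx = np.arange(1, n + 1)
    area = ndimage.sum_labels(peaks, labels, idx)
    bary = np.array(ndimage.center_of_mass(corr * peaks, labels, idx))
    max_corr = ndimage.maximum(corr, labels, idx)
    max_int = ndimage.maximum(linv.data, labels, idx)
    s = bary[:, 0] + 0.0
    r = bary[:, 1] + linv.r_range[0]
    v = bary[:, 2] + linv.v_range[0]
    df = pd.DataFrame(
        {"area": area, "s": s, "r": r, "v": v, "max_corr": max_corr, "max_int": max_int}
    )
    if r_window is not None:
        df = df[(df.r >= r_window[0]) & (df.r <= r_window[1])].reset_index(drop=True)
    n = len(df)
    if n == 0:
        return CandidateSet(df, linv=linv, corr=corr)
    # nearest-neighbor group features (sentinels for a lone candidate)
    base = df[["area", "s", "r", "v", "max_corr", "max_int"]].to_numpy()
    if n > 1:
        tree = cKDTree(df[["s", "r", "v"]].to_numpy())
        _, nn = tree.query(df[["s", "r", "v"]].to_numpy(), k=2)
        nn = nn[:, 1]
        nn_feat = base[nn]
        rel = df[["s", "r", "v"]].to_numpy()[nn] - df[["s", "r", "v"]].to_numpy()
    else:
        nn_feat = np.zeros((1, 6))
        rel = np.zeros((1, 3))
    for k, name in enumerate(["nn_area", "nn_s", "nn_r", "nn_v", "nn_max_corr", "nn_max_int"]):
        df[name] = nn_feat[:, k]
    df["nn_ds"], df["nn_dr"], df["nn_dv"] = rel[:, 0], rel[:, 1], rel[:, 2]
    return CandidateSet(df, linv=linv, corr=corr)


def _mip_rs(linv: LinearizedVolume) -> np.ndarray:
    """Maximum-intensity projection over v, transposed to (r, s)."""
    return linv.data.max(axis=2).T


def _crop2d(mip: np.ndarray, center_r: float, center_s: float, h: int, w: int) -> np.ndarray:
    """Zero-padded (h, w) crop of the (r, s) projection, centered."""
    out = np.zeros((h, w), dtype=np.float32)
    r0 = int(round(center_r)) - h // 2
    s0 = int(round(center_s)) - w // 2
    r_lo, r_hi = max(r0, 0), min(r0 + h, mip.shape[0])
    s_lo, s_hi = max(s0, 0), min(s0 + w, mip.shape[1])
    if r_lo < r_hi and s_lo < s_hi:
        out[r_lo - r0:r_hi - r0, s_lo - s0:s_hi - s0] = mip[r_lo:r_hi, s_lo:s_hi]
    return out


def extract_crops161(cands: CandidateSet, mask: np.ndarray | None = None) -> np.ndarray:
    """Stage-2 intensity crops: 21 x 69 around each barycenter, resized
    to 7 x 23 and flattened to 161 values.

    Crops are computed lazily and cached: only rows selected by ``mask``
    (default all) that have not been computed yet are extracted.
    """
    n = len(cands)
    if cands.crops161 is None:
        cands.crops161 = np.zeros((n, 161), dtype=np.float32)
        cands._crops_done = np.zeros(n, dtype=bool)
    linv = cands.linv
    mip = _mip_rs(linv)
    scale = max(mip.max(), 1.0)
    want = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(want & ~cands._crops_done)
    pos = cands.df[["s", "r"]].to_numpy()
    for i in idx:
        s, r = pos[i]
        ri = r - linv.r_range[0]
        crop = _crop2d(mip, ri, s, CROP_H, CROP2_W)  # (69, 21): height 69, width 21
        small = resize(crop / scale, (23, 7), anti_aliasing=True)
        cands.crops161[i] = small.reshape(-1)
        cands._crops_done[i] = True
    return cands.crops161


def add_sector_features(cands: CandidateSet, scores: np.ndarray) -> None:
    """Stage-1 scores and relative positions of the nearest candidate in
    six 60-degree sectors of the s-r plane (r axis = initial line).

    Absent sectors get sentinel (-1, 0, 0).
    """
    df = cands.df
    n = len(df)
    feats = np.zeros((n, N_SECTORS, 3), dtype=float)
    feats[:, :, 0] = -1.0
    if n > 1:
        pts = df[["s", "r"]].to_numpy()
        tree = cKDTree(pts)
        neighbors = tree.query_ball_point(pts, SECTOR_RADIUS)
        for i in range(n):
            best = {}
            for j in neighbors[i]:
                if j == i:
                    continue
                ds, dr = pts[j, 0] - pts[i, 0], pts[j, 1] - pts[i, 1]
                d = np.hypot(ds, dr)
                ang = np.arctan2(ds, dr) % (2 * np.pi)  # measured from the r axis
                sec = min(int(ang / (np.pi / 3)), N_SECTORS - 1)
                if sec not in best or d < best[sec][0]:
                    best[sec] = (d, j, ds, dr)
            for sec, (d, j, ds, dr) in best.items():
                feats[i, sec] = (scores[j], ds, dr)
    for sec in range(N_SECTORS):
        df[f"sec{sec}_score"] = feats[:, sec, 0]
        df[f"sec{sec}_ds"] = feats[:, sec, 1]
        df[f"sec{sec}_dr"] = feats[:, sec, 2]


def stage2_features(cands: CandidateSet, mask: np.ndarray | None = None) -> np.ndarray:
    cols = STAGE1_FEATURES + ["stage1_score"] + [
        f"sec{k}_{f}" for k in range(N_SECTORS) for f in ("score", "ds", "dr")
    ]
    crops = extract_crops161(cands, mask)
    return np.hstack([cands.df[cols].to_numpy(), crops])


@dataclass
class DetectorModels:
    """The staged model stack: two tree ensembles per cell kind plus the
    row and gap convolutional classifiers."""

    stage1_ihc: HistGradientBoostingClassifier
    stage2_ihc: RandomForestClassifier
    stage1_ohc: HistGradientBoostingClassifier
    stage2_ohc: RandomForestClassifier
    row_classifier: TinyConvNet
    gap_classifier: TinyConvNet
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in ("stage1_ihc", "stage2_ihc", "stage1_ohc", "stage2_ohc"):
            with open(path / f"{name}.pkl", "wb") as f:
                pickle.dump(getattr(self, name), f)
        np.savez(path / "row_classifier.npz", **self.row_classifier.to_arrays())
        np.savez(path / "gap_classifier.npz", **self.gap_classifier.to_arrays())
        (path / "metadata.json").write_text(json.dumps(self.metadata, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DetectorModels":
        path = Path(path)
        kw = {}
        for name in ("stage1_ihc", "stage2_ihc", "stage1_ohc", "stage2_ohc"):
            with open(path / f"{name}.pkl", "rb") as f:
                kw[name] = pickle.load(f)
        kw["row_classifier"] = TinyConvNet.from_arrays(dict(np.load(path / "row_classifier.npz")))
        kw["gap_classifier"] = TinyConvNet.from_arrays(dict(np.load(path / "gap_classifier.npz")))
        kw["metadata"] = json.loads((path / "metadata.json").read_text())
        return cls(**kw)


def label_candidates(
    cands: CandidateSet, truth_srv: np.ndarray, truth_kind: np.ndarray,
    truth_row: np.ndarray, tolerance: float = 4.0,
) -> pd.DataFrame:
    """Match candidates to ground-truth cells within ``tolerance`` um.

    Returns a frame with boolean ``is_ihc``/``is_ohc`` and ``row``
    (0 = unmatched or IHC) per candidate; matching is one-to-one greedy
    by distance.
    """
    n = len(cands)
    out = pd.DataFrame(
        {"is_ihc": np.zeros(n, bool), "is_ohc": np.zeros(n, bool), "row": np.zeros(n, int)}
    )
    if n == 0 or len(truth_srv) == 0:
        return out
    cpos = cands.df[["s", "r", "v"]].to_numpy()
    pairs = cKDTree(cpos).query_ball_tree(cKDTree(truth_srv), tolerance)
    entries = []
    for i, js in enumerate(pairs):
        for j in js:
            entries.append((np.linalg.norm(cpos[i] - truth_srv[j]), i, j))
    entries.sort()
    used_c, used_t = set(), set()
    for d, i, j in entries:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        if truth_kind[j] == "IHC":
            out.loc[i, "is_ihc"] = True
        else:
            out.loc[i, "is_ohc"] = True
            out.loc[i, "row"] = truth_row[j]
    return out


def _row_crops(cands: CandidateSet, mask: np.ndarray) -> np.ndarray:
    linv = cands.linv
    mip = _mip_rs(linv)
    sel = cands.df[["s", "r"]].to_numpy()[mask]
    crops = np.empty((len(sel), CROP_H, CROP_W), dtype=np.float32)
    for i, (s, r) in enumerate(sel):
        crops[i] = _crop2d(mip, r - linv.r_range[0], s, CROP_H, CROP_W)
    return crops


def build_gap_training_crops(
    linv: LinearizedVolume,
    truth_srv: np.ndarray,
    truth_kind: np.ndarray,
    lost_srv: np.ndarray,
    rng: np.random.Generator,
    max_per_class: int = 120,
) -> tuple[np.ndarray, np.ndarray]:
    """Training crops for the gap classifier.

    Positives are centered on surviving OHCs (with +-2 um jitter);
    negatives on truly lost-cell sites and on midpoints between
    neighboring OHCs (cell-free but near cells).
    """
    mip = _mip_rs(linv)
    ohc = truth_srv[truth_kind == "OHC"]
    pos_idx = rng.permutation(len(ohc))[:max_per_class]
    crops, labels = [], []
    for i in pos_idx:
        s, r = ohc[i, 0] + rng.uniform(-2, 2), ohc[i, 1] + rng.uniform(-1, 1)
        crops.append(_crop2d(mip, r - linv.r_range[0], s, CROP_H, CROP_W))
        labels.append(1)
    neg_sites = list(lost_srv[:, :2]) if len(lost_srv) else []
    # midpoints between left-right neighbors in the same row band
    order = np.argsort(ohc[:, 0])
    oo = ohc[order]
    for a, b in zip(oo[:-1], oo[1:]):
        if abs(a[1] - b[1]) < 3.5 and 5 < b[0] - a[0] < 12:
            neg_sites.append(((a[0] + b[0]) / 2, (a[1] + b[1]) / 2))
    rng.shuffle(neg_sites)
    for s, r in neg_sites[:max_per_class]:
        crops.append(_crop2d(mip, r - linv.r_range[0], s, CROP_H, CROP_W))
        labels.append(0)
    return np.asarray(crops, dtype=np.float32), np.asarray(labels, dtype=int)


def _f_score(y_true, y_pred) -> tuple[float, float, float]:
    tp = int(np.sum(y_true & y_pred))
    recall = tp / max(int(np.sum(y_true)), 1)
    precision = tp / max(int(np.sum(y_pred)), 1)
    f = 2 * recall * precision / max(recall + precision, 1e-12)
    return recall, precision, f


def train_models(
    candidate_sets: list[CandidateSet],
    label_frames: list[pd.DataFrame],
    gap_crops: np.ndarray,
    gap_labels: np.ndarray,
    seed: int = 0,
    ihc_slab_sets: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> DetectorModels:
    """Train the full model stack on labeled candidates from phantoms.

    Stage-1 ensembles (300 boosting stages) are trained on the pooled
    candidates; stage-2 feature vectors use *out-of-phantom* stage-1
    scores (leave-one-phantom-out) so that score distributions match
    inference.  ``ihc_slab_sets`` (feature matrix, label vector pairs
    aligned with ``candidate_sets``) add candidates harvested from the
    narrow IHC slab of the first linearization pass to the stage-1 IHC
    training pool — neighborhood features differ there (the nearest
    group of an IHC is another IHC, not an OHC row-1 cell), so the
    model must see both regimes.  The row classifier is trained on
    crops of matched OHC candidates, the gap classifier on the provided
    crops.  Held-out performance (per-phantom CV) is in ``metadata``.
    """
    if not candidate_sets:
        raise ValueError("no training candidates")
    for labels in label_frames:
        if labels.is_ihc.sum() == 0 or labels.is_ohc.sum() == 0:
            raise ValueError("a training phantom lacks positive labels for one class")
    X1 = [c.df[STAGE1_FEATURES].to_numpy() for c in candidate_sets]
    y_ihc = [lf.is_ihc.to_numpy() for lf in label_frames]
    y_ohc = [lf.is_ohc.to_numpy() for lf in label_frames]

    def fit_stage1(ys, extra=None):
        def pool(exclude=None):
            xs = [x for j, x in enumerate(X1) if j != exclude]
            yy = [y for j, y in enumerate(ys) if j != exclude]
            if extra is not None:
                xs += [x for j, (x, _) in enumerate(extra) if j != exclude]
                yy += [y for j, (_, y) in enumerate(extra) if j != exclude]
            return np.vstack(xs), np.concatenate(yy)

        model = HistGradientBoostingClassifier(max_iter=300, random_state=seed)
        model.fit(*pool())
        # leave-one-phantom-out scores for stage-2 training
        oof = []
        for i in range(len(X1)):
            if len(X1) > 1:
                m = HistGradientBoostingClassifier(max_iter=300, random_state=seed)
                m.fit(*pool(exclude=i))
            else:
                m = model
            oof.append(m.predict_proba(X1[i])[:, 1])
        return model, oof

    stage1_ihc, oof_ihc = fit_stage1(y_ihc, extra=ihc_slab_sets)
    stage1_ohc, oof_ohc = fit_stage1(y_ohc)

    def fit_stage2(oof_scores, ys):
        Xs, Ys = [], []
        for cands, scores, y in zip(candidate_sets, oof_scores, ys):
            cands.df["stage1_score"] = scores
            add_sector_features(cands, scores)
            Xs.append(stage2_features(cands))
            Ys.append(y)
        model = RandomForestClassifier(
            n_estimators=300, random_state=seed, n_jobs=1, min_samples_leaf=2
        )
        model.fit(np.vstack(Xs), np.concatenate(Ys))
        return model

    stage2_ihc = fit_stage2(oof_ihc, y_ihc)
    stage2_ohc = fit_stage2(oof_ohc, y_ohc)

    # row classifier: crops of matched OHC candidates, labels = true row
    row_crop_list, row_label_list = [], []
    for cands, lf in zip(candidate_sets, label_frames):
        mask = lf.is_ohc.to_numpy()
        row_crop_list.append(_row_crops(cands, mask))
        row_label_list.append(lf.row.to_numpy()[mask] - 1)
    row_X = np.vstack(row_crop_list)
    row_y = np.concatenate(row_label_list)
    row_net = TinyConvNet((CROP_H, CROP_W), (60,), 3, seed=seed)
    row_net.fit(row_X, row_y, epochs=8, seed=seed + 1)

    gap_net = TinyConvNet((CROP_H, CROP_W), (60, 20), 2, seed=seed)
    gap_net.fit(gap_crops, gap_labels, epochs=4, seed=seed + 2)

    report = {
        "row_classifier_train_acc": float((row_net.predict(row_X) == row_y).mean()),
        "gap_classifier_train_acc": float((gap_net.predict(gap_crops) == gap_labels).mean()),
        "n_candidates": int(sum(len(c) for c in candidate_sets)),
        "seed": seed,
        "stage1_oof": {},
    }
    for name, oof, ys in (("IHC1", oof_ihc, y_ihc), ("OHC1", oof_ohc, y_ohc)):
        rec, prec, f = _f_score(
            np.concatenate(ys), np.concatenate(oof) >= 0.5
        )
        report["stage1_oof"][name] = {"recall": rec, "precision": prec, "f_score": f}
    return DetectorModels(
        stage1_ihc, stage2_ihc, stage1_ohc, stage2_ohc, row_net, gap_net, report
    )


def _score_candidates(
    cands: CandidateSet, stage1, stage2, stage1_thresh: float
) -> np.ndarray:
    """Run both stages; returns stage-2 probability (0 where pruned)."""
    n = len(cands)
    if n == 0:
        return np.zeros(0)
    s1 = stage1.predict_proba(cands.df[STAGE1_FEATURES].to_numpy())[:, 1]
    cands.df["stage1_score"] = s1
    add_sector_features(cands, s1)
    keep = s1 >= stage1_thresh
    out = np.zeros(n)
    if keep.any():
        X2 = stage2_features(cands, keep)
        out[keep] = stage2.predict_proba(X2[keep])[:, 1]
    return out


def _chain_ihc(df: pd.DataFrame, min_spacing: float = 6.0) -> pd.DataFrame:
    """Select the score-maximal chain of IHC candidates with > 6 um spacing.

    Dynamic program over candidates sorted by s: maximize total score
    subject to consecutive spacing strictly above ``min_spacing``.
    """
    if len(df) == 0:
        return df
    d = df.sort_values("s").reset_index(drop=True)
    s = d.s.to_numpy()
    score = d.score.to_numpy()
    n = len(d)
    best = np.zeros(n)
    prev = -np.ones(n, dtype=int)
    for i in range(n):
        best[i] = score[i]
        for j in range(i):
            if s[i] - s[j] > min_spacing and best[j] + score[i] > best[i]:
                best[i] = best[j] + score[i]
                prev[i] = j
    i = int(np.argmax(best))
    chain = []
    while i >= 0:
        chain.append(i)
        i = prev[i]
    return d.iloc[chain[::-1]].reset_index(drop=True)


def detect_ihc(
    linv: LinearizedVolume,
    models: DetectorModels,
    cands: CandidateSet,
    stage1_thresh: float = 0.1,
    stage2_thresh: float = 0.5,
) -> pd.DataFrame:
    """Ordered IHC chain from scored candidates."""
    score = _score_candidates(cands, models.stage1_ihc, models.stage2_ihc, stage1_thresh)
    df = cands.df.copy()
    df["score"] = score
    sel = df[df.score >= stage2_thresh].copy()
    chain = _chain_ihc(sel)
    chain["kind"] = "IHC"
    chain["row"] = 0
    chain["provenance"] = "stage2"
    return chain


def detect_ohc(
    linv: LinearizedVolume,
    models: DetectorModels,
    cands: CandidateSet,
    stage1_thresh: float = 0.1,
    stage2_thresh: float = 0.5,
    recover_gaps: bool = True,
) -> pd.DataFrame:
    """OHCs with row labels (1-3) and optional gap recovery."""
    score = _score_candidates(cands, models.stage1_ohc, models.stage2_ohc, stage1_thresh)
    df = cands.df.copy()
    df["score"] = score
    accepted = df[df.score >= stage2_thresh].copy()
    if len(accepted) == 0:
        accepted["row"] = []
        accepted["kind"] = []
        accepted["provenance"] = []
        return accepted
    crops = _row_crops(cands, (score >= stage2_thresh))
    rows = models.row_classifier.predict(crops) + 1
    accepted["row"] = rows
    # convention check: mean r must increase with row index; remap if not
    means = accepted.groupby("row").r.mean()
    order = means.sort_values().index.to_numpy()
    if not np.array_equal(order, np.sort(means.index.to_numpy())):
        remap = {old: new + 1 for new, old in enumerate(order)}
        accepted["row"] = accepted["row"].map(remap)
    accepted["kind"] = "OHC"
    accepted["provenance"] = "stage2"
    accepted = accepted.sort_values(["row", "s"]).reset_index(drop=True)
    if recover_gaps:
        recovered = recover_gap_cells(linv, models, accepted, df)
        if len(recovered):
            accepted = (
                pd.concat([accepted, recovered], ignore_index=True)
                .sort_values(["row", "s"])
                .reset_index(drop=True)
            )
    return accepted


def recover_gap_cells(
    linv: LinearizedVolume,
    models: DetectorModels,
    accepted: pd.DataFrame,
    all_candidates: pd.DataFrame,
    gap_factor: float = 1.5,
    match_radius: float = 5.0,
) -> pd.DataFrame:
    """Assess within-row gaps exceeding ``gap_factor`` x average spacing.

    Rectangular crops are placed at equal distances within each flagged
    gap; where the gap classifier predicts a cell, the nearest unused
    correlation peak is recovered (provenance ``gap_recovered``).
    """
    mip = _mip_rs(linv)
    # pool of unused peaks: candidates not within 3 um of an accepted cell
    # and near the epithelial surface (accepted cells define the v band)
    if len(accepted):
        acc_tree = cKDTree(accepted[["s", "r", "v"]].to_numpy())
        d_near, _ = acc_tree.query(all_candidates[["s", "r", "v"]].to_numpy())
        v_center = accepted.v.median()
        pool = all_candidates[
            (d_near > 3.0) & ((all_candidates.v - v_center).abs() <= 8.0)
        ]
    else:
        pool = all_candidates
    recovered = []
    used_pool = set()
    for row in sorted(accepted.row.unique()):
        rdf = accepted[accepted.row == row].sort_values("s")
        if len(rdf) < 3:
            continue
        s_vals = rdf.s.to_numpy()
        r_vals = rdf.r.to_numpy()
        spacings = np.diff(s_vals)
        avg = spacings.mean()
        for i, gap in enumerate(spacings):
            if gap <= gap_factor * avg:  # strict: a gap of exactly 1.5x is not flagged
                continue
            n_missing = int(round(gap / avg)) - 1
            if n_missing < 1:
                continue
            for k in range(1, n_missing + 1):
                fs = s_vals[i] + gap * k / (n_missing + 1)
                fr = r_vals[i] + (r_vals[i + 1] - r_vals[i]) * k / (n_missing + 1)
                crop = _crop2d(mip, fr - linv.r_range[0], fs, CROP_H, CROP_W)
                if models.gap_classifier.predict(crop[None])[0] != 1:
                    continue
                # nearest unused correlation peak
                cand = pool[
                    (pool.s - fs) ** 2 + (pool.r - fr) ** 2 < match_radius**2
                ]
                cand = cand[~cand.index.isin(used_pool)]
                if len(cand) == 0:
                    continue
                d = ((cand.s - fs) ** 2 + (cand.r - fr) ** 2).to_numpy()
                j = cand.index[int(np.argmin(d))]
                used_pool.add(j)
                rec = all_candidates.loc[j].copy()
                rec["row"] = row
                rec["kind"] = "OHC"
                rec["provenance"] = "gap_recovered"
                rec["score"] = rec.get("score", 0.0)
                recovered.append(rec)
    return pd.DataFrame(recovered)


def detect_cells(
    linv: LinearizedVolume,
    models: DetectorModels,
    corr_threshold: float = 0.3,
    template: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full staged detection on a straightened volume.

    Returns the cell map: one row per accepted cell with linearized
    (s, r, v) and source-volume (x, y, z) coordinates, kind, OHC row,
    final score and provenance.
    """
    if template is None:
        template = build_template(linv)
    corr, peaks = match_template_volume(linv, template, corr_threshold)
    cands = form_candidates(corr, peaks, linv)
    ihc = detect_ihc(linv, models, cands)
    ohc = detect_ohc(linv, models, cands)
    cells = pd.concat([ihc, ohc], ignore_index=True)
    keep = ["kind", "row", "s", "r", "v", "score", "provenance"]
    cells = cells[keep].copy()
    world = linv.spiral.world_from_linear(
        cells.s.to_numpy(), cells.r.to_numpy(), cells.v.to_numpy()
    )
    cells[["x", "y", "z"]] = world
    cells.insert(0, "id", np.arange(len(cells)))
    return cells


def watershed_baseline(linv: LinearizedVolume, min_distance: int = 2) -> pd.DataFrame:
    """Intensity-based 3D-watershed segmentation baseline.

    Smooth, threshold (robust background statistic), seed with local
    maxima, and segment; segment centroids are returned as cells.
    """
    data = ndimage.gaussian_filter(linv.data.astype(np.float32), 1.5)
    thr = _robust_threshold(data)
    mask = data > thr
    coords = peak_local_max(
        data, min_distance=min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(data.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-data, markers, mask=mask)
    idx = np.arange(1, labels.max() + 1)
    if len(idx) == 0:
        return pd.DataFrame(columns=["s", "r", "v", "x", "y", "z"])
    com = np.array(ndimage.center_of_mass(mask, labels, idx))
    out = pd.DataFrame(
        {
            "s": com[:, 0],
            "r": com[:, 1] + linv.r_range[0],
            "v": com[:, 2] + linv.v_range[0],
        }
    )
    world = linv.spiral.world_from_linear(out.s.to_numpy(), out.r.to_numpy(), out.v.to_numpy())
    out[["x", "y", "z"]] = world
    return out


def evaluate_detection(
    detected: np.ndarray, truth: np.ndarray, tolerance: float = 4.0
) -> dict:
    """Detection-efficiency metrics by greedy one-to-one matching.

    Returns detected/undetected/erroneous counts plus the recover rate
    (matched / truth; recall) and accuracy rate (matched / reported;
    precision).
    """
    detected = np.atleast_2d(np.asarray(detected, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if detected.size == 0 or truth.size == 0:
        n_d = 0 if detected.size == 0 else len(detected)
        n_t = 0 if truth.size == 0 else len(truth)
        return {
            "detected_n": 0,
            "undetected_n": n_t,
            "erroneous_n": n_d,
            "recover_rate": 0.0,
            "accuracy_rate": 0.0,
        }
    pairs = []
    balls = cKDTree(detected).query_ball_tree(cKDTree(truth), tolerance)
    for i, js in enumerate(balls):
        for j in js:
            pairs.append((np.linalg.norm(detected[i] - truth[j]), i, j))
    pairs.sort()
    used_d, used_t = set(), set()
    for dist, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
    matched = len(used_d)
    return {
        "detected_n": matched,
        "undetected_n": len(truth) - matched,
        "erroneous_n": len(detected) - matched,
        "recover_rate": matched / len(truth),
        "accuracy_rate": matched / len(detected),
    }
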