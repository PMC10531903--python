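"""Episignature construction: probe scoring and selection, clustering and
MDS summaries, leave-one-out cross-validation, and a linear SVM whose
calibrated class probability is reported as the methylation variant
pathogenicity (MVP) score.

Probe selection pipeline: rank probes by score = |Δβ| · (−log10 adjusted
p), keep the top k, drop probes whose (direction-folded) AUC falls below
a floor, then greedily prune probes correlated above a ceiling with an
already-kept, higher-scored probe.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.svm import SVC

from . import differential_methylation as dm


class SelectionError(RuntimeError):
    """No probe survived selection."""


class DataError(ValueError):
    """New samples lack probes the model requires."""


@dataclass
class SelectionParams:
    top_k: int = 500
    auc_min: float = 0.9
    corr_max: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc_min <= 1.0:
            raise ValueError("auc_min must be in [0, 1]")
        if not 0.0 < self.corr_max <= 1.0:
            raise ValueError("corr_max must be in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


# ---------------------------------------------------------------------------
# probe scoring
# ---------------------------------------------------------------------------

def score_probes(stats: pd.DataFrame) -> pd.Series:
    """score = |Δβ| × (−log10 BH-adjusted p); 0 when the adjusted p is 1.

    Adjusted p-values of exactly 0 are clamped to the smallest positive
    float with a warning.
    """
    p = stats["p_adjusted"].to_numpy(dtype=float).copy()
    if (p == 0).any():
        warnings.warn("p_adjusted == 0 clamped to smallest positive float",
                      RuntimeWarning, stacklevel=2)
        p[p == 0] = np.finfo(float).tiny
    score = np.abs(stats["delta_beta"].to_numpy()) * (-np.log10(p))
    return pd.Series(score, index=stats.index, name="score")


def probe_auc(values: pd.Series | np.ndarray, case_ids, control_ids,
              index=None) -> float:
    """Direction-folded AUC for one probe (>= 0.5 whichever group is
    higher); ties count 1/2; constant rows give 0.5."""
    if isinstance(values, pd.Series):
        case = values.loc[list(case_ids)].to_numpy(dtype=float)
        ctrl = values.loc[list(control_ids)].to_numpy(dtype=float)
    else:
        values = pd.Series(np.asarray(values, dtype=float), index=index)
        return probe_auc(values, case_ids, control_ids)
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([case, ctrl]))
    u = ranks[:len(case)].sum() - len(case) * (len(case) + 1) / 2.0
    auc = u / (len(case) * len(ctrl))
    return float(max(auc, 1.0 - auc))


def probe_auc_matrix(beta: pd.DataFrame, case_ids, control_ids) -> pd.Series:
    """Vectorized direction-folded AUC for every probe row."""
    case_ids, control_ids = list(case_ids), list(control_ids)
    x = beta[case_ids + control_ids].to_numpy(dtype=float)
    n1, n2 = len(case_ids), len(control_ids)
    ranks = rankdata(x, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n2)
    return pd.Series(np.maximum(auc, 1.0 - auc), index=beta.index, name="auc")


def attach_auc_scores(stats: pd.DataFrame, beta: pd.DataFrame,
                      case_ids, control_ids) -> pd.DataFrame:
    """Return ``stats`` with ``auc`` and ``score`` columns filled in."""
    out = stats.copy()
    out["auc"] = probe_auc_matrix(beta.loc[stats.index], case_ids,
                                  control_ids)
    out["score"] = score_probes(out)
    out.attrs.update(stats.attrs)
    return out


# ---------------------------------------------------------------------------
# probe selection
# ---------------------------------------------------------------------------

def select_probes(
    stats: pd.DataFrame,
    beta: pd.DataFrame,
    params: SelectionParams | None = None,
    allow_empty: bool = False,
) -> list[str]:
    """Top-k by score → AUC floor → greedy correlation pruning.

    The returned list preserves descending score order (ties broken by
    probe id).  Raises :class:`SelectionError` when nothing survives,
    unless ``allow_empty``.
    """
    params = params or SelectionParams()
    tbl = stats.dropna(subset=["score", "auc"]).copy()
    # descending score, probe id as deterministic tie-break
    tbl = tbl.iloc[np.lexsort((tbl.index.to_numpy(),
                               -tbl["score"].to_numpy()))]
    tbl = tbl.head(params.top_k)
    tbl = tbl[tbl["auc"] >= params.auc_min]
    survivors = tbl.index.tolist()
    if not survivors:
        if allow_empty:
            return []
        raise SelectionError("no probe survived score/AUC filtering")

    x = beta.loc[survivors].to_numpy(dtype=float)
    sd = x.std(axis=1)
    xc = x - x.mean(axis=1, keepdims=True)
    kept_rows: list[int] = []
    for i in range(len(survivors)):
        ok = True
        for k in kept_rows:
            denom = sd[i] * sd[k] * x.shape[1]
            r = 0.0 if denom == 0 else float(np.dot(xc[i], xc[k]) / denom)
            if abs(r) > params.corr_max:
                ok = False
                break
        if ok:
            kept_rows.append(i)
    selected = [survivors[i] for i in kept_rows]
    if not selected and not allow_empty:
        raise SelectionError("correlation pruning removed every probe")
    return selected


# ---------------------------------------------------------------------------
# clustering and MDS
# ---------------------------------------------------------------------------

def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def hierarchical_cluster(
    beta_subset: pd.DataFrame, method: str = "average"
) -> tuple[str, list[str]]:
    """Agglomerative clustering of samples on Euclidean distance between
    their beta vectors; returns (newick, leaf order)."""
    if beta_subset.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    x = beta_subset.to_numpy(dtype=float).T
    link = hierarchy.linkage(x, method=method, metric="euclidean")
    labels = list(beta_subset.columns)
    leaves = [labels[i] for i in hierarchy.leaves_list(link)]
    return _linkage_to_newick(link, labels), leaves


def mds_embedding(beta_subset: pd.DataFrame, n_dims: int = 2) -> pd.DataFrame:
    """Classical (metric) MDS of the pairwise Euclidean distance matrix.

    Double-center −D²/2, take the top eigenpairs; coordinates are scaled
    eigenvectors.  Sign per axis is fixed deterministically (largest
    |coordinate| made positive).  All-equal input gives all-zero
    coordinates.
    """
    n = beta_subset.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples for MDS")
    x = beta_subset.to_numpy(dtype=float).T
    d2 = squareform(pdist(x, metric="euclidean")) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:n_dims]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        if np.allclose(coords[:, k], 0):
            continue
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] *= -1
    return pd.DataFrame(coords, index=beta_subset.columns,
                        columns=[f"dim{k + 1}" for k in range(coords.shape[1])])


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

def loo_crossvalidate(
    beta: pd.DataFrame,
    m: pd.DataFrame,
    samples: pd.DataFrame,
    case_ids,
    control_ids,
    params: SelectionParams | None = None,
    prior_df: float | None = None,
) -> list[dict]:
    """One round per case: rerun the DMP fit and probe selection with that
    case held out, then place the held-out sample by its proximity to the
    case vs control centroid in that round's MDS embedding."""
    case_ids, control_ids = list(case_ids), list(control_ids)
    if len(case_ids) < 3:
        raise ValueError("need >= 3 cases for leave-one-out rounds")
    params = params or SelectionParams()
    rounds = []
    for held in case_ids:
        train_cases = [c for c in case_ids if c != held]
        stats = dm.dmp_statistics(beta, m, samples, train_cases, control_ids,
                                  prior_df=prior_df)
        stats = attach_auc_scores(stats, beta, train_cases, control_ids)
        selected = select_probes(stats, beta[train_cases + control_ids],
                                 params)
        coords = mds_embedding(
            beta.loc[selected, train_cases + control_ids + [held]])
        case_centroid = coords.loc[train_cases].mean(axis=0)
        ctrl_centroid = coords.loc[control_ids].mean(axis=0)
        p = coords.loc[held]
        d_case = float(np.linalg.norm(p - case_centroid))
        d_ctrl = float(np.linalg.norm(p - ctrl_centroid))
        rounds.append({
            "held_out": held,
            "selected_probes": selected,
            "placement": "case" if d_case <= d_ctrl else "control",
            "dist_case": d_case,
            "dist_control": d_ctrl,
        })
    return rounds


# ---------------------------------------------------------------------------
# SVM classifier and MVP scores
# ---------------------------------------------------------------------------

def _platt_fit(margins: np.ndarray, labels: np.ndarray,
               max_iter: int = 200) -> tuple[float, float]:
    """Platt scaling: fit P(case|margin) = 1/(1+exp(a·margin+b)) by
    Newton-optimized regularized log-likelihood (a < 0 when larger margins
    mean 'case')."""
    prior1 = labels.sum()
    prior0 = len(labels) - prior1
    hi = (prior1 + 1.0) / (prior1 + 2.0)
    lo = 1.0 / (prior0 + 2.0)
    t = np.where(labels > 0, hi, lo)
    a, b = 0.0, float(np.log((prior0 + 1.0) / (prior1 + 1.0)))
    for _ in range(max_iter):
        fapb = a * margins + b
        p = np.where(fapb >= 0, np.exp(-fapb) / (1 + np.exp(-fapb)),
                     1 / (1 + np.exp(fapb)))
        d = t - p
        w = p * (1 - p)
        g1 = float(np.dot(margins, d))
        g0 = float(d.sum())
        h11 = float(np.dot(margins ** 2, w)) + 1e-12
        h01 = float(np.dot(margins, w))
        h00 = float(w.sum()) + 1e-12
        det = h11 * h00 - h01 ** 2
        if abs(det) < 1e-300:
            break
        da = -(h00 * g1 - h01 * g0) / det
        db = -(h11 * g0 - h01 * g1) / det
        a += da
        b += db
        if abs(da) < 1e-10 and abs(db) < 1e-10:
            break
    return float(a), float(b)


def _sigmoid_prob(margin: np.ndarray, a: float, b: float) -> np.ndarray:
    f = a * np.asarray(margin, dtype=float) + b
    return np.where(f >= 0, np.exp(-f) / (1 + np.exp(-f)), 1 / (1 + np.exp(f)))


@dataclass
class EpisignatureModel:
    """Linear decision function over selected-probe betas plus a logistic
    calibration mapping the margin to an MVP probability."""

    probe_ids: list[str]
    weights: np.ndarray
    bias: float
    calibration: tuple[float, float]
    metadata: dict = field(default_factory=dict)
    training_scores: dict[str, float] = field(default_factory=dict)

    def decision(self, beta_new: pd.DataFrame) -> pd.Series:
        missing = [p for p in self.probe_ids if p not in beta_new.index]
        if missing:
            raise DataError(
                f"{len(missing)} model probes missing from input, e.g. "
                f"{missing[:5]}")
        x = beta_new.loc[self.probe_ids].to_numpy(dtype=float).T
        return pd.Series(x @ self.weights + self.bias,
                         index=beta_new.columns, name="margin")

    def mvp(self, beta_new: pd.DataFrame) -> pd.Series:
        a, b = self.calibration
        margins = self.decision(beta_new)
        return pd.Series(_sigmoid_prob(margins.to_numpy(), a, b),
                         index=margins.index, name="mvp")

    def to_json(self) -> str:
        return json.dumps({
            "probe_ids": list(self.probe_ids),
            "weights": [float(w) for w in self.weights],
            "bias": float(self.bias),
            "calibration": [float(c) for c in self.calibration],
            "metadata": self.metadata,
            "training_scores": {k: float(v)
                                for k, v in self.training_scores.items()},
        }, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "EpisignatureModel":
        d = json.loads(text)
        return cls(probe_ids=d["probe_ids"],
                   weights=np.asarray(d["weights"], dtype=float),
                   bias=d["bias"],
                   calibration=tuple(d["calibration"]),
                   metadata=d.get("metadata", {}),
                   training_scores=d.get("training_scores", {}))

    @classmethod
    def load(cls, path: str | Path) -> "EpisignatureModel":
        return cls.from_json(Path(path).read_text())


def _fit_linear_svm(x: np.ndarray, y: np.ndarray,
                    c: float = 1.0) -> tuple[np.ndarray, float]:
    svm = SVC(kernel="linear", C=c, class_weight="balanced")
    svm.fit(x, y)
    return svm.coef_.ravel().copy(), float(svm.intercept_[0])


def train_classifier(
    beta_sel: pd.DataFrame,
    case_ids,
    control_ids,
    seed: int = 0,
    extra_control_ids=None,
    c: float = 1.0,
) -> tuple[EpisignatureModel, pd.DataFrame]:
    """Linear SVM (cases vs controls) with Platt-calibrated MVP scores.

    Controls are split into four 75/25 train/test folds so each control is
    a test sample exactly once; cases stay in training for every fold and
    their reported MVP is the mean over the four fold models.  The
    returned model is refit on all samples, with its calibration fit on
    the full training margins, and stores each training sample's
    final-model score for reproducible reclassification.
    """
    case_ids = list(case_ids)
    controls = list(control_ids) + list(extra_control_ids or [])
    if len(case_ids) < 2 or len(controls) < 2:
        raise ValueError("need >= 2 samples per class")
    if len(controls) < 8:
        raise ValueError("need >= 8 controls for four 75/25 folds")
    rng = np.random.default_rng(seed)
    shuffled = np.array(sorted(controls))
    rng.shuffle(shuffled)
    folds = [shuffled[i::4].tolist() for i in range(4)]

    xc = beta_sel[case_ids].to_numpy(dtype=float).T
    mvp_acc: dict[str, list[float]] = {s: [] for s in case_ids + controls}
    for fold in folds:
        train_ctrl = [s for s in controls if s not in fold]
        x = np.vstack([xc, beta_sel[train_ctrl].to_numpy(dtype=float).T])
        y = np.concatenate([np.ones(len(case_ids)),
                            np.zeros(len(train_ctrl))])
        w, b = _fit_linear_svm(x, y, c=c)
        a_cal, b_cal = _platt_fit(x @ w + b, y)
        for s in case_ids:
            margin = beta_sel.loc[:, s].to_numpy(dtype=float) @ w + b
            mvp_acc[s].append(float(_sigmoid_prob(np.array([margin]),
                                                  a_cal, b_cal)[0]))
        for s in fold:
            margin = beta_sel.loc[:, s].to_numpy(dtype=float) @ w + b
            mvp_acc[s].append(float(_sigmoid_prob(np.array([margin]),
                                                  a_cal, b_cal)[0]))

    report = pd.DataFrame({
        "sample_id": case_ids + controls,
        "role": ["training_case"] * len(case_ids)
                + ["training_control"] * len(controls),
        "mvp": [float(np.mean(mvp_acc[s])) for s in case_ids + controls],
        "n_folds_averaged": [len(mvp_acc[s]) for s in case_ids + controls],
    }).set_index("sample_id")

    x_all = np.vstack([xc, beta_sel[controls].to_numpy(dtype=float).T])
    y_all = np.concatenate([np.ones(len(case_ids)), np.zeros(len(controls))])
    w, b = _fit_linear_svm(x_all, y_all, c=c)
    a_cal, b_cal = _platt_fit(x_all @ w + b, y_all)
    model = EpisignatureModel(
        probe_ids=list(beta_sel.index),
        weights=w,
        bias=b,
        calibration=(a_cal, b_cal),
        metadata={"seed": int(seed), "n_cases": len(case_ids),
                  "n_controls": len(controls), "svm_c": c,
                  "kernel": "linear", "class_weight": "balanced"},
    )
    final_scores = model.mvp(beta_sel[case_ids + controls])
    model.training_scores = {s: float(v) for s, v in final_scores.items()}
    return model, report


def classify_samples(model: EpisignatureModel,
                     beta_new: pd.DataFrame) -> pd.DataFrame:
    """MVP scores for new samples under a trained model."""
    scores = model.mvp(beta_new)
    return pd.DataFrame({"mvp": scores, "role": "test"},
                        index=scores.index)
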