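"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, and the
multimodal feature-fusion harness combining Markov-model-derived and
imaging-derived feature blocks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .states import AD, NC


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("confusion matrix is empty")


def confusion_metrics(cm: ConfusionMatrix, as_printed: bool = False) -> dict:
    """Accuracy, specificity and sensitivity from confusion counts.

    accuracy = (TP+TN)/(TP+TN+FP+FN); specificity = TN/(TN+FP);
    sensitivity = TP/(TP+FN).  A metric whose denominator is zero is
    reported as NaN (undefined), never as 0.  ``as_printed=True`` switches
    sensitivity to the precision-like TP/(TP+FP) variant for fidelity
    experiments with sources that define it that way.
    """
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens_den = cm.tp + (cm.fp if as_printed else cm.fn)
    return {
        "accuracy": ratio(cm.tp + cm.tn, cm.tp + cm.tn + cm.fp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "sensitivity": ratio(cm.tp, sens_den),
    }


@dataclass
class ROCCurve:
    """Threshold-swept operating points and the area under the curve.

    fpr/tpr are nondecreasing, anchored at (0,0) and (1,1); AUC is the
    trapezoidal area, equivalent to the Mann–Whitney probability with ties
    counted 1/2.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr,
                             "tpr": self.tpr})


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and AUC for scalar scores against binary labels.

    Raises on single-class labels (the curve is undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


# --------------------------------------------------------------- features

MODALITY_BLOCKS = ("mm", "dti", "smri")


def build_feature_table(fit=None, profiles=None, smri: pd.DataFrame | None = None,
                        blocks=("mm", "dti"), horizons=(1.0, 2.0, 5.0),
                        max_failure_fraction: float = 0.25) -> pd.DataFrame:
    """Assemble the per-subject fused feature table.

    Blocks (concatenated, then z-scored per column):

    * ``mm``   — Markov-model features: predicted AD-onset probability at
      each horizon from the subject's first observed state, given their
      covariates, under the fitted intensity model.
    * ``dti``  — per retained tract, the subject's node-mean FA and MD.
    * ``smri`` — synthetic volumetric features supplied as a DataFrame
      indexed by subject_id.

    Returns a DataFrame indexed by subject_id with a ``label`` column and
    feature columns prefixed ``<block>__``.  Raises when a requested
    block is missing subjects present in another block.
    """
    blocks = tuple(blocks)
    unknown = set(blocks) - set(MODALITY_BLOCKS)
    if unknown:
        raise ValueError(f"unknown blocks: {sorted(unknown)}")
    pieces: dict[str, pd.DataFrame] = {}

    if "mm" in blocks:
        if fit is None:
            raise ValueError("mm block requested but no fit supplied")
        data = fit.model.data
        cols = {f"mm__p_ad_{h:g}yr": [] for h in horizons}
        sids = []
        cov_cols = fit.model._cov_cols
        for s in data.subjects:
            sids.append(s.subject_id)
            state = data.states.names[s.state_idx[0]]
            V = s.covariates[cov_cols]
            for h in horizons:
                cols[f"mm__p_ad_{h:g}yr"].append(fit.predict_onset(V, state, h))
        pieces["mm"] = pd.DataFrame(cols, index=pd.Index(sids, name="subject_id"))

    if "dti" in blocks:
        if profiles is None:
            raise ValueError("dti block requested but no profiles supplied")
        from .tractstats import exclude_untrackable_tracts

        retained, _ = exclude_untrackable_tracts(profiles, max_failure_fraction)
        cols = {}
        for tract in retained:
            j = profiles.tract_index(tract)
            key = tract.lower().replace(" ", "_")
            fa = profiles.fa[:, j, :].mean(axis=1)
            md = profiles.md[:, j, :].mean(axis=1)
            # untracked subjects get the tracked-subject mean (imputation)
            trk = profiles.tracked[:, j]
            fa = np.where(trk, fa, fa[trk].mean())
            md = np.where(trk, md, md[trk].mean())
            cols[f"dti__{key}_fa"] = fa
            cols[f"dti__{key}_md"] = md
        pieces["dti"] = pd.DataFrame(
            cols, index=pd.Index(profiles.subject_ids, name="subject_id"))

    if "smri" in blocks:
        if smri is None:
            raise ValueError("smri block requested but no smri table supplied")
        sm = smri.copy()
        sm.columns = [c if c.startswith("smri__") else f"smri__{c}" for c in sm.columns]
        sm.index.name = "subject_id"
        pieces["smri"] = sm

    if not pieces:
        raise ValueError("at least one block must be requested")
    idx = None
    for name, df in pieces.items():
        idx = df.index if idx is None else idx
        missing = set(idx) ^ set(df.index)
        if missing:
            raise ValueError(f"block {name!r} subject mismatch: {sorted(missing)[:10]}")
    table = pd.concat([pieces[b] for b in blocks], axis=1)

    # labels: group from profiles if available, else panel groups
    if profiles is not None and len(profiles.group) and profiles.group[0]:
        labels = pd.Series(profiles.group, index=profiles.subject_ids)
    elif fit is not None and fit.model.data.groups:
        labels = pd.Series(fit.model.data.groups)
    else:
        raise ValueError("no source of labels (profiles group / panel groups)")
    table.insert(0, "label", labels.reindex(table.index))
    if table["label"].isna().any():
        raise ValueError("some subjects have no label")

    feat = table.columns.drop("label")
    mu = table[feat].mean()
    sd = table[feat].std(ddof=0).replace(0.0, 1.0)
    table[feat] = (table[feat] - mu) / sd
    return table


@dataclass
class EvalResult:
    """Pooled out-of-fold evaluation of one block combination."""

    blocks: tuple
    confusion: ConfusionMatrix
    roc: ROCCurve
    metrics: dict = field(default_factory=dict)


def cross_validated_eval(table: pd.DataFrame, classifier=None, folds: int = 5,
                         seed: int = 0, positive: str = AD, negative: str = NC,
                         block_combinations=None) -> dict:
    """Stratified k-fold cross-validated evaluation per block combination.

    The headline binary task is AD vs NC (aMCI rows are dropped); change
    `positive`/`negative` to evaluate other contrasts.  Out-of-fold
    predicted probabilities are pooled into a single confusion matrix
    (threshold 0.5) and ROC curve per combination.  Deterministic given
    the seed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    sub = table[table["label"].isin([positive, negative])]
    y = (sub["label"] == positive).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.bincount(y).min() < folds:
        raise ValueError(
            f"cannot form {folds} stratified folds: smallest class has "
            f"{np.bincount(y).min()} members")
    feat_cols = [c for c in sub.columns if c != "label"]
    present_blocks = tuple(dict.fromkeys(c.split("__")[0] for c in feat_cols))
    if block_combinations is None:
        block_combinations = [present_blocks]
    results = {}
    for combo in block_combinations:
        combo = tuple(combo)
        cols = [c for c in feat_cols if c.split("__")[0] in combo]
        if not cols:
            raise ValueError(f"no features for blocks {combo}")
        X = sub[cols].to_numpy(dtype=float)
        clf = classifier if classifier is not None else LogisticRegression(max_iter=1000)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        prob = np.empty(len(y))
        for train, test in skf.split(X, y):
            import sklearn.base

            est = sklearn.base.clone(clf)
            est.fit(X[train], y[train])
            prob[test] = est.predict_proba(X[test])[:, 1]
        pred = (prob >= 0.5).astype(int)
        cm = ConfusionMatrix(
            tp=int(((pred == 1) & (y == 1)).sum()),
            tn=int(((pred == 0) & (y == 0)).sum()),
            fp=int(((pred == 1) & (y == 0)).sum()),
            fn=int(((pred == 0) & (y == 1)).sum()),
        )
        roc = roc_auc(prob, y)
        results[combo] = EvalResult(blocks=combo, confusion=cm, roc=roc,
                                    metrics=confusion_metrics(cm) | {"auc": roc.auc})
    return results


def generate_smri_features(group_assignments: dict, seed: int = 0,
                           effect: float = 1.0) -> pd.DataFrame:
    """Synthetic volumetric (structural-MRI-like) feature block.

    Hippocampal and entorhinal volumes plus ventricle size with additive
    group effects (NC > aMCI > AD for volumes, reversed for ventricles)
    scaled by `effect` standard deviations, i.i.d. unit noise.  Synthetic
    stand-in for real segmentation outputs.
    """
    rng = np.random.default_rng(seed)
    shift = {NC: 0.0, "aMCI": -0.5 * effect, AD: -1.0 * effect}
    rows = {}
    for sid, g in group_assignments.items():
        s = shift.get(g, 0.0)
        rows[sid] = {
            "hippocampus_vol": 4.0 + s + rng.normal(0, 1),
            "entorhinal_vol": 2.0 + s + rng.normal(0, 1),
            "ventricle_vol": 20.0 - 2 * s + rng.normal(0, 1),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject_id")
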