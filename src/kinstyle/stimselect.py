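"""Representative-movement selection via Fisher linear discriminant analysis.

For a pair of intents, the kinematic feature columns predict the intent;
trials are projected onto the discriminant axis and, per intent, the trials
closest to their own class centroid (the mean variate score) are kept as
the representative stimuli.  The cluster composition of the selected set is
then profiled to check that it mirrors the natural prevalence of movement
styles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .kinfeat import FeatureMatrix

DEFAULT_RIDGE = 1e-6


@dataclass
class LDAModel:
    """Two-class Fisher discriminant in kinematic feature space."""

    classes: list[str]
    class_means: dict[str, np.ndarray]
    pooled_covariance: np.ndarray
    projection: np.ndarray           # (d,) discriminant axis
    centroids: dict[str, float]      # class -> mean discriminant score
    eigenvalue: float                # between/within separation along axis

    def scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.projection


def _resolve(features: FeatureMatrix | np.ndarray,
             intents: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, FeatureMatrix):
        X = features.X
        if intents is None:
            intents = features.meta["intent"].to_numpy()
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    if intents is None:
        raise InvalidArgumentError("intent labels required")
    return X, np.asarray(intents)


def fit_lda(features: FeatureMatrix | np.ndarray,
            intents: np.ndarray | None = None,
            ridge: float = DEFAULT_RIDGE) -> LDAModel:
    """Fit a two-class Fisher discriminant.

    The axis is w = (S_w + ridge*I)^-1 (mu_1 - mu_0) with S_w the pooled
    within-class covariance; this maximizes between- over within-class
    scatter.  The small ridge keeps the solve well-posed when the feature
    count exceeds the trial count.
    """
    X, y = _resolve(features, intents)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise InvalidArgumentError(
            f"exactly 2 classes required, got {classes}")
    groups = {c: X[y == c] for c in classes}
    for c, g in groups.items():
        if g.shape[0] < 2:
            raise InvalidArgumentError(f"class {c!r} needs >= 2 trials")
    d = X.shape[1]
    means = {c: g.mean(axis=0) for c, g in groups.items()}
    Sw = np.zeros((d, d))
    for c, g in groups.items():
        resid = g - means[c]
        Sw += resid.T @ resid
    Sw /= (X.shape[0] - 2)
    diff = means[classes[1]] - means[classes[0]]
    w = np.linalg.solve(Sw + ridge * np.eye(d), diff)
    nw = np.linalg.norm(w)
    if nw > 0:
        w = w / nw
    centroids = {c: float(means[c] @ w) for c in classes}
    within = float(w @ Sw @ w)
    between = float((diff @ w) ** 2) / 4.0
    eigenvalue = between / within if within > 0 else np.inf
    return LDAModel(classes=classes, class_means=means,
                    pooled_covariance=Sw, projection=w,
                    centroids=centroids, eigenvalue=eigenvalue)


def select_representatives(model: LDAModel,
                           features: FeatureMatrix | np.ndarray,
                           intents: np.ndarray | None = None,
                           trial_ids: np.ndarray | None = None,
                           n_select: int = 50,
                           n_equate: int | None = None
                           ) -> dict[str, list]:
    """Pick, per intent, the trials nearest their own centroid score.

    Counts are first equated across intents to ``n_equate`` (default: the
    smallest intent count) by dropping the trials farthest from the
    centroid, then the ``n_select`` nearest remain.  Distance is the 1-D
    absolute difference on the discriminant axis; ties break by trial id.
    """
    X, y = _resolve(features, intents)
    if trial_ids is None:
        if isinstance(features, FeatureMatrix):
            trial_ids = features.meta["trial_id"].to_numpy()
        else:
            trial_ids = np.arange(X.shape[0])
    trial_ids = np.asarray(trial_ids)
    scores = model.scores(X)
    counts = {c: int((y == c).sum()) for c in model.classes}
    if n_equate is None:
        n_equate = min(counts.values())
    n_equate = min(n_equate, min(counts.values()))
    if n_select > n_equate:
        raise InvalidArgumentError(
            f"n_select={n_select} exceeds available per-intent count "
            f"{n_equate}")
    out: dict[str, list] = {}
    for c in model.classes:
        mask = y == c
        dist = np.abs(scores[mask] - model.centroids[c])
        ids = trial_ids[mask]
        order = np.lexsort((ids, dist))
        kept = order[:n_equate][:n_select]
        out[c] = ids[kept].tolist()
    return out


def cluster_profile(selection: dict[str, list],
                    assignments: pd.DataFrame) -> pd.DataFrame:
    """Cluster composition of the selected movements, per intent.

    ``assignments`` must carry columns trial_id, participant, intent,
    cluster.  Returns one row per (intent, cluster) with the share of
    selected trials (%), the number of distinct contributing participants
    (actors) and the per-actor movement counts.
    """
    lookup = assignments.set_index("trial_id")
    rows = []
    for intent, ids in selection.items():
        missing = [t for t in ids if t not in lookup.index]
        if missing:
            raise InvalidArgumentError(
                f"selected trials without cluster labels: {missing[:5]}")
        sub = lookup.loc[ids]
        total = len(sub)
        for cluster, grp in sub.groupby("cluster"):
            per_actor = grp.groupby("participant").size()
            rows.append({
                "intent": intent,
                "cluster": int(cluster),
                "share_pct": 100.0 * len(grp) / total,
                "n_actors": int(per_actor.shape[0]),
                "movements_per_actor":
                    ",".join(str(int(v)) for v in per_actor.sort_index()),
            })
    return pd.DataFrame(rows).sort_values(["intent", "cluster"]) \
                             .reset_index(drop=True)
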