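"""Random-forest burn classification and reference-based accuracy metrics.

The classifier is a 200-tree random forest (minimum leaf population 10, at
most 450 leaves per tree, sqrt feature subsampling, 50% bootstrap fraction)
trained once on labeled polygons of a reference year and reused across all
years, assuming independence between the spectral fire signal and time.
Per-pixel burn probability is the fraction of trees voting burned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon as draw_polygon
from sklearn.ensemble import RandomForestClassifier

from peatfire.composites import FEATURE_NAMES, FeatureComposite

#: Ensemble settings, mirrored by :func:`train_rf`.
RF_SETTINGS = {
    "n_trees": 200,
    "min_leaf_population": 10,
    "max_nodes": 450,
    "variables_per_split": "sqrt",
    "bag_fraction": 0.5,
}


@dataclass
class TrainingSample:
    """One labeled polygon: pixel indices inside it plus the binary label."""

    rows: np.ndarray
    cols: np.ndarray
    label: int  # 1 = burned, 0 = unburned
    year: int

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        if self.rows.size == 0:
            raise ValueError("training sample must cover at least one pixel")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (unburned) or 1 (burned)")

    @classmethod
    def from_polygon(cls, vertices_rc: np.ndarray, label: int, year: int,
                     shape: tuple[int, int]) -> "TrainingSample":
        """Rasterize a (row, col) polygon to its interior pixels."""
        v = np.asarray(vertices_rc, dtype=float)
        rr, cc = draw_polygon(v[:, 0], v[:, 1], shape=shape)
        return cls(rows=rr, cols=cc, label=label, year=year)


def extract_training_matrix(samples: list[TrainingSample],
                            stacks: dict[int, FeatureComposite]
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Pool valid pixels of every sample polygon into (X, y).

    All pixels inside each labeled polygon become training rows (no
    per-polygon aggregation); pixels invalid in the year's feature stack are
    skipped.
    """
    xs, ys = [], []
    for s in samples:
        stack = stacks[s.year]
        ok = stack.valid[s.rows, s.cols]
        if not ok.any():
            continue
        xs.append(stack.table(s.rows[ok], s.cols[ok]))
        ys.append(np.full(int(ok.sum()), s.label))
    if not xs:
        raise ValueError("no valid training pixels")
    return np.vstack(xs), np.concatenate(ys)


@dataclass
class BurnClassifier:
    """Fitted forest plus the feature ordering it was trained with."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    burned_train_mean_pb: float
    format_version: int = 1

    @property
    def settings(self) -> dict:
        return dict(RF_SETTINGS)

    def save(self, path) -> None:
        """Serialize the fitted model (joblib, with a format version)."""
        import joblib

        joblib.dump({"format_version": self.format_version,
                     "forest": self.forest,
                     "feature_names": self.feature_names,
                     "burned_train_mean_pb": self.burned_train_mean_pb}, path)

    @classmethod
    def load(cls, path) -> "BurnClassifier":
        import joblib

        blob = joblib.load(path)
        if blob.get("format_version") != 1:
            raise ValueError(
                f"unsupported model format {blob.get('format_version')!r}")
        return cls(forest=blob["forest"],
                   feature_names=tuple(blob["feature_names"]),
                   burned_train_mean_pb=blob["burned_train_mean_pb"])


def train_rf(X: np.ndarray, y: np.ndarray, seed: int = 0,
             feature_names: tuple[str, ...] = FEATURE_NAMES) -> BurnClassifier:
    """Train the burn/unburned random forest on pooled polygon pixels.

    The "maximum nodes" budget is mapped to scikit-learn's per-tree
    ``max_leaf_nodes`` cap (450 leaves implies at most 899 nodes per binary
    tree); leaf population and bag fraction map directly.  Rows may arrive
    in any order: they are canonically sorted before fitting so shuffling
    the samples does not change the model under a fixed seed.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")
    order = np.lexsort(np.vstack([X.T, y]))
    X, y = X[order], y[order]
    forest = RandomForestClassifier(
        n_estimators=RF_SETTINGS["n_trees"],
        min_samples_leaf=RF_SETTINGS["min_leaf_population"],
        max_leaf_nodes=RF_SETTINGS["max_nodes"],
        max_features=RF_SETTINGS["variables_per_split"],
        bootstrap=True,
        max_samples=RF_SETTINGS["bag_fraction"],
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(X, y)
    pb_train = _vote_share(forest, X)
    return BurnClassifier(
        forest=forest,
        feature_names=tuple(feature_names),
        burned_train_mean_pb=float(pb_train[y == 1].mean()),
    )


def _vote_share(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting for the burned class (majority leaf vote)."""
    burned_idx = int(np.nonzero(forest.classes_ == 1)[0][0])
    votes = np.zeros(X.shape[0])
    for tree in forest.estimators_:
        votes += tree.predict(X) == forest.classes_[burned_idx]
    return votes / len(forest.estimators_)


@dataclass
class BurnProbabilityMap:
    """Per-pixel burn probability P_b with its validity mask."""

    p_b: np.ndarray
    valid: np.ndarray
    year: int


def predict_probability(clf: BurnClassifier, stack: FeatureComposite,
                        column_order: tuple[str, ...] | None = None
                        ) -> BurnProbabilityMap:
    """Vote-share burn probability on every valid pixel of a feature stack.

    ``column_order`` names the feature order of the stack if it differs from
    the classifier's training order; columns are realigned by name so the
    probability is invariant to feature-column permutations.
    """
    feats = stack.features
    names = tuple(column_order) if column_order is not None else stack.names
    if names != clf.feature_names:
        idx = [names.index(n) for n in clf.feature_names]
        feats = feats[..., idx]
    valid = stack.valid & np.isfinite(feats).all(axis=-1)
    p = np.full(stack.valid.shape, np.nan)
    rr, cc = np.nonzero(valid)
    if rr.size:
        p[rr, cc] = _vote_share(clf.forest, feats[rr, cc, :])
    return BurnProbabilityMap(p_b=p, valid=valid, year=stack.year)


@dataclass
class AccuracyReport:
    """Pixel-count accuracy of a predicted mask against a reference mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def omission_error(self) -> float:
        """Percent of reference burned pixels missed: 100 * FN/(TP+FN)."""
        denom = self.tp + self.fn
        return 100.0 * self.fn / denom if denom else float("nan")

    @property
    def commission_error(self) -> float:
        """Percent of predicted burned pixels that are false: 100 * FP/(TP+FP)."""
        denom = self.tp + self.fp
        return 100.0 * self.fp / denom if denom else float("nan")

    @property
    def dice(self) -> float:
        """Dice coefficient 2TP / (2TP + FP + FN); 0 when nothing overlaps."""
        denom = 2 * self.tp + self.fp + self.fn
        return 2.0 * self.tp / denom if denom else float("nan")


def dice_from_errors(omission_pct: float, commission_pct: float) -> float:
    """Dice via the harmonic identity 2 / (1/(1-E_o) + 1/(1-E_c))."""
    eo = omission_pct / 100.0
    ec = commission_pct / 100.0
    return 2.0 / (1.0 / (1.0 - eo) + 1.0 / (1.0 - ec))


def evaluate_against_reference(predicted: np.ndarray, reference: np.ndarray,
                               valid: np.ndarray | None = None) -> AccuracyReport:
    """Confusion counts of predicted vs reference burned masks on one grid."""
    predicted = np.asarray(predicted, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference masks must share a grid")
    if valid is not None:
        predicted = predicted & valid
        reference = reference & valid
    tp = int((predicted & reference).sum())
    fp = int((predicted & ~reference).sum())
    fn = int((~predicted & reference).sum())
    tn = int(predicted.size - tp - fp - fn)
    return AccuracyReport(tp=tp, fp=fp, fn=fn, tn=tn)
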