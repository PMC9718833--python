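"""Linear discriminant model over contact fingerprints and the
spatiotemporal selectivity code.

A three-class (Gs/Gi/Gq) LDA fitted on per-frame binary fingerprints
yields a two-dimensional discriminant space plus per-class weight vectors
over contact pairs. Each pair's class weight is combined with its mean
temporal frequency in that class into a composite score

    wGx(p) = w_X(p) · cGx(p),

and the top-k pairs per class (k = 10 by default) form the spatiotemporal
code. Per-class weights use scikit-learn's one-vs-rest coefficient
convention for multiclass LDA, fixed here so that ranks are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import train_test_split

from .errors import (
    AlignmentError,
    DataError,
    DegenerateModelError,
    ParameterError,
    SplitError,
)
from .fingerprints import CLASSES, FingerprintMatrix, PersistenceLabels

_SIGN_EPS = 1e-12


@dataclass
class LDAModel:
    classes: tuple[str, ...]
    pairs: list[str]
    scalings: np.ndarray  # (n_pairs, 2), deterministically signed
    coef: np.ndarray  # (n_classes, n_pairs)
    intercept: np.ndarray  # (n_classes,)
    class_means: np.ndarray  # (n_classes, n_pairs)
    xbar: np.ndarray  # (n_pairs,) overall mean used for projection
    explained_variance_ratio: np.ndarray  # (2,)
    solver: str = "svd"

    def weights(self, cls: str) -> np.ndarray:
        return self.coef[self.classes.index(cls)]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef.T + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.decision_scores(np.asarray(X, float)), axis=1)
        return np.asarray([self.classes[i] for i in idx], dtype=object)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.xbar) @ self.scalings

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": list(self.classes),
            "pairs": self.pairs,
            "scalings": self.scalings.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "class_means": self.class_means.tolist(),
            "xbar": self.xbar.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "solver": self.solver,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "LDAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=tuple(d["classes"]),
            pairs=list(d["pairs"]),
            scalings=np.asarray(d["scalings"], float),
            coef=np.asarray(d["coef"], float),
            intercept=np.asarray(d["intercept"], float),
            class_means=np.asarray(d["class_means"], float),
            xbar=np.asarray(d["xbar"], float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], float),
            solver=d["solver"],
        )


def _fix_signs(scalings: np.ndarray) -> np.ndarray:
    """Flip each component so its first nonzero loading is positive."""
    out = scalings.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.nonzero(np.abs(col) > _SIGN_EPS)[0]
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out


def _check_fit_inputs(X: np.ndarray, y: np.ndarray) -> None:
    present, counts = np.unique(y, return_counts=True)
    if set(present) != set(CLASSES):
        raise DegenerateModelError(
            f"need exactly the classes {CLASSES}, got {sorted(present)}"
        )
    if counts.min() < 2:
        raise DegenerateModelError("every class needs at least 2 frames")
    if np.all(X == X[0], axis=0).all():
        raise DegenerateModelError("all features constant; model has no rank")


def fit_lda(
    matrix: FingerprintMatrix,
    labels: Sequence[str] | None = None,
) -> LDAModel:
    """Fit the 3-class discriminant model (SVD solver, empirical priors).

    Deterministic given input order; the two discriminant components are
    re-signed so the first nonzero loading of each is positive.
    """
    X = matrix.data.astype(float)
    y = np.asarray(labels if labels is not None else matrix.class_labels, dtype=object)
    if len(y) != X.shape[0]:
        raise DataError("label count does not match fingerprint rows")
    _check_fit_inputs(X, y)

    est = LinearDiscriminantAnalysis(solver="svd", n_components=2)
    est.fit(X, y)
    # reorder from sklearn's sorted class order into the canonical Gs/Gi/Gq
    order = [list(est.classes_).index(c) for c in CLASSES]
    return LDAModel(
        classes=tuple(CLASSES),
        pairs=list(matrix.pairs),
        scalings=_fix_signs(np.asarray(est.scalings_, float)[:, :2]),
        coef=np.asarray(est.coef_, float)[order],
        intercept=np.asarray(est.intercept_, float)[order],
        class_means=np.asarray(est.means_, float)[order],
        xbar=np.asarray(est.xbar_, float),
        explained_variance_ratio=np.asarray(est.explained_variance_ratio_, float)[:2],
    )


def holdout_accuracy(
    matrix: FingerprintMatrix,
    labels: Sequence[str] | None = None,
    split: float = 0.8,
    seed: int = 0,
) -> float:
    """Accuracy on a random stratified holdout (default 80:20 train:test)."""
    X = matrix.data.astype(float)
    y = np.asarray(labels if labels is not None else matrix.class_labels, dtype=object)
    strata = np.asarray(
        [f"{s}|{c}" for s, c in zip(matrix.system_ids, y)], dtype=object
    )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, random_state=seed, stratify=strata
    )
    if set(np.unique(y_tr)) != set(np.unique(y)):
        raise SplitError("a class is absent from the training split")
    train = FingerprintMatrix(
        pairs=list(matrix.pairs),
        data=X_tr.astype(np.uint8),
        system_ids=np.asarray(["train"] * len(y_tr), dtype=object),
        class_labels=y_tr,
        frame_ids=np.arange(len(y_tr)),
    )
    model = fit_lda(train, labels=y_tr)
    return float(np.mean(model.predict(X_te) == y_te))


# ---------------------------------------------------------------------------
# Composite scores and the code
# ---------------------------------------------------------------------------

def class_mean_frequencies(
    freq_table: pd.DataFrame, system_to_class: Mapping[str, str]
) -> pd.DataFrame:
    """cGx: mean contact frequency over each class's systems (classes × pairs)."""
    rows = {}
    for cls in CLASSES:
        systems = [s for s in freq_table.index if system_to_class.get(str(s)) == cls]
        if not systems:
            raise DataError(f"no systems for class {cls}")
        rows[cls] = freq_table.loc[systems].mean(axis=0)
    return pd.DataFrame(rows).T


def composite_scores(
    model: LDAModel,
    freq_by_class: pd.DataFrame,
) -> pd.DataFrame:
    """Per (class, pair): cGx, wGx = w_X(p)·cGx(p), and within-class rank.

    Ties broken by larger |w_X(p)| then lexicographic pair key.
    """
    if sorted(freq_by_class.columns) != sorted(model.pairs):
        raise AlignmentError("frequency table and model have different pair universes")
    freq = freq_by_class[model.pairs]
    records = []
    for cls in model.classes:
        w = model.weights(cls)
        c = freq.loc[cls].to_numpy(float)
        wgx = w * c
        order = sorted(
            range(len(model.pairs)),
            key=lambda j: (-wgx[j], -abs(w[j]), model.pairs[j]),
        )
        rank = np.empty(len(order), dtype=int)
        for r, j in enumerate(order, start=1):
            rank[j] = r
        for j, p in enumerate(model.pairs):
            records.append(
                {
                    "class": cls,
                    "pair_key": p,
                    "weight": w[j],
                    "cGx": c[j],
                    "wGx": wgx[j],
                    "rank": int(rank[j]),
                }
            )
    return pd.DataFrame.from_records(records)


def extract_code(
    score_table: pd.DataFrame,
    k: int = 10,
    persistence: PersistenceLabels | None = None,
    in_pdb: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Top-k pairs per class by descending wGx — the spatiotemporal code.

    Annotates each entry with its persistence label and, when known,
    whether the contact already exists in the starting structure.
    """
    n_pairs = score_table["pair_key"].nunique()
    if k > n_pairs:
        raise ParameterError(f"k={k} exceeds universe size {n_pairs}")
    rows = []
    for cls in CLASSES:
        sub = score_table[score_table["class"] == cls].sort_values("rank")
        top = sub.head(k)
        for _, r in top.iterrows():
            rows.append(
                {
                    "class": cls,
                    "rank": int(r["rank"]),
                    "pair_key": r["pair_key"],
                    "wGx": float(r["wGx"]),
                    "cGx": float(r["cGx"]),
                    "persistence_label": (
                        persistence.label_of(r["pair_key"]) if persistence else ""
                    ),
                    "in_pdb": bool(in_pdb.get(r["pair_key"], False)) if in_pdb else None,
                }
            )
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# Projection of external fingerprints
# ---------------------------------------------------------------------------

@dataclass
class ProjectionResult:
    coordinates: pd.DataFrame  # component1, component2, predicted, true label
    accuracy: float | None
    n_missing_pairs: int  # model pairs absent from the input (imputed 0)
    n_dropped_pairs: int  # input pairs unknown to the model (carry no weight)


def project_and_classify(
    model: LDAModel,
    matrix: FingerprintMatrix,
    target_class: str | None = None,
) -> ProjectionResult:
    """Project fingerprints into the discriminant plane and classify them.

    The input universe is aligned to the model's: missing pairs are imputed
    as absent (0) and novel pairs are dropped; both are tallied in the
    result so alignment loss is visible.
    """
    if matrix.n_rows == 0:
        raise DataError("empty fingerprint matrix")
    col = {p: j for j, p in enumerate(matrix.pairs)}
    X = np.zeros((matrix.n_rows, len(model.pairs)), dtype=float)
    n_missing = 0
    for jm, p in enumerate(model.pairs):
        ji = col.get(p)
        if ji is None:
            n_missing += 1
        else:
            X[:, jm] = matrix.data[:, ji]
    n_dropped = len(matrix.pairs) - (len(model.pairs) - n_missing)

    coords = model.transform(X)
    predicted = model.predict(X)
    df = pd.DataFrame(
        {
            "component1": coords[:, 0],
            "component2": coords[:, 1],
            "predicted": predicted,
            "true_label": matrix.class_labels,
        }
    )
    accuracy = (
        float(np.mean(predicted == target_class)) if target_class is not None else None
    )
    return ProjectionResult(
        coordinates=df,
        accuracy=accuracy,
        n_missing_pairs=n_missing,
        n_dropped_pairs=n_dropped,
    )


def compare_position_subsets(
    values: Mapping[str, float],
    subset: Iterable[str],
) -> tuple[float, float | None]:
    """Mean of a per-position statistic over a subset vs its complement.

    Generic position-subset comparison (e.g. population-variant frequency
    at code positions vs all remaining positions). Returns ``None`` for the
    complement mean when the subset covers every position.
    """
    subset = set(subset)
    if not subset:
        raise ParameterError("subset is empty")
    missing = subset - set(values)
    if missing:
        raise DataError(f"values missing for positions {sorted(missing)}")
    in_vals = [values[p] for p in subset]
    out_vals = [v for p, v in values.items() if p not in subset]
    mean_out = float(np.mean(out_vals)) if out_vals else None
    return float(np.mean(in_vals)), mean_out
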