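"""Structural-class model: four regressions, one sign decision tree.

``StructuralClassModel`` is built from a training set of domains (440D
feature vectors, secondary-structure strings, class labels); ``fit()``
estimates the 4 x 441 coefficient matrix mapping sequence features to
the (x, y1, y2, z) structural scores and returns a
``StructuralClassResults`` carrying the coefficients, training
diagnostics and prediction methods.

Each structural dimension is trained on the union of the two class
groups it separates:

* x  : all-alpha vs all-beta
* y1 : all-alpha vs mixed alpha-beta (alpha/beta + alpha+beta)
* y2 : all-beta vs mixed alpha-beta
* z  : alpha/beta vs alpha+beta

and a query's class follows from the signs of its predicted scores:
x > 0 with y1 < 0 is all-alpha; x <= 0 with y2 < 0 is all-beta;
otherwise z > 0 is alpha/beta and z <= 0 is alpha+beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import regression
from .features import N_FEATURES, feature_labels
from .targets import (
    CLASSES,
    DIMENSIONS,
    REQUIRED_SIGNS,
    StructuralVector,
    TargetParams,
    make_target,
)

__all__ = [
    "DomainDataset",
    "ModelMatrix",
    "StructuralClassModel",
    "StructuralClassResults",
    "build_subsets",
    "train",
    "predict_vector",
    "decide",
]

#: Class pair each dimension's training subset unites.
SUBSET_GROUPS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "x": (("all-alpha",), ("all-beta",)),
    "y1": (("all-alpha",), ("alpha/beta", "alpha+beta")),
    "y2": (("all-beta",), ("alpha/beta", "alpha+beta")),
    "z": (("alpha/beta",), ("alpha+beta",)),
}


@dataclass
class DomainDataset:
    """A set of domains: ids, feature matrix, secondary structure, labels."""

    ids: list[str]
    X: np.ndarray
    ss: list[str] | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.ids)
        if self.X.shape != (n, N_FEATURES):
            raise ValueError(
                f"feature matrix shape {self.X.shape} != ({n}, {N_FEATURES})"
            )
        for name, attr in (("ss", self.ss), ("labels", self.labels)):
            if attr is not None and len(attr) != n:
                raise ValueError(f"{name} has {len(attr)} entries for {n} domains")
        if self.labels is not None:
            unknown = set(self.labels) - set(CLASSES)
            if unknown:
                raise ValueError(f"unknown class labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, idx) -> "DomainDataset":
        idx = np.asarray(idx)
        if idx.dtype != bool:
            idx = idx.astype(int)
        else:
            idx = np.flatnonzero(idx)
        return DomainDataset(
            [self.ids[i] for i in idx],
            self.X[idx],
            [self.ss[i] for i in idx] if self.ss is not None else None,
            [self.labels[i] for i in idx] if self.labels is not None else None,
        )


def build_subsets(labels) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-dimension training subsets and required target signs.

    Returns ``{dim: (row indices, +/-1 signs)}``.  The positive-sign
    group of a dimension is the one its score must exceed zero for.
    """
    labels = list(labels)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for dim in DIMENSIONS:
        sign_by_class: dict[str, int] = {}
        for group in SUBSET_GROUPS[dim]:
            for cls in group:
                sign_by_class[cls] = REQUIRED_SIGNS[cls][DIMENSIONS.index(dim)]
        idx = [i for i, lab in enumerate(labels) if lab in sign_by_class]
        signs = np.array([sign_by_class[labels[i]] for i in idx], dtype=float)
        if len(set(signs.tolist())) < 2:
            present = sorted({labels[i] for i in idx})
            raise ValueError(
                f"dimension {dim!r}: training subset needs both class groups, "
                f"found only {present}"
            )
        out[dim] = (np.array(idx, dtype=int), signs)
    return out


@dataclass
class ModelMatrix:
    """The trained 4 x 441 coefficient matrix plus its preprocessing.

    ``coefficients[d]`` holds 440 standardized-feature slopes followed by
    the intercept; slopes outside a dimension's selected feature set are
    zero when forward selection is used.
    """

    coefficients: np.ndarray  # (4, 441)
    means: np.ndarray  # (440,)
    scales: np.ndarray  # (440,)
    selected: dict[str, list[int]] | None = None
    target_params: TargetParams = field(default_factory=TargetParams)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if self.coefficients.shape != (4, N_FEATURES + 1):
            raise ValueError(
                f"coefficient matrix must be 4 x {N_FEATURES + 1}, "
                f"got {self.coefficients.shape}"
            )

    def to_dict(self) -> dict:
        return {
            "feature_labels": list(feature_labels()),
            "coefficients": {
                dim: self.coefficients[d].tolist() for d, dim in enumerate(DIMENSIONS)
            },
            "standardization": {
                "means": self.means.tolist(),
                "scales": self.scales.tolist(),
            },
            "selected": self.selected,
            "target_params": {
                "window": self.target_params.window,
                "theta": self.target_params.theta,
                "delta": self.target_params.delta,
                "margin": self.target_params.margin,
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelMatrix":
        coef = np.array([payload["coefficients"][dim] for dim in DIMENSIONS])
        std = payload["standardization"]
        selected = payload.get("selected")
        if selected is not None:
            selected = {dim: [int(i) for i in idx] for dim, idx in selected.items()}
        return cls(
            coef,
            np.array(std["means"], dtype=float),
            np.array(std["scales"], dtype=float),
            selected,
            TargetParams(**payload.get("target_params", {})),
        )


def predict_vector(model: ModelMatrix, X: np.ndarray) -> np.ndarray:
    """Predicted (x, y1, y2, z) scores, one row per domain."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"feature matrix must have {N_FEATURES} columns")
    Xs = regression.standardize_apply(X, model.means, model.scales)
    return Xs @ model.coefficients[:, :N_FEATURES].T + model.coefficients[:, N_FEATURES]


def decide(v) -> str:
    """Map a structural vector to its class by the sign decision tree.

    Zero scores fall to the "else" branch: x = 0 routes to the beta
    side, y = 0 to mixed, z = 0 to alpha+beta.
    """
    if isinstance(v, StructuralVector):
        v = v.as_array()
    x, y1, y2, z = (float(c) for c in np.asarray(v, dtype=float))
    if x > 0:
        if y1 < 0:
            return "all-alpha"
    else:
        if y2 < 0:
            return "all-beta"
    return "alpha/beta" if z > 0 else "alpha+beta"


class StructuralClassModel:
    """Iterative-MLR structural class predictor, before fitting.

    Parameters
    ----------
    dataset
        Training domains with features, secondary structure and labels.
    target_params
        Constants of the structural-score construction.
    n_features
        Forward-selection budget per dimension; ``None`` uses all 440.
    """

    def __init__(
        self,
        dataset: DomainDataset,
        target_params: TargetParams | None = None,
        n_features: int | None = None,
        ridge_lambda: float = regression.RIDGE_LAMBDA,
    ) -> None:
        if dataset.ss is None or dataset.labels is None:
            raise ValueError("training requires secondary structure and labels")
        if n_features is not None and not 0 < n_features <= N_FEATURES:
            raise ValueError(f"n_features must be in [1, {N_FEATURES}]")
        self.dataset = dataset
        self.target_params = target_params or TargetParams()
        self.n_features = n_features
        self.ridge_lambda = ridge_lambda

    @classmethod
    def from_files(cls, features_path, ss_path, labels_path, **kwargs):
        from . import io

        ids, X = io.read_feature_table(features_path)
        ss = io.read_ss_table(ss_path)
        labels = io.read_labels(labels_path)
        missing = [i for i in ids if i not in ss or i not in labels]
        if missing:
            raise ValueError(
                f"domains missing secondary structure or label: {missing[:5]}"
            )
        dataset = DomainDataset(ids, X, [ss[i] for i in ids], [labels[i] for i in ids])
        return cls(dataset, **kwargs)

    def fit(self) -> "StructuralClassResults":
        ds = self.dataset
        # 4D targets for every training domain
        targets = np.array(
            [
                make_target(s, lab, self.target_params).as_array()
                for s, lab in zip(ds.ss, ds.labels)
            ]
        )
        means, scales = regression.standardize_fit(ds.X)
        Xs = regression.standardize_apply(ds.X, means, scales)
        subsets = build_subsets(ds.labels)

        coef = np.zeros((4, N_FEATURES + 1))
        selected: dict[str, list[int]] = {}
        diagnostics: dict[str, dict] = {}
        for d, dim in enumerate(DIMENSIONS):
            idx, signs = subsets[dim]
            Xd, td = Xs[idx], targets[idx, d]
            if self.n_features is not None:
                sel = regression.forward_select(Xd, td, self.n_features)
            else:
                sel = list(range(N_FEATURES))
            design = np.hstack([Xd[:, sel], np.ones((len(idx), 1))])
            beta = regression.iterative_fit(
                design, td, signs, self.target_params.margin, self.ridge_lambda
            )
            coef[d, sel] = beta[:-1]
            coef[d, N_FEATURES] = beta[-1]
            selected[dim] = sorted(int(i) for i in sel)
            fitted = design @ beta
            diagnostics[dim] = {
                "n_obs": int(len(idx)),
                "n_features": len(sel),
                "train_sign_accuracy": float(np.mean(np.sign(fitted) == signs)),
            }

        model = ModelMatrix(
            coef, means, scales,
            selected if self.n_features is not None else None,
            self.target_params,
        )
        return StructuralClassResults(model, diagnostics)


class StructuralClassResults:
    """Fitted structural-class model: coefficients, diagnostics, prediction."""

    def __init__(self, model_matrix: ModelMatrix, diagnostics: dict | None = None):
        self.model_matrix = model_matrix
        self.diagnostics = diagnostics or {}

    @property
    def coefficients(self) -> pd.DataFrame:
        """4 x 441 coefficients as a labelled DataFrame."""
        return pd.DataFrame(
            self.model_matrix.coefficients,
            index=list(DIMENSIONS),
            columns=list(feature_labels()) + ["intercept"],
        )

    def predict_vector(self, X) -> np.ndarray:
        return predict_vector(self.model_matrix, X)

    def predict(self, X, ids=None) -> pd.DataFrame:
        """Predicted scores and classes, one row per domain."""
        V = self.predict_vector(X)
        classes = [decide(v) for v in V]
        df = pd.DataFrame(V, columns=list(DIMENSIONS))
        df.insert(0, "domain_id", ids if ids is not None else range(len(V)))
        df["class"] = classes
        return df

    def summary(self) -> str:
        """Human-readable fit summary."""
        mm = self.model_matrix
        n_nonzero = (np.abs(mm.coefficients[:, :N_FEATURES]) > 0).sum(axis=1)
        lines = [
            "Structural class model (iterative MLR)",
            "=" * 54,
            f"{'dim':<5}{'separates':<30}{'n_obs':>6}{'feats':>6}{'sign%':>7}",
            "-" * 54,
        ]
        for d, dim in enumerate(DIMENSIONS):
            a, b = SUBSET_GROUPS[dim]
            pair = f"{'+'.join(a)} | {'+'.join(b)}"
            diag = self.diagnostics.get(dim, {})
            acc = diag.get("train_sign_accuracy")
            lines.append(
                f"{dim:<5}{pair:<30}{diag.get('n_obs', '-'):>6}"
                f"{n_nonzero[d]:>6}{'' if acc is None else f'{100 * acc:>6.1f}'}"
            )
        lines.append("-" * 54)
        lines.append(
            f"coefficients: 4 x {N_FEATURES + 1} = {4 * (N_FEATURES + 1)} "
            f"(selection budget: {mm.selected and len(mm.selected['x']) or 'all'})"
        )
        return "\n".join(lines)

    def save(self, path) -> None:
        from . import io

        io.write_model(self.model_matrix, path)


def train(
    dataset: DomainDataset,
    target_params: TargetParams | None = None,
    n_features: int | None = None,
) -> ModelMatrix:
    """Convenience wrapper: fit and return the bare coefficient matrix."""
    results = StructuralClassModel(dataset, target_params, n_features).fit()
    return results.model_matrix
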