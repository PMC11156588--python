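"""Per-electrode classification and the electrode-voting trigger policy.

Each electrode gets its own small feedforward network (35 inputs = the
flattened M x P feature matrix, two hidden layers, two output classes:
"pregrooming" vs "other"), trained on z-scored features.  Stimulation is
triggered only when a strict majority (>50%) of electrode classifiers
predicts "pregrooming"; all ties resolve to the negative class — the
conservative choice for a stimulation policy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

PREGROOMING = 1
OTHER = 0


@dataclass(frozen=True)
class VotePolicy:
    """Strict-majority trigger rule: fire iff positive fraction > threshold."""

    threshold_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")


@dataclass
class Decision:
    """One voting outcome across electrodes at time ``t_s``."""

    t_s: float
    electrode_outputs: np.ndarray
    positive_fraction: float
    triggered: bool


def vote(
    per_electrode_classes,
    policy: VotePolicy = VotePolicy(),
    t_s: float = float("nan"),
) -> Decision:
    """Aggregate per-electrode class outputs into a trigger decision."""
    outputs = np.asarray(per_electrode_classes, dtype=int)
    if outputs.size == 0:
        raise ValueError("vote requires at least one electrode output")
    frac = float(np.mean(outputs == PREGROOMING))
    return Decision(
        t_s=t_s,
        electrode_outputs=outputs,
        positive_fraction=frac,
        triggered=frac > policy.threshold_fraction,
    )


class ElectrodeClassifier(ClassifierMixin, BaseEstimator):
    """Two-class feedforward network for a single electrode.

    A minimal MLP (two hidden layers, logistic activations, softmax-
    equivalent output normalization, cross-entropy objective with L2
    regularization, L-BFGS solver) on per-feature z-scored inputs; L-BFGS
    is well suited to networks this small and makes training fully
    deterministic given the seed.  Prediction is "pregrooming"
    only when its class score strictly exceeds 0.5; an exact tie resolves to
    "other".  Training is deterministic given ``random_state``.
    """

    def __init__(
        self,
        hidden_layer_sizes=(16, 8),
        activation="logistic",
        solver="lbfgs",
        alpha=1e-2,
        max_iter=500,
        early_stopping=False,
        validation_fraction=0.15,
        n_iter_no_change=20,
        random_state=None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.solver = solver
        self.alpha = alpha
        self.max_iter = max_iter
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.n_iter_no_change = n_iter_no_change
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(
                "training set contains a single class; both 'pregrooming' and "
                "'other' windows are required"
            )
        self.scaler_ = StandardScaler().fit(X)
        extra = {}
        if self.solver in ("sgd", "adam"):
            extra = dict(
                early_stopping=self.early_stopping,
                validation_fraction=self.validation_fraction,
                n_iter_no_change=self.n_iter_no_change,
            )
        self.mlp_ = MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation=self.activation,
            solver=self.solver,
            alpha=self.alpha,
            max_iter=self.max_iter,
            random_state=self.random_state,
            **extra,
        ).fit(self.scaler_.transform(X), y)
        self.classes_ = self.mlp_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "mlp_")
        X = check_array(X)
        return self.mlp_.predict_proba(self.scaler_.transform(X))

    def predict(self, X):
        proba = self.predict_proba(X)
        pos_col = int(np.argmax(self.classes_ == PREGROOMING))
        return np.where(proba[:, pos_col] > 0.5, PREGROOMING, OTHER)


class VotingGroomingDetector(ClassifierMixin, BaseEstimator):
    """One classifier per electrode plus the strict-majority vote.

    ``fit`` expects ``X`` of shape ``(n_windows, n_electrodes, n_features)``
    and a shared label vector; one network is trained per electrode (never a
    pooled model), with per-electrode seeds derived deterministically from
    ``random_state``.
    """

    def __init__(
        self,
        hidden_layer_sizes=(16, 8),
        activation="logistic",
        solver="lbfgs",
        alpha=1e-2,
        max_iter=500,
        early_stopping=False,
        validation_fraction=0.15,
        n_iter_no_change=20,
        threshold_fraction=0.5,
        random_state=None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.solver = solver
        self.alpha = alpha
        self.max_iter = max_iter
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.n_iter_no_change = n_iter_no_change
        self.threshold_fraction = threshold_fraction
        self.random_state = random_state

    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, None, :]
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, n_electrodes, n_features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y, dtype=int)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        seeds = np.random.SeedSequence(self.random_state).generate_state(X.shape[1])
        self.electrodes_ = []
        for c in range(X.shape[1]):
            clf = ElectrodeClassifier(
                hidden_layer_sizes=self.hidden_layer_sizes,
                activation=self.activation,
                solver=self.solver,
                alpha=self.alpha,
                max_iter=self.max_iter,
                early_stopping=self.early_stopping,
                validation_fraction=self.validation_fraction,
                n_iter_no_change=self.n_iter_no_change,
                random_state=int(seeds[c] % (2**31)),
            )
            self.electrodes_.append(clf.fit(X[:, c, :], y))
        self.n_channels_ = X.shape[1]
        self.n_features_in_ = X.shape[2]
        self.classes_ = np.array([OTHER, PREGROOMING])
        return self

    @property
    def policy(self) -> VotePolicy:
        return VotePolicy(self.threshold_fraction)

    def electrode_predictions(self, X) -> np.ndarray:
        check_is_fitted(self, "electrodes_")
        X = self._check_X(X)
        if X.shape[1] != self.n_channels_:
            raise ValueError(
                f"model covers {self.n_channels_} channels, got {X.shape[1]}"
            )
        return np.stack(
            [clf.predict(X[:, c, :]) for c, clf in enumerate(self.electrodes_)], axis=1
        )

    def positive_fraction(self, X) -> np.ndarray:
        return (self.electrode_predictions(X) == PREGROOMING).mean(axis=1)

    def predict(self, X) -> np.ndarray:
        frac = self.positive_fraction(X)
        return np.where(frac > self.threshold_fraction, PREGROOMING, OTHER)

    def decide(self, features_one_decision: np.ndarray, t_s: float = float("nan")) -> Decision:
        """Vote on a single decision's (n_electrodes, n_features) matrix."""
        outputs = self.electrode_predictions(features_one_decision[None, :, :])[0]
        return vote(outputs, self.policy, t_s=t_s)


# ---------------------------------------------------------------------------
# Model bundle persistence (HDF5: JSON config + weight arrays)
# ---------------------------------------------------------------------------


def save_model_bundle(path, detector: VotingGroomingDetector) -> None:
    check_is_fitted(detector, "electrodes_")
    with h5py.File(path, "w") as f:
        f.attrs["params"] = json.dumps(detector.get_params())
        f.attrs["n_channels"] = detector.n_channels_
        f.attrs["n_features"] = detector.n_features_in_
        for c, clf in enumerate(detector.electrodes_):
            g = f.create_group(f"electrode_{c:03d}")
            g.create_dataset("scaler_mean", data=clf.scaler_.mean_)
            g.create_dataset("scaler_scale", data=clf.scaler_.scale_)
            g.attrs["classes"] = clf.classes_
            g.attrs["random_state"] = clf.random_state
            for i, (W, b) in enumerate(zip(clf.mlp_.coefs_, clf.mlp_.intercepts_)):
                g.create_dataset(f"W{i}", data=W)
                g.create_dataset(f"b{i}", data=b)


def _rebuild_mlp(g, params) -> MLPClassifier:
    from sklearn.preprocessing import LabelBinarizer

    coefs, intercepts = [], []
    i = 0
    while f"W{i}" in g:
        coefs.append(g[f"W{i}"][()])
        intercepts.append(g[f"b{i}"][()])
        i += 1
    classes = np.asarray(g.attrs["classes"])
    mlp = MLPClassifier(
        hidden_layer_sizes=tuple(params["hidden_layer_sizes"]),
        activation=params["activation"],
    )
    mlp.coefs_ = coefs
    mlp.intercepts_ = intercepts
    mlp.n_layers_ = len(coefs) + 1
    mlp.n_outputs_ = coefs[-1].shape[1]
    mlp.out_activation_ = "logistic" if mlp.n_outputs_ == 1 else "softmax"
    mlp.classes_ = classes
    mlp.n_features_in_ = coefs[0].shape[0]
    mlp._label_binarizer = LabelBinarizer().fit(classes)
    return mlp


def load_model_bundle(path) -> VotingGroomingDetector:
    with h5py.File(path, "r") as f:
        params = json.loads(f.attrs["params"])
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        det = VotingGroomingDetector(**params)
        det.n_channels_ = int(f.attrs["n_channels"])
        det.n_features_in_ = int(f.attrs["n_features"])
        det.classes_ = np.array([OTHER, PREGROOMING])
        det.electrodes_ = []
        for c in range(det.n_channels_):
            g = f[f"electrode_{c:03d}"]
            clf = ElectrodeClassifier(
                hidden_layer_sizes=params["hidden_layer_sizes"],
                activation=params["activation"],
                random_state=int(g.attrs["random_state"]),
            )
            scaler = StandardScaler()
            scaler.mean_ = g["scaler_mean"][()]
            scaler.scale_ = g["scaler_scale"][()]
            scaler.var_ = scaler.scale_**2
            scaler.n_features_in_ = len(scaler.mean_)
            scaler.n_samples_seen_ = 1
            clf.scaler_ = scaler
            clf.mlp_ = _rebuild_mlp(g, params)
            clf.classes_ = clf.mlp_.classes_
            clf.n_features_in_ = clf.mlp_.n_features_in_
            det.electrodes_.append(clf)
    return det


def train_electrode_ensemble(
    dataset,
    seed: int | None = None,
    **params,
) -> VotingGroomingDetector:
    """Train one classifier per electrode on a labeled window dataset."""
    det = VotingGroomingDetector(random_state=seed, **params)
    return det.fit(dataset.X, dataset.y)
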