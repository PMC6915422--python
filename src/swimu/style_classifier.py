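"""Per-lap stroke-style classification from accelerometer energy features.

Backstroke is special-cased: it is the only style swum supine, so the
low-pass-filtered vertical accelerometer channel sits near -1 g instead of
+1 g and a simple mean threshold recognizes it.  The remaining three styles
(butterfly, breaststroke, front crawl) are separated by a classifier on the
per-lap "energy" of each accelerometer channel,

    E_channel = round( sum_n |x(n) - mean(x)| / N ),

computed on the 0.5 Hz low-pass-filtered channel converted from g to m/s^2.
Front crawl has much higher y-energy (body roll each stroke); butterfly has
higher z-energy (undulation) and x-energy (speed) than breaststroke.

Two trainable models are provided with the hyperparameters that performed
best in the source experiments: an SVM with a polynomial kernel (degree 1,
box constraint 1e5) and a 3-10-3 neural network trained by gradient descent
with momentum (alpha = 0.5, eta = 0.3).  Rounding in the energy formula is
half-away-from-zero; the g -> m/s^2 factor is 9.80665.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import firwin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "EnergyFeatures",
    "StyleModel",
    "hamming_lowpass",
    "is_backstroke",
    "channel_energy",
    "extract_features",
    "train_model",
    "classify_lap",
    "rule_classify",
]

logger = logging.getLogger(__name__)

G_TO_MS2 = 9.80665
THREE_CLASS_LABELS = ("butterfly", "breaststroke", "front_crawl")
BACKSTROKE_AZ_THRESHOLD_G = -0.5

#: energy-filter settings: 48th-order (49-tap) Hamming FIR, 0.5 Hz cutoff
ENERGY_FILTER_ORDER = 48
ENERGY_CUTOFF_HZ = 0.5


@dataclass(frozen=True)
class EnergyFeatures:
    """Rounded mean-absolute-deviation energy of the three accel channels."""

    Ex: int
    Ey: int
    Ez: int

    def as_array(self) -> np.ndarray:
        return np.array([self.Ex, self.Ey, self.Ez], dtype=float)


# --------------------------------------------------------------------------
# filtering and features
# --------------------------------------------------------------------------


def hamming_lowpass(
    x: np.ndarray,
    fs: float,
    order: int = ENERGY_FILTER_ORDER,
    cutoff: float = ENERGY_CUTOFF_HZ,
) -> np.ndarray:
    """Zero-lag Hamming-windowed FIR low-pass of a uniformly sampled series.

    The linear-phase filter (``order`` + 1 taps) is applied by centered
    convolution on a reflect-padded copy, which compensates the order/2
    group delay and keeps the output the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2.0 * cutoff:
        raise ValueError("fs must exceed twice the cutoff")
    if len(x) <= order:
        raise ValueError(f"series length {len(x)} <= filter order {order}")
    taps = firwin(order + 1, cutoff, window="hamming", fs=fs)
    xp = np.pad(x, order, mode="reflect")
    return np.convolve(xp, taps, mode="same")[order:-order]


def is_backstroke(az: np.ndarray, threshold_g: float = BACKSTROKE_AZ_THRESHOLD_G) -> bool:
    """Backstroke rule: mean filtered vertical acceleration below -0.5 g.

    ``az`` must already be low-pass filtered.  A mean near 0 g (swimmer on
    the side) is logged as a degenerate orientation and classified prone.
    """
    az = np.asarray(az, dtype=float)
    if len(az) == 0:
        raise ValueError("empty lap")
    m = float(np.mean(az))
    if abs(m) < 0.25:
        logger.warning("mean az %.2f g is far from both +1 g and -1 g", m)
    return m < threshold_g


def _round_half_away(v: float) -> int:
    return int(np.sign(v) * np.floor(np.abs(v) + 0.5))


def channel_energy(x: np.ndarray) -> int:
    """Rounded mean absolute deviation of one (filtered, m/s^2) channel."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty span")
    return _round_half_away(float(np.mean(np.abs(x - np.mean(x)))))


def extract_features(
    ax: np.ndarray, ay: np.ndarray, az: np.ndarray, fs: float
) -> EnergyFeatures:
    """Per-lap energies of the three accelerometer channels (logged in g).

    Each channel is 0.5 Hz low-pass filtered, converted to m/s^2, and
    reduced to its rounded mean absolute deviation.
    """
    es = []
    for x in (ax, ay, az):
        filt = hamming_lowpass(np.asarray(x, dtype=float), fs) * G_TO_MS2
        es.append(channel_energy(filt))
    return EnergyFeatures(*es)


# --------------------------------------------------------------------------
# trainable three-class models
# --------------------------------------------------------------------------


class StyleModel:
    """A trained butterfly/breaststroke/front-crawl classifier.

    ``kind`` is ``"svm"`` (polynomial kernel, degree 1, C = 1e5) or
    ``"ann"`` (3-10-3 logistic MLP, SGD with momentum 0.5 and learning rate
    0.3).  Instances restored from JSON predict through a hand-written
    forward pass (one-vs-one kernel vote for the SVM, logistic forward pass
    for the MLP) that reproduces the fitted estimator's predictions.
    """

    def __init__(self, kind: str, params: dict, state: dict, estimator=None):
        if kind not in ("svm", "ann"):
            raise ValueError("kind must be 'svm' or 'ann'")
        self.kind = kind
        self.params = params
        self.state = state  # fitted weights / support vectors
        self._estimator = estimator  # fitted sklearn object, not serialized

    # -- prediction ----------------------------------------------------------

    def predict(self, features: EnergyFeatures | np.ndarray) -> str:
        if isinstance(features, EnergyFeatures):
            X = features.as_array()[None, :]
        else:
            X = np.atleast_2d(np.asarray(features, dtype=float))
        labels = self.state["classes"]
        if self.kind == "svm":
            idx = self._svm_predict(X)
        else:
            idx = self._ann_predict(X)
        out = [labels[i] for i in idx]
        return out[0] if len(out) == 1 else out

    def _svm_predict(self, X: np.ndarray) -> np.ndarray:
        sv = np.asarray(self.state["support_vectors"])
        dual = np.asarray(self.state["dual_coef"])
        intercept = np.asarray(self.state["intercept"])
        n_sv = np.asarray(self.state["n_support"])
        gamma = self.state["gamma"]
        coef0 = self.params["coef0"]
        degree = self.params["degree"]
        n_classes = len(self.state["classes"])
        K = (gamma * X @ sv.T + coef0) ** degree  # (n, n_sv)
        starts = np.concatenate(([0], np.cumsum(n_sv)))
        votes = np.zeros((len(X), n_classes), dtype=int)
        scores = np.zeros((len(X), n_classes))
        p = 0
        for i in range(n_classes):
            for j in range(i + 1, n_classes):
                ki = K[:, starts[i] : starts[i + 1]]
                kj = K[:, starts[j] : starts[j + 1]]
                dec = (
                    ki @ dual[j - 1, starts[i] : starts[i + 1]]
                    + kj @ dual[i, starts[j] : starts[j + 1]]
                    + intercept[p]
                )
                votes[:, i] += dec > 0
                votes[:, j] += dec <= 0
                scores[:, i] += dec
                scores[:, j] -= dec
                p += 1
        # vote winner; break ties by the aggregated decision value
        order = votes + 1e-9 * np.tanh(scores)
        return np.argmax(order, axis=1)

    def _ann_predict(self, X: np.ndarray) -> np.ndarray:
        W1, b1 = np.asarray(self.state["coefs"][0]), np.asarray(self.state["intercepts"][0])
        W2, b2 = np.asarray(self.state["coefs"][1]), np.asarray(self.state["intercepts"][1])
        h = 1.0 / (1.0 + np.exp(-(X @ W1 + b1)))
        z = h @ W2 + b2
        return np.argmax(z, axis=1)

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return o

        state = {
            k: [enc(x) for x in v] if isinstance(v, list) else enc(v)
            for k, v in self.state.items()
        }
        Path(path).write_text(
            json.dumps({"kind": self.kind, "params": self.params, "state": state})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StyleModel":
        raw = json.loads(Path(path).read_text())
        return cls(raw["kind"], raw["params"], raw["state"])


def train_model(
    features,
    labels,
    kind: str = "svm",
    seed: int = 0,
) -> StyleModel:
    """Fit a three-class style model on per-lap energy features.

    ``features`` is a sequence of :class:`EnergyFeatures` (or length-3
    arrays); every class in :data:`THREE_CLASS_LABELS` must be represented.
    The ANN uses one-hot targets internally (argmax decoding), logistic
    activations, and SGD with momentum; training stops on a loss plateau.
    Randomness (weight init, batch order) is fully seeded.
    """
    X = np.array(
        [f.as_array() if isinstance(f, EnergyFeatures) else np.asarray(f, float) for f in features]
    )
    y = np.asarray(labels)
    present = set(y)
    missing = set(THREE_CLASS_LABELS) - present
    if missing:
        raise ValueError(f"missing classes in training data: {sorted(missing)}")
    unknown = present - set(THREE_CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")

    if kind == "svm":
        params = {"C": 1e5, "degree": 1, "coef0": 0.0, "gamma": "scale"}
        clf = SVC(
            kernel="poly",
            C=params["C"],
            degree=params["degree"],
            coef0=params["coef0"],
            gamma=params["gamma"],
        )
        clf.fit(X, y)
        state = {
            "classes": [str(c) for c in clf.classes_],
            "support_vectors": clf.support_vectors_,
            "dual_coef": clf.dual_coef_,
            "intercept": clf.intercept_,
            "n_support": clf.n_support_,
            "gamma": float(clf._gamma),
        }
        return StyleModel("svm", params, state, estimator=clf)
    if kind == "ann":
        params = {
            "hidden": 10,
            "momentum": 0.5,
            "learning_rate": 0.3,
            "max_iter": 3000,
        }
        clf = MLPClassifier(
            hidden_layer_sizes=(params["hidden"],),
            activation="logistic",
            solver="sgd",
            learning_rate_init=params["learning_rate"],
            momentum=params["momentum"],
            nesterovs_momentum=False,
            max_iter=params["max_iter"],
            tol=1e-6,
            n_iter_no_change=25,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X, y)
        state = {
            "classes": [str(c) for c in clf.classes_],
            "coefs": [c for c in clf.coefs_],
            "intercepts": [b for b in clf.intercepts_],
        }
        return StyleModel("ann", params, state, estimator=clf)
    raise ValueError("kind must be 'svm' or 'ann'")


# --------------------------------------------------------------------------
# lap classification
# --------------------------------------------------------------------------


def rule_classify(features: EnergyFeatures) -> str:
    """Model-free fallback for the three prone styles.

    Front crawl when the y-channel dominates; otherwise butterfly when the
    z-energy clears a small threshold, else breaststroke.  An ad-hoc
    heuristic for running the pipeline without a trained model; the trained
    SVM/ANN are the evaluated classifiers.
    """
    if features.Ey > features.Ex and features.Ey > features.Ez:
        return "front_crawl"
    return "butterfly" if features.Ez >= 4 else "breaststroke"


def classify_lap(
    ax: np.ndarray,
    ay: np.ndarray,
    az: np.ndarray,
    fs: float,
    model: StyleModel | None = None,
) -> str:
    """Classify one lap: backstroke short-circuit, then the 3-class model.

    The backstroke z-axis rule runs first on the filtered vertical channel;
    only non-backstroke laps reach the trained model (or the rule fallback
    when ``model`` is None), so no lap can receive both routes.
    """
    az_f = hamming_lowpass(np.asarray(az, dtype=float), fs)
    if is_backstroke(az_f):
        return "backstroke"
    feats = extract_features(ax, ay, az, fs)
    if model is None:
        return rule_classify(feats)
    return model.predict(feats)
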