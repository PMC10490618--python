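"""Deep neural decision forest classifier.

A fully connected embedding network maps the feature vector to a compact
representation (128 dimensions by default); an ensemble of soft decision
trees consumes the embedding.  Each internal tree node routes a sample left
with probability sigmoid(w . z + b); each leaf carries a class distribution
parameterized through a softmax.  The prediction is the routing-weighted
average of leaf distributions, averaged over trees, and the whole model is
trained jointly by minimizing the negative log-likelihood with mini-batch
Adam — joint optimization was chosen over alternating leaf/route updates
for simplicity; both reach the fixtures' accuracy.

Implemented directly in numpy with hand-derived gradients; the parameter
count at default sizes is small enough that a CPU epoch over a few
thousand vectors takes a fraction of a second.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.utils import check_random_state
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_X_y

__all__ = ["DNDFClassifier", "build_dndf", "evaluate"]

logger = logging.getLogger(__name__)

_CLIP = 1e-7


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class DNDFClassifier(ClassifierMixin, BaseEstimator):
    """Soft decision forest on top of a learned embedding.

    Parameters
    ----------
    hidden_layers : tuple of int
        Widths of the rectifier layers before the linear embedding output.
    embed_dim : int
        Embedding width fed to the trees (128 by default).
    n_trees, tree_depth : int
        Forest shape: ``2**tree_depth`` leaves per tree.
    epochs, batch_size, learning_rate, l2 : training schedule (Adam).
    standardize : bool
        Standardize features with training-split mean/std before the network.
    class_weight : "balanced" or None
        Inverse-frequency loss weights for imbalanced labels.
    random_state : int or None
        Seeds initialization and batch shuffling; same seed, same model.

    Attributes (after fit)
    ----------------------
    classes_, loss_trace_, n_features_in_ and the parameter arrays in
    ``params_``.
    """

    def __init__(self, hidden_layers=(512, 256), embed_dim=128, n_trees=10,
                 tree_depth=6, epochs=50, batch_size=64, learning_rate=1e-3,
                 l2=1e-5, standardize=True, class_weight=None,
                 random_state=None, verbose=0):
        self.hidden_layers = hidden_layers
        self.embed_dim = embed_dim
        self.n_trees = n_trees
        self.tree_depth = tree_depth
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.l2 = l2
        self.standardize = standardize
        self.class_weight = class_weight
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------

    def _tree_paths(self):
        """Leaf-to-node incidence masks for one tree (all trees share shape).

        ``left[leaf, node]`` is 1 when ``node`` lies on the root path of
        ``leaf`` and the path goes left there; similarly ``right``.
        """
        depth = self.tree_depth
        n_leaves = 1 << depth
        n_nodes = n_leaves - 1
        left = np.zeros((n_leaves, n_nodes))
        right = np.zeros((n_leaves, n_nodes))
        for leaf in range(n_leaves):
            node = 0
            for level in range(depth):
                go_left = not (leaf >> (depth - 1 - level)) & 1
                (left if go_left else right)[leaf, node] = 1.0
                node = 2 * node + (1 if go_left else 2)
        return left, right

    def initialize(self, n_features: int, n_classes: int) -> "DNDFClassifier":
        """Seeded parameter initialization; untrained leaves are uniform."""
        if min(self.embed_dim, self.n_trees, self.tree_depth,
               self.epochs, self.batch_size) <= 0:
            raise ValueError("all architecture sizes must be positive")
        rng = check_random_state(self.random_state)
        widths = [n_features, *self.hidden_layers, self.embed_dim]
        layers = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            layers.append([W, np.zeros(fan_out)])
        n_nodes = (1 << self.tree_depth) - 1
        n_leaves = 1 << self.tree_depth
        Wr = rng.normal(0.0, 0.1, size=(self.n_trees * n_nodes, self.embed_dim))
        br = np.zeros(self.n_trees * n_nodes)
        leaf_logits = np.zeros((self.n_trees, n_leaves, n_classes))
        self.params_ = {"layers": layers, "Wr": Wr, "br": br,
                        "leaf_logits": leaf_logits}
        self._left, self._right = self._tree_paths()
        self._n_classes = n_classes
        return self

    # ------------------------------------------------------------------
    # forward / backward
    # ------------------------------------------------------------------

    def _forward(self, X):
        layers = self.params_["layers"]
        acts = [X]
        h = X
        for W, b in layers[:-1]:
            h = _relu(h @ W + b)
            acts.append(h)
        W, b = layers[-1]
        z = h @ W + b                                # (B, embed)
        a = z @ self.params_["Wr"].T + self.params_["br"]
        a = a.reshape(len(X), self.n_trees, -1)      # (B, T, nodes)
        d = np.clip(_sigmoid(a), _CLIP, 1.0 - _CLIP)
        log_mu = np.log(d) @ self._left.T + np.log(1.0 - d) @ self._right.T
        mu = np.exp(log_mu)                          # (B, T, leaves)
        pi = _softmax(self.params_["leaf_logits"], axis=-1)  # (T, L, C)
        probs = np.einsum("btl,tlc->bc", mu, pi) / self.n_trees
        return {"acts": acts, "z": z, "d": d, "mu": mu, "pi": pi,
                "probs": probs}

    def _backward(self, X, y_idx, fwd, sample_w):
        B = len(X)
        probs, mu, pi, d = fwd["probs"], fwd["mu"], fwd["pi"], fwd["d"]
        grads = {}
        p_y = np.clip(probs[np.arange(B), y_idx], 1e-12, None)
        g_probs = np.zeros_like(probs)
        g_probs[np.arange(B), y_idx] = -sample_w / p_y          # dL/dP
        g_S = g_probs / self.n_trees                            # per-tree share
        g_mu = np.einsum("bc,tlc->btl", g_S, pi)
        g_pi = np.einsum("bc,btl->tlc", g_S, mu)
        # softmax over classes within each leaf
        grads["leaf_logits"] = pi * (g_pi - (g_pi * pi).sum(-1, keepdims=True))
        g_leafmu = g_mu * mu
        gl = g_leafmu @ self._left                              # (B, T, nodes)
        gr = g_leafmu @ self._right
        g_a = gl * (1.0 - d) - gr * d
        g_a = g_a.reshape(B, -1)
        grads["Wr"] = g_a.T @ fwd["z"]
        grads["br"] = g_a.sum(axis=0)
        g_z = g_a @ self.params_["Wr"]
        layers = self.params_["layers"]
        grads["layers"] = [None] * len(layers)
        g_h = g_z
        for li in range(len(layers) - 1, -1, -1):
            W, _ = layers[li]
            h_in = fwd["acts"][li]
            grads["layers"][li] = [h_in.T @ g_h, g_h.sum(axis=0)]
            if li > 0:
                g_h = (g_h @ W.T) * (fwd["acts"][li] > 0)
        return grads

    # ------------------------------------------------------------------
    # sklearn API
    # ------------------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        y_idx = np.searchsorted(self.classes_, y)
        self.n_features_in_ = X.shape[1]
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            self.scale_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
            X = (X - self.mean_) / self.scale_
        self.initialize(X.shape[1], len(self.classes_))
        rng = check_random_state(None if self.random_state is None
                                 else self.random_state + 1)
        if self.class_weight == "balanced":
            counts = np.bincount(y_idx, minlength=len(self.classes_))
            cw = len(y_idx) / (len(self.classes_) * np.maximum(counts, 1))
        else:
            cw = np.ones(len(self.classes_))
        weights = cw[y_idx]

        flat, unflat = self._flatten()
        m = np.zeros_like(flat)
        v = np.zeros_like(flat)
        step = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        n = len(X)
        self.loss_trace_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb, wb = X[idx], y_idx[idx], weights[idx]
                fwd = self._forward(xb)
                p_y = np.clip(fwd["probs"][np.arange(len(idx)), yb], 1e-12, None)
                loss = -np.mean(wb * np.log(p_y))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"NaN/Inf loss at epoch {epoch}: last batch sizes "
                        f"{xb.shape}, lr={self.learning_rate}")
                epoch_loss += loss * len(idx)
                grads = self._backward(xb, yb, fwd, wb / len(idx))
                g = self._flatten_grads(grads)
                if self.l2:
                    g += self.l2 * flat
                step += 1
                m = beta1 * m + (1 - beta1) * g
                v = beta2 * v + (1 - beta2) * g * g
                mh = m / (1 - beta1 ** step)
                vh = v / (1 - beta2 ** step)
                flat -= self.learning_rate * mh / (np.sqrt(vh) + eps)
                unflat(flat)
            self.loss_trace_.append(epoch_loss / n)
            if self.verbose:
                logger.info("epoch %d loss %.5f", epoch, self.loss_trace_[-1])
        return self

    def _flatten(self):
        """View parameters as one vector plus a writer putting it back."""
        parts = []
        for W, b in self.params_["layers"]:
            parts += [W.ravel(), b.ravel()]
        parts += [self.params_["Wr"].ravel(), self.params_["br"].ravel(),
                  self.params_["leaf_logits"].ravel()]
        flat = np.concatenate(parts)

        def unflat(vec):
            pos = 0
            for pair in self.params_["layers"]:
                for j, arr in enumerate(pair):
                    pair[j] = vec[pos:pos + arr.size].reshape(arr.shape)
                    pos += arr.size
            for key in ("Wr", "br", "leaf_logits"):
                arr = self.params_[key]
                self.params_[key] = vec[pos:pos + arr.size].reshape(arr.shape)
                pos += arr.size
        return flat, unflat

    def _flatten_grads(self, grads):
        parts = []
        for W, b in grads["layers"]:
            parts += [W.ravel(), b.ravel()]
        parts += [grads["Wr"].ravel(), grads["br"].ravel(),
                  grads["leaf_logits"].ravel()]
        return np.concatenate(parts)

    def predict_proba(self, X):
        if not hasattr(self, "params_"):
            raise NotFittedError("DNDFClassifier is not fitted")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, "
                             f"got {X.shape[1]}")
        if self.standardize and hasattr(self, "mean_"):
            X = (X - self.mean_) / self.scale_
        return self._forward(X)["probs"]

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def leaf_distributions(self) -> np.ndarray:
        """(n_trees, n_leaves, n_classes) softmax leaf distributions."""
        if not hasattr(self, "params_"):
            raise NotFittedError("model not initialized")
        return _softmax(self.params_["leaf_logits"], axis=-1)

    def routing_probabilities(self, X) -> np.ndarray:
        """(n, n_trees, n_leaves) probability of reaching each leaf."""
        if not hasattr(self, "params_"):
            raise NotFittedError("model not initialized")
        X = check_array(X, dtype=float)
        if self.standardize and hasattr(self, "mean_"):
            X = (X - self.mean_) / self.scale_
        return self._forward(X)["mu"]

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------

    def save(self, path) -> None:
        arrays = {"Wr": self.params_["Wr"], "br": self.params_["br"],
                  "leaf_logits": self.params_["leaf_logits"],
                  "classes": self.classes_}
        for i, (W, b) in enumerate(self.params_["layers"]):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        if self.standardize and hasattr(self, "mean_"):
            arrays["mean"] = self.mean_
            arrays["scale"] = self.scale_
        arrays["config"] = np.array([repr(self.get_params())], dtype=object)
        np.savez(path, **arrays, allow_pickle=True)

    @classmethod
    def load(cls, path) -> "DNDFClassifier":
        import ast
        data = np.load(path, allow_pickle=True)
        model = cls(**ast.literal_eval(str(data["config"][0])))
        n_layers = sum(1 for k in data.files if k.startswith("W") and k != "Wr")
        model.params_ = {
            "layers": [[data[f"W{i}"], data[f"b{i}"]] for i in range(n_layers)],
            "Wr": data["Wr"], "br": data["br"],
            "leaf_logits": data["leaf_logits"],
        }
        model.classes_ = data["classes"]
        model._n_classes = len(model.classes_)
        model._left, model._right = model._tree_paths()
        model.n_features_in_ = model.params_["layers"][0][0].shape[0]
        if "mean" in data.files:
            model.mean_ = data["mean"]
            model.scale_ = data["scale"]
        return model


def build_dndf(input_dim: int, n_classes: int, **kwargs) -> DNDFClassifier:
    """Construct and seed-initialize an untrained forest."""
    model = DNDFClassifier(**kwargs)
    return model.initialize(input_dim, n_classes)


def evaluate(model, X, y) -> dict:
    """Confusion matrix and standard per-class metrics for a fitted model.

    Returns raw and row-normalized confusion matrices (rows = true class),
    per-class precision/recall/F1, accuracy, and the macro averages.
    """
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

    y = np.asarray(y)
    unknown = set(np.unique(y)) - set(model.classes_)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} absent from training classes")
    y_pred = model.predict(X)
    labels = list(model.classes_)
    cm = confusion_matrix(y, y_pred, labels=labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm_norm = cm / cm.sum(axis=1, keepdims=True)
    cm_norm = np.nan_to_num(cm_norm)
    prec, rec, f1, support = precision_recall_fscore_support(
        y, y_pred, labels=labels, zero_division=0)
    return {
        "labels": labels,
        "confusion": cm,
        "confusion_normalized": cm_norm,
        "precision": prec,
        "recall": rec,
        "f1": f1,
        "support": support,
        "accuracy": float((y_pred == y).mean()),
        "macro_precision": float(prec.mean()),
        "macro_recall": float(rec.mean()),
        "macro_f1": float(f1.mean()),
    }
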