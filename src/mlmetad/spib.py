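"""State Predictive Information Bottleneck (SPIB) reaction coordinates.

SPIB learns a low-dimensional reaction coordinate (RC) as a *linear*
combination of collective variables whose compressed representation
predicts the metastable-state label a lag time into the future.  The
variational model is

    encoder   z = W x~ + b + eps * exp(logvar / 2)      (x~ z-scored CVs)
    decoder   p(y_{t+lag} | z_t) = softmax(MLP(z_t))

trained on the objective  CE(y_{t+lag}, decoder(z_t)) + beta * KL(q || N(0, I)),
where beta is the information-bottleneck trade-off.  Training alternates
with iterative label refinement: each frame is relabeled with the state the
decoder predicts for it, empty states are dropped, and training repeats
until fewer than a convergence fraction of frames change label.

Because the encoder mean map is linear in the z-scored CVs, a trained model
transfers to any system exposing the same CV names, and the RC compiles to
an exact linear bias variable for well-tempered metadynamics.

The estimator follows scikit-learn conventions (``fit`` / ``transform`` /
``predict``, ``get_params``, trailing-underscore fitted attributes); the
tiny network is trained with hand-written backpropagation and Adam.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .metad import BiasVariable
from .trajectory import Trajectory

__all__ = [
    "SPIB", "SPIBConfig", "StateLabels", "initial_labels", "train_spib",
    "project_rc", "rc_statistics", "RCStatistics", "save_model", "load_model",
]


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

@dataclass
class StateLabels:
    """Per-frame discrete state labels.

    ``origin`` records whether the labels come from cutoff rules
    (``rule-initialized``) or from SPIB refinement (``refined``).
    """

    labels: np.ndarray
    vocabulary: list[int]
    origin: str = "rule-initialized"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def degenerate(self) -> bool:
        """True when fewer than two states are populated."""
        return len(self.vocabulary) < 2


def initial_labels(traj: Trajectory, rules: list[tuple[str, str, float]]) -> StateLabels:
    """Rule-initialized labels from cutoff predicates on named CVs.

    Each rule is ``(cv_name, op, cutoff)`` with ``op`` in ``{"<", ">"}``;
    a frame's label is the integer whose bits are the predicate outcomes,
    so one rule partitions frames into states {0, 1} exactly by predicate.
    Every frame is assigned; a rule naming a missing CV raises ``KeyError``.
    """
    if not rules:
        raise ValueError("at least one labeling rule is required")
    n = traj.n_frames
    labels = np.zeros(n, dtype=int)
    for bit, (cv_name, op, cutoff) in enumerate(rules):
        col = traj.cv(cv_name)
        if op == "<":
            hit = col < cutoff
        elif op == ">":
            hit = col > cutoff
        else:
            raise ValueError(f"unknown rule operator {op!r}; use '<' or '>'")
        labels |= hit.astype(int) << bit
    vocab = sorted(int(v) for v in np.unique(labels))
    return StateLabels(labels=labels, vocabulary=vocab)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SPIBConfig:
    """SPIB hyperparameters.

    lag : prediction horizon in frames (>= 1).
    latent_dim : RC dimensionality (default 2).
    ib_weight : KL trade-off coefficient beta (default 1e-2).
    hidden_units : decoder hidden-layer width.
    learning_rate, epochs, batch_size : Adam settings.
    refine_every : epochs between label-refinement passes.
    refine_tol : convergence fraction of changed frames (in (0, 1)).
    max_refine_rounds : refinement budget.
    seed : RNG seed; training is deterministic given the seed.
    """

    lag: int = 10
    latent_dim: int = 2
    ib_weight: float = 1e-2
    hidden_units: int = 16
    learning_rate: float = 5e-3
    epochs: int = 60
    batch_size: int = 512
    refine_every: int = 5
    refine_tol: float = 0.02
    max_refine_rounds: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not (0.0 < self.refine_tol < 1.0):
            raise ValueError("refine_tol must be in (0, 1)")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(logits):
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


class SPIB(BaseEstimator, TransformerMixin):
    """State Predictive Information Bottleneck estimator.

    Parameters mirror :class:`SPIBConfig`.  ``fit`` expects the CV matrix
    ``X`` (frames x CVs) and per-frame integer labels ``y``; multiple
    trajectories are passed as lists (lag pairs never cross trajectory
    boundaries).  ``transform`` projects CVs onto the learned RC (encoder
    mean map, no sampling noise); ``predict`` returns the decoder's state.
    """

    def __init__(self, lag: int = 10, latent_dim: int = 2,
                 ib_weight: float = 1e-2, hidden_units: int = 16,
                 learning_rate: float = 5e-3, epochs: int = 60,
                 batch_size: int = 512, refine_every: int = 5,
                 refine_tol: float = 0.02, max_refine_rounds: int = 20,
                 random_state: int = 0):
        self.lag = lag
        self.latent_dim = latent_dim
        self.ib_weight = ib_weight
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.refine_every = refine_every
        self.refine_tol = refine_tol
        self.max_refine_rounds = max_refine_rounds
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y, cv_names: list[str] | None = None,
            norm_mask: np.ndarray | None = None):
        """Train encoder/decoder with iterative label refinement.

        Parameters
        ----------
        X : array (n, d) or list of arrays
        y : int array (n,) or list of arrays, aligned with X
        cv_names : optional names stored for transfer (exact-match applies).
        norm_mask : optional boolean mask (or list of masks) selecting the
            frames whose statistics define the stored z-scoring constants
            (conventionally the bound state); all frames when omitted.
        """
        X_list = [np.asarray(x, dtype=float) for x in (X if isinstance(X, list) else [X])]
        y_list = [np.asarray(v, dtype=int) for v in (y if isinstance(y, list) else [y])]
        if len(X_list) != len(y_list):
            raise ValueError("X and y must contain the same number of trajectories")
        for xa, ya in zip(X_list, y_list):
            if xa.shape[0] != ya.shape[0]:
                raise ValueError("each trajectory needs one label per frame")
        lag = int(self.lag)
        if any(xa.shape[0] <= lag for xa in X_list):
            raise ValueError("lag must be shorter than the shortest trajectory")
        classes = np.unique(np.concatenate(y_list))
        if classes.size < 2:
            raise ValueError("at least two label classes are required to train SPIB")
        d = X_list[0].shape[1]
        if any(xa.shape[1] != d for xa in X_list):
            raise ValueError("all trajectories must share the CV roster")
        if cv_names is not None and len(cv_names) != d:
            raise ValueError("cv_names length must match the CV count")

        Xa = np.concatenate(X_list)
        if norm_mask is not None:
            m_list = [np.asarray(m, bool) for m in (norm_mask if isinstance(norm_mask, list) else [norm_mask])]
            mask = np.concatenate(m_list)
            if mask.shape[0] != Xa.shape[0] or not mask.any():
                raise ValueError("norm_mask must be a nonempty per-frame mask")
        else:
            mask = np.ones(Xa.shape[0], dtype=bool)
        mu = Xa[mask].mean(axis=0)
        sd = Xa[mask].std(axis=0)
        sd = np.where(sd > 1e-12, sd, 1.0)  # constant CVs carry no signal
        self.input_mean_ = mu
        self.input_std_ = sd
        self.cv_names_ = list(cv_names) if cv_names is not None else None

        Z_list = [(xa - mu) / sd for xa in X_list]
        # remap labels onto 0..C-1
        remap = {int(c): i for i, c in enumerate(classes)}
        y_list = [np.vectorize(remap.get)(ya) for ya in y_list]
        C = classes.size

        rng = np.random.default_rng(self.random_state)
        k, H = int(self.latent_dim), int(self.hidden_units)
        params = {
            "W": rng.normal(0.0, 0.1, size=(k, d)),
            "b": np.zeros(k),
            "logvar": np.full(k, -2.0),
            "U1": rng.normal(0.0, np.sqrt(2.0 / k), size=(k, H)),
            "c1": np.zeros(H),
            "U2": rng.normal(0.0, np.sqrt(2.0 / H), size=(H, C)),
            "c2": np.zeros(C),
        }
        adam_m = {n: np.zeros_like(v) for n, v in params.items()}
        adam_v = {n: np.zeros_like(v) for n, v in params.items()}
        adam_t = 0

        # lag-pair indices into the concatenated arrays
        offsets = np.cumsum([0] + [z.shape[0] for z in Z_list[:-1]])
        in_idx = np.concatenate([off + np.arange(z.shape[0] - lag)
                                 for off, z in zip(offsets, Z_list)])
        Zc = np.concatenate(Z_list)
        yc = np.concatenate(y_list)

        beta = float(self.ib_weight)
        lr = float(self.learning_rate)
        n_pairs = in_idx.size
        bs = min(int(self.batch_size), n_pairs)

        def epoch(targets):
            nonlocal adam_t
            order = rng.permutation(n_pairs)
            for start in range(0, n_pairs, bs):
                sel = in_idx[order[start:start + bs]]
                xb = Zc[sel]
                yb = targets[sel + lag]
                B = xb.shape[0]
                mean = xb @ params["W"].T + params["b"]
                std = np.exp(0.5 * params["logvar"])
                eps = rng.standard_normal(mean.shape)
                z = mean + eps * std
                h_pre = z @ params["U1"] + params["c1"]
                h = _relu(h_pre)
                logits = h @ params["U2"] + params["c2"]
                p = _softmax(logits)
                dlogits = p.copy()
                dlogits[np.arange(B), yb] -= 1.0
                dlogits /= B
                g = {}
                g["U2"] = h.T @ dlogits
                g["c2"] = dlogits.sum(axis=0)
                dh = dlogits @ params["U2"].T
                dh[h_pre <= 0.0] = 0.0
                g["U1"] = z.T @ dh
                g["c1"] = dh.sum(axis=0)
                dz = dh @ params["U1"].T
                dmean = dz + beta * mean / B
                g["W"] = dmean.T @ xb
                g["b"] = dmean.sum(axis=0)
                g["logvar"] = ((dz * eps * std).sum(axis=0) * 0.5
                               + 0.5 * beta * (np.exp(params["logvar"]) - 1.0))
                adam_t += 1
                for name in params:
                    adam_m[name] = 0.9 * adam_m[name] + 0.1 * g[name]
                    adam_v[name] = 0.999 * adam_v[name] + 0.001 * g[name] ** 2
                    mhat = adam_m[name] / (1.0 - 0.9 ** adam_t)
                    vhat = adam_v[name] / (1.0 - 0.999 ** adam_t)
                    params[name] -= lr * mhat / (np.sqrt(vhat) + 1e-8)

        def predict_all():
            mean = Zc @ params["W"].T + params["b"]
            h = _relu(mean @ params["U1"] + params["c1"])
            logits = h @ params["U2"] + params["c2"]
            return np.argmax(logits, axis=1)

        targets = yc.copy()
        self.converged_ = False
        rounds = 0
        for rounds in range(1, int(self.max_refine_rounds) + 1):
            for _ in range(int(self.refine_every)):
                epoch(targets)
            pred = predict_all()
            changed = float(np.mean(pred != targets))
            occupied = np.unique(pred)
            if occupied.size < 2:
                # collapse: keep previous labels, stop refining
                warnings.warn("SPIB refinement collapsed to a single state; "
                              "stopping refinement", RuntimeWarning)
                break
            targets = pred
            if changed < float(self.refine_tol):
                self.converged_ = True
                break
        total = int(self.refine_every) * rounds
        for _ in range(max(0, int(self.epochs) - total)):
            epoch(targets)
        if not self.converged_:
            warnings.warn("SPIB label refinement did not converge within "
                          f"{self.max_refine_rounds} rounds", RuntimeWarning)

        self.encoder_weights_ = params["W"]
        self.encoder_bias_ = params["b"]
        self.noise_logvar_ = params["logvar"]
        self.decoder_params_ = {n: params[n] for n in ("U1", "c1", "U2", "c2")}
        self.classes_ = classes
        final = predict_all()
        self.labels_ = StateLabels(labels=final,
                                   vocabulary=sorted(int(v) for v in np.unique(final)),
                                   origin="refined")
        self.n_states_ = len(self.labels_.vocabulary)
        self.n_refine_rounds_ = rounds
        imp = np.linalg.norm(self.encoder_weights_, axis=0)
        nrm = np.linalg.norm(imp)
        self.weight_importance_ = imp / (nrm if nrm > 0 else 1.0)
        return self

    # -- application ------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "encoder_weights_"):
            raise RuntimeError("SPIB model is not fitted")

    def transform(self, X) -> np.ndarray:
        """Deterministic RC projection: z-score, then the encoder mean map."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_mean_.size:
            raise ValueError(
                f"expected {self.input_mean_.size} CVs, got {X.shape[1]}")
        Z = (X - self.input_mean_) / self.input_std_
        return Z @ self.encoder_weights_.T + self.encoder_bias_

    def predict(self, X) -> np.ndarray:
        """Most probable future state for each frame."""
        rc = self.transform(X)
        dp = self.decoder_params_
        h = _relu(rc @ dp["U1"] + dp["c1"])
        logits = h @ dp["U2"] + dp["c2"]
        return self.classes_[np.argmax(logits, axis=1)]

    def bias_variables(self, cv_defs, dim: int) -> list[BiasVariable]:
        """Compile each RC into a linear :class:`BiasVariable` over positions.

        ``cv_defs`` must be the model's CV roster (exact name match) with
        linear extractors; the chain rule through the z-scoring and the
        encoder mean map is folded into one weight vector per RC.
        """
        self._check_fitted()
        if self.cv_names_ is not None:
            names = [d.name for d in cv_defs]
            if names != self.cv_names_:
                raise ValueError(
                    f"CV roster {names} does not match model inputs {self.cv_names_}")
        cv_w = np.array([d.linear_weights(dim) for d in cv_defs])  # (d, dim)
        out = []
        for kk in range(self.encoder_weights_.shape[0]):
            wk = (self.encoder_weights_[kk] / self.input_std_) @ cv_w
            offset = (self.encoder_bias_[kk]
                      - np.dot(self.encoder_weights_[kk],
                               self.input_mean_ / self.input_std_))
            out.append(BiasVariable(name=f"rc{kk + 1}", weights=wk,
                                    mean=-offset, std=1.0))
        return out


# ---------------------------------------------------------------------------
# functional wrappers (spec-shaped surface)
# ---------------------------------------------------------------------------

def train_spib(trajs: list[Trajectory], labels: StateLabels | list[StateLabels],
               config: SPIBConfig, norm_mask=None) -> SPIB:
    """Train SPIB on one or more trajectories with per-frame labels."""
    trajs = trajs if isinstance(trajs, list) else [trajs]
    labels_list = labels if isinstance(labels, list) else [labels]
    X = [t.cv_matrix for t in trajs]
    y = [l.labels for l in labels_list]
    names = trajs[0].cv_names or None
    model = SPIB(lag=config.lag, latent_dim=config.latent_dim,
                 ib_weight=config.ib_weight, hidden_units=config.hidden_units,
                 learning_rate=config.learning_rate, epochs=config.epochs,
                 batch_size=config.batch_size, refine_every=config.refine_every,
                 refine_tol=config.refine_tol,
                 max_refine_rounds=config.max_refine_rounds,
                 random_state=config.seed)
    model.fit(X, y, cv_names=names, norm_mask=norm_mask)
    model.config_digest_ = config.digest()
    return model


def project_rc(model: SPIB, traj: Trajectory) -> np.ndarray:
    """RC series for a trajectory, matching the model's CV names exactly."""
    model._check_fitted()
    if model.cv_names_ is not None:
        missing = [n for n in model.cv_names_ if n not in traj.cv_names]
        if missing:
            raise KeyError(f"trajectory lacks model input CVs {missing}")
        X = np.column_stack([traj.cv(n) for n in model.cv_names_])
    else:
        X = traj.cv_matrix
    return model.transform(X)


@dataclass
class RCStatistics:
    """Bound-state RC statistics and the derived WT-MetaD hill width."""

    mean: np.ndarray
    std: np.ndarray  # population std within the bound state
    sigma: np.ndarray  # 0.25 * std, the round-2 hill-width rule
    degenerate: bool = False  # any RC constant in the bound state


def rc_statistics(rc: np.ndarray, bound_mask: np.ndarray,
                  fraction: float = 0.25) -> RCStatistics:
    """Per-RC mean/std within the bound state and sigma = fraction * std."""
    rc = np.asarray(rc, dtype=float)
    if rc.ndim == 1:
        rc = rc[:, None]
    mask = np.asarray(bound_mask, dtype=bool)
    if mask.shape[0] != rc.shape[0]:
        raise ValueError("bound mask length must equal the RC series length")
    if not mask.any():
        raise ValueError("bound mask selects no frames")
    sub = rc[mask]
    mean = sub.mean(axis=0)
    std = sub.std(axis=0)  # population (ddof=0)
    sigma = fraction * std
    return RCStatistics(mean=mean, std=std, sigma=sigma,
                        degenerate=bool(np.any(std <= 0)))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: SPIB, path) -> None:
    """Serialize a fitted model as self-describing JSON."""
    model._check_fitted()
    doc = {
        "format": "mlmetad-spib-1",
        "params": model.get_params(),
        "cv_names": model.cv_names_,
        "input_mean": model.input_mean_.tolist(),
        "input_std": model.input_std_.tolist(),
        "encoder_weights": model.encoder_weights_.tolist(),
        "encoder_bias": model.encoder_bias_.tolist(),
        "noise_logvar": model.noise_logvar_.tolist(),
        "decoder": {k: v.tolist() for k, v in model.decoder_params_.items()},
        "classes": model.classes_.tolist(),
        "labels": model.labels_.labels.tolist(),
        "converged": bool(model.converged_),
        "config_digest": getattr(model, "config_digest_", None),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> SPIB:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "mlmetad-spib-1":
        raise ValueError("not an mlmetad SPIB model file")
    model = SPIB(**doc["params"])
    model.cv_names_ = doc["cv_names"]
    model.input_mean_ = np.array(doc["input_mean"])
    model.input_std_ = np.array(doc["input_std"])
    model.encoder_weights_ = np.array(doc["encoder_weights"])
    model.encoder_bias_ = np.array(doc["encoder_bias"])
    model.noise_logvar_ = np.array(doc["noise_logvar"])
    model.decoder_params_ = {k: np.array(v) for k, v in doc["decoder"].items()}
    model.classes_ = np.array(doc["classes"])
    lab = np.array(doc["labels"], dtype=int)
    model.labels_ = StateLabels(labels=lab,
                                vocabulary=sorted(int(v) for v in np.unique(lab)),
                                origin="refined")
    model.n_states_ = len(model.labels_.vocabulary)
    model.converged_ = doc["converged"]
    model.config_digest_ = doc.get("config_digest")
    imp = np.linalg.norm(model.encoder_weights_, axis=0)
    nrm = np.linalg.norm(imp)
    model.weight_importance_ = imp / (nrm if nrm > 0 else 1.0)
    return model
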