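"""Continuous and discrete neural decoders.

The operative decoder is a ridge-regularized linear filter mapping lagged
binned neural features (200-ms spike counts or band powers) to a 1-D
cursor/hand position.  A position-velocity Kalman filter and a
pooled-covariance LDA classifier are provided behind the same fit/predict
surface, plus thin factories for the standard discrete classifiers
(decision tree, SVM, k-NN).

Calibration follows the two-stage cursor protocol: an open-loop block in
which the user tracks a slowly moving target trains a preliminary filter;
a second block, in which the preliminary filter's prediction cursor is
displayed alongside the target, retrains the filter on closed-loop data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .synth import SyntheticParticipant, make_cursor_training_block

DEFAULT_LAGS = (0, 1, 2, 3, 4)  # bins of 200 ms -> 0-800 ms of history


def assemble_feature_matrix(
    features: np.ndarray,
    lags: Sequence[int] = DEFAULT_LAGS,
    target: Optional[np.ndarray] = None,
):
    """Build a lagged design matrix from a channels-by-bins feature array.

    Row t (for t >= max lag) concatenates the feature vectors at bins
    t - lag for each lag, channel-major within each lag.  Rows with
    incomplete history are dropped, and the target (if given) is aligned
    accordingly.

    Returns
    -------
    X : ndarray, shape (n_bins - max_lag, n_channels * n_lags)
    y : ndarray or None, aligned target
    offset : int, index of the first retained bin
    """
    lags = tuple(int(l) for l in lags)
    if len(lags) == 0:
        raise ValueError("lags must be non-empty")
    if min(lags) < 0:
        raise ValueError("lags must be non-negative")
    F = np.atleast_2d(np.asarray(features, dtype=float))
    n_ch, n_bins = F.shape
    offset = max(lags)
    if n_bins <= offset:
        raise ValueError("not enough bins to cover the maximum lag")
    rows = n_bins - offset
    X = np.empty((rows, n_ch * len(lags)))
    for j, lag in enumerate(lags):
        X[:, j * n_ch : (j + 1) * n_ch] = F[:, offset - lag : n_bins - lag].T
    y = None
    if target is not None:
        y = np.asarray(target, dtype=float)[offset:]
    return X, y, offset


@dataclass
class LinearFilterModel:
    """Fitted linear filter: standardized ridge least squares.

    ``weights`` are in original feature units (one per channel x lag
    column of the design matrix); the stored normalization (per-feature
    mean and scale from training) is applied before prediction so the
    ridge penalty acts on standardized features.
    """

    weights: np.ndarray
    intercept: float
    lags: tuple
    n_channels: int
    ridge: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    train_r2: float = float("nan")
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "lags": list(self.lags),
                "n_channels": self.n_channels,
                "ridge": self.ridge,
                "feature_mean": self.feature_mean.tolist(),
                "feature_scale": self.feature_scale.tolist(),
                "train_r2": self.train_r2,
                "meta": self.meta,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearFilterModel":
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"]),
            intercept=float(d["intercept"]),
            lags=tuple(d["lags"]),
            n_channels=int(d["n_channels"]),
            ridge=float(d["ridge"]),
            feature_mean=np.asarray(d["feature_mean"]),
            feature_scale=np.asarray(d["feature_scale"]),
            train_r2=float(d["train_r2"]),
            meta=d.get("meta", {}),
        )


def fit_linear_filter(
    design: np.ndarray,
    target: np.ndarray,
    ridge: float = 1e-3,
    lags: Sequence[int] = DEFAULT_LAGS,
    n_channels: Optional[int] = None,
) -> LinearFilterModel:
    """Ridge least squares with unpenalized intercept.

    Features are standardized (stored with the model), so ``ridge`` is
    the penalty on standardized coefficients; the default 1e-3
    corresponds to 1e-3 times the mean feature variance in original
    units.  Minimizes ||y - Xw - b||^2 + ridge * ||w_std||^2.

    Raises
    ------
    ValueError
        If ridge is 0 and the (standardized, centered) design is
        singular — e.g. an all-constant feature column.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("design/target shape mismatch")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / scale
    yc = y - y.mean()
    G = Z.T @ Z
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    if ridge == 0:
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("singular design: add ridge regularization")
        w_std = np.linalg.lstsq(Z, yc, rcond=None)[0]
    else:
        w_std = np.linalg.solve(G + ridge * np.eye(Z.shape[1]), Z.T @ yc)
    weights = w_std / scale
    intercept = float(y.mean() - mu @ weights)
    pred = X @ weights + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum(yc**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if n_channels is None:
        n_channels = X.shape[1] // len(tuple(lags))
    return LinearFilterModel(
        weights=weights,
        intercept=intercept,
        lags=tuple(lags),
        n_channels=int(n_channels),
        ridge=float(ridge),
        feature_mean=mu,
        feature_scale=scale,
        train_r2=r2,
    )


def predict_linear(model: LinearFilterModel, features: np.ndarray) -> np.ndarray:
    """Causal filter output, one value per feature bin after warm-up.

    ``features`` is channels x bins with the training channel set; the
    first max(lags) bins have incomplete history and produce no output.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[0] != model.n_channels:
        raise ValueError(
            f"channel mismatch: model expects {model.n_channels}, got {F.shape[0]}"
        )
    X, _, _ = assemble_feature_matrix(F, model.lags)
    return X @ model.weights + model.intercept


# ---------------------------------------------------------------------------
# Position-velocity Kalman filter


@dataclass
class KalmanModel:
    """Linear-Gaussian state-space model with kinematic state.

    State x = (position, velocity) per controlled dimension evolves as
    x_{t+1} = A x_t + w, w ~ N(0, W); neural observations follow
    z_t = H x_t + q, q ~ N(0, Q).
    """

    A: np.ndarray
    W: np.ndarray
    H: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        for name in ("W", "Q"):
            M = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(M)) < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")
            setattr(self, name, M)
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]


def fit_kalman(states: np.ndarray, observations: np.ndarray) -> KalmanModel:
    """Least-squares system identification of (A, W, H, Q).

    ``states`` is time x state-dim (position and velocity columns);
    ``observations`` is time x n-features.  A minimizes
    ||X_{2:} - X_{1:-1} A'||, W is the residual covariance; H minimizes
    ||Z - X H'||, Q its residual covariance.
    """
    X = np.atleast_2d(np.asarray(states, dtype=float))
    Z = np.atleast_2d(np.asarray(observations, dtype=float))
    if X.shape[0] != Z.shape[0]:
        raise ValueError("states and observations must align in time")
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("not enough samples to identify the model")
    X1, X2 = X[:-1], X[1:]
    A = np.linalg.lstsq(X1, X2, rcond=None)[0].T
    rw = X2 - X1 @ A.T
    W = rw.T @ rw / max(rw.shape[0] - 1, 1)
    H = np.linalg.lstsq(X, Z, rcond=None)[0].T
    rq = Z - X @ H.T
    Q = rq.T @ rq / max(rq.shape[0] - 1, 1)
    # symmetrize against floating-point drift
    return KalmanModel(A=A, W=(W + W.T) / 2, H=H, Q=(Q + Q.T) / 2)


def kalman_step(
    model: KalmanModel,
    mean: np.ndarray,
    cov: np.ndarray,
    observation: np.ndarray,
):
    """One predict/update recursion; returns posterior (mean, cov)."""
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if np.min(np.linalg.eigvalsh((cov + cov.T) / 2)) < -1e-10:
        raise ValueError("prior covariance must be positive semi-definite")
    z = np.atleast_1d(np.asarray(observation, dtype=float))
    A, W, H, Q = model.A, model.W, model.H, model.Q
    m_pred = A @ mean
    P_pred = A @ cov @ A.T + W
    S = H @ P_pred @ H.T + Q
    K = P_pred @ H.T @ np.linalg.pinv(S)
    mean_post = m_pred + K @ (z - H @ m_pred)
    P_post = (np.eye(model.state_dim) - K @ H) @ P_pred
    return mean_post, (P_post + P_post.T) / 2


def kalman_filter(model: KalmanModel, observations: np.ndarray, mean0=None, cov0=None):
    """Run the recursion over a sequence; returns the posterior means."""
    Z = np.atleast_2d(np.asarray(observations, dtype=float))
    d = model.state_dim
    mean = np.zeros(d) if mean0 is None else np.asarray(mean0, dtype=float)
    cov = np.eye(d) if cov0 is None else np.asarray(cov0, dtype=float)
    out = np.empty((Z.shape[0], d))
    for t in range(Z.shape[0]):
        mean, cov = kalman_step(model, mean, cov, Z[t])
        out[t] = mean
    return out


# ---------------------------------------------------------------------------
# Pooled-covariance LDA


@dataclass
class LdaModel:
    classes: np.ndarray
    means: np.ndarray           # k x d
    pooled_cov: np.ndarray      # d x d
    priors: np.ndarray          # k, sums to 1
    _cov_inv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        try:
            self._cov_inv = np.linalg.inv(self.pooled_cov)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                "singular pooled covariance: refit with shrinkage > 0"
            ) from err


def fit_lda(features: np.ndarray, labels: Sequence, shrinkage: float = 0.0) -> LdaModel:
    """Gaussian LDA with pooled within-class covariance.

    ``shrinkage`` in [0, 1] blends the pooled covariance toward a
    spherical matrix with the same average variance, guarding against
    singularity in high dimensions.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least two samples")
    d = X.shape[1]
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((d, d))
    for c, m in zip(classes, means):
        r = X[y == c] - m
        pooled += r.T @ r
    pooled /= X.shape[0] - len(classes)
    if shrinkage > 0:
        pooled = (1 - shrinkage) * pooled + shrinkage * np.trace(pooled) / d * np.eye(d)
    priors = counts / counts.sum()
    try:
        model = LdaModel(classes=classes, means=means, pooled_cov=pooled, priors=priors)
    except ValueError as err:
        raise ValueError(
            "singular pooled covariance: refit with shrinkage > 0"
        ) from err
    return model


def predict_lda(model: LdaModel, features: np.ndarray):
    """Class of the maximal linear discriminant; ties go to the first class."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    Ci = model._cov_inv
    scores = np.empty((X.shape[0], len(model.classes)))
    for k, (m, p) in enumerate(zip(model.means, model.priors)):
        with np.errstate(divide="ignore"):
            logp = np.log(p) if p > 0 else -np.inf
        scores[:, k] = X @ Ci @ m - 0.5 * m @ Ci @ m + logp
    idx = np.argmax(scores, axis=1)  # argmax takes the first maximum: tie-break
    out = model.classes[idx]
    return out if out.shape[0] > 1 else out[0]


def discrete_classifier(kind: str, **kwargs):
    """Factory for the standard discrete classifiers behind one surface.

    ``kind`` in {"lda", "tree", "svm", "knn"}; returns an estimator with
    sklearn's fit/predict API.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    table = {
        "lda": LinearDiscriminantAnalysis,
        "tree": DecisionTreeClassifier,
        "svm": SVC,
        "knn": KNeighborsClassifier,
    }
    if kind not in table:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return table[kind](**kwargs)


# ---------------------------------------------------------------------------
# Two-stage cursor calibration


def _closed_loop_block(
    participant: SyntheticParticipant,
    model: LinearFilterModel,
    target: np.ndarray,
    rng: np.random.Generator,
):
    """Simulate a block in which the prediction cursor is displayed.

    At each bin the participant sees the previous bin's prediction; the
    decoder output is computed causally from the counts so far.
    """
    n_bins = len(target)
    n_ch = participant.n_channels
    counts = np.zeros((n_ch, n_bins))
    preds = np.full(n_bins, 0.5)
    max_lag = max(model.lags)
    feedback = 0.5  # cursor starts mid-screen
    for t in range(n_bins):
        c_t = participant.respond(
            np.array([target[t]]), feedback=np.array([feedback]), rng=rng
        )[:, 0]
        counts[:, t] = c_t
        if t >= max_lag:
            row = np.concatenate([counts[:, t - lag] for lag in model.lags])
            preds[t] = float(row @ model.weights + model.intercept)
        feedback = preds[t]
    return counts, preds


def two_stage_calibration(
    participant: SyntheticParticipant,
    duration: float = 60.0,
    half_period: float = 5.0,
    ridge: float = 1e-3,
    lags: Sequence[int] = DEFAULT_LAGS,
    seed: int = 0,
) -> LinearFilterModel:
    """Open-loop then closed-loop cursor-training calibration.

    Stage 1 fits a preliminary filter on a one-minute open-loop block
    (triangle-wave target, 5 s per screen traverse).  Stage 2 replays
    the protocol with the stage-1 prediction cursor displayed (fed back
    into the participant model) and refits on the closed-loop data.

    Returns the stage-2 model; ``meta`` records both blocks' training
    R^2 and the stage-1 weights.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20]))
    _, target = make_cursor_training_block(
        duration=duration, half_period=half_period, dt=participant.bin_width
    )
    counts1 = participant.respond(target, rng=rng)
    X1, y1, _ = assemble_feature_matrix(counts1, lags, target)
    model1 = fit_linear_filter(X1, y1, ridge=ridge, lags=lags, n_channels=participant.n_channels)

    counts2, _ = _closed_loop_block(participant, model1, target, rng)
    X2, y2, _ = assemble_feature_matrix(counts2, lags, target)
    model2 = fit_linear_filter(X2, y2, ridge=ridge, lags=lags, n_channels=participant.n_channels)
    model2.meta = {
        "stage1_r2": model1.train_r2,
        "stage2_r2": model2.train_r2,
        "stage1_weights": model1.weights.tolist(),
        "seed": seed,
    }
    return model2


def closed_loop_tracking_corr(
    participant: SyntheticParticipant,
    model: LinearFilterModel,
    duration: float = 60.0,
    half_period: float = 5.0,
    seed: int = 1,
) -> float:
    """Held-out closed-loop tracking quality: corr(prediction, target)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    _, target = make_cursor_training_block(
        duration=duration, half_period=half_period, dt=participant.bin_width
    )
    _, preds = _closed_loop_block(participant, model, target, rng)
    warm = max(model.lags)
    return float(np.corrcoef(preds[warm:], target[warm:])[0, 1])


def closed_loop_tracking_error(
    participant: SyntheticParticipant,
    model: LinearFilterModel,
    duration: float = 60.0,
    half_period: float = 5.0,
    seed: int = 1,
) -> float:
    """Held-out closed-loop tracking RMSE to the target.

    Unlike the correlation score this is sensitive to gain errors: a
    filter calibrated open-loop can overshoot badly once its own output
    is fed back through a reactive participant while remaining perfectly
    correlated with the target, so the error is the metric on which
    closed-loop retraining shows its value.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    _, target = make_cursor_training_block(
        duration=duration, half_period=half_period, dt=participant.bin_width
    )
    _, preds = _closed_loop_block(participant, model, target, rng)
    warm = max(model.lags)
    return float(np.sqrt(np.mean((preds[warm:] - target[warm:]) ** 2)))
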