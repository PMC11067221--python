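"""Latent tensor reconstruction: factorized multi-view polynomial regression.

The model approximates a degree-``n_d`` polynomial regression over the
cross-view feature products.  The weight tensor over those monomials is
represented in CP form as a weighted sum of ``n_t`` rank-one tensors

    T = sum_t  lambda_t  (x)_d  p_t^(d),

and each per-view factor matrix P^(d) (n_t x n_x_d) is further decomposed at
a second level as

    P^(d) = V^(d) U^(d)^T D^(d),

with unit-norm rows of V^(d) and U^(d) and a diagonal per-feature scale
D^(d).  Multi-label output is obtained through a projection Q (n_y x n_t)
with unit-norm columns, and optional ReLU activations are inserted inside
the per-view maps:

    pi(x) = Q ( lambda ⊙ prod_d B( V^(d) A( U^(d)^T D^(d) x^(d) ) ) ).

Training minimises the regularised mean squared error

    (1 / 2 m n_y) ||Y - Yhat||_F^2  +  (C_lambda / 2 n_t) ||lambda||^2

subject to the unit-norm constraints, by projected mini-batch gradient
descent (gradient step, then renormalisation).  Gradients are analytic;
the whole model is plain numpy and deterministic given a seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._optim import make_optimizer

logger = logging.getLogger(__name__)

_ACTIVATIONS = ("identity", "relu")


def _act(name: str, x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) if name == "relu" else x


def _act_grad(name: str, pre: np.ndarray) -> np.ndarray:
    return (pre > 0).astype(float) if name == "relu" else np.ones_like(pre)


@dataclass
class LTRParams:
    """Raw parameter container for one latent-tensor-reconstruction model."""

    U: list[np.ndarray]          # per view: (n_x_d, k_d), unit-norm rows
    scale: list[np.ndarray]      # per view: (n_x_d,), diagonal of D^(d)
    V: list[np.ndarray]          # per view: (n_t, k_d), unit-norm rows
    lam: np.ndarray              # (n_t,)
    Q: np.ndarray                # (n_y, n_t), unit-norm columns
    activation_A: str = "identity"
    activation_B: str = "identity"

    @property
    def n_views(self) -> int:
        return len(self.U)

    @property
    def n_t(self) -> int:
        return self.lam.shape[0]

    @property
    def view_dims(self) -> list[int]:
        return [u.shape[0] for u in self.U]

    def copy(self) -> "LTRParams":
        return LTRParams(
            U=[u.copy() for u in self.U],
            scale=[s.copy() for s in self.scale],
            V=[v.copy() for v in self.V],
            lam=self.lam.copy(),
            Q=self.Q.copy(),
            activation_A=self.activation_A,
            activation_B=self.activation_B,
        )

    def constraint_residuals(self) -> float:
        """Largest deviation of any constrained norm from 1."""
        res = 0.0
        for d in range(self.n_views):
            res = max(res, float(np.abs(
                np.linalg.norm(self.V[d], axis=1) - 1.0).max()))
            res = max(res, float(np.abs(
                np.linalg.norm(self.U[d], axis=1) - 1.0).max()))
        res = max(res, float(np.abs(
            np.linalg.norm(self.Q, axis=0) - 1.0).max()))
        return res


@dataclass
class TrainReport:
    objective: list[float] = field(default_factory=list)
    val_objective: list[float] = field(default_factory=list)
    constraint_residuals: list[float] = field(default_factory=list)
    seed: int = 0
    epochs_run: int = 0


def _unit_rows(M: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1)
    dead = norms < 1e-300
    if dead.any():
        logger.info("replacing %d zero rows with random unit vectors",
                    int(dead.sum()))
        M = M.copy()
        M[dead] = rng.normal(size=(int(dead.sum()), M.shape[1]))
        norms = np.linalg.norm(M, axis=1)
    return M / norms[:, None]


def project_constraints(params: LTRParams, seed: int = 0) -> LTRParams:
    """Renormalise V/U rows and Q columns to unit norm (in place-safe copy).

    Zero rows or columns are replaced by seeded random unit vectors before
    normalising.  Idempotent on feasible models.
    """
    rng = np.random.default_rng(seed)
    out = params.copy()
    out.V = [_unit_rows(v, rng) for v in out.V]
    out.U = [_unit_rows(u, rng) for u in out.U]
    out.Q = _unit_rows(out.Q.T, rng).T
    return out


def init_params(view_dims: Sequence[int], n_y: int, n_t: int,
                k_d: Sequence[int] | int | None = None,
                activation_A: str = "identity",
                activation_B: str = "identity",
                seed: int = 0) -> LTRParams:
    """Seeded random init projected onto the norm constraints."""
    if any(d < 1 for d in view_dims) or n_y < 1 or n_t < 1:
        raise ValueError("dimensions must be positive")
    if isinstance(k_d, int):
        k_d = [k_d] * len(view_dims)
    if k_d is None:
        k_d = [min(n_t, d) for d in view_dims]
    for kd, nx in zip(k_d, view_dims):
        if kd > nx:
            logger.info("k_d=%d exceeds view dim %d", kd, nx)
    rng = np.random.default_rng(seed)
    params = LTRParams(
        U=[rng.normal(size=(nx, kd)) for nx, kd in zip(view_dims, k_d)],
        scale=[np.ones(nx) for nx in view_dims],
        V=[rng.normal(size=(n_t, kd)) for kd in k_d],
        lam=0.1 * rng.normal(size=n_t),
        Q=rng.normal(size=(n_y, n_t)),
        activation_A=activation_A,
        activation_B=activation_B,
    )
    return project_constraints(params, seed=seed)


def _view_factors(params: LTRParams, X: Sequence[np.ndarray]):
    """Per-view latent factors H^(d) (m x n_t) plus the intermediates."""
    inter = []
    for d in range(params.n_views):
        Z = X[d] * params.scale[d][None, :]
        preA = Z @ params.U[d]
        A = _act(params.activation_A, preA)
        preB = A @ params.V[d].T
        H = _act(params.activation_B, preB)
        inter.append((Z, preA, A, preB, H))
    return inter


def forward(params: LTRParams, x: Sequence[np.ndarray]) -> np.ndarray:
    """Model output pi(x) for a single sample (tuple of per-view vectors)."""
    X = [np.asarray(v, dtype=float)[None, :] for v in x]
    return predict_scores(params, X)[0]


def predict_scores(params: LTRParams, X: Sequence[np.ndarray]) -> np.ndarray:
    """Raw (unclipped) score matrix (m x n_y) for aligned view matrices."""
    for d, xd in enumerate(X):
        if xd.shape[1] != params.U[d].shape[0]:
            raise ValueError(
                f"view {d}: {xd.shape[1]} features, model expects "
                f"{params.U[d].shape[0]}"
            )
    inter = _view_factors(params, X)
    P = np.ones((X[0].shape[0], params.n_t))
    for (_, _, _, _, H) in inter:
        P = P * H
    return (P * params.lam[None, :]) @ params.Q.T


def objective(params: LTRParams, X: Sequence[np.ndarray], Y: np.ndarray,
              C_lambda: float = 0.0) -> float:
    """Regularised mean squared error of the optimisation objective."""
    Yhat = predict_scores(params, X)
    m, n_y = Y.shape
    mse = float(np.sum((Y - Yhat) ** 2)) / (2.0 * m * n_y)
    reg = C_lambda / (2.0 * params.n_t) * float(np.sum(params.lam ** 2))
    return mse + reg


def _gradients(params: LTRParams, X: Sequence[np.ndarray], Y: np.ndarray,
               C_lambda: float, m_total: int):
    """Analytic gradients of the objective on one mini-batch.

    The MSE term is scaled by the full-dataset 1/(2 m n_y) so that summing
    batch gradients over an epoch matches the full-batch gradient.
    """
    n_y = Y.shape[1]
    inter = _view_factors(params, X)
    Hs = [it[4] for it in inter]
    P = np.ones((X[0].shape[0], params.n_t))
    for H in Hs:
        P = P * H
    G = P * params.lam[None, :]
    Yhat = G @ params.Q.T

    R = (Yhat - Y) / (m_total * n_y)            # dL/dYhat
    gQ = R.T @ G                                 # (n_y, n_t)
    dG = R @ params.Q                            # (m, n_t)
    glam = (dG * P).sum(axis=0) + C_lambda / params.n_t * params.lam
    dP = dG * params.lam[None, :]

    gU, gscale, gV = [], [], []
    for d in range(params.n_views):
        Z, preA, A, preB, H = inter[d]
        others = np.ones_like(P)
        for e in range(params.n_views):
            if e != d:
                others = others * Hs[e]
        dH = dP * others
        dpreB = dH * _act_grad(params.activation_B, preB)
        gV.append(dpreB.T @ A)
        dA = dpreB @ params.V[d]
        dpreA = dA * _act_grad(params.activation_A, preA)
        gU.append(Z.T @ dpreA)
        dZ = dpreA @ params.U[d].T
        gscale.append((dZ * X[d]).sum(axis=0))
    return gU, gscale, gV, glam, gQ


def fit_params(
    params: LTRParams,
    X: Sequence[np.ndarray],
    Y: np.ndarray,
    C_lambda: float = 0.0,
    epochs: int = 100,
    batch_size: int = 128,
    learning_rate: float = 1e-3,
    optimizer: str = "adam",
    seed: int = 0,
    X_val: Sequence[np.ndarray] | None = None,
    Y_val: np.ndarray | None = None,
) -> tuple[LTRParams, TrainReport]:
    """Projected mini-batch gradient training of the Table-style objective.

    Per epoch: seeded shuffle, gradient steps per mini-batch, then projection
    back onto the unit-norm constraints.  Returns the best model by
    validation objective when validation data is given, else the final model.
    """
    params = project_constraints(params, seed=seed)
    m = Y.shape[0]
    report = TrainReport(seed=seed)
    report.objective.append(objective(params, X, Y, C_lambda))
    rng = np.random.default_rng(seed)

    flat = (params.U + params.scale + params.V + [params.lam]
            + [params.Q])
    opt = make_optimizer(optimizer, flat, learning_rate)
    nv = params.n_views

    best = params.copy()
    best_val = np.inf
    for epoch in range(epochs):
        order = rng.permutation(m)
        for s in range(0, m, batch_size):
            idx = order[s:s + batch_size]
            Xb = [xd[idx] for xd in X]
            gU, gscale, gV, glam, gQ = _gradients(
                params, Xb, Y[idx], C_lambda / (-(-m // batch_size)), m
            )
            opt.step(gU + gscale + gV + [glam] + [gQ])
        projected = project_constraints(params, seed=seed)
        for tgt, src in zip(flat, projected.U + projected.scale
                            + projected.V + [projected.lam] + [projected.Q]):
            tgt[...] = src
        obj = objective(params, X, Y, C_lambda)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: objective={obj}"
            )
        report.objective.append(obj)
        report.constraint_residuals.append(params.constraint_residuals())
        if X_val is not None and Y_val is not None and len(Y_val):
            vobj = objective(params, X_val, Y_val, C_lambda)
            report.val_objective.append(vobj)
            if vobj < best_val:
                best_val = vobj
                best = params.copy()
        report.epochs_run = epoch + 1
    if X_val is not None and Y_val is not None and len(Y_val) and epochs > 0:
        return best, report
    return params, report


def explicit_weight_tensor(params: LTRParams,
                           size_guard: int = 10 ** 6) -> np.ndarray:
    """Materialise the CP weight tensor T (identity activations only).

    T = sum_t lambda_t (x)_d p_t^(d) with p_t^(d) the t-th row of
    V^(d) U^(d)^T D^(d).  The contraction <T, (x)_d x^(d)> equals the model
    output with Q replaced by an all-ones vector.
    """
    if params.activation_A != "identity" or params.activation_B != "identity":
        raise ValueError("explicit tensor requires identity activations")
    dims = params.view_dims
    if int(np.prod(dims)) > size_guard:
        raise ValueError(f"tensor of shape {tuple(dims)} exceeds size guard")
    P = [params.V[d] @ params.U[d].T * params.scale[d][None, :]
         for d in range(params.n_views)]   # (n_t, n_x_d) each
    T = np.zeros(dims)
    for t in range(params.n_t):
        rank1 = params.lam[t]
        for d in range(params.n_views):
            rank1 = np.multiply.outer(rank1, P[d][t])
        T += rank1
    return T


def polynomial_coefficient(params: LTRParams,
                           indices: Sequence[int]) -> float:
    """Coefficient of one cross-view monomial: sum_t lambda_t prod_d p^(d)[t, j_d]."""
    if params.activation_A != "identity" or params.activation_B != "identity":
        raise ValueError("polynomial coefficients require identity activations")
    if len(indices) != params.n_views:
        raise ValueError("need one index per view")
    acc = params.lam.copy()
    for d, j in enumerate(indices):
        if not 0 <= j < params.view_dims[d]:
            raise IndexError(f"index {j} out of range for view {d}")
        p_col = params.V[d] @ params.U[d][j] * params.scale[d][j]
        acc = acc * p_col
    return float(acc.sum())


class LatentTensorReconstruction(BaseEstimator):
    """Multi-view multi-label regressor in factorized polynomial (CP) form.

    scikit-learn style estimator: ``fit(X, Y)`` where ``X`` is a list of
    per-view feature matrices sharing row order and ``Y`` a binary (or real)
    label matrix; ``predict(X)`` returns scores clipped to [0, 1] (disable
    with ``clip_scores=False``); ``decision_function(X)`` returns raw scores.

    Parameters
    ----------
    n_t : int
        CP rank — number of rank-one components of the weight tensor.
    k_d : int, sequence of int, or None
        Inner dimension of the second-level factorization per view;
        None uses min(n_t, n_x_d).
    C_lambda : float
        Weight of the (C/2 n_t)||lambda||^2 regulariser.
    activation_A, activation_B : {"identity", "relu"}
        Activations inside (A) and outside (B) the second-level map.
    epochs, batch_size, learning_rate, optimizer, random_state
        Training controls; all randomness is seeded by ``random_state``.
    """

    def __init__(self, n_t: int = 16, k_d=None, C_lambda: float = 0.0,
                 activation_A: str = "identity",
                 activation_B: str = "identity",
                 epochs: int = 100, batch_size: int = 128,
                 learning_rate: float = 1e-3, optimizer: str = "adam",
                 clip_scores: bool = True, random_state: int = 0):
        self.n_t = n_t
        self.k_d = k_d
        self.C_lambda = C_lambda
        self.activation_A = activation_A
        self.activation_B = activation_B
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.clip_scores = clip_scores
        self.random_state = random_state

    def _validate(self, X) -> list[np.ndarray]:
        if hasattr(X, "X"):           # MultiViewDataset
            X = X.X
        X = [np.asarray(xd, dtype=float) for xd in X]
        m = X[0].shape[0]
        for d, xd in enumerate(X):
            if xd.ndim != 2 or xd.shape[0] != m:
                raise ValueError(f"view {d} misaligned: shape {xd.shape}")
            if not np.all(np.isfinite(xd)):
                raise ValueError(f"view {d} contains non-finite values")
        return X

    def fit(self, X, Y, X_val=None, Y_val=None):
        if self.activation_A not in _ACTIVATIONS or \
                self.activation_B not in _ACTIVATIONS:
            raise ValueError(f"activations must be one of {_ACTIVATIONS}")
        X = self._validate(X)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        params = init_params(
            [xd.shape[1] for xd in X], Y.shape[1], self.n_t, self.k_d,
            self.activation_A, self.activation_B, seed=self.random_state,
        )
        if X_val is not None:
            X_val = self._validate(X_val)
            Y_val = np.asarray(Y_val, dtype=float)
            if Y_val.ndim == 1:
                Y_val = Y_val[:, None]
        self.params_, self.report_ = fit_params(
            params, X, Y, C_lambda=self.C_lambda, epochs=self.epochs,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            optimizer=self.optimizer, seed=self.random_state,
            X_val=X_val, Y_val=Y_val,
        )
        self.n_outputs_ = Y.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted")
        return predict_scores(self.params_, self._validate(X))

    def predict(self, X) -> np.ndarray:
        S = self.decision_function(X)
        return np.clip(S, 0.0, 1.0) if self.clip_scores else S

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        """Serialise the fitted model to a single .npz archive."""
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted")
        p = self.params_
        arrays = {"lam": p.lam, "Q": p.Q}
        for d in range(p.n_views):
            arrays[f"U{d}"] = p.U[d]
            arrays[f"scale{d}"] = p.scale[d]
            arrays[f"V{d}"] = p.V[d]
        header = json.dumps({
            "format": "goltr-ltr", "version": 1, "n_views": p.n_views,
            "activation_A": p.activation_A, "activation_B": p.activation_B,
            "config": self.get_params(),
        })
        np.savez(path, header=np.array(header), **arrays)

    @classmethod
    def load(cls, path) -> "LatentTensorReconstruction":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            if header.get("format") != "goltr-ltr":
                raise ValueError("not a goltr model archive")
            nv = header["n_views"]
            params = LTRParams(
                U=[z[f"U{d}"] for d in range(nv)],
                scale=[z[f"scale{d}"] for d in range(nv)],
                V=[z[f"V{d}"] for d in range(nv)],
                lam=z["lam"], Q=z["Q"],
                activation_A=header["activation_A"],
                activation_B=header["activation_B"],
            )
        est = cls(**header["config"])
        est.params_ = params
        est.n_outputs_ = params.Q.shape[0]
        return est
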