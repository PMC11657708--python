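"""Radial basis function network trained through an epsilon-insensitive dual QP.

The model chains two nonlinearities.  First, fuzzy C-means (FCM)
clustering of the training features supplies M Gaussian hidden units:
center c_i is the membership-weighted mean of the data and width
delta_i the membership-weighted mean squared distance to that center,
so the hidden map is

    xt_i(x) = exp(-||x - c_i||^2 / delta_i),        i = 1..M.

Second, instead of fitting the output weights by least squares or
gradient descent, a linear model p' xt is trained under the
epsilon-insensitive loss (residuals smaller than eps cost nothing)
with quadratic slacks and a structural risk term ||p||^2, with eps
itself entering the objective through a 2*lambda*eps term.  A Gaussian
kernel K(xt_i, xt_j) = exp(-gamma ||xt_i - xt_j||^2) on the *hidden*
vectors kernelizes the problem.  The dual is the simplex-constrained
concave QP

    max_{a, a* >= 0}  [a' a*'] [ (2/lambda) y; -(2/lambda) y ]
                      - [a' a*'] Kt [a; a*]
    s.t.  sum(a) + sum(a*) = 1,

    Kt = [[ K + (mu n / lambda) I,  -K ],
          [ -K,  K + (mu n / lambda) I ]],

where mu is the equilibrium factor balancing slack penalties.  The
primal weights are implicit: slacks recover as xi_i = a_i mu n, and
the decision value of a test point is

    f(x) = lambda * sum_i (a_i - a*_i) K(xt_i, xt(x)).

Binary class targets are +/-1; the six-class problem is handled
one-vs-rest with an argmax over the per-class decision values (ties
broken toward the lowest class index).  Note eps is never solved for
explicitly — the simplex constraint internalizes the 2*lambda*eps
term — but an effective eps (the largest residual among training
points whose dual variables are inactive) is reported for diagnostics.

The QP is solved by an accelerated projected-gradient method (FISTA
with adaptive restart) on the probability simplex; Kt is positive
definite thanks to the mu n / lambda diagonal shift, so the solution
is unique and a KKT residual below 1e-6 is required.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .texture import FeatureTable

__all__ = [
    "FCMResult",
    "RBFLayer",
    "DualSolution",
    "FastRBFConfig",
    "FastRBFModel",
    "fcm_fit",
    "rbf_parameters",
    "hidden_map",
    "build_dual_kernel",
    "solve_dual",
    "project_simplex",
    "fit_multiclass",
]

WIDTH_FLOOR = 1e-8


@dataclass
class FCMResult:
    """Soft clustering: row-stochastic memberships and cluster centers."""

    memberships: np.ndarray  # n x M
    centers: np.ndarray  # M x d
    objective_history: list


@dataclass
class RBFLayer:
    centers: np.ndarray  # M x d
    widths: np.ndarray  # M, strictly positive

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.float64))
        self.widths = np.asarray(self.widths, dtype=np.float64).ravel()
        if self.widths.size != self.centers.shape[0]:
            raise ValueError("one width per center required")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be strictly positive")


@dataclass
class DualSolution:
    alpha: np.ndarray
    alpha_star: np.ndarray
    xi: np.ndarray | None
    xi_star: np.ndarray | None
    objective: float
    kkt_residual: float
    n_iterations: int


def fcm_fit(
    X: np.ndarray,
    M: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> FCMResult:
    """Standard alternating fuzzy C-means with fuzzifier m > 1.

    Memberships are initialized at random (row-normalized), then the
    center step (u^m-weighted means) and membership step (inverse
    distance ratios with exponent 2/(m-1)) alternate until the
    objective sum_ji u_ji^m ||x_j - c_i||^2 changes by less than tol.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n, d = X.shape
    if not (1 <= M <= n):
        raise ValueError("need n >= M >= 1")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if np.unique(X, axis=0).shape[0] < M:
        warnings.warn(
            "fewer distinct points than clusters; some clusters will collapse",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    U = rng.random((n, M)) + 1e-3
    U /= U.sum(axis=1, keepdims=True)
    history: list[float] = []
    centers = np.zeros((M, d))
    for _ in range(max_iter):
        W = U**m
        centers = (W.T @ X) / W.sum(axis=0)[:, None]
        d2 = cdist(X, centers, "sqeuclidean")
        zero = d2 <= 1e-300
        if zero.any():
            U = np.where(zero, 1.0, 0.0)
            U /= U.sum(axis=1, keepdims=True)
            rows = ~zero.any(axis=1)
        else:
            rows = np.ones(n, dtype=bool)
        if rows.any():
            inv = d2[rows] ** (-1.0 / (m - 1.0))
            U[rows] = inv / inv.sum(axis=1, keepdims=True)
        obj = float(np.sum((U**m) * d2))
        history.append(obj)
        if len(history) > 1 and abs(history[-2] - obj) < tol:
            break
    return FCMResult(memberships=U, centers=centers, objective_history=history)


def rbf_parameters(X: np.ndarray, fcm: FCMResult) -> RBFLayer:
    """Hidden-unit centers and widths from the FCM memberships.

    c_i is the plain membership-weighted mean and delta_i the
    membership-weighted mean squared distance to c_i, floored at 1e-8
    so a collapsed cluster still yields a valid Gaussian unit.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    U = fcm.memberships
    colsum = U.sum(axis=0)
    centers = (U.T @ X) / colsum[:, None]
    d2 = cdist(X, centers, "sqeuclidean")
    widths = (U * d2).sum(axis=0) / colsum
    return RBFLayer(centers, np.maximum(widths, WIDTH_FLOOR))


def hidden_map(X: np.ndarray, layer: RBFLayer) -> np.ndarray:
    """Gaussian responses exp(-||x - c_i||^2 / delta_i), in (0, 1]."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    d2 = cdist(X, layer.centers, "sqeuclidean")
    return np.exp(-d2 / layer.widths[None, :])


def build_dual_kernel(Xh: np.ndarray, lam: float, mu: float, gamma: float) -> np.ndarray:
    """The 2n x 2n block matrix Kt of the dual QP (symmetric PD)."""
    if min(lam, mu, gamma) <= 0:
        raise ValueError("lam, mu and gamma must be positive")
    Xh = np.atleast_2d(np.asarray(Xh, dtype=np.float64))
    n = Xh.shape[0]
    K = np.exp(-gamma * cdist(Xh, Xh, "sqeuclidean"))
    shift = (mu * n / lam) * np.eye(n)
    top = K + shift
    return np.block([[top, -K], [-K, top]])


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {z >= 0, sum z = 1} (sort-based)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.flatnonzero(u - css / np.arange(1, v.size + 1) > 0)[-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _kkt_residual(Q: np.ndarray, c: np.ndarray, z: np.ndarray) -> float:
    g = 2.0 * Q @ z - c
    nu = g.min()
    return float(np.max(z * (g - nu)))


def solve_dual(
    Ktilde: np.ndarray,
    y: np.ndarray,
    lam: float,
    mu: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 100000,
) -> DualSolution:
    """Maximize the dual objective over the probability simplex.

    FISTA with adaptive restart on  min z'Qz - c'z,  z in simplex,
    Q = Ktilde, c = (2/lambda)[y; -y].  Terminates when the scaled KKT
    complementarity residual drops below ``tol`` (contract: 1e-6).
    When ``mu`` is given, slacks xi = alpha * mu * n are recovered.
    """
    Q = np.asarray(Ktilde, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.size
    if Q.shape != (2 * n, 2 * n):
        raise ValueError("Ktilde must be 2n x 2n for n targets")
    c = (2.0 / lam) * np.concatenate([y, -y])

    L = 2.0 * float(np.linalg.eigvalsh(Q)[-1])
    L = max(L, 1e-12)
    z = np.full(2 * n, 1.0 / (2 * n))
    zy = z.copy()
    t = 1.0
    resid = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        g = 2.0 * Q @ zy - c
        z_new = project_simplex(zy - g / L)
        if np.dot(zy - z_new, z_new - z) > 0:  # adaptive restart
            t = 1.0
            zy = z_new.copy()
        else:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            zy = z_new + ((t - 1.0) / t_new) * (z_new - z)
            t = t_new
        z = z_new
        if it % 25 == 0 or it == max_iter:
            resid = _kkt_residual(Q, c, z)
            if resid < tol:
                break
    resid = _kkt_residual(Q, c, z)
    if resid > 1e-6:
        warnings.warn(
            f"dual QP solver stopped with KKT residual {resid:.2e} "
            f"after {it} iterations",
            stacklevel=2,
        )
    alpha, alpha_star = z[:n], z[n:]
    obj = float(c @ z - z @ Q @ z)
    xi = alpha * mu * n if mu is not None else None
    xi_star = alpha_star * mu * n if mu is not None else None
    return DualSolution(alpha, alpha_star, xi, xi_star, obj, resid, it)


# ---------------------------------------------------------------------------
# multiclass model

@dataclass
class FastRBFConfig:
    M: int = 20  # hidden units
    m: float = 2.0  # FCM fuzzifier
    lam: float = 1.0  # structural-risk weight
    mu: float = 0.1  # equilibrium (slack) factor
    gamma: float | None = None  # kernel bandwidth on hidden space; None -> 1/M
    seed: int = 0
    standardize: bool = True
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 300


@dataclass
class FastRBFModel:
    """Trained one-vs-rest model: shared hidden layer, one dual per class."""

    layer: RBFLayer
    Xh_train: np.ndarray  # n x M hidden vectors of the training set
    duals: list  # DualSolution per class
    classes: np.ndarray
    mask: np.ndarray  # feature mask applied before the hidden layer
    config: FastRBFConfig
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    eps_effective: list = field(default_factory=list)

    @property
    def gamma(self) -> float:
        return self.config.gamma if self.config.gamma is not None else 1.0 / self.config.M

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] == self.mask.size:
            X = X[:, self.mask]
        elif X.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"expected {self.mask.size} raw or {int(self.mask.sum())} masked "
                f"features, got {X.shape[1]}"
            )
        X = (X - self.scaler_mean) / self.scaler_scale
        return hidden_map(X, self.layer)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """n x n_classes matrix of per-class decision values."""
        Xh = self._hidden(X)
        Kx = np.exp(-self.gamma * cdist(self.Xh_train, Xh, "sqeuclidean"))
        lam = self.config.lam
        out = np.empty((Xh.shape[0], len(self.duals)))
        for k, dual in enumerate(self.duals):
            out[:, k] = lam * ((dual.alpha - dual.alpha_star) @ Kx)
        return out

    def decision_value(self, class_index: int, x: np.ndarray) -> float:
        """Decision value of one class for one raw feature vector."""
        return float(self.decision_function(np.atleast_2d(x))[0, class_index])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax over per-class decision values; ties -> lowest class."""
        scores = self.decision_function(X)
        return self.classes[np.argmax(scores, axis=1)]

    # -- serialization ------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "config": {
                "M": self.config.M,
                "m": self.config.m,
                "lam": self.config.lam,
                "mu": self.config.mu,
                "gamma": self.config.gamma,
                "seed": self.config.seed,
                "standardize": self.config.standardize,
                "fcm_tol": self.config.fcm_tol,
                "fcm_max_iter": self.config.fcm_max_iter,
            },
            "classes": self.classes.tolist(),
            "mask": [int(b) for b in self.mask],
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "centers": self.layer.centers.tolist(),
            "widths": self.layer.widths.tolist(),
            "Xh_train": self.Xh_train.tolist(),
            "alpha": [d.alpha.tolist() for d in self.duals],
            "alpha_star": [d.alpha_star.tolist() for d in self.duals],
            "eps_effective": self.eps_effective,
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FastRBFModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        cfg = FastRBFConfig(**payload["config"])
        duals = [
            DualSolution(
                alpha=np.array(a), alpha_star=np.array(s), xi=None, xi_star=None,
                objective=np.nan, kkt_residual=np.nan, n_iterations=0,
            )
            for a, s in zip(payload["alpha"], payload["alpha_star"])
        ]
        return cls(
            layer=RBFLayer(np.array(payload["centers"]), np.array(payload["widths"])),
            Xh_train=np.array(payload["Xh_train"]),
            duals=duals,
            classes=np.array(payload["classes"], dtype=np.int64),
            mask=np.array(payload["mask"], dtype=bool),
            config=cfg,
            scaler_mean=np.array(payload["scaler_mean"]),
            scaler_scale=np.array(payload["scaler_scale"]),
            eps_effective=list(payload.get("eps_effective", [])),
        )


def fit_multiclass(
    table: FeatureTable,
    mask: np.ndarray | None = None,
    config: FastRBFConfig = FastRBFConfig(),
) -> FastRBFModel:
    """Fit the shared hidden layer once, then one dual QP per class.

    ``mask`` restricts the feature columns (None keeps all).  Features
    are z-scored before clustering so no single descriptor scale
    dominates the distance geometry.
    """
    classes = np.unique(table.y)
    if classes.size < 2:
        raise ValueError("training data must contain at least two classes")
    if mask is None:
        mask = np.ones(table.n_features, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.size != table.n_features:
        raise ValueError("mask length must equal the table's feature count")
    if not mask.any():
        raise ValueError("mask selects no features")

    X = table.X[:, mask]
    n = X.shape[0]
    if config.standardize:
        mean = X.mean(axis=0)
        scale = np.maximum(X.std(axis=0), 1e-12)
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale

    M = min(config.M, n)
    if M < config.M:
        warnings.warn(f"reducing hidden units to n={n}", stacklevel=2)
    fcm = fcm_fit(Xs, M, m=config.m, tol=config.fcm_tol,
                  max_iter=config.fcm_max_iter, seed=config.seed)
    layer = rbf_parameters(Xs, fcm)
    Xh = hidden_map(Xs, layer)

    gamma = config.gamma if config.gamma is not None else 1.0 / M
    Ktilde = build_dual_kernel(Xh, config.lam, config.mu, gamma)

    duals = []
    eps_eff = []
    K = np.exp(-gamma * cdist(Xh, Xh, "sqeuclidean"))
    for c in classes:
        t = np.where(table.y == c, 1.0, -1.0)
        dual = solve_dual(Ktilde, t, config.lam, mu=config.mu)
        duals.append(dual)
        # diagnostic effective epsilon: largest residual among samples
        # whose dual variables are (numerically) inactive
        f = config.lam * ((dual.alpha - dual.alpha_star) @ K)
        inactive = (dual.alpha + dual.alpha_star) < 1e-8
        resid = np.abs(t - f)
        eps_eff.append(float(resid[inactive].max()) if inactive.any() else 0.0)

    return FastRBFModel(
        layer=layer,
        Xh_train=Xh,
        duals=duals,
        classes=classes,
        mask=mask,
        config=config,
        scaler_mean=mean,
        scaler_scale=scale,
        eps_effective=eps_eff,
    )
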