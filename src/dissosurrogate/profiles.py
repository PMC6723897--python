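"""Dissolution-profile predictors.

A feed-forward network with three inputs (drug content, polymer content,
compression force), one tanh hidden layer and a 53-neuron linear output
layer mapping to the full dissolution curve, trained by Levenberg-Marquardt
(LM) either unregularized with validation-based early stopping or under
Bayesian regularization (BR, evidence-approximation updates of the weight
decay and noise precisions).  A multi-response PLS2 model on the same
inputs/targets serves as the linear baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "MinMaxScaler",
    "ProfileANN",
    "TrainRun",
    "SweepResult",
    "init_ann",
    "ann_forward",
    "train_lm",
    "train_br",
    "neuron_sweep",
    "PLSDirectModel",
    "pls_direct_fit",
]


class MinMaxScaler:
    """Per-feature min-max map to [-1, 1], fitted on training data only."""

    def __init__(self) -> None:
        self.lo: np.ndarray | None = None
        self.hi: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.lo is not None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)
        return self

    def _span(self) -> np.ndarray:
        span = self.hi - self.lo
        return np.where(span == 0, 1.0, span)  # constant feature maps to -1

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("scaler not fitted")
        return 2.0 * (np.atleast_2d(np.asarray(X, dtype=float)) - self.lo) / self._span() - 1.0

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("scaler not fitted")
        return (np.atleast_2d(np.asarray(Xs, dtype=float)) + 1.0) / 2.0 * self._span() + self.lo

    def to_dict(self) -> dict:
        return {"lo": self.lo.tolist(), "hi": self.hi.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        sc = cls()
        sc.lo = np.asarray(d["lo"], dtype=float)
        sc.hi = np.asarray(d["hi"], dtype=float)
        return sc


@dataclass
class ProfileANN:
    """3 -> H -> 53 feed-forward network with tanh hidden, linear output."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    in_scaler: MinMaxScaler = field(default_factory=MinMaxScaler)
    out_scaler: MinMaxScaler = field(default_factory=MinMaxScaler)
    trainer: str = ""
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def hidden_count(self) -> int:
        return self.W1.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.W2.shape[0]

    @property
    def n_weights(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size

    def forward(self, X: np.ndarray) -> np.ndarray:
        return ann_forward(self, X)


def init_ann(hidden: int, rng: np.random.Generator, n_inputs: int = 3,
             n_outputs: int = 53) -> ProfileANN:
    """Small fan-in-scaled uniform random initialization."""
    if not 1 <= hidden:
        raise ValueError("hidden neuron count must be positive")
    s1 = 1.0 / np.sqrt(n_inputs)
    s2 = 1.0 / np.sqrt(hidden)
    return ProfileANN(
        W1=rng.uniform(-s1, s1, size=(hidden, n_inputs)),
        b1=rng.uniform(-s1, s1, size=hidden),
        W2=rng.uniform(-s2, s2, size=(n_outputs, hidden)),
        b2=rng.uniform(-s2, s2, size=n_outputs),
    )


def ann_forward(net: ProfileANN, X: np.ndarray) -> np.ndarray:
    """Scale inputs, propagate, inverse-scale the outputs (% released)."""
    if not (net.in_scaler.fitted and net.out_scaler.fitted):
        raise RuntimeError("scaling maps are not fitted; train the network first")
    Xs = net.in_scaler.transform(X)
    A = np.tanh(Xs @ net.W1.T + net.b1)
    Ys = A @ net.W2.T + net.b2
    return net.out_scaler.inverse_transform(Ys)


def _pack(net: ProfileANN) -> np.ndarray:
    return np.concatenate([net.W1.ravel(), net.b1, net.W2.ravel(), net.b2])


def _unpack(theta: np.ndarray, net: ProfileANN) -> None:
    H, ni = net.W1.shape
    K = net.W2.shape[0]
    i = 0
    net.W1 = theta[i:i + H * ni].reshape(H, ni); i += H * ni
    net.b1 = theta[i:i + H]; i += H
    net.W2 = theta[i:i + K * H].reshape(K, H); i += K * H
    net.b2 = theta[i:i + K]


def _forward_scaled(theta: np.ndarray, net: ProfileANN, Xs: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    H, ni = net.W1.shape
    K = net.W2.shape[0]
    i = 0
    W1 = theta[i:i + H * ni].reshape(H, ni); i += H * ni
    b1 = theta[i:i + H]; i += H
    W2 = theta[i:i + K * H].reshape(K, H); i += K * H
    b2 = theta[i:i + K]
    A = np.tanh(Xs @ W1.T + b1)
    return A @ W2.T + b2, A


def _jacobian(theta: np.ndarray, net: ProfileANN, Xs: np.ndarray,
              A: np.ndarray) -> np.ndarray:
    """Jacobian of the scaled outputs w.r.t. the flat parameter vector.

    Rows are ordered (sample, output); columns follow the packing order
    W1, b1, W2, b2.
    """
    n, ni = Xs.shape
    H = net.W1.shape[0]
    K = net.W2.shape[0]
    i = H * ni + H
    W2 = theta[i:i + K * H].reshape(K, H)
    D = 1.0 - A ** 2  # n x H, tanh derivative
    # d y_k / d W1[j,i] = W2[k,j] * D[s,j] * x[s,i]
    J_w1 = np.einsum("sj,si,kj->skji", D, Xs, W2).reshape(n, K, H * ni)
    J_b1 = np.einsum("sj,kj->skj", D, W2)
    eye = np.eye(K)
    J_w2 = np.einsum("kc,sj->skcj", eye, A).reshape(n, K, K * H)
    J_b2 = np.broadcast_to(eye, (n, K, K))
    J = np.concatenate([J_w1, J_b1, J_w2, J_b2], axis=2)
    return J.reshape(n * K, theta.size)


@dataclass
class TrainRun:
    """One training run: seed, split, trained network, ranking statistic."""

    seed: int | None
    net: ProfileANN
    split: dict | None = None
    summed_rmsep: float | None = None
    history: dict = field(default_factory=dict)


def _fit_scalers(net: ProfileANN, X: np.ndarray, Y: np.ndarray) -> None:
    net.in_scaler.fit(X)
    net.out_scaler.fit(Y)


def train_lm(net: ProfileANN, X_train: np.ndarray, Y_train: np.ndarray,
             X_val: np.ndarray | None = None, Y_val: np.ndarray | None = None,
             max_epochs: int = 1000, seed: int | None = None,
             mu0: float = 1e-3, mu_max: float = 1e10, patience: int = 6,
             grad_tol: float = 1e-7) -> TrainRun:
    """Levenberg-Marquardt training with validation-based early stopping.

    Damped Gauss-Newton on the flattened weights: (J'J + mu I) dtheta = -J'r,
    mu divided by 10 on improvement and multiplied by 10 on failure.  Stops
    when the validation MSE has risen for ``patience`` consecutive epochs
    (returning the best-validation weights), when mu exceeds ``mu_max`` or
    the gradient vanishes.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float))
    if X_train.shape[0] < net.hidden_count + 1:
        raise ValueError("need at least H+1 training samples")
    _fit_scalers(net, X_train, Y_train)
    Xs = net.in_scaler.transform(X_train)
    Ys = net.out_scaler.transform(Y_train)
    has_val = X_val is not None and len(np.atleast_2d(X_val)) > 0
    if has_val:
        Xv = net.in_scaler.transform(X_val)
        Yv = net.out_scaler.transform(Y_val)

    theta = _pack(net)
    mu = mu0
    out, A = _forward_scaled(theta, net, Xs)
    r = (out - Ys).ravel()
    sse = float(r @ r)
    best_val = np.inf
    best_theta = theta.copy()
    rises = 0
    train_mse, val_mse = [], []
    for _ in range(max_epochs):
        J = _jacobian(theta, net, Xs, A)
        g = J.T @ r
        if np.max(np.abs(g)) < grad_tol:
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= mu_max:
            try:
                step = np.linalg.solve(JtJ + mu * np.eye(theta.size), -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            out_new, A_new = _forward_scaled(theta + step, net, Xs)
            r_new = (out_new - Ys).ravel()
            sse_new = float(r_new @ r_new)
            if sse_new < sse:
                theta = theta + step
                r, A, sse = r_new, A_new, sse_new
                mu = max(mu / 10.0, 1e-20)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            break
        train_mse.append(sse / r.size)
        if has_val:
            vout, _ = _forward_scaled(theta, net, Xv)
            vmse = float(np.mean((vout - Yv) ** 2))
            val_mse.append(vmse)
            if vmse < best_val:
                best_val = vmse
                best_theta = theta.copy()
                rises = 0
            else:
                rises += 1
                if rises > patience:
                    break
    final = best_theta if has_val else theta
    _unpack(final, net)
    net.trainer = "lm"
    net.seed = seed
    net.diagnostics = {"train_mse": train_mse, "val_mse": val_mse,
                       "final_mse": train_mse[-1] if train_mse else sse / r.size}
    return TrainRun(seed=seed, net=net,
                    history={"train_mse": train_mse, "val_mse": val_mse})


def train_br(net: ProfileANN, X_train: np.ndarray, Y_train: np.ndarray,
             max_epochs: int = 300, seed: int | None = None,
             mu0: float = 1e-3, mu_max: float = 1e10,
             ftol: float = 1e-10) -> TrainRun:
    """Bayesian-regularization training.

    Minimizes F = beta*E_D + alpha*E_W (E_D sum-squared error of the scaled
    residuals, E_W sum-squared weights) by damped Gauss-Newton steps; after
    each accepted step the evidence approximation updates the effective
    parameter count gamma = N_w - 2*alpha*tr(H^-1) with H = 2*beta*J'J +
    2*alpha*I, then alpha = gamma / (2 E_W) and beta = (n_obs - gamma) /
    (2 E_D).  No validation-based early stopping.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float))
    if X_train.shape[0] < net.hidden_count + 1:
        raise ValueError("need at least H+1 training samples")
    _fit_scalers(net, X_train, Y_train)
    Xs = net.in_scaler.transform(X_train)
    Ys = net.out_scaler.transform(Y_train)

    theta = _pack(net)
    N = theta.size
    n_obs = Ys.size
    alpha, beta = 0.01, 1.0
    mu = mu0
    out, A = _forward_scaled(theta, net, Xs)
    r = (out - Ys).ravel()
    ed = float(r @ r)
    ew = float(theta @ theta)
    gamma = float(N)
    gammas, objective = [], []
    for _ in range(max_epochs):
        J = _jacobian(theta, net, Xs, A)
        g = beta * (J.T @ r) + alpha * theta
        JtJ = J.T @ J
        F = beta * ed + alpha * ew
        accepted = False
        while mu <= mu_max:
            lhs = beta * JtJ + (alpha + mu) * np.eye(N)
            try:
                step = np.linalg.solve(lhs, -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            cand = theta + step
            out_new, A_new = _forward_scaled(cand, net, Xs)
            r_new = (out_new - Ys).ravel()
            ed_new = float(r_new @ r_new)
            ew_new = float(cand @ cand)
            F_new = beta * ed_new + alpha * ew_new
            if F_new < F:
                theta, r, A = cand, r_new, A_new
                ed, ew = ed_new, ew_new
                mu = max(mu / 10.0, 1e-20)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            break
        # Evidence-approximation hyperparameter update.
        H = 2.0 * beta * JtJ + 2.0 * alpha * np.eye(N)
        try:
            cho = scipy.linalg.cho_factor(H, check_finite=False)
            trinv = float(np.trace(scipy.linalg.cho_solve(cho, np.eye(N),
                                                          check_finite=False)))
        except np.linalg.LinAlgError:
            trinv = float(np.trace(np.linalg.pinv(H + 1e-8 * np.eye(N))))
        gamma = N - 2.0 * alpha * trinv
        gamma = float(np.clip(gamma, 0.0, N))
        if ew > 1e3 * np.finfo(float).eps:
            alpha = gamma / (2.0 * ew)
        if ed > 1e3 * np.finfo(float).eps and n_obs > gamma:
            beta = (n_obs - gamma) / (2.0 * ed)
        gammas.append(gamma)
        objective.append(ed)
        # The regularized objective is pinned near n_obs/2 by the evidence
        # update, so convergence is judged on the data misfit E_D instead.
        if len(objective) > 3 and abs(objective[-2] - ed) <= ftol * max(1.0, ed):
            break
    _unpack(theta, net)
    net.trainer = "br"
    net.seed = seed
    net.diagnostics = {"gamma": gammas, "alpha": alpha, "beta": beta,
                       "final_mse": ed / n_obs, "objective": objective}
    return TrainRun(seed=seed, net=net,
                    history={"gamma": gammas, "objective": objective})


@dataclass
class SweepResult:
    """Outcome of the hidden-neuron sweep."""

    h_values: tuple[int, ...]
    mean_summed_rmsep: np.ndarray        # per H, averaged over runs
    runs: dict[int, list[TrainRun]]      # per H
    best_run: TrainRun
    best_h: int


def _split_70_15_15(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    perm = rng.permutation(n)
    n_val = int(round(0.15 * n))
    n_tst = int(round(0.15 * n))
    return {
        "val": np.sort(perm[:n_val]),
        "test": np.sort(perm[n_val:n_val + n_tst]),
        "train": np.sort(perm[n_val + n_tst:]),
    }


def neuron_sweep(X_train: np.ndarray, Y_train: np.ndarray,
                 X_test: np.ndarray, Y_test: np.ndarray,
                 trainer: str = "br", runs: int = 100,
                 h_values: Sequence[int] = tuple(range(1, 11)),
                 seed: int = 0, max_epochs: int = 300) -> SweepResult:
    """Hidden-neuron sweep with replicate training runs.

    For each hidden-layer size H, ``runs`` networks are trained, each on a
    fresh random 70/15/15 split of the training tablets (the 15% validation
    share drives LM early stopping; BR ignores it during optimization).
    Every trained network predicts the external test tablets; the per-tablet
    profile RMSEP values are summed, the per-H mean is recorded, and the
    single run with the globally lowest summed RMSEP becomes the selected
    model.
    """
    if trainer not in ("lm", "br"):
        raise ValueError("trainer must be 'lm' or 'br'")
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float))
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    Y_test = np.atleast_2d(np.asarray(Y_test, dtype=float))
    if X_test.shape[0] == 0:
        raise ValueError("external test set is empty")
    n = X_train.shape[0]
    h_values = tuple(int(h) for h in h_values)
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(h_values) * runs))

    all_runs: dict[int, list[TrainRun]] = {h: [] for h in h_values}
    means = np.zeros(len(h_values))
    best: TrainRun | None = None
    best_h = h_values[0]
    for ih, h in enumerate(h_values):
        sums = np.zeros(runs)
        for k in range(runs):
            child = next(children)
            run_seed = int(child.generate_state(1)[0] % (2 ** 31))
            rng = np.random.default_rng(child)
            split = _split_70_15_15(n, rng)
            net = init_ann(h, rng, n_inputs=X_train.shape[1],
                           n_outputs=Y_train.shape[1])
            if trainer == "lm":
                run = train_lm(net, X_train[split["train"]], Y_train[split["train"]],
                               X_train[split["val"]], Y_train[split["val"]],
                               max_epochs=max_epochs, seed=run_seed)
            else:
                run = train_br(net, X_train[split["train"]], Y_train[split["train"]],
                               max_epochs=max_epochs, seed=run_seed)
            pred = run.net.forward(X_test)
            per_tablet = np.sqrt(np.mean((pred - Y_test) ** 2, axis=1))
            run.split = {k2: v.tolist() for k2, v in split.items()}
            run.summed_rmsep = float(per_tablet.sum())
            sums[k] = run.summed_rmsep
            all_runs[h].append(run)
            if best is None or run.summed_rmsep < best.summed_rmsep:
                best = run
                best_h = h
        means[ih] = sums.mean()
    assert best is not None
    return SweepResult(h_values=h_values, mean_summed_rmsep=means,
                       runs=all_runs, best_run=best, best_h=best_h)


@dataclass
class PLSDirectModel:
    """Multi-response PLS2 from autoscaled inputs to centered profiles."""

    n_lv: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    coef: np.ndarray  # n_inputs x n_outputs, on autoscaled X

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean) / self.x_sd
        return self.y_mean + Xs @ self.coef


def pls_direct_fit(X: np.ndarray, Y: np.ndarray, n_lv: int = 3,
                   max_inner: int = 500, tol: float = 1e-12) -> PLSDirectModel:
    """NIPALS PLS2 on autoscaled inputs and mean-centered profile targets."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if n_lv > X.shape[1]:
        raise ValueError(f"n_lv={n_lv} exceeds the input dimension {X.shape[1]}")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    if np.any(x_sd == 0):
        raise ValueError("constant input column cannot be autoscaled")
    y_mean = Y.mean(axis=0)
    Xc = (X - x_mean) / x_sd
    Yc = Y - y_mean
    n, m = Xc.shape
    W = np.zeros((m, n_lv))
    P = np.zeros((m, n_lv))
    Q = np.zeros((Yc.shape[1], n_lv))
    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(n_lv):
        u = Yd[:, int(np.argmax(np.var(Yd, axis=0)))].copy()
        t = np.zeros(n)
        for _ in range(max_inner):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e3 * np.finfo(float).eps:
                break
            w /= nw
            t_new = Xd @ w
            q = Yd.T @ t_new / (t_new @ t_new)
            u = Yd @ q / (q @ q)
            if np.linalg.norm(t_new - t) < tol * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        tt = t @ t
        if tt < 1e3 * np.finfo(float).eps:
            W, P, Q = W[:, :a], P[:, :a], Q[:, :a]
            break
        p = Xd.T @ t / tt
        q = Yd.T @ t / tt
        Xd -= np.outer(t, p)
        Yd -= np.outer(t, q)
        W[:, a], P[:, a], Q[:, a] = w, p, q
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSDirectModel(n_lv=W.shape[1], x_mean=x_mean, x_sd=x_sd,
                          y_mean=y_mean, coef=B)
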