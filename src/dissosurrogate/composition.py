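"""Chemometric calibration of tablet composition from pretreated spectra.

NIPALS PLS1 regression of one analyte (DR or HPMC mass fraction) on a
spectral matrix, principal component analysis for exploration,
contiguous-block cross-validation, RMSE/R^2 calibration metrics and a
genetic algorithm selecting contiguous wavelength windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import SpectrumSet

__all__ = [
    "PLSCompositionModel",
    "CalibrationMetrics",
    "GAConfig",
    "pca",
    "pls_fit",
    "contiguous_block_cv",
    "select_n_lv",
    "metrics",
    "ga_select",
    "predict_composition",
]

_EPS = np.finfo(float).eps


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS PLS1 on centered data: weights W, loadings P, y-loadings q, scores T."""
    X = Xc.copy()
    y = yc.copy()
    n, m = X.shape
    W = np.zeros((m, n_lv))
    P = np.zeros((m, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    for a in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e3 * _EPS:
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < 1e3 * _EPS:
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            break
        p = X.T @ t / tt
        qa = (y @ t) / tt
        X -= np.outer(t, p)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
    return W, P, q, T


def _coefs_per_lv(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression vectors B_a for every component count a = 1..A (m x A)."""
    m, A = W.shape
    B = np.zeros((m, A))
    for a in range(1, A + 1):
        Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
        B[:, a - 1] = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
    return B


@dataclass
class PLSCompositionModel:
    """Fitted NIPALS PLS1 calibration of one analyte (% w/w)."""

    analyte: str
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # m x A
    loadings: np.ndarray      # m x A
    y_loadings: np.ndarray    # A
    scores: np.ndarray        # n x A
    coef: np.ndarray          # m, at n_lv components
    channel_mask: np.ndarray | None = None   # over the preprocessed grid
    wavenumbers: np.ndarray | None = None    # preprocessed training grid
    preprocess_state: dict | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"channel count {X.shape[1]} does not match training ({self.x_mean.size})")
        return self.y_mean + (X - self.x_mean) @ self.coef


@dataclass
class CalibrationMetrics:
    """RMSE (% w/w) and R^2 on calibration, cross-validation and test sets."""

    rmsec: float
    rmsecv: float
    rmsep: float
    r2c: float
    r2cv: float
    r2p: float


def pca(X: np.ndarray, n_pc: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS principal component analysis of a centered matrix.

    Returns (scores, loadings, explained-variance fractions); loadings are
    orthonormal columns and scores = X @ loadings.
    """
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if n_pc > rank:
        raise ValueError(f"n_pc={n_pc} exceeds matrix rank {rank}")
    total_ss = float(np.sum(X ** 2))
    Xd = X.copy()
    n, m = X.shape
    scores = np.zeros((n, n_pc))
    loadings = np.zeros((m, n_pc))
    explained = np.zeros(n_pc)
    for a in range(n_pc):
        t = Xd[:, int(np.argmax(np.var(Xd, axis=0)))].copy()
        for _ in range(1000):
            p = Xd.T @ t / (t @ t)
            p /= np.linalg.norm(p)
            t_new = Xd @ p
            if np.linalg.norm(t_new - t) < 1e-12 * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        scores[:, a] = t
        loadings[:, a] = p
        explained[a] = (t @ t) / total_ss
        Xd -= np.outer(t, p)
    return scores, loadings, explained


def pls_fit(X: np.ndarray, y: np.ndarray, n_lv: int, analyte: str = "",
            channel_mask: np.ndarray | None = None,
            wavenumbers: np.ndarray | None = None,
            preprocess_state: dict | None = None) -> PLSCompositionModel:
    """Fit a PLS1 model; centering of X and y is handled internally."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n != y.size:
        raise ValueError("row count of X must equal length of y")
    if n_lv < 1:
        raise ValueError("n_lv must be at least 1")
    if n < n_lv + 1:
        raise ValueError(f"need at least n_lv+1={n_lv + 1} samples, got {n}")
    if np.var(y) == 0:
        raise ValueError("response y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals_pls1(X - x_mean, y - y_mean, n_lv)
    if W.shape[1] == 0:
        raise ValueError("no usable latent variable (X has no variance)")
    B = _coefs_per_lv(W, P, q)
    return PLSCompositionModel(
        analyte=analyte, n_lv=W.shape[1], x_mean=x_mean, y_mean=y_mean,
        weights=W, loadings=P, y_loadings=q, scores=T, coef=B[:, -1],
        channel_mask=channel_mask, wavenumbers=wavenumbers,
        preprocess_state=preprocess_state)


def contiguous_block_cv(X: np.ndarray, y: np.ndarray, n_lv_max: int,
                        n_splits: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous-block cross-validation in the stored sample order.

    Samples are partitioned, in their given order, into ``n_splits`` blocks
    whose sizes differ by at most one; each block is predicted by a model
    fitted on the remainder.  Returns (rmsecv, r2cv), one entry per latent
    variable count 1..n_lv_max, pooled over all out-of-block residuals.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n_splits < 2:
        raise ValueError("n_splits must be at least 2")
    if n_splits > n:
        raise ValueError("n_splits cannot exceed the sample count")
    blocks = np.array_split(np.arange(n), n_splits)
    max_block = max(len(b) for b in blocks)
    cap = min(n_lv_max, n - max_block - 1, X.shape[1])
    if cap < 1:
        raise ValueError("too few samples for even one latent variable")
    residuals = np.zeros((n, cap))
    for block in blocks:
        train = np.setdiff1d(np.arange(n), block)
        Xt, yt = X[train], y[train]
        x_mean = Xt.mean(axis=0)
        y_mean = yt.mean()
        W, P, q, _ = _nipals_pls1(Xt - x_mean, yt - y_mean, cap)
        B = _coefs_per_lv(W, P, q)
        pred = y_mean + (X[block] - x_mean) @ B  # block x A
        if B.shape[1] < cap:  # rank-deficient fold: reuse the deepest model
            pad = np.repeat(pred[:, -1:], cap - B.shape[1], axis=1)
            pred = np.hstack([pred, pad])
        residuals[block] = pred - y[block, None]
    rmsecv = np.sqrt(np.mean(residuals ** 2, axis=0))
    sstot = np.sum((y - y.mean()) ** 2)
    r2cv = 1.0 - np.sum(residuals ** 2, axis=0) / sstot
    return rmsecv, r2cv


def select_n_lv(rmsecv: np.ndarray, rel_tol: float = 0.02) -> int:
    """Fewest latent variables whose RMSECV is within rel_tol of the minimum."""
    rmsecv = np.asarray(rmsecv, dtype=float)
    best = rmsecv.min()
    return int(np.argmax(rmsecv <= (1.0 + rel_tol) * best)) + 1


def _rmse_r2(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    res = yhat - y
    rmse = float(np.sqrt(np.mean(res ** 2)))
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res ** 2)) / sstot if sstot > 0 else np.nan
    return rmse, r2


def metrics(model: PLSCompositionModel, X_cal: np.ndarray, y_cal: np.ndarray,
            X_test: np.ndarray, y_test: np.ndarray,
            cv_result: tuple[np.ndarray, np.ndarray] | None = None
            ) -> CalibrationMetrics:
    """RMSEC/RMSECV/RMSEP and the matching R^2 values for a fitted model."""
    y_cal = np.asarray(y_cal, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if y_cal.size == 0 or y_test.size == 0:
        raise ValueError("calibration and test sets must be nonempty")
    rmsec, r2c = _rmse_r2(y_cal, model.predict(X_cal))
    rmsep, r2p = _rmse_r2(y_test, model.predict(X_test))
    if cv_result is not None:
        rmsecv_all, r2cv_all = cv_result
        idx = min(model.n_lv, len(rmsecv_all)) - 1
        rmsecv, r2cv = float(rmsecv_all[idx]), float(r2cv_all[idx])
    else:
        rmsecv, r2cv = np.nan, np.nan
    return CalibrationMetrics(rmsec=rmsec, rmsecv=rmsecv, rmsep=rmsep,
                              r2c=r2c, r2cv=r2cv, r2p=r2p)


@dataclass
class GAConfig:
    """Genetic-algorithm settings for contiguous-window variable selection."""

    population: int = 64
    window_width: int = 10        # channels per window
    max_lv: int = 6
    replicate_runs: int = 3
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.01   # per-window flip probability
    tournament: int = 2
    elitism: int = 1
    n_splits: int = 30
    init_density: float = 0.5

    def __post_init__(self) -> None:
        if self.population % 2 != 0:
            raise ValueError("population size must be even")
        if self.window_width < 1:
            raise ValueError("window width must be at least 1")


@dataclass
class GAResult:
    channel_mask: np.ndarray
    model: PLSCompositionModel
    rmsecv: float
    n_lv: int
    history: list[float] = field(default_factory=list)  # best fitness per generation


def _window_slices(n_channels: int, width: int) -> list[slice]:
    return [slice(i, min(i + width, n_channels)) for i in range(0, n_channels, width)]


def _mask_from_chromosome(chrom: np.ndarray, slices: list[slice], m: int) -> np.ndarray:
    mask = np.zeros(m, dtype=bool)
    for bit, sl in zip(chrom, slices):
        if bit:
            mask[sl] = True
    return mask


def ga_select(X: np.ndarray, y: np.ndarray, config: GAConfig = GAConfig(),
              seed: int = 0) -> GAResult:
    """Genetic-algorithm selection of contiguous wavelength windows.

    Chromosomes are bit-vectors over contiguous windows of
    ``config.window_width`` channels; fitness is the best contiguous-block
    RMSECV of a PLS model with at most ``config.max_lv`` latent variables on
    the selected channels.  Tournament selection, single-point crossover at
    window boundaries, per-window mutation and one-elite survival; the best
    of ``replicate_runs`` independent runs is returned.  Fully seeded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if m < config.window_width:
        raise ValueError("fewer channels than one window")
    slices = _window_slices(m, config.window_width)
    n_win = len(slices)
    cache: dict[bytes, tuple[float, int]] = {}

    def fitness(chrom: np.ndarray) -> tuple[float, int]:
        key = chrom.tobytes()
        if key in cache:
            return cache[key]
        if not chrom.any():
            out = (np.inf, 0)  # all-zero chromosome: worst fitness, never returned
        else:
            mask = _mask_from_chromosome(chrom, slices, m)
            rmsecv, _ = contiguous_block_cv(X[:, mask], y, config.max_lv,
                                            n_splits=config.n_splits)
            a = int(np.argmin(rmsecv))
            out = (float(rmsecv[a]), a + 1)
        cache[key] = out
        return out

    ss = np.random.SeedSequence(seed)
    best_overall: tuple[float, int, np.ndarray, list[float]] | None = None
    for child in ss.spawn(config.replicate_runs):
        rng = np.random.default_rng(child)
        pop = rng.random((config.population, n_win)) < config.init_density
        for row in pop:  # guarantee a live chromosome
            if not row.any():
                row[rng.integers(n_win)] = True
        fits = np.array([fitness(c)[0] for c in pop])
        history = [float(fits.min())]
        for _ in range(config.generations):
            order = np.argsort(fits)
            elite = pop[order[: config.elitism]].copy()
            children = [*elite]
            while len(children) < config.population:
                parents = []
                for _ in range(2):
                    contenders = rng.integers(0, config.population, size=config.tournament)
                    parents.append(pop[contenders[np.argmin(fits[contenders])]].copy())
                c1, c2 = parents
                if rng.random() < config.crossover_rate and n_win > 1:
                    cut = int(rng.integers(1, n_win))
                    c1[cut:], c2[cut:] = c2[cut:].copy(), c1[cut:].copy()
                for c in (c1, c2):
                    flips = rng.random(n_win) < config.mutation_rate
                    c[flips] = ~c[flips]
                children.extend([c1, c2])
            pop = np.array(children[: config.population])
            fits = np.array([fitness(c)[0] for c in pop])
            history.append(float(fits.min()))
        ib = int(np.argmin(fits))
        f, lv = fitness(pop[ib])
        if best_overall is None or f < best_overall[0]:
            best_overall = (f, lv, pop[ib].copy(), history)

    assert best_overall is not None
    f, lv, chrom, history = best_overall
    mask = _mask_from_chromosome(chrom, slices, m)
    model = pls_fit(X[:, mask], y, lv, channel_mask=mask)
    return GAResult(channel_mask=mask, model=model, rmsecv=f, n_lv=lv,
                    history=history)


def predict_composition(model: PLSCompositionModel, S: SpectrumSet) -> np.ndarray:
    """Predict analyte content (% w/w) for preprocessed test spectra."""
    if model.wavenumbers is not None:
        if (S.wavenumbers.size != model.wavenumbers.size
                or not np.allclose(S.wavenumbers, model.wavenumbers)):
            raise ValueError("test spectra grid does not match the training grid")
    X = S.intensities
    if model.channel_mask is not None:
        X = X[:, model.channel_mask]
    return model.predict(X)
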