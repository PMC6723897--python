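"""Profile-comparison statistics and factorial effects analysis.

The f2 similarity factor, f2 = 50*log10(100 * [1 + mean_t w_t (R_t-T_t)^2]^-1/2),
is the regulatory statistic for dissolution-profile equivalence: 100 at
identity, and 50..100 means the two profiles are accepted as equivalent.
Also: per-profile RMSEP, normalization of profiles to the mean (8%) drug
content, a 3^3 factorial effects analysis with linear, quadratic and
linear-by-linear interaction terms, and assembly of the ANN-vs-PLS
comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .synthetic import TabletRecord

__all__ = [
    "f2_similarity",
    "profile_rmsep",
    "normalize_to_mean_dr",
    "F2Report",
    "build_f2_report",
    "EffectsTable",
    "effects_analysis",
    "effects_from_profiles",
    "compare_models",
]


def f2_similarity(R: np.ndarray, T: np.ndarray,
                  weights: np.ndarray | None = None,
                  truncate_after_85: bool = False) -> float:
    """f2 similarity factor between a reference and a test profile.

    ``weights`` defaults to all ones.  ``truncate_after_85`` optionally
    applies the regulatory convention of keeping points only up to the first
    reference sample beyond 85% dissolved; by default all points enter.
    """
    R = np.asarray(R, dtype=float)
    T = np.asarray(T, dtype=float)
    if R.shape != T.shape or R.ndim != 1 or R.size < 1:
        raise ValueError("profiles must be 1-D vectors of equal length")
    w = np.ones_like(R) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != R.shape:
        raise ValueError("weights length must match the profiles")
    if truncate_after_85:
        above = np.flatnonzero(R >= 85.0)
        if above.size:
            keep = slice(0, above[0] + 1)
            R, T, w = R[keep], T[keep], w[keep]
    msd = float(np.mean(w * (R - T) ** 2))
    return float(50.0 * np.log10(100.0 / np.sqrt(1.0 + msd)))


def profile_rmsep(R: np.ndarray, T: np.ndarray) -> float:
    """Root mean squared deviation between two profiles (% released)."""
    R = np.asarray(R, dtype=float)
    T = np.asarray(T, dtype=float)
    if R.shape != T.shape:
        raise ValueError("profiles must have equal length")
    return float(np.sqrt(np.mean((R - T) ** 2)))


def normalize_to_mean_dr(released: np.ndarray, dr_true: float,
                         dr_ref: float = 8.0) -> np.ndarray:
    """Rescale a profile to the reference (8%) drug content."""
    if dr_true <= 0:
        raise ValueError("dr_true must be positive")
    return np.asarray(released, dtype=float) * (dr_ref / dr_true)


@dataclass
class F2Report:
    """Per-tablet f2 and RMSEP for one model, with aggregate summaries."""

    model_name: str
    table: pd.DataFrame  # columns: tablet_id, f2, rmsep, equivalent

    @property
    def mean_f2(self) -> float:
        return float(self.table["f2"].mean())

    @property
    def min_f2(self) -> float:
        return float(self.table["f2"].min())

    @property
    def n_equivalent(self) -> int:
        return int(self.table["equivalent"].sum())


def build_f2_report(model_name: str, tablet_ids: Sequence[str],
                    measured: np.ndarray, predicted: np.ndarray) -> F2Report:
    """F2Report from matching (tablets x time points) profile matrices."""
    measured = np.atleast_2d(np.asarray(measured, dtype=float))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    if measured.shape != predicted.shape or measured.shape[0] != len(tablet_ids):
        raise ValueError("profile matrices and tablet ids must align")
    rows = []
    for i, tid in enumerate(tablet_ids):
        f2 = f2_similarity(measured[i], predicted[i])
        rows.append({
            "tablet_id": tid,
            "f2": f2,
            "rmsep": profile_rmsep(measured[i], predicted[i]),
            "equivalent": bool(50.0 <= f2 <= 100.0),
        })
    return F2Report(model_name=model_name, table=pd.DataFrame(rows))


_TERM_NAMES = ("intercept", "DR(L)", "HPMC(L)", "Force(L)",
               "DR(Q)", "HPMC(Q)", "Force(Q)",
               "DRxHPMC", "DRxForce", "HPMCxForce")


@dataclass
class EffectsTable:
    """Standardized effects of the coded 3^3 factorial model."""

    table: pd.DataFrame  # term, coef, se, t, p, significant; ranked by |t|
    df_resid: int
    sigma2: float

    def ranked_terms(self) -> list[str]:
        sub = self.table[self.table["term"] != "intercept"]
        return list(sub.sort_values("abs_t", ascending=False)["term"])


def _code(values: np.ndarray) -> np.ndarray:
    levels = np.unique(values)
    if levels.size != 3:
        raise ValueError(f"expected exactly 3 factor levels, got {levels.size}")
    coded = np.select([values == levels[0], values == levels[1]], [-1.0, 0.0], 1.0)
    return coded


def effects_analysis(dr: np.ndarray, hpmc: np.ndarray, force: np.ndarray,
                     response: np.ndarray, alpha: float = 0.05) -> EffectsTable:
    """Least-squares factorial effects model on coded (-1, 0, +1) factors.

    The model has 10 terms: intercept, three linear effects, three quadratic
    effects and the three linear-by-linear interactions.  The standardized
    effect is the t-statistic coefficient / SE; significance is tested on
    the residual degrees of freedom at the given level.
    """
    dr = np.asarray(dr, dtype=float)
    hpmc = np.asarray(hpmc, dtype=float)
    force = np.asarray(force, dtype=float)
    y = np.asarray(response, dtype=float)
    a, b, c = _code(dr), _code(hpmc), _code(force)
    combos = {(x1, x2, x3) for x1, x2, x3 in zip(a, b, c)}
    if len(combos) != 27:
        raise ValueError("full 3^3 factorial requires all 27 factor combinations")
    X = np.column_stack([np.ones_like(a), a, b, c, a ** 2, b ** 2, c ** 2,
                         a * b, a * c, b * c])
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough observations for the 10-term model")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ssres = float(resid @ resid)
    sstot = float(np.sum((y - y.mean()) ** 2))
    df = n - p
    sigma2 = ssres / df
    xtx_inv = np.linalg.inv(X.T @ X)
    if sstot > 0 and ssres <= 1e-18 * sstot:
        # Exact fit: zero residual variance, so nonzero coefficients are
        # infinitely significant and null ones have a zero statistic.
        scale = np.max(np.abs(coef))
        t = np.where(np.abs(coef) > 1e-8 * max(scale, 1.0), np.inf, 0.0)
        se = np.zeros(p)
        pvals = np.where(np.isinf(t), 0.0, 1.0)
    else:
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        t = coef / se
        pvals = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    table = pd.DataFrame({
        "term": _TERM_NAMES,
        "coef": coef,
        "se": se,
        "t": t,
        "abs_t": np.abs(t),
        "p": pvals,
        "significant": pvals < alpha,
    })
    return EffectsTable(table=table, df_resid=df, sigma2=sigma2)


def effects_from_profiles(tablets: Sequence[TabletRecord], profiles: np.ndarray,
                          times: np.ndarray, response_time: float,
                          normalize: bool = True) -> EffectsTable:
    """Effects analysis of the factorial block at one response time (min).

    Uses the dissolution value at ``response_time`` (15 or 960 min in the
    study protocol), normalized to the mean (8%) drug content, as the
    dependent variable; factors are the nominal settings.
    """
    times = np.asarray(times, dtype=float)
    idx = np.flatnonzero(np.isclose(times, response_time))
    if idx.size == 0:
        raise ValueError(f"response time {response_time} min is not on the grid")
    j = int(idx[0])
    keep = [i for i, tb in enumerate(tablets) if tb.setting.origin == "factorial"]
    if not keep:
        raise ValueError("no factorial tablets present")
    dr = np.array([tablets[i].setting.dr_nominal for i in keep])
    hp = np.array([tablets[i].setting.hpmc_nominal for i in keep])
    fc = np.array([tablets[i].setting.force for i in keep])
    y = np.array([
        normalize_to_mean_dr(profiles[i, j], tablets[i].dr_true)
        if normalize else profiles[i, j]
        for i in keep
    ], dtype=float)
    return effects_analysis(dr, hp, fc, y)


def compare_models(ann_reports: Mapping[str, F2Report],
                   pls_reports: Mapping[str, F2Report]) -> pd.DataFrame:
    """Mean f2 of ANN vs PLS-direct per input source, plus equivalence counts.

    Rows: ANN, PLS, difference, and per-model counts of tablets inside the
    50..100 equivalence band; one column per input source.
    """
    if set(ann_reports) != set(pls_reports):
        raise ValueError("ANN and PLS reports must cover the same input sources")
    sources = list(ann_reports)
    for src in sources:
        a_ids = list(ann_reports[src].table["tablet_id"])
        p_ids = list(pls_reports[src].table["tablet_id"])
        if a_ids != p_ids:
            raise ValueError(f"tablet sets differ between reports for {src!r}")
    data = {
        "ANN": [ann_reports[s].mean_f2 for s in sources],
        "PLS": [pls_reports[s].mean_f2 for s in sources],
    }
    df = pd.DataFrame(data, index=sources).T
    df.loc["difference"] = df.loc["ANN"] - df.loc["PLS"]
    df.loc["ANN equivalent (n)"] = [ann_reports[s].n_equivalent for s in sources]
    df.loc["PLS equivalent (n)"] = [pls_reports[s].n_equivalent for s in sources]
    df.index.name = "modeling method"
    return df
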