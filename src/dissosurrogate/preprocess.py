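"""Spectral pretreatment operators for NIR/Raman tablet spectra.

Implements the operator vocabulary used by chemometric calibration of
compacted solid dosage forms: spectral-region exclusion, asymmetric
least-squares (Whittaker) baseline removal, standard normal variate,
multiplicative signal correction, Savitzky-Golay derivatives and mean
centering.  Operators are pure functions on :class:`SpectrumSet`; fit-type
state (the MSC reference, column means) is returned separately so the
identical transform can be replayed on held-out spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import scipy.linalg
import scipy.signal
import scipy.sparse

__all__ = [
    "SpectrumSet",
    "PreprocessRecipe",
    "exclude_regions",
    "asls_baseline",
    "snv",
    "msc",
    "savgol_derivative",
    "mean_center",
    "apply_recipe",
    "RAMAN_RECIPE",
    "NIR_TRANS_RECIPE",
    "NIR_REFL_RECIPE",
]


@dataclass(frozen=True)
class SpectrumSet:
    """A sample x channel intensity matrix on a common wavenumber grid.

    ``provenance`` is an append-only tuple of applied operator descriptions;
    together with the fitted state it fully determines reproducibility.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_ids: tuple[str, ...]
    modality: str = ""
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        xs = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", xs)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if wn.ndim != 1:
            raise ValueError("wavenumbers must be a 1-D vector")
        if xs.shape[1] != wn.size:
            raise ValueError(
                f"intensity columns ({xs.shape[1]}) do not match wavenumber grid ({wn.size})"
            )
        if xs.shape[0] != len(self.sample_ids):
            raise ValueError("one sample_id per spectrum is required")
        d = np.diff(wn)
        if wn.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def with_data(self, intensities: np.ndarray, step: str,
                  wavenumbers: np.ndarray | None = None) -> "SpectrumSet":
        return replace(
            self,
            intensities=np.asarray(intensities, dtype=float),
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            provenance=self.provenance + (step,),
        )

    def subset(self, sample_mask: np.ndarray) -> "SpectrumSet":
        ids = tuple(s for s, keep in zip(self.sample_ids, sample_mask) if keep)
        return replace(self, intensities=self.intensities[np.asarray(sample_mask)],
                       sample_ids=ids)


def exclude_regions(s: SpectrumSet, keep_windows: Sequence[Sequence[float]]) -> SpectrumSet:
    """Retain only channels inside the union of closed keep-windows (cm^-1)."""
    wn = s.wavenumbers
    mask = np.zeros(wn.size, dtype=bool)
    for lo, hi in keep_windows:
        mask |= (wn >= lo) & (wn <= hi)
    if not mask.any():
        raise ValueError("no channels retained by keep windows")
    desc = "exclude(keep=" + ",".join(f"[{lo},{hi}]" for lo, hi in keep_windows) + ")"
    return s.with_data(s.intensities[:, mask], desc, wavenumbers=wn[mask])


def _second_diff_penalty_bands(m: int, lam: float) -> np.ndarray:
    """Upper banded form (bandwidth 2) of lam * D2'D2 for m channels."""
    d2 = scipy.sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m - 2, m))
    dtd = (d2.T @ d2).tocsr() * lam
    ab = np.zeros((3, m))
    ab[2] = dtd.diagonal(0)
    ab[1, 1:] = dtd.diagonal(1)
    ab[0, 2:] = dtd.diagonal(2)
    return ab


def asls_baseline_vector(y: np.ndarray, p: float = 0.001, lam: float = 1e4,
                         max_iter: int = 50) -> np.ndarray:
    """Asymmetric least-squares (Whittaker) baseline of one spectrum.

    Minimizes sum w_i (y_i - z_i)^2 + lam * sum (Delta^2 z)^2 with asymmetric
    weights w = p where y > z else 1 - p, iterated until the weight vector is
    stable (changed fraction < 1e-6) or ``max_iter`` sweeps.
    """
    y = np.asarray(y, dtype=float)
    m = y.size
    if m < 3:
        raise ValueError("AsLS baseline needs at least 3 channels")
    if not 0.0 < p < 1.0:
        raise ValueError("asymmetry p must be in (0, 1)")
    if lam <= 0:
        raise ValueError("smoothness lam must be positive")
    penalty = _second_diff_penalty_bands(m, lam)
    w = np.ones(m)
    z = y
    for _ in range(max_iter):
        ab = penalty.copy()
        ab[2] += w
        z = scipy.linalg.solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        changed = np.count_nonzero(w_new != w) / m
        w = w_new
        if changed < 1e-6:
            break
    return z


def asls_baseline(s: SpectrumSet, p: float = 0.001, lam: float = 1e4,
                  max_iter: int = 50) -> SpectrumSet:
    """Subtract an AsLS/Whittaker baseline from each spectrum."""
    if s.n_channels < 3:
        raise ValueError("AsLS baseline needs at least 3 channels")
    corrected = np.empty_like(s.intensities)
    for i in range(s.n_samples):
        corrected[i] = s.intensities[i] - asls_baseline_vector(
            s.intensities[i], p=p, lam=lam, max_iter=max_iter)
    return s.with_data(corrected, f"asls(p={p},lam={lam})")


def snv(s: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: per-spectrum mean 0, sd 1 (n-1 denominator)."""
    mu = s.intensities.mean(axis=1, keepdims=True)
    sd = s.intensities.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"zero-variance spectrum for sample {s.sample_ids[bad[0]]}")
    return s.with_data((s.intensities - mu) / sd, "snv")


def msc(s: SpectrumSet, reference: np.ndarray | str = "mean") -> SpectrumSet:
    """Multiplicative signal correction against a reference spectrum.

    Each spectrum y is regressed as y = a + b*ref by OLS and returned as
    (y - a) / b.  ``reference="mean"`` uses this set's mean spectrum; to
    replay a training transform on test data, pass the stored reference.
    """
    if s.n_channels < 2:
        raise ValueError("MSC needs at least 2 channels")
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError(f"unknown MSC reference policy {reference!r}")
        ref = s.intensities.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.size != s.n_channels:
            raise ValueError("MSC reference length does not match channel count")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("degenerate MSC reference (constant)")
    y = s.intensities
    b = (y - y.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(b == 0):
        bad = int(np.flatnonzero(b == 0)[0])
        raise ValueError(f"degenerate MSC fit (b=0) for sample {s.sample_ids[bad]}")
    a = y.mean(axis=1) - b * ref.mean()
    corrected = (y - a[:, None]) / b[:, None]
    return s.with_data(corrected, "msc")


def msc_reference(s: SpectrumSet) -> np.ndarray:
    """Mean spectrum of a (training) set, for storage as the MSC reference."""
    return s.intensities.mean(axis=0)


def savgol_derivative(s: SpectrumSet, window: int = 5, polyorder: int = 2,
                      deriv: int = 1) -> SpectrumSet:
    """Savitzky-Golay derivative with respect to channel index.

    Edges use the local polynomial fit on the truncated window
    (``mode="interp"``); the constant index-vs-wavenumber scaling is absorbed
    by any subsequent regression.
    """
    if window % 2 == 0:
        raise ValueError("SavGol window must be odd")
    if window > s.n_channels:
        raise ValueError("SavGol window exceeds channel count")
    if polyorder >= window:
        raise ValueError("SavGol polynomial order must be smaller than window")
    out = scipy.signal.savgol_filter(
        s.intensities, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=1.0, axis=1, mode="interp")
    return s.with_data(out, f"savgol(w={window},o={polyorder},d={deriv})")


def mean_center(s: SpectrumSet, mean: np.ndarray | str = "fit") -> tuple[SpectrumSet, np.ndarray]:
    """Column mean centering; returns the centered set and the means used."""
    if isinstance(mean, str):
        if mean != "fit":
            raise ValueError(f"unknown centering policy {mean!r}")
        mu = s.intensities.mean(axis=0)
    else:
        mu = np.asarray(mean, dtype=float)
        if mu.size != s.n_channels:
            raise ValueError("stored mean length does not match channel count")
    return s.with_data(s.intensities - mu, "center"), mu


@dataclass
class PreprocessRecipe:
    """Ordered list of pretreatment steps, each a dict with an ``op`` key."""

    steps: list[dict[str, Any]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {"steps": [dict(st) for st in self.steps]}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PreprocessRecipe":
        return cls(steps=[dict(st) for st in d.get("steps", [])])


# Recipes used by the calibration pipeline.  Raman: region exclusion, AsLS
# baseline (p=0.001, lambda=1e4), SNV, mean centering.  NIR: region exclusion,
# 5-point quadratic Savitzky-Golay first derivative, MSC, mean centering.
RAMAN_RECIPE = PreprocessRecipe([
    {"op": "exclude", "windows": [[350.0, 1680.0]]},
    {"op": "asls", "p": 0.001, "lam": 1e4},
    {"op": "snv"},
    {"op": "center"},
])

NIR_TRANS_RECIPE = PreprocessRecipe([
    {"op": "exclude", "windows": [[7600.0, 8000.0], [8500.0, 13000.0]]},
    {"op": "savgol", "window": 5, "polyorder": 2, "deriv": 1},
    {"op": "msc"},
    {"op": "center"},
])

NIR_REFL_RECIPE = PreprocessRecipe([
    {"op": "exclude", "windows": [[4200.0, 7400.0]]},
    {"op": "savgol", "window": 5, "polyorder": 2, "deriv": 1},
    {"op": "msc"},
    {"op": "center"},
])

DEFAULT_RECIPES = {
    "raman_trans": RAMAN_RECIPE,
    "raman_refl": RAMAN_RECIPE,
    "nir_trans": NIR_TRANS_RECIPE,
    "nir_refl": NIR_REFL_RECIPE,
}


def apply_recipe(s: SpectrumSet, recipe: PreprocessRecipe,
                 fitted_state: dict[str, Any] | None = None
                 ) -> tuple[SpectrumSet, dict[str, Any]]:
    """Apply pretreatment steps in order.

    When ``fitted_state`` is None the data-dependent steps (MSC reference,
    column means) are fitted on ``s`` (training mode) and returned; otherwise
    the stored state is replayed so held-out spectra see the identical
    transform.
    """
    fitting = fitted_state is None
    state: dict[str, Any] = {} if fitting else fitted_state
    out = s
    for i, step in enumerate(recipe.steps):
        op = step["op"]
        key = f"{i}:{op}"
        if op == "exclude":
            out = exclude_regions(out, step["windows"])
        elif op == "asls":
            out = asls_baseline(out, p=step.get("p", 0.001),
                                lam=step.get("lam", 1e4),
                                max_iter=step.get("max_iter", 50))
        elif op == "snv":
            out = snv(out)
        elif op == "msc":
            if fitting:
                ref = msc_reference(out)
                state[key] = {"reference": ref.tolist()}
            else:
                ref = np.asarray(state[key]["reference"], dtype=float)
            out = msc(out, reference=ref)
        elif op == "savgol":
            out = savgol_derivative(out, window=step.get("window", 5),
                                    polyorder=step.get("polyorder", 2),
                                    deriv=step.get("deriv", 1))
        elif op == "center":
            if fitting:
                out, mu = mean_center(out, "fit")
                state[key] = {"mean": mu.tolist()}
            else:
                out, _ = mean_center(out, np.asarray(state[key]["mean"], dtype=float))
        else:
            raise ValueError(f"unknown preprocessing operator {op!r}")
    return out, state
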