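"""Synthetic tablet study: design, dissolution kinetics and mixture spectra.

Emulates a three-factor extended-release tablet study: drotaverine (DR)
content, hydroxypropyl methylcellulose (HPMC) content and compression force
are varied over a 3^3 factorial design plus ten one-factor-at-a-time
settings.  Each tablet gets a ground-truth composition, a Weibull-shaped
dissolution curve whose time constant responds nonlinearly (Hill-type) to
HPMC and weakly to compression force, and four simulated spectra (NIR/Raman
x transmission/reflection) built from Gaussian pure-component bands with
modality-specific baselines, multiplicative scatter and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .preprocess import SpectrumSet

__all__ = [
    "DesignSetting",
    "TabletRecord",
    "DissolutionProfile",
    "KineticsConfig",
    "ModalityConfig",
    "SimulatorConfig",
    "TabletDataset",
    "TEST_SETTING_IDS",
    "MODALITIES",
    "build_design",
    "dissolution_time_grid",
    "simulate_profile",
    "pure_component_spectra",
    "simulate_spectra",
    "generate_dataset",
]

TEST_SETTING_IDS = frozenset({1, 4, 14, 17, 27, 29, 34})
DR_LEVELS = (6.0, 8.0, 10.0)
HPMC_LEVELS = (10.0, 20.0, 30.0)
FORCE_LEVELS = (63.8, 95.7, 127.6)

# One-factor-at-a-time settings around the center point (ids 28..37).
_ADDITIONAL = (
    (7.0, 20.0, 63.8), (7.5, 20.0, 63.8), (8.5, 20.0, 63.8), (9.0, 20.0, 63.8),
    (8.0, 5.0, 63.8), (8.0, 15.0, 63.8), (8.0, 25.0, 63.8), (8.0, 35.0, 63.8),
    (8.0, 20.0, 31.9), (8.0, 20.0, 159.5),
)

MODALITIES = ("nir_trans", "nir_refl", "raman_trans", "raman_refl")

COMPONENTS = ("dr", "hpmc", "mcc", "mgst")


@dataclass(frozen=True)
class DesignSetting:
    setting_id: int
    dr_nominal: float     # % w/w
    hpmc_nominal: float   # % w/w
    force: float          # MPa
    role: str             # "train" | "test"
    origin: str           # "factorial" | "additional"


@dataclass(frozen=True)
class TabletRecord:
    tablet_id: str
    setting: DesignSetting
    dr_true: float
    hpmc_true: float
    force_measured: float


@dataclass(frozen=True)
class DissolutionProfile:
    times: np.ndarray     # minutes, strictly increasing
    released: np.ndarray  # % of nominal dose

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.released, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "released", r)
        if t.size != r.size:
            raise ValueError("times and released must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("released values must be finite")


def build_design() -> list[DesignSetting]:
    """The 37-setting experimental design: 27 factorial + 10 additional.

    The factorial block enumerates DR x HPMC x force with DR varying fastest
    and force slowest; seven settings (1, 4, 14, 17, 27, 29, 34) are held out
    for testing, the remaining thirty calibrate the models.
    """
    settings: list[DesignSetting] = []
    sid = 1
    for force in FORCE_LEVELS:
        for hpmc in HPMC_LEVELS:
            for dr in DR_LEVELS:
                settings.append(DesignSetting(
                    sid, dr, hpmc, force,
                    "test" if sid in TEST_SETTING_IDS else "train", "factorial"))
                sid += 1
    for dr, hpmc, force in _ADDITIONAL:
        settings.append(DesignSetting(
            sid, dr, hpmc, force,
            "test" if sid in TEST_SETTING_IDS else "train", "additional"))
        sid += 1
    return settings


def dissolution_time_grid() -> np.ndarray:
    """Sampling grid of the 24 h dissolution run (53 points, minutes).

    Dense early sampling (2, 5, 10, 15, 30, 45, 60 min) followed by one
    sample every 30 min out to 1440 min.
    """
    early = [2.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0]
    late = np.arange(90.0, 1441.0, 30.0)
    return np.concatenate([early, late])


@dataclass(frozen=True)
class KineticsConfig:
    """Weibull release kinetics with Hill-type HPMC retardation.

    Noise-free release is D(t) = Dmax * (1 - exp(-(t/tau)^beta)) with
    Dmax = 100 * dr / dr_ref (the plateau scales with drug load relative to
    the 8% center point) and tau = tau0 * h(hpmc) * g(force), where
    h(c) = 1 + amp * c^n / (half^n + c^n) saturates: release is nearly
    immediate at 10% HPMC, strongly retarded at 20% and only marginally more
    at 30%.  g(F) = (F / force_ref)^force_exp is a weak increasing force
    effect acting on the early part of the curve.
    """

    tau0: float = 4.0          # min, time constant of the polymer-free matrix
    weibull_beta: float = 0.9  # Weibull shape
    hpmc_half: float = 19.0    # % w/w, half-effect HPMC concentration
    hpmc_hill: float = 7.0     # Hill steepness
    hpmc_amp: float = 70.0     # maximal fold retardation
    force_ref: float = 95.7    # MPa (center point)
    force_exp: float = 0.15    # force sensitivity
    dr_ref: float = 8.0        # % w/w, plateau normalization reference


def simulate_profile(dr_true: float, hpmc_true: float, force: float,
                     times: np.ndarray, config: KineticsConfig = KineticsConfig(),
                     noise_sd: float = 0.0,
                     rng: np.random.Generator | None = None) -> DissolutionProfile:
    """Dissolution curve of one tablet; additive Gaussian noise if requested."""
    if dr_true <= 0 or hpmc_true <= 0 or force <= 0:
        raise ValueError("composition and force must be positive")
    t = np.asarray(times, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("time grid must be strictly increasing")
    c = hpmc_true
    hill = c ** config.hpmc_hill / (config.hpmc_half ** config.hpmc_hill + c ** config.hpmc_hill)
    tau = config.tau0 * (1.0 + config.hpmc_amp * hill) * (force / config.force_ref) ** config.force_exp
    dmax = 100.0 * dr_true / config.dr_ref
    released = dmax * (1.0 - np.exp(-((t / tau) ** config.weibull_beta)))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        released = np.clip(released + rng.normal(0.0, noise_sd, size=t.size), 0.0, None)
    return DissolutionProfile(times=t, released=released)


Peak = tuple[float, float, float]  # (center cm^-1, sd cm^-1, height per % w/w)


@dataclass(frozen=True)
class ModalityConfig:
    """Instrument model for one modality: grid, bands, baseline and noise."""

    grid_start: float
    grid_stop: float
    grid_step: float
    peaks: Mapping[str, tuple[Peak, ...]]
    baseline_amp: float = 0.0
    baseline_decay: float = 0.0    # >0: exponential fluorescence-like slope
    baseline_slope: float = 0.0    # linear tilt across the grid
    baseline_jitter: float = 0.3   # relative sd of per-sample baseline amplitude
    scatter_sd: float = 0.05       # sd of the per-sample multiplicative factor
    noise_sd: float = 0.05         # additive noise sd (intensity units)
    edge_regions: tuple[tuple[float, float, float], ...] = ()  # (lo, hi, factor)

    def grid(self) -> np.ndarray:
        n = int(np.floor((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


def _default_modalities() -> dict[str, ModalityConfig]:
    # Narrow aromatic-drug bands dominate the Raman fingerprint region; the
    # polymer shows broad overtone/combination features in the NIR, partly
    # overlapped by the cellulose filler in the Raman.  Reflection geometry
    # carries 3-4x the additive noise of transmission.
    raman_peaks = {
        "dr": ((1645.0, 8.0, 1.0), (1605.0, 7.0, 0.9), (1560.0, 9.0, 0.7),
               (1345.0, 10.0, 0.8), (900.0, 12.0, 0.3)),
        # Both celluloses share the skeletal bands around 1120/1090 cm^-1, so
        # the HPMC Raman signature is almost collinear with the MCC filler
        # and carries only a faint distinct feature near 945 cm^-1.
        "hpmc": ((1090.0, 16.0, 0.29), (1120.0, 20.0, 0.125), (1380.0, 22.0, 0.175),
                 (520.0, 14.0, 0.195), (435.0, 12.0, 0.145), (945.0, 16.0, 0.045)),
        "mcc": ((1090.0, 16.0, 0.30), (1120.0, 20.0, 0.12), (1380.0, 22.0, 0.18),
                (520.0, 14.0, 0.20), (435.0, 12.0, 0.15)),
        "mgst": ((1296.0, 10.0, 0.40), (1060.0, 8.0, 0.30)),
    }
    # All organic components share the C-H combination band near 8650 cm^-1
    # with the same per-percent response; because the formulation sums to
    # 100%, that band is composition-independent and anchors the MSC slope.
    ch_band = (8650.0, 150.0, 0.25)
    nir_peaks = {
        "hpmc": ((11000.0, 220.0, 0.50), (10300.0, 200.0, 0.45), (9800.0, 180.0, 0.40),
                 (8850.0, 160.0, 0.35), (7750.0, 140.0, 0.30), (5200.0, 150.0, 0.15),
                 ch_band),
        "dr": ((8600.0, 120.0, 0.25), (12100.0, 180.0, 0.15), (6000.0, 130.0, 0.20),
               ch_band),
        "mcc": ((10400.0, 350.0, 0.20), (9000.0, 300.0, 0.15), (4800.0, 250.0, 0.30),
                (6900.0, 280.0, 0.20), ch_band),
        "mgst": ((5800.0, 120.0, 0.20), ch_band),
    }
    raman_common = dict(peaks=raman_peaks, baseline_amp=30.0, baseline_decay=300.0,
                        baseline_slope=-2.0)
    nir_common = dict(peaks=nir_peaks, baseline_amp=5.0, baseline_decay=0.0,
                      baseline_slope=1.5)
    return {
        "raman_trans": ModalityConfig(
            grid_start=200.0, grid_stop=1890.0, grid_step=4.0, noise_sd=0.08,
            edge_regions=((200.0, 350.0, 8.0), (1680.0, 1890.0, 8.0)),
            **raman_common),
        "raman_refl": ModalityConfig(
            grid_start=200.0, grid_stop=1890.0, grid_step=4.0, noise_sd=0.30,
            edge_regions=((200.0, 350.0, 8.0), (1680.0, 1890.0, 8.0)),
            **raman_common),
        "nir_trans": ModalityConfig(
            grid_start=4000.0, grid_stop=15000.0, grid_step=32.0, noise_sd=0.03,
            edge_regions=((4000.0, 7600.0, 6.0), (8000.0, 8500.0, 6.0)),
            **nir_common),
        "nir_refl": ModalityConfig(
            grid_start=4000.0, grid_stop=10000.0, grid_step=8.0, noise_sd=0.20,
            edge_regions=((4000.0, 4200.0, 5.0), (7400.0, 10000.0, 5.0)),
            **nir_common),
    }


@dataclass(frozen=True)
class SimulatorConfig:
    """Everything that defines one synthetic dataset realization."""

    seed: int = 0
    n_per_setting: int = 4
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    modalities: Mapping[str, ModalityConfig] = field(default_factory=_default_modalities)
    composition_rel_sd: float = 0.02   # between-tablet noise, relative to nominal
    force_sd: float = 1.0              # MPa
    profile_sd: float = 1.0            # % released, additive measurement noise
    # global multiplier on all instrument-noise sources (additive spectral
    # noise, multiplicative scatter spread, baseline jitter)
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.composition_rel_sd, self.force_sd, self.profile_sd,
               self.noise_scale) < 0:
            raise ValueError("noise magnitudes must be nonnegative")


def pure_component_spectra(grid: np.ndarray,
                           peaks: Mapping[str, Sequence[Peak]]) -> np.ndarray:
    """Component x channel matrix of Gaussian-band pure spectra (unit conc.)."""
    s = np.zeros((len(COMPONENTS), grid.size))
    for i, comp in enumerate(COMPONENTS):
        for center, width, height in peaks.get(comp, ()):
            if width <= 0:
                raise ValueError("peak widths must be positive")
            s[i] += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return s


def _concentrations(tablets: Sequence[TabletRecord]) -> np.ndarray:
    """Component concentrations (% w/w): DR, HPMC, MCC filler, 1% MgSt."""
    c = np.zeros((len(tablets), len(COMPONENTS)))
    for k, tb in enumerate(tablets):
        mgst = 1.0
        c[k] = [tb.dr_true, tb.hpmc_true, 100.0 - tb.dr_true - tb.hpmc_true - mgst, mgst]
    return c


def simulate_spectra(tablets: Sequence[TabletRecord], modality: str,
                     config: SimulatorConfig,
                     rng: np.random.Generator | None = None) -> SpectrumSet:
    """Mixture spectra of one modality for a list of tablets.

    intensity(s, v) = m_s * sum_i c_i * s_i(v) + b_s(v) + eps, with a
    per-sample multiplicative scatter factor m_s, a smooth per-sample
    baseline b_s (steep low-wavenumber fluorescence slope for Raman) and
    additive noise inflated inside the configured noisy-edge regions.
    """
    if not tablets:
        raise ValueError("tablets must be nonempty")
    if modality not in config.modalities:
        raise ValueError(f"unknown modality {modality!r}")
    mc = config.modalities[modality]
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = mc.grid()
    pure = pure_component_spectra(grid, mc.peaks)
    conc = _concentrations(tablets)
    signal = conc @ pure

    n = len(tablets)
    scatter = 1.0 + rng.normal(0.0, mc.scatter_sd * config.noise_scale, size=(n, 1))
    amp = mc.baseline_amp * (1.0 + mc.baseline_jitter * config.noise_scale
                             * rng.normal(size=(n, 1)))
    span = grid[-1] - grid[0]
    rel = (grid - grid[0]) / span
    if mc.baseline_decay > 0:
        shape = np.exp(-(grid - grid[0]) / mc.baseline_decay)
    else:
        shape = np.ones_like(grid)
    baseline = amp * shape + mc.baseline_slope * amp / max(mc.baseline_amp, 1e-12) * rel

    noise_sd = np.full(grid.size, mc.noise_sd * config.noise_scale)
    for lo, hi, factor in mc.edge_regions:
        noise_sd[(grid >= lo) & (grid <= hi)] *= factor
    eps = rng.normal(size=(n, grid.size)) * noise_sd

    return SpectrumSet(
        wavenumbers=grid,
        intensities=scatter * signal + baseline + eps,
        sample_ids=tuple(tb.tablet_id for tb in tablets),
        modality=modality,
        provenance=(f"simulated({modality})",),
    )


@dataclass(frozen=True)
class TabletDataset:
    """All artifacts of one simulated study."""

    config: SimulatorConfig
    design: tuple[DesignSetting, ...]
    tablets: tuple[TabletRecord, ...]
    spectra: Mapping[str, SpectrumSet]
    times: np.ndarray
    profiles_true: np.ndarray       # tablets x 53, noise-free
    profiles_measured: np.ndarray   # tablets x 53, with measurement noise

    @property
    def train_mask(self) -> np.ndarray:
        return np.array([tb.setting.role == "train" for tb in self.tablets])

    @property
    def test_mask(self) -> np.ndarray:
        return ~self.train_mask

    def tablet_ids(self) -> tuple[str, ...]:
        return tuple(tb.tablet_id for tb in self.tablets)


def generate_dataset(config: SimulatorConfig = SimulatorConfig()) -> TabletDataset:
    """Generate the full study: 37 settings x n tablets, 4 spectra, profiles.

    All randomness flows from ``config.seed`` through independent
    per-purpose streams, so regeneration is bit-identical and changing only
    the seed changes noise realizations but not the noise-free kinetics map.
    """
    design = build_design()
    times = dissolution_time_grid()
    ss = np.random.SeedSequence(config.seed)
    keys = ("tablets", "profiles", *MODALITIES)
    rngs = dict(zip(keys, (np.random.default_rng(c) for c in ss.spawn(len(keys)))))

    rng_t = rngs["tablets"]
    tablets: list[TabletRecord] = []
    for st in design:
        for r in range(1, config.n_per_setting + 1):
            dr = st.dr_nominal * (1.0 + config.composition_rel_sd * rng_t.normal())
            hp = st.hpmc_nominal * (1.0 + config.composition_rel_sd * rng_t.normal())
            fc = st.force + config.force_sd * rng_t.normal()
            tablets.append(TabletRecord(
                tablet_id=f"S{st.setting_id:02d}R{r}",
                setting=st,
                dr_true=max(dr, 1e-6),
                hpmc_true=max(hp, 1e-6),
                force_measured=max(fc, 1e-6),
            ))

    rng_p = rngs["profiles"]
    n = len(tablets)
    profiles_true = np.empty((n, times.size))
    profiles_measured = np.empty_like(profiles_true)
    for k, tb in enumerate(tablets):
        clean = simulate_profile(tb.dr_true, tb.hpmc_true, tb.force_measured,
                                 times, config.kinetics)
        profiles_true[k] = clean.released
        noisy = clean.released + rng_p.normal(0.0, config.profile_sd, size=times.size)
        profiles_measured[k] = np.clip(noisy, 0.0, None)

    spectra = {m: simulate_spectra(tablets, m, config, rng=rngs[m])
               for m in MODALITIES}

    return TabletDataset(
        config=config, design=tuple(design), tablets=tuple(tablets),
        spectra=spectra, times=times,
        profiles_true=profiles_true, profiles_measured=profiles_measured,
    )
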