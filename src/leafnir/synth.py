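"""Synthetic pear-leaf spectra with nitrogen-linked absorption structure.

The generator produces vegetation-shaped reflectance on the 350-2500 nm grid
from an analytic closed form: a logistic red edge rising to an NIR plateau,
a Gaussian green peak at 550 nm, chlorophyll absorption wells at 450 and
680 nm, water absorption wells at 1440 and 1900 nm (plus the 2500 nm tail),
and protein/N absorption wells at 1510, 1690, 2150 and 2180 nm.  Well depths
at the chlorophyll and protein features grow linearly with leaf N, so
absorption depth is strictly monotone in N by construction.  The shape is a
deliberately simple, invertible stand-in for radiative-transfer models: every
term is documented below and can be re-evaluated independently in tests.

Measurement modes
-----------------
``black_background``  absolute reflectance, values in [0, 1].
``white_background``  transflectance: a transmittance-like positive offset is
    added, concentrated in 800-1300, 1550-1850 and ~2200 nm (values <= 1.5).
``solar_25deg``       bare-fibre sun-lit measurement: high-variance noise
    inside the atmospheric water-vapour windows (1350-1460, 1790-1970,
    2350-2500 nm) and a depressed 2000-2500 nm region.

Realism caveats built into the defaults, because field calibrations live in
this regime:

* spectra respond to an *effective* N (true N plus a latent biochemical
  nuisance with SD ``n_latent_sd``), bounding how well any calibration can
  predict the chemical reference;
* leaf water content, leaf structure (NIR plateau amplitude) and a smooth
  baseline drift vary leaf-to-leaf independently of N, so the dominant
  variance directions of a spectral library are *not* the N-informative
  ones — the reason variance-ranked methods (PCR) trail supervised ones
  (PLSR) on real leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import DEFAULT_GRID, Mode, SpectraSet, Spectrum, WavelengthGrid

# -- fixed spectral constants (nm / reflectance units) ----------------------

RED_EDGE_BASE_NM = 700.0      # red-edge inflection at N = 0
RED_EDGE_SHIFT_PER_GKG = 0.6  # inflection shifts red with N
RED_EDGE_WIDTH_NM = 16.0
NIR_PLATEAU_BASE = 0.43       # plateau amplitude at N = 0
NIR_PLATEAU_PER_GKG = 0.0016  # plateau brightening with N (NIR-confined)
NIR_GAIN_CENTRE_NM = 1050.0
NIR_GAIN_WIDTH_NM = 350.0
VIS_BASE = 0.05
GREEN_PEAK_NM, GREEN_SD_NM = 550.0, 40.0
GREEN_AMP_BASE, GREEN_AMP_PER_GKG = 0.16, 0.0012  # green peak shrinks with N
SWIR_TAPER_PER_NM = 8e-5      # linear decline beyond 1300 nm

WATER_WELLS = ((1440.0, 50.0, 0.26), (1900.0, 60.0, 0.34), (2500.0, 120.0, 0.12))

# N-coupled absorption wells: (centre nm, sd nm, depth at N=0, depth gain per g/kg)
DEFAULT_INFORMATIVE_BANDS = (
    (450.0, 30.0, 0.010, 0.0010),   # chlorophyll a/b blue
    (680.0, 25.0, 0.020, 0.0015),   # chlorophyll red
    (1510.0, 30.0, 0.004, 0.0022),  # N-H first overtone (protein)
    (1690.0, 25.0, 0.003, 0.0018),  # C-H aromatic / protein
    (2150.0, 22.0, 0.004, 0.0025),  # amide combination
    (2180.0, 18.0, 0.003, 0.0020),  # amide combination
)

# white-background transflectance offset lobes: (centre, sd, amplitude)
TRANSFLECTANCE_LOBES = ((1050.0, 180.0, 0.10), (1700.0, 110.0, 0.06), (2200.0, 90.0, 0.04))

# atmospheric water-vapour windows for the solar mode (standard field practice)
ATMOSPHERIC_WINDOWS = ((1350, 1460), (1790, 1970), (2350, 2500))
SOLAR_WINDOW_NOISE_SD = 0.08
SOLAR_SWIR_DEPRESSION = 0.12   # fractional dimming ramped over 2000-2500 nm


@dataclass
class Treatment:
    """One fertilization level: label and its leaf-N distribution."""

    label: str
    mean_n_gkg: float
    sd_n_gkg: float

    def __post_init__(self) -> None:
        if self.sd_n_gkg < 0:
            raise ValueError("sd_n_gkg must be >= 0")
        if not (10.0 <= self.mean_n_gkg <= 40.0):
            raise ValueError(f"treatment mean {self.mean_n_gkg} outside 10-40 g/kg")


def default_treatments() -> list[Treatment]:
    """Five N rates; pooled distribution has mean 25.4, SD 3.0 g/kg."""
    # between-treatment variance 8 + within-treatment variance 1 = 9
    return [
        Treatment("N0", 21.4, 1.0),
        Treatment("N1", 23.4, 1.0),
        Treatment("N2", 25.4, 1.0),
        Treatment("N3", 27.4, 1.0),
        Treatment("N4", 29.4, 1.0),
    ]


N_CLIP_GKG = (17.0, 36.0)


@dataclass
class SimulationConfig:
    """Study-condition defaults: 5 N rates x 3 trees x 12 leaves x 2 DAB x 2 years = 720 leaves."""

    n_trees_per_treatment: int = 3
    leaves_per_tree: int = 12
    treatments: list[Treatment] = field(default_factory=default_treatments)
    dab: tuple[int, ...] = (50, 80)
    years: tuple[int, ...] = (2014, 2015)
    mode: Mode = Mode.BLACK_BACKGROUND
    noise_additive_sd: float = 0.008
    noise_multiplicative_sd: float = 0.01
    n_latent_sd: float = 1.1
    water_content_sd: float = 0.12      # fractional spread of water-well depth
    structure_sd: float = 0.025         # leaf-structure spread of the NIR plateau
    smooth_drift_sd: float = 0.015      # baseline drift amplitude (reflectance)
    smooth_drift_scale_nm: float = 80.0 # correlation length of the drift
    informative_bands: tuple = DEFAULT_INFORMATIVE_BANDS
    # N -> chlorophyll/structure couplings (linear gains; zero them to leave
    # only the `informative_bands` wells N-sensitive)
    red_edge_shift_per_gkg: float = RED_EDGE_SHIFT_PER_GKG
    green_amp_per_gkg: float = GREEN_AMP_PER_GKG
    nir_plateau_per_gkg: float = NIR_PLATEAU_PER_GKG
    grid: WavelengthGrid = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode = Mode.coerce(self.mode)
        for sd in (self.noise_additive_sd, self.noise_multiplicative_sd,
                   self.n_latent_sd, self.water_content_sd, self.structure_sd,
                   self.smooth_drift_sd):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")
        if self.n_trees_per_treatment <= 0 or self.leaves_per_tree <= 0:
            raise ValueError("counts must be positive")

    @property
    def n_samples(self) -> int:
        return (len(self.treatments) * self.n_trees_per_treatment *
                self.leaves_per_tree * len(self.dab) * len(self.years))


# ---------------------------------------------------------------------------
# closed-form shape
# ---------------------------------------------------------------------------

def leaf_shape(wavelengths_nm: np.ndarray, n_gkg: float,
               informative_bands=DEFAULT_INFORMATIVE_BANDS,
               water_scale: float = 1.0, plateau_shift: float = 0.0,
               red_edge_shift_per_gkg: float = RED_EDGE_SHIFT_PER_GKG,
               green_amp_per_gkg: float = GREEN_AMP_PER_GKG,
               nir_plateau_per_gkg: float = NIR_PLATEAU_PER_GKG) -> np.ndarray:
    """Noise-free black-background reflectance at the given N.

    R(l) = VIS_BASE
         + green(N) * exp(-(l-550)^2 / (2*40^2))
         + (plateau(N) + plateau_shift) / (1 + exp(-(l - edge(N)) / 16))
         - taper * max(l - 1300, 0)
         - water_scale * sum water wells
         - sum N-coupled wells (depth = d0 + gain * N)
         + NIR brightening confined by a Gaussian gain around 1050 nm,
    clipped to [0, 1].

    ``water_scale`` (leaf water content) and ``plateau_shift`` (leaf
    structure/thickness) are per-leaf nuisance factors, neutral by default.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    edge = RED_EDGE_BASE_NM + red_edge_shift_per_gkg * n_gkg
    r = np.full_like(lam, VIS_BASE)
    r += (GREEN_AMP_BASE - green_amp_per_gkg * n_gkg) * np.exp(
        -((lam - GREEN_PEAK_NM) ** 2) / (2 * GREEN_SD_NM**2))
    sigmoid = 1.0 / (1.0 + np.exp(-(lam - edge) / RED_EDGE_WIDTH_NM))
    nir_gain = np.exp(-((lam - NIR_GAIN_CENTRE_NM) ** 2) / (2 * NIR_GAIN_WIDTH_NM**2))
    r += (NIR_PLATEAU_BASE + plateau_shift
          + nir_plateau_per_gkg * n_gkg * nir_gain) * sigmoid
    r -= SWIR_TAPER_PER_NM * np.clip(lam - 1300.0, 0.0, None)
    for centre, sd, depth in WATER_WELLS:
        r -= water_scale * depth * np.exp(-((lam - centre) ** 2) / (2 * sd**2))
    for centre, sd, d0, gain in informative_bands:
        r -= (d0 + gain * n_gkg) * np.exp(-((lam - centre) ** 2) / (2 * sd**2))
    return np.clip(r, 0.0, 1.0)


def transflectance_offset(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Non-negative white-background addition (transmitted light re-reflected)."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    off = np.zeros_like(lam)
    for centre, sd, amp in TRANSFLECTANCE_LOBES:
        off += amp * np.exp(-((lam - centre) ** 2) / (2 * sd**2))
    return off


def simulate_leaf_spectrum(n_gkg: float, mode: Mode | str, config: SimulationConfig,
                           rng: np.random.Generator, sample_id: str = "leaf",
                           meta: dict | None = None) -> Spectrum:
    """One leaf measurement at the stated N under the stated geometry."""
    if n_gkg <= 0:
        raise ValueError("n_gkg must be positive")
    mode = Mode.coerce(mode)
    lam = config.grid.wavelengths.astype(float)
    n_eff = n_gkg + rng.normal(0.0, config.n_latent_sd)
    water = 1.0 + rng.normal(0.0, config.water_content_sd)
    plateau = rng.normal(0.0, config.structure_sd)
    r = leaf_shape(lam, n_eff, config.informative_bands,
                   water_scale=water, plateau_shift=plateau,
                   red_edge_shift_per_gkg=config.red_edge_shift_per_gkg,
                   green_amp_per_gkg=config.green_amp_per_gkg,
                   nir_plateau_per_gkg=config.nir_plateau_per_gkg)
    if config.smooth_drift_sd > 0:
        # smooth baseline drift: unit-variance Gaussian-filtered white noise
        from scipy.ndimage import gaussian_filter1d
        sigma = config.smooth_drift_scale_nm / config.grid.step_nm
        g = gaussian_filter1d(rng.normal(0.0, 1.0, lam.size), sigma, mode="reflect")
        sd = g.std()
        if sd > 0:
            r = r + config.smooth_drift_sd * g / sd

    upper = 1.0
    if mode is Mode.WHITE_BACKGROUND:
        r = r + transflectance_offset(lam)
        upper = 1.5
    elif mode is Mode.SOLAR_25DEG:
        ramp = np.clip((lam - 2000.0) / 500.0, 0.0, 1.0)
        r = r * (1.0 - SOLAR_SWIR_DEPRESSION * ramp)
        for lo, hi in ATMOSPHERIC_WINDOWS:
            inside = (lam >= lo) & (lam <= hi)
            r[inside] += rng.normal(0.0, SOLAR_WINDOW_NOISE_SD, inside.sum())

    r = r * (1.0 + rng.normal(0.0, config.noise_multiplicative_sd))
    r = r + rng.normal(0.0, config.noise_additive_sd, lam.size)
    r = np.clip(r, 0.0, upper)
    return Spectrum(sample_id, config.grid, r, mode, meta or {})


def simulate_dataset(config: SimulationConfig) -> SpectraSet:
    """Full seeded library: N drawn per treatment (clipped), one spectrum per leaf."""
    rng = np.random.default_rng(config.seed)
    spectra, n_values = [], []
    i = 0
    for year in config.years:
        for day in config.dab:
            for trt in config.treatments:
                for tree in range(config.n_trees_per_treatment):
                    for leaf in range(config.leaves_per_tree):
                        n = float(np.clip(rng.normal(trt.mean_n_gkg, trt.sd_n_gkg),
                                          *N_CLIP_GKG))
                        sid = f"{year}_{day}_{trt.label}_t{tree}_l{leaf}"
                        meta = {"year": year, "dab": day, "treatment": trt.label,
                                "tree": f"{trt.label}-{tree}"}
                        spectra.append(simulate_leaf_spectrum(
                            n, config.mode, config, rng, sample_id=sid, meta=meta))
                        n_values.append(n)
                        i += 1
    return SpectraSet(spectra, np.array(n_values))


def plant_outliers(spectra_set: SpectraSet, k: int, magnitude: float = 3.0,
                   rng: np.random.Generator | None = None) -> tuple[SpectraSet, list[str]]:
    """Multiply k random spectra by ``magnitude``; returns (contaminated set, planted ids).

    Test fixture for the PCA outlier screen: ground truth is returned so
    recovery can be scored.
    """
    n = len(spectra_set)
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    rng = rng if rng is not None else np.random.default_rng()
    idx = rng.choice(n, size=k, replace=False)
    X, _ = spectra_set.matrix(drop_masked=False)
    X = X.copy()
    X[idx] *= magnitude
    planted = [spectra_set.sample_ids[i] for i in sorted(idx)]
    return spectra_set.with_values(X), planted
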