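"""Pre-treatment chain for field leaf spectra.

Fixed order, each step logged in a :class:`PretreatmentRecord`:

    ratio to white reference -> replicate averaging -> (solar only:
    atmospheric band removal) -> unit-vector normalization ->
    PCA/Hotelling-T2 outlier elimination -> random calibration/validation
    split.

The outlier screen centres the spectra, projects onto the leading principal
components and flags samples whose Hotelling T2 on the scores exceeds the
(1-alpha) quantile of the in-sample reference distribution
T2 ~ (n-1)^2/n * Beta(k/2, (n-k-1)/2)
(the Beta form applies when the screened samples themselves estimated the
components; the familiar F form is for new observations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spectra import Mode, SpectraSet, Spectrum
from .synth import ATMOSPHERIC_WINDOWS

logger = logging.getLogger(__name__)


@dataclass
class PretreatmentRecord:
    """Audit trail: every removal/transformation sufficient to recount samples and bands."""

    steps: list[str] = field(default_factory=list)
    removed_band_ranges_nm: list[tuple[int, int]] = field(default_factory=list)
    n_bands_masked: int = 0
    removed_sample_ids: list[str] = field(default_factory=list)
    normalization_constants: dict[str, float] = field(default_factory=dict)

    def log(self, step: str) -> None:
        self.steps.append(step)
        logger.info("pretreatment: %s", step)

    def as_text(self) -> str:
        lines = ["# pretreatment record"] + [f"- {s}" for s in self.steps]
        return "\n".join(lines) + "\n"


def ratio_to_reference(leaf_radiance: np.ndarray, white_radiance: np.ndarray) -> np.ndarray:
    """Reflectance = leaf radiance / white-standard radiance, elementwise."""
    leaf = np.asarray(leaf_radiance, dtype=float)
    white = np.asarray(white_radiance, dtype=float)
    if leaf.shape != white.shape:
        raise ValueError("leaf and reference radiance vectors differ in length")
    bad = np.flatnonzero(white <= 0)
    if bad.size:
        raise ValueError(f"non-positive white reference at band index {bad[0]}")
    return leaf / white


def average_replicates(scans: list[Spectrum]) -> Spectrum:
    """Per-band mean over replicate scans of one leaf (two points x five scans)."""
    if not scans:
        raise ValueError("no scans to average")
    leaf_ids = {s.meta.get("leaf_id", s.sample_id) for s in scans}
    if len(leaf_ids) != 1:
        raise ValueError(f"mixed leaf ids in replicate set: {sorted(leaf_ids)}")
    grid = scans[0].grid
    for s in scans:
        if s.grid != grid or s.mode != scans[0].mode:
            raise ValueError("replicates must share grid and mode")
    mean_vals = np.mean([s.values for s in scans], axis=0)
    mask = np.any([s.mask for s in scans], axis=0)
    meta = {k: v for k, v in scans[0].meta.items()
            if k not in ("scan", "point")}  # collapse to leaf level
    return Spectrum(leaf_ids.pop(), grid, mean_vals, scans[0].mode, meta, mask=mask)


def remove_atmospheric_bands(spectra_set: SpectraSet,
                             windows=ATMOSPHERIC_WINDOWS,
                             record: PretreatmentRecord | None = None) -> SpectraSet:
    """Mask water-vapour windows for solar-mode sets; other modes pass through."""
    record = record if record is not None else PretreatmentRecord()
    if spectra_set.mode is not Mode.SOLAR_25DEG:
        logger.warning("remove_atmospheric_bands: mode %s needs no removal; set unchanged",
                       spectra_set.mode.value)
        record.log(f"atmospheric removal skipped (mode {spectra_set.mode.value})")
        return spectra_set
    wl = spectra_set.grid.wavelengths
    mask = spectra_set.mask.copy()
    for lo, hi in windows:
        if lo < spectra_set.grid.start_nm or hi > spectra_set.grid.end_nm:
            raise ValueError(f"window {lo}-{hi} nm outside {spectra_set.grid}")
        mask |= (wl >= lo) & (wl <= hi)
    X, _ = spectra_set.matrix(drop_masked=False)
    out = spectra_set.with_values(X, mask=mask)
    n_masked = int(mask.sum())
    record.removed_band_ranges_nm.extend([tuple(w) for w in windows])
    record.n_bands_masked = n_masked
    record.log(f"masked {n_masked} bands in windows {list(windows)}")
    return out


def normalize_spectrum(spectrum: Spectrum,
                       record: PretreatmentRecord | None = None) -> Spectrum:
    """Unit-vector (Euclidean) normalization over unmasked bands."""
    valid = spectrum.values[~spectrum.mask]
    norm = float(np.linalg.norm(valid))
    if norm == 0.0:
        raise ValueError(f"all-zero spectrum {spectrum.sample_id} cannot be normalized")
    vals = spectrum.values / norm
    if record is not None:
        record.normalization_constants[spectrum.sample_id] = norm
    return Spectrum(spectrum.sample_id, spectrum.grid, vals, spectrum.mode,
                    dict(spectrum.meta), mask=spectrum.mask.copy())


def normalize_set(spectra_set: SpectraSet,
                  record: PretreatmentRecord | None = None) -> SpectraSet:
    out = SpectraSet([normalize_spectrum(s, record) for s in spectra_set],
                     spectra_set.n_gkg.copy())
    if record is not None:
        record.log(f"unit-vector normalization of {len(out)} spectra")
    return out


def pca_outlier_screen(spectra_set: SpectraSet, k_components: int = 5,
                       alpha: float = 0.005, max_removed_fraction: float = 0.05,
                       record: PretreatmentRecord | None = None
                       ) -> tuple[SpectraSet, list[str]]:
    """Hotelling-T2 screen on the leading principal components.

    Removes samples with T2 above the (1-alpha) quantile of the in-sample
    Beta reference; raises if more than ``max_removed_fraction`` of the set
    would go (degenerate dataset).
    """
    n = len(spectra_set)
    if n <= 2:
        raise ValueError("need more than 2 samples for a covariance estimate")
    if not (1 <= k_components < n):
        raise ValueError("require n > k_components >= 1")
    X, _ = spectra_set.matrix(drop_masked=True)
    Xc = X - X.mean(axis=0)
    # economy SVD: scores = U*S, per-component variance S^2/(n-1)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    if np.sum(S > 1e-12) < k_components:
        raise ValueError("rank below requested number of components")
    scores = U[:, :k_components] * S[:k_components]
    var = (S[:k_components] ** 2) / (n - 1)
    t2 = np.sum(scores**2 / var, axis=1)
    crit = ((n - 1) ** 2 / n
            * stats.beta.ppf(1 - alpha, k_components / 2, (n - k_components - 1) / 2))
    flagged = np.flatnonzero(t2 > crit)
    if flagged.size > max_removed_fraction * n:
        raise ValueError(
            f"outlier screen would remove {flagged.size}/{n} samples "
            f"(> {max_removed_fraction:.0%}); dataset looks degenerate")
    removed_ids = [spectra_set.sample_ids[i] for i in flagged]
    keep = [i for i in range(n) if i not in set(flagged.tolist())]
    kept = spectra_set.subset(keep)
    if record is not None:
        record.removed_sample_ids.extend(removed_ids)
        record.log(f"PCA/T2 screen (k={k_components}, alpha={alpha}): "
                   f"removed {len(removed_ids)} of {n}")
    return kept, removed_ids


def split_calibration_validation(spectra_set: SpectraSet, n_calibration: int,
                                 seed: int, record: PretreatmentRecord | None = None
                                 ) -> tuple[SpectraSet, SpectraSet]:
    """Uniform random partition without replacement, reproducible from seed."""
    n = len(spectra_set)
    if not (0 < n_calibration < n):
        raise ValueError(f"n_calibration must be in (0, {n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal = spectra_set.subset(sorted(perm[:n_calibration].tolist()))
    val = spectra_set.subset(sorted(perm[n_calibration:].tolist()))
    if record is not None:
        record.log(
            f"random split seed={seed}: calibration n={len(cal)} "
            f"(N {cal.n_gkg.mean():.1f}+/-{cal.n_gkg.std(ddof=1):.1f} g/kg), "
            f"validation n={len(val)} "
            f"(N {val.n_gkg.mean():.1f}+/-{val.n_gkg.std(ddof=1):.1f} g/kg)")
    return cal, val
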