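"""Exhaustive two-band spectral-index search against leaf N.

Three standard two-band indices built from reflectance R at bands l1, l2:

    DSI(l1, l2)  = R(l1) - R(l2)            difference
    RSI(l1, l2)  = R(l1) / R(l2)            ratio
    NDSI(l1, l2) = (R(l1) - R(l2)) / (R(l1) + R(l2))   normalized difference

The reduced-sampling search reads reflectance at 10 nm intervals over
350-2500 nm (216 bands) and, for every ordered band pair, regresses N on the
index by simple linear regression, recording R^2 (squared Pearson).  Ordered
pairs are retained because RSI is order-sensitive; DSI/NDSI matrices are
symmetric because R^2 is invariant under a sign flip of the regressor.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .spectra import MASK_SENTINEL, SpectraSet, WavelengthGrid


class IndexKind(str, Enum):
    DSI = "dsi"
    RSI = "rsi"
    NDSI = "ndsi"

    @classmethod
    def coerce(cls, value: "IndexKind | str") -> "IndexKind":
        if isinstance(value, IndexKind):
            return value
        try:
            return cls(str(value).lower())
        except ValueError as exc:
            raise ValueError(f"unknown index kind: {value!r}") from exc


def index_values(kind: IndexKind | str, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Index formula applied elementwise; zero denominators come out non-finite."""
    kind = IndexKind.coerce(kind)
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    if kind is IndexKind.DSI:
        return r1 - r2
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind is IndexKind.RSI:
            return np.where(r2 != 0, r1 / r2, np.nan)
        return np.where(r1 + r2 != 0, (r1 - r2) / (r1 + r2), np.nan)


def resample_to_interval(spectra_set: SpectraSet, interval_nm: int) -> SpectraSet:
    """Keep bands at start, start+interval, ... (exact band-centre values, no averaging)."""
    grid = spectra_set.grid
    if interval_nm % grid.step_nm != 0:
        raise ValueError(f"interval {interval_nm} nm not a multiple of grid step {grid.step_nm}")
    if interval_nm == grid.step_nm:
        return spectra_set
    wl = grid.wavelengths
    keep = (wl - grid.start_nm) % interval_nm == 0
    new_grid = WavelengthGrid(grid.start_nm, int(wl[keep][-1]), interval_nm)
    from .spectra import Spectrum  # local import to avoid cycle at module load
    out = [
        Spectrum(s.sample_id, new_grid, s.values[keep], s.mode, dict(s.meta),
                 mask=s.mask[keep])
        for s in spectra_set
    ]
    return SpectraSet(out, spectra_set.n_gkg.copy())


def compute_index(kind: IndexKind | str, spectra_set: SpectraSet,
                  lambda1_nm: float, lambda2_nm: float) -> np.ndarray:
    """Per-sample index values at two (unmasked) band centres."""
    i1 = spectra_set.grid.index_of(lambda1_nm)
    i2 = spectra_set.grid.index_of(lambda2_nm)
    mask = spectra_set.mask
    if mask[i1] or mask[i2]:
        raise ValueError("requested band is masked")
    X, _ = spectra_set.matrix(drop_masked=False)
    return index_values(kind, X[:, i1], X[:, i2])


@dataclass
class IndexSearchResult:
    """R^2 over all ordered band pairs for one index kind, plus the argmax."""

    kind: IndexKind
    wavelengths_nm: np.ndarray
    r2_matrix: np.ndarray              # (m, m), NaN on degenerate pairs
    best_pair: tuple[float, float]     # (l1, l2) nm
    best_r2: float
    best_model: tuple[float, float]    # slope, intercept of N ~ index


def _pairwise_r2(kind: IndexKind, R: np.ndarray, y: np.ndarray) -> np.ndarray:
    """R^2 (squared Pearson of index vs y) for all ordered band pairs.

    Loops over l1 rows, vectorizing over l2; NaN where the index is constant
    or any sample's index is non-finite (degenerate pair).
    """
    n, m = R.shape
    yc = y - y.mean()
    ss_y = yc @ yc
    out = np.full((m, m), np.nan)
    for i in range(m):
        V = index_values(kind, R[:, i][:, None], R)   # (n, m)
        ok = np.all(np.isfinite(V), axis=0)
        Vc = V - V.mean(axis=0)
        ss_v = np.einsum("ij,ij->j", Vc, Vc)
        cov = yc @ Vc
        good = ok & (ss_v > 1e-24) & (ss_y > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = cov**2 / (ss_v * ss_y)
        out[i, good] = r2[good]
    return out


def exhaustive_search(spectra_set: SpectraSet, kind: IndexKind | str,
                      interval_nm: int = 10) -> IndexSearchResult:
    """Score every ordered band pair by linear-regression R^2 against N.

    Ties broken toward the lexicographically smallest (l1, l2).
    """
    kind = IndexKind.coerce(kind)
    sub = resample_to_interval(spectra_set, interval_nm)
    X, wl = sub.matrix(drop_masked=True)
    y = sub.n_gkg
    r2 = _pairwise_r2(kind, X, y)
    if np.all(np.isnan(r2)):
        raise ValueError("no valid band pair (all degenerate)")
    flat = np.nanargmax(r2)            # row-major: first max = lexicographic smallest
    i, j = np.unravel_index(flat, r2.shape)
    v = index_values(kind, X[:, i], X[:, j])
    slope, intercept = np.polyfit(v, y, 1)
    return IndexSearchResult(
        kind=kind, wavelengths_nm=wl, r2_matrix=r2,
        best_pair=(float(wl[i]), float(wl[j])), best_r2=float(r2[i, j]),
        best_model=(float(slope), float(intercept)),
    )


def export_contour(result: IndexSearchResult, path, image_path=None) -> None:
    """Write the R^2 matrix as a delimited table labelled by nm; optional contour plot."""
    labels = [str(int(w)) for w in result.wavelengths_nm]
    df = pd.DataFrame(result.r2_matrix, index=labels, columns=labels)
    df.to_csv(path, na_rep=MASK_SENTINEL, float_format="%.10g",
              index_label="lambda1_nm")
    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5))
        w = result.wavelengths_nm
        cs = ax.contourf(w, w, result.r2_matrix.T, levels=12, cmap="viridis")
        fig.colorbar(cs, ax=ax, label=r"$R^2$")
        ax.set_xlabel(r"$\lambda_1$ (nm)")
        ax.set_ylabel(r"$\lambda_2$ (nm)")
        ax.set_title(f"{result.kind.value.upper()} vs leaf N")
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)


def import_contour(path) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`export_contour`: returns (wavelengths_nm, r2_matrix)."""
    df = pd.read_csv(path, index_col=0, na_values=[MASK_SENTINEL])
    wl = df.index.to_numpy(dtype=float)
    return wl, df.to_numpy(dtype=float)
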