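"""Domain containers for leaf spectral libraries.

A spectral library is a set of per-leaf reflectance (or transflectance)
vectors on a shared wavelength grid, aligned by sample id to a vector of
chemically measured nitrogen concentrations (g/kg).  All indexing is by
wavelength value in nm, never by raw array position, so coarsened grids
(e.g. 10 nm resampling) cannot silently misalign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel written to delimited files for masked bands.
MASK_SENTINEL = "NA"


class Mode(str, Enum):
    """Measurement geometry of a spectral library."""

    BLACK_BACKGROUND = "black_background"   # leaf clip, absolute reflectance
    WHITE_BACKGROUND = "white_background"   # leaf clip, transflectance
    SOLAR_25DEG = "solar_25deg"             # 25 deg bare fibre under sun

    @classmethod
    def coerce(cls, value: "Mode | str") -> "Mode":
        if isinstance(value, Mode):
            return value
        try:
            return cls(value)
        except ValueError as exc:
            raise ValueError(f"unknown measurement mode: {value!r}") from exc


class FormatError(ValueError):
    """Raised when a spectral table violates the expected layout."""


class AlignmentError(ValueError):
    """Raised when spectra and reference N values cannot be aligned by id."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform band-centre axis in nm (default 350-2500 nm at 1 nm: 2151 bands)."""

    start_nm: int
    end_nm: int
    step_nm: int

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.end_nm <= self.start_nm:
            raise ValueError("end_nm must exceed start_nm")
        if (self.end_nm - self.start_nm) % self.step_nm != 0:
            raise ValueError("grid span must be a multiple of step_nm")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.start_nm, self.end_nm + self.step_nm, self.step_nm)

    @property
    def n_bands(self) -> int:
        return (self.end_nm - self.start_nm) // self.step_nm + 1

    def index_of(self, wavelength_nm: float) -> int:
        """Position of a band centre; raises if not on the grid."""
        offset = wavelength_nm - self.start_nm
        idx, rem = divmod(offset, self.step_nm)
        if rem != 0 or not (0 <= idx < self.n_bands):
            raise KeyError(f"{wavelength_nm} nm is not a band centre of {self}")
        return int(idx)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"grid {self.start_nm}-{self.end_nm} nm @ {self.step_nm} nm"


DEFAULT_GRID = WavelengthGrid(350, 2500, 1)


@dataclass
class Spectrum:
    """One leaf measurement: a reflectance-like vector plus provenance."""

    sample_id: str
    grid: WavelengthGrid
    values: np.ndarray
    mode: Mode
    meta: dict = field(default_factory=dict)
    mask: np.ndarray | None = None  # True where a band has been removed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mode = Mode.coerce(self.mode)
        if self.values.shape != (self.grid.n_bands,):
            raise ValueError(
                f"values length {self.values.size} != grid band count {self.grid.n_bands}"
            )
        if self.mask is None:
            self.mask = np.zeros(self.grid.n_bands, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.grid.n_bands,):
                raise ValueError("mask length != grid band count")
        valid = self.values[~self.mask]
        if valid.size and np.nanmin(valid) < -1e-9:
            raise ValueError(f"negative reflectance in sample {self.sample_id}")

    def at(self, wavelength_nm: float) -> float:
        """Reflectance at a band centre (by wavelength, not position)."""
        i = self.grid.index_of(wavelength_nm)
        if self.mask[i]:
            raise ValueError(f"band {wavelength_nm} nm is masked in {self.sample_id}")
        return float(self.values[i])


class SpectraSet:
    """Ordered collection of spectra on one grid, id-aligned to N (g/kg).

    Construction verifies the alignment between spectra and the reference
    table by sample id; silent positional matching is never used.
    """

    def __init__(self, spectra: Sequence[Spectrum], n_gkg: Mapping[str, float] | Sequence[float]):
        spectra = list(spectra)
        if not spectra:
            raise ValueError("empty SpectraSet")
        grid = spectra[0].grid
        mode = spectra[0].mode
        for s in spectra:
            if s.grid != grid:
                raise ValueError("all spectra must share one grid")
            if s.mode != mode:
                raise ValueError(
                    f"mixed measurement modes in one set: {s.mode} vs {mode}"
                )
        ids = [s.sample_id for s in spectra]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sample ids")
        if isinstance(n_gkg, Mapping):
            missing = [i for i in ids if i not in n_gkg]
            if missing:
                raise AlignmentError(f"missing N reference for samples: {missing[:5]}")
            n_vec = np.array([float(n_gkg[i]) for i in ids])
        else:
            n_vec = np.asarray(n_gkg, dtype=float)
            if n_vec.shape != (len(ids),):
                raise AlignmentError("N vector length != number of spectra")
        self.spectra = spectra
        self.n_gkg = n_vec
        self.grid = grid
        self.mode = mode

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    @property
    def mask(self) -> np.ndarray:
        """Union of per-spectrum masks (a band masked anywhere is masked for the set)."""
        m = np.zeros(self.grid.n_bands, dtype=bool)
        for s in self.spectra:
            m |= s.mask
        return m

    def matrix(self, drop_masked: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(X, wavelengths) design matrix; masked bands dropped (or error if not allowed)."""
        X = np.vstack([s.values for s in self.spectra])
        wl = self.grid.wavelengths
        if drop_masked:
            keep = ~self.mask
            return X[:, keep], wl[keep]
        if self.mask.any():
            raise ValueError("set contains masked bands; pass drop_masked=True")
        return X, wl

    def subset(self, indices: Iterable[int]) -> "SpectraSet":
        idx = list(indices)
        return SpectraSet([self.spectra[i] for i in idx], self.n_gkg[idx])

    def with_values(self, X: np.ndarray, mask: np.ndarray | None = None) -> "SpectraSet":
        """Copy of the set with replaced value matrix (same ids/meta/grid)."""
        if X.shape != (len(self), self.grid.n_bands):
            raise ValueError("value matrix shape mismatch")
        out = []
        for i, s in enumerate(self.spectra):
            out.append(
                Spectrum(s.sample_id, s.grid, X[i].copy(), s.mode, dict(s.meta),
                         mask=(s.mask if mask is None else mask.copy()))
            )
        return SpectraSet(out, self.n_gkg.copy())


# ---------------------------------------------------------------------------
# Delimited text I/O
# ---------------------------------------------------------------------------

_META_PREFIX = "meta_"
_N_COLUMN = "n_gkg"


def _parse_band_columns(columns: Sequence[str]) -> tuple[list[str], np.ndarray]:
    band_cols, wavelengths = [], []
    for c in columns:
        try:
            wavelengths.append(float(c))
            band_cols.append(c)
        except ValueError:
            continue
    if len(band_cols) < 2:
        raise FormatError("fewer than two numeric band columns found")
    wl = np.array(wavelengths)
    steps = np.diff(wl)
    if np.any(steps <= 0):
        raise FormatError("band columns are not strictly increasing in wavelength")
    if not np.allclose(steps, steps[0]):
        raise FormatError("band columns are not uniformly spaced")
    return band_cols, wl


def read_spectra_table(path, mode: Mode | str) -> SpectraSet:
    """Read a delimited spectral library.

    Layout: first column ``sample_id``, an ``n_gkg`` reference column,
    optional ``meta_*`` metadata columns, then one column per band labelled
    by its wavelength in nm.  Percent-scale reflectance (values > 1.5 over a
    mostly-vegetation spectrum) is auto-rescaled to fraction with a warning.
    """
    mode = Mode.coerce(mode)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str})
    except OSError as exc:
        raise OSError(f"cannot read spectral table {path}: {exc}") from exc
    if "sample_id" not in df.columns:
        raise FormatError("first column must be sample_id")
    band_cols, wl = _parse_band_columns(df.columns)
    step = wl[1] - wl[0]
    if step != int(step) or wl[0] != int(wl[0]):
        raise FormatError("band centres must lie on an integer nm grid")
    grid = WavelengthGrid(int(wl[0]), int(wl[-1]), int(step))

    if _N_COLUMN not in df.columns:
        raise AlignmentError(f"missing {_N_COLUMN} reference column")
    if df[_N_COLUMN].isna().any():
        bad = df.loc[df[_N_COLUMN].isna(), "sample_id"].tolist()
        raise AlignmentError(f"missing N for samples: {bad[:5]}")

    values = df[band_cols].to_numpy(dtype=float)
    mask = np.isnan(values)
    values = np.where(mask, 0.0, values)
    finite = values[~mask]
    if finite.size and np.median(finite[finite > 0]) > 1.5:
        logger.warning("values look percent-scaled (median > 1.5); rescaling to fraction")
        values = values / 100.0

    meta_cols = [c for c in df.columns if c.startswith(_META_PREFIX)]
    spectra = []
    for i, row in enumerate(df.itertuples(index=False)):
        meta = {c[len(_META_PREFIX):]: getattr(row, c) for c in meta_cols}
        spectra.append(
            Spectrum(getattr(row, "sample_id"), grid, values[i], mode, meta, mask=mask[i])
        )
    return SpectraSet(spectra, df[_N_COLUMN].to_numpy(dtype=float))


def write_spectra_table(spectra_set: SpectraSet, path) -> None:
    """Write a library in the layout ``read_spectra_table`` inverts.

    Masked bands are serialized as the ``NA`` sentinel and restored as
    masked on read.
    """
    grid = spectra_set.grid
    meta_keys: list[str] = []
    for s in spectra_set:
        for k in s.meta:
            if k not in meta_keys:
                meta_keys.append(k)
    records = []
    for s, n in zip(spectra_set, spectra_set.n_gkg):
        rec: dict = {"sample_id": s.sample_id, _N_COLUMN: n}
        for k in meta_keys:
            rec[_META_PREFIX + k] = s.meta.get(k, "")
        vals = s.values.astype(object)
        vals[s.mask] = np.nan
        for wl, v in zip(grid.wavelengths, vals):
            rec[str(int(wl))] = v
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    try:
        df.to_csv(path, index=False, na_rep=MASK_SENTINEL, float_format="%.12g")
    except OSError as exc:
        raise OSError(f"cannot write spectral table {path}: {exc}") from exc
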