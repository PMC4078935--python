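"""Spectral data model and preprocessing operators for NIRS calibration.

A :class:`SpectraSet` holds absorbance spectra on a shared wavelength grid,
with a replicate structure (several scans per liver sample). Preprocessing
follows the chemometric conventions of scanning-NIRS software: wavelength
trimming, replicate averaging, scatter correction (SNV, detrend, MSC) and
gap-segment derivatives with moving-average smoothing.

The canonical recipe used for fatty-liver melting-rate calibration is SNV
followed by a first derivative with a 10-point gap and 5-point smoothing,
applied after trimming to the 800-2500 nm near-infrared window.

Operator order is fixed as trim -> replicate average -> normalization ->
derivative/smoothing: the scatter correction acts on the raw absorbance
shape, the derivative on the corrected spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter


@dataclass
class SpectraSet:
    """Absorbance spectra on a common strictly increasing wavelength grid.

    values has shape (n_rows, n_wavelengths); each row is one scan,
    identified by (sample_id, replicate_id).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: np.ndarray
    replicate_ids: np.ndarray
    instrument: str = "surface"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids)
        self.replicate_ids = np.asarray(self.replicate_ids)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.values.shape[1] != len(self.wavelengths):
            raise ValueError("values width does not match wavelength grid")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain missing or non-finite values")

    @property
    def n_spectra(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "replicate", self.replicate_ids)
        df.insert(0, "sample", self.sample_ids)
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_spectra_csv(path, instrument: str = "surface") -> SpectraSet:
    """Read wide-format spectra (sample, replicate, one column per nm)."""
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c not in ("sample", "replicate")]
    return SpectraSet(
        wavelengths=np.array([float(c) for c in wl_cols]),
        values=df[wl_cols].to_numpy(float),
        sample_ids=df["sample"].to_numpy(),
        replicate_ids=df["replicate"].to_numpy(),
        instrument=instrument,
    )


@dataclass(frozen=True)
class PreprocessRecipe:
    """A composable preprocessing recipe.

    Parameters
    ----------
    derivative_order : 0, 1 or 2
    derivative_gap : gap-segment width in data points (>= 1 when order > 0)
    smooth_window : moving-average segment in data points (1 = none)
    normalization : "none", "snv", "detrend" or "msc"
    wavelength_window : (low, high) nm pair applied before everything else
    savitzky_golay : use a centered Savitzky-Golay derivative instead of the
        gap-segment convention (sensitivity-check variant)
    """

    derivative_order: int = 0
    derivative_gap: int = 1
    smooth_window: int = 1
    normalization: str = "none"
    wavelength_window: tuple = (800.0, 2500.0)
    savitzky_golay: bool = False

    def __post_init__(self):
        if self.derivative_order not in (0, 1, 2):
            raise ValueError("derivative order must be 0, 1 or 2")
        if self.derivative_gap < 1 or self.smooth_window < 1:
            raise ValueError("gap and smoothing window must be >= 1")
        if self.normalization not in ("none", "snv", "detrend", "msc"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def describe(self) -> str:
        return (
            f"d{self.derivative_order},gap{self.derivative_gap},"
            f"smooth{self.smooth_window},{self.normalization}"
        )


#: the recipe selected for melting-rate calibration: SNV then first
#: derivative over a 10-point gap with 5-point smoothing
DEFAULT_RECIPE = PreprocessRecipe(
    derivative_order=1, derivative_gap=10, smooth_window=5, normalization="snv"
)


def trim(spectra: SpectraSet, window_nm) -> SpectraSet:
    """Keep only wavelengths inside the closed interval ``window_nm``."""
    lo, hi = window_nm
    mask = (spectra.wavelengths >= lo) & (spectra.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"no wavelengths inside [{lo}, {hi}] nm")
    return replace(
        spectra, wavelengths=spectra.wavelengths[mask], values=spectra.values[:, mask]
    )


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Pointwise mean over replicates; one output spectrum per sample."""
    order = pd.unique(spectra.sample_ids)
    out = np.empty((len(order), len(spectra.wavelengths)))
    counts = np.empty(len(order), dtype=int)
    for i, sid in enumerate(order):
        rows = spectra.values[spectra.sample_ids == sid]
        out[i] = rows.mean(axis=0)
        counts[i] = rows.shape[0]
    meta = dict(spectra.meta, replicate_counts=dict(zip(order.tolist(), counts.tolist())))
    return SpectraSet(
        wavelengths=spectra.wavelengths,
        values=out,
        sample_ids=order,
        replicate_ids=np.zeros(len(order), dtype=int),
        instrument=spectra.instrument,
        meta=meta,
    )


def snv(values: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and unit-SD scaling.

    Removes multiplicative scatter and additive offset; invariant under any
    affine transform a*x + b (a > 0) of the input.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    sd = values.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum: SNV undefined")
    return (values - values.mean(axis=1, keepdims=True)) / sd


def detrend(values: np.ndarray, wavelengths: np.ndarray, degree: int = 2) -> np.ndarray:
    """Subtract a least-squares polynomial baseline (degree 2 by default)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    x = (wavelengths - wavelengths.mean()) / (np.ptp(wavelengths) or 1.0)
    V = np.vander(x, degree + 1)
    coef, *_ = np.linalg.lstsq(V, values.T, rcond=None)
    return values - (V @ coef).T


def msc(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed as x = a + b * reference; returns
    (x - a) / b, so a spectrum that is an affine transform of the reference
    is mapped back to the reference exactly.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ref = np.asarray(reference, dtype=float)
    if ref.std() == 0:
        raise ValueError("degenerate (constant) MSC reference")
    out = np.empty_like(values)
    rc = ref - ref.mean()
    denom = rc @ rc
    for i, x in enumerate(values):
        b = (rc @ (x - x.mean())) / denom
        if b == 0:
            raise ValueError("spectrum orthogonal to MSC reference")
        a = x.mean() - b * ref.mean()
        out[i] = (x - a) / b
    return out


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over ``window`` points; edges are dropped.

    Output width shrinks by window - 1; the surviving grid is the interior
    points for which the full segment exists.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if window <= 1:
        return values.copy()
    kernel = np.ones(window) / window
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, values)


def gap_segment_derivative(
    values: np.ndarray, order: int, gap: int, segment: int = 1
) -> np.ndarray:
    """Gap-segment derivative as used by scanning-NIRS calibration software.

    The first-derivative value at point i is the difference between the mean
    of a ``segment``-point block centered ``gap``/2 points to the right and
    the mean of the block to the left, divided by the gap; order 2 applies
    the same operator twice. Edge points without full support are dropped,
    so the output is shorter than the input (by order * (gap + segment - 1)
    points).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    out = values.copy()
    for _ in range(order):
        seg_means = moving_average(out, segment)  # width m - segment + 1
        if seg_means.shape[1] <= gap:
            raise ValueError("spectrum too short for requested gap/segment")
        out = (seg_means[:, gap:] - seg_means[:, :-gap]) / gap
    return out


def _derivative_trim_offsets(order: int, gap: int, segment: int) -> int:
    """Points dropped from each edge by the gap-segment derivative."""
    per_pass = (segment - 1) + gap
    return order * per_pass


def apply_recipe(spectra: SpectraSet, recipe: PreprocessRecipe) -> SpectraSet:
    """Apply a full preprocessing recipe; replicates must be averaged first
    if per-sample spectra are wanted (the recipe operates row-wise)."""
    s = trim(spectra, recipe.wavelength_window)
    vals = s.values
    wl = s.wavelengths
    if recipe.normalization == "snv":
        vals = snv(vals)
    elif recipe.normalization == "detrend":
        vals = detrend(vals, wl)
    elif recipe.normalization == "msc":
        vals = msc(vals, vals.mean(axis=0))
    if recipe.derivative_order > 0:
        if recipe.savitzky_golay:
            width = max(recipe.derivative_gap + recipe.smooth_window, 5)
            if width % 2 == 0:
                width += 1
            vals = savgol_filter(
                vals, width, polyorder=min(3, width - 1),
                deriv=recipe.derivative_order, axis=1,
            )
        else:
            vals = gap_segment_derivative(
                vals, recipe.derivative_order, recipe.derivative_gap,
                recipe.smooth_window,
            )
            drop = _derivative_trim_offsets(
                recipe.derivative_order, recipe.derivative_gap, recipe.smooth_window
            )
            # centered mapping: derivative value i sits between the two
            # segment centers; index by the midpoint of its support
            lo = drop // 2
            wl = wl[lo : lo + vals.shape[1]]
    elif recipe.smooth_window > 1:
        vals = moving_average(vals, recipe.smooth_window)
        lo = (recipe.smooth_window - 1) // 2
        wl = wl[lo : lo + vals.shape[1]]
    return replace(spectra, wavelengths=wl, values=vals)
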