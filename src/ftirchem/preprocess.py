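"""Spectral conditioning chain for fingerprint-region ATR spectra.

Order of operations: crop to the fingerprint region, per-spectrum
normalization, moving-average smoothing, Savitzky-Golay second derivative
(11 points by default).  Autoscaling (per-variable mean 0 / sd 1, learned
on training data only) is a separate step applied inside model fitting.

The derivative step both resolves overlapping bands and suppresses additive
baseline terms; the normalization step removes multiplicative scatter.
Band maxima appear as negative minima in the second derivative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectraSet, WavenumberGrid

__all__ = [
    "PreprocessConfig",
    "Scaler",
    "crop_region",
    "normalize",
    "normalize_set",
    "moving_average",
    "sg_second_derivative",
    "fit_scaler",
    "apply_scaler",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    region: tuple[float, float] = (1000.0, 1500.0)
    normalization: str = "vector"      # "vector" | "snv" | "none"
    ma_window: int = 5
    sg_window: int = 11
    sg_polyorder: int = 3
    derivative_order: int = 2          # 0 skips the derivative step

    def __post_init__(self) -> None:
        lo, hi = self.region
        if not lo < hi:
            raise ValueError("region must satisfy lo < hi")
        if self.ma_window % 2 == 0 or self.ma_window < 1:
            raise ValueError("ma_window must be a positive odd integer")
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must exceed sg_polyorder")
        if self.normalization not in ("vector", "snv", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.derivative_order not in (0, 2):
            raise ValueError("derivative_order must be 0 (skip) or 2")


def crop_region(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Retain grid points with lo <= nu <= hi (closed interval)."""
    mask = (s.grid.values >= lo) & (s.grid.values <= hi)
    if not mask.any():
        raise ValueError(f"crop [{lo}, {hi}] leaves no grid points")
    grid = WavenumberGrid(values=s.grid.values[mask], step=s.grid.step)
    return s.with_absorbance(s.absorbance[:, mask], f"crop:[{lo},{hi}]", grid=grid)


def normalize(row: np.ndarray, mode: str, sample: str = "?") -> np.ndarray:
    """Normalize one spectrum: unit Euclidean norm ("vector") or SNV."""
    row = np.asarray(row, dtype=float)
    if mode == "none":
        return row.copy()
    if mode == "vector":
        nrm = np.linalg.norm(row)
        if nrm == 0:
            raise ValueError(f"cannot vector-normalize all-zero spectrum {sample!r}")
        return row / nrm
    if mode == "snv":
        sd = row.std(ddof=1)
        if sd == 0:
            raise ValueError(f"cannot SNV-normalize constant spectrum {sample!r}")
        return (row - row.mean()) / sd
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize_set(s: SpectraSet, mode: str) -> SpectraSet:
    if mode == "none":
        return s.with_absorbance(s.absorbance.copy(), "normalize:none")
    out = np.empty_like(s.absorbance)
    for i in range(s.n_samples):
        out[i] = normalize(s.absorbance[i], mode, sample=s.sample_ids[i])
    return s.with_absorbance(out, f"normalize:{mode}")


def moving_average(row: np.ndarray, window: int) -> np.ndarray:
    """Centered mean filter; near the edges the window shrinks symmetrically."""
    if window % 2 == 0 or window < 1:
        raise ValueError("moving-average window must be a positive odd integer")
    row = np.asarray(row, dtype=float)
    n = row.shape[-1]
    if window > n:
        raise ValueError("window exceeds spectrum length")
    if window == 1:
        return row.copy()
    half = window // 2
    csum = np.concatenate(
        [np.zeros(row.shape[:-1] + (1,)), np.cumsum(row, axis=-1)], axis=-1
    )
    idx = np.arange(n)
    k = np.minimum(half, np.minimum(idx, n - 1 - idx))
    return (csum[..., idx + k + 1] - csum[..., idx - k]) / (2 * k + 1)


def sg_second_derivative(row: np.ndarray, window: int, polyorder: int,
                         step: float) -> np.ndarray:
    """Savitzky-Golay second derivative w.r.t. wavenumber (units AU cm^2).

    Interior points are exact for polynomials up to ``polyorder``; the edge
    points come from evaluating the polynomial fitted to the one-sided end
    window.  Dividing by the squared grid step makes the result invariant
    to the data interval.
    """
    if window % 2 == 0 or window <= polyorder or polyorder < 2:
        raise ValueError("require odd window > polyorder >= 2")
    if step <= 0:
        raise ValueError("grid step must be positive")
    return savgol_filter(
        np.asarray(row, dtype=float), window_length=window, polyorder=polyorder,
        deriv=2, delta=step, mode="interp", axis=-1,
    )


@dataclass
class Scaler:
    """Per-variable autoscaling parameters learned on a training set."""

    mean: np.ndarray
    sd: np.ndarray
    wavenumbers: np.ndarray = field(repr=False)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def fit_scaler(train: SpectraSet | np.ndarray) -> Scaler:
    """Learn column means and sds (n-1 denominator) from training spectra.

    Zero-variance columns get sd 1 with a warning: after centering they
    carry no information and must not blow up the scaling.
    """
    if isinstance(train, SpectraSet):
        X, nus = train.absorbance, train.grid.values
    else:
        X = np.asarray(train, dtype=float)
        nus = np.arange(X.shape[1], dtype=float)
    if X.shape[0] < 2:
        raise ValueError("autoscaling requires at least 2 training samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    flat = sd <= 1e-10 * np.maximum(1.0, np.abs(mean))
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance column(s); their sd set to 1",
            stacklevel=2,
        )
        sd = np.where(flat, 1.0, sd)
    return Scaler(mean=mean, sd=sd, wavenumbers=np.asarray(nus, dtype=float))


def apply_scaler(scaler: Scaler, s: SpectraSet) -> SpectraSet:
    if scaler.mean.size != len(s.grid):
        raise ValueError("scaler was fitted on a different grid")
    return s.with_absorbance(scaler.transform(s.absorbance), "autoscale")


def preprocess(s: SpectraSet, cfg: PreprocessConfig) -> SpectraSet:
    """Crop -> normalize -> moving average -> S-G second derivative.

    Every step is per-spectrum, so the chain is independent of how samples
    are split into training and test sets; autoscaling is deliberately NOT
    part of this chain and is fitted on training data inside each model.
    """
    out = crop_region(s, *cfg.region)
    out = normalize_set(out, cfg.normalization)
    if cfg.ma_window > 1:
        out = out.with_absorbance(
            moving_average(out.absorbance, cfg.ma_window), f"moving_average:{cfg.ma_window}"
        )
    if cfg.derivative_order == 2:
        if not out.grid.is_uniform:
            raise ValueError("S-G derivative requires a uniform wavenumber grid")
        out = out.with_absorbance(
            sg_second_derivative(out.absorbance, cfg.sg_window, cfg.sg_polyorder,
                                 out.grid.step),
            f"sg_deriv2:w={cfg.sg_window},poly={cfg.sg_polyorder}",
        )
    return out
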