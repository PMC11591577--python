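"""In-memory containers for ATR-FTIR spectra.

A :class:`SpectraSet` couples an absorbance matrix (samples x grid points)
with a :class:`WavenumberGrid`, per-sample metadata and a provenance trail.
Every processing stage consumes and produces a ``SpectraSet``, so the trail
records the full conditioning history of the data it carries.

The on-disk dialect is a wide CSV: ``sample_id,group,<nu1>,<nu2>,...`` with
wavenumber column labels in descending order, one row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Tolerance used when matching a wavenumber to a grid point (cm^-1).
GRID_MATCH_TOL = 1e-6


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly descending wavenumber axis in cm^-1.

    Stored high-to-low, the convention of mid-IR spectrometers.  The default
    axis spans the fingerprint region 1500-1000 cm^-1 at a 0.5 cm^-1 data
    interval (1001 points), so band positions printed at half-wavenumber
    granularity are addressable exactly.
    """

    values: np.ndarray
    step: float = 0.5

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("wavenumber grid must be a non-empty 1-D array")
        diffs = np.diff(vals)
        if not (np.all(diffs < 0) or np.all(diffs > 0)):
            raise ValueError("wavenumber grid must be strictly monotone")
        if np.any(diffs > 0):  # ascending input: store descending
            object.__setattr__(self, "values", vals[::-1].copy())

    @classmethod
    def default(cls, lo: float = 1000.0, hi: float = 1500.0, step: float = 0.5) -> "WavenumberGrid":
        n = int(round((hi - lo) / step)) + 1
        return cls(values=hi - step * np.arange(n), step=step)

    def __len__(self) -> int:
        return self.values.size

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.values)
        return bool(np.allclose(d, d[0], rtol=0, atol=1e-9))

    def index_of(self, nu: float) -> int:
        """Exact column index of wavenumber ``nu`` (error if off-grid)."""
        hits = np.flatnonzero(np.abs(self.values - nu) <= GRID_MATCH_TOL)
        if hits.size != 1:
            raise KeyError(f"wavenumber {nu} cm^-1 is not on the grid")
        return int(hits[0])

    def contains(self, nu: float) -> bool:
        return bool(np.any(np.abs(self.values - nu) <= GRID_MATCH_TOL))


@dataclass
class SpectraSet:
    """Absorbance matrix plus sample metadata on a shared wavenumber grid.

    ``absorbance`` holds raw AU before derivative processing and derivative
    units (AU cm^2) afterwards; ``provenance`` records which is which.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    sample_ids: list[str]
    groups: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x grid points)")
        n, p = self.absorbance.shape
        if p != len(self.grid):
            raise ValueError(
                f"absorbance has {p} columns but the grid has {len(self.grid)} points"
            )
        if len(self.sample_ids) != n or self.groups.size != n:
            raise ValueError("sample_ids/groups length must match the number of rows")
        if np.isnan(self.absorbance).any():
            raise ValueError("absorbance matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.groups.tolist()))

    def with_absorbance(self, matrix: np.ndarray, note: str,
                        grid: WavenumberGrid | None = None) -> "SpectraSet":
        """New set with replaced matrix and one provenance entry appended."""
        return SpectraSet(
            grid=grid if grid is not None else self.grid,
            absorbance=matrix,
            sample_ids=list(self.sample_ids),
            groups=self.groups.copy(),
            provenance=[*self.provenance, note],
        )

    def subset_groups(self, keep: list[str]) -> "SpectraSet":
        missing = set(keep) - set(self.groups.tolist())
        if missing:
            raise KeyError(f"groups not present in the set: {sorted(missing)}")
        mask = np.isin(self.groups, list(keep))
        return self.take(np.flatnonzero(mask))

    def take(self, rows: np.ndarray) -> "SpectraSet":
        rows = np.asarray(rows, dtype=int)
        return SpectraSet(
            grid=self.grid,
            absorbance=self.absorbance[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            groups=self.groups[rows],
            provenance=list(self.provenance),
        )

    def group_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.groups == label)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.absorbance, columns=[f"{v:g}" for v in self.grid.values])
        df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraSet":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id" or df.columns[1] != "group":
            raise ValueError("expected wide CSV starting with sample_id,group columns")
        nus = np.array([float(c) for c in df.columns[2:]])
        step = float(np.median(np.abs(np.diff(nus)))) if nus.size > 1 else 0.5
        grid = WavenumberGrid(values=nus, step=step)
        mat = df.iloc[:, 2:].to_numpy(dtype=float)
        if np.any(np.diff(nus) > 0):  # grid was stored ascending: flip data too
            mat = mat[:, ::-1]
        return cls(
            grid=grid,
            absorbance=mat,
            sample_ids=df["sample_id"].astype(str).tolist(),
            groups=df["group"].to_numpy(dtype=object),
            provenance=[f"loaded:{path}"],
        )
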