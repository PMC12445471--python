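"""Equi-volume cortical depth binning.

A cortical column is modeled with local cross-sectional area varying linearly
with normalized depth from the inner (white) boundary area ``A_in`` at depth 0
to the outer (pial) area ``A_out`` at depth 1.  Equi-volume depth surfaces are
placed so each bin encloses the same tissue volume, which pushes boundaries
toward the thinner end of the column (gyral crowns vs sulcal fundi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ColumnGeometry",
    "DepthBinning",
    "equivolume_depth",
    "bin_boundaries",
    "trim_bins",
    "assign_depth_bins",
    "read_geometry_csv",
]

# relative |A_out - A_in| below which the closed form is replaced by rho=alpha
FLAT_TOL = 1e-9


@dataclass(frozen=True)
class ColumnGeometry:
    """Local column geometry: boundary areas (mm^2) and thickness (mm)."""

    A_in: float
    A_out: float
    thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.A_in <= 0 or self.A_out <= 0:
            raise ValueError("boundary areas must be positive")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass(frozen=True)
class DepthBinning:
    """Depth-bin boundaries as normalized depth fractions.

    ``boundaries`` has ``n_bins + 1`` strictly increasing entries; depth 0 is
    the inner (white) boundary and bin 1 is the deepest bin (``direction``
    records this convention explicitly).  For an untrimmed binning the
    boundaries span [0, 1]; a trimmed binning covers the middle sub-interval
    that remains after dropping the first and last bins of a 7-bin solution.
    """

    n_bins: int
    boundaries: np.ndarray
    trimmed: bool = False
    direction: str = "deep_to_superficial"

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        if len(b) != self.n_bins + 1:
            raise ValueError("boundaries must have n_bins + 1 entries")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if not self.trimmed and (abs(b[0]) > 1e-12 or abs(b[-1] - 1.0) > 1e-12):
            raise ValueError("untrimmed boundaries must span [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, self.n_bins + 1),
                "rho_lower": self.boundaries[:-1],
                "rho_upper": self.boundaries[1:],
                "trimmed": self.trimmed,
                "direction": self.direction,
            }
        )


def equivolume_depth(alpha, geom: ColumnGeometry):
    """Depth fraction ``rho`` enclosing volume fraction ``alpha`` of the column.

    With area ``A(rho) = A_in + (A_out - A_in) * rho`` the cumulative volume is
    quadratic in ``rho``; inverting gives the closed form
    ``rho = (-A_in + sqrt(alpha*A_out^2 + (1-alpha)*A_in^2)) / (A_out - A_in)``,
    degrading gracefully to ``rho = alpha`` in the flat-cortex limit.
    Accepts scalars or arrays of ``alpha``.
    """
    a = np.asarray(alpha, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("alpha must lie in [0, 1]")
    ai, ao = geom.A_in, geom.A_out
    if abs(ao - ai) < FLAT_TOL * max(ai, ao):
        rho = a.copy()
    else:
        rho = (-ai + np.sqrt(a * ao**2 + (1.0 - a) * ai**2)) / (ao - ai)
    rho = np.clip(rho, 0.0, 1.0)
    return rho if rho.ndim else float(rho)


def bin_boundaries(n_bins: int, geom: ColumnGeometry) -> DepthBinning:
    """Equi-volume boundaries for ``n_bins`` bins: each holds 1/n_bins of volume."""
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    alphas = np.arange(n_bins + 1) / n_bins
    return DepthBinning(n_bins=n_bins, boundaries=equivolume_depth(alphas, geom))


def trim_bins(binning: DepthBinning) -> DepthBinning:
    """Drop the first and last of 7 equi-volume bins, keeping the middle 5.

    Retained bins are renumbered 1..5 from deep to superficial; each still
    holds 1/7 of the column volume.
    """
    if binning.n_bins != 7:
        raise ValueError(f"trim_bins requires a 7-bin input, got {binning.n_bins}")
    if binning.trimmed:
        raise ValueError("binning is already trimmed")
    return DepthBinning(
        n_bins=5,
        boundaries=binning.boundaries[1:-1],
        trimmed=True,
        direction=binning.direction,
    )


def assign_depth_bins(depths, binning: DepthBinning) -> np.ndarray:
    """Map normalized metric depths to 1-based bin labels (1 = deepest).

    The bin intervals are left-closed, right-open except the last, which is
    closed.  For a trimmed binning, depths outside the retained interval get
    label 0 (trimmed out).
    """
    d = np.atleast_1d(np.asarray(depths, dtype=float))
    if np.any((d < 0) | (d > 1)):
        raise ValueError("depths must lie in [0, 1]")
    b = binning.boundaries
    labels = np.searchsorted(b[1:-1], d, side="right") + 1
    labels[d == b[-1]] = binning.n_bins
    if binning.trimmed:
        labels = np.where((d < b[0]) | (d > b[-1]), 0, labels)
    return labels.astype(np.int64)


def read_geometry_csv(path: str) -> pd.DataFrame:
    """Read a column-geometry table with columns column_id, A_in, A_out, thickness."""
    df = pd.read_csv(path)
    required = {"column_id", "A_in", "A_out"}
    if not required <= set(df.columns):
        raise ValueError(f"geometry CSV must have columns {sorted(required)}")
    if "thickness" not in df.columns:
        df["thickness"] = 1.0
    return df
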