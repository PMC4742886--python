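"""Ensemble statistics over many translocation events.

Angle/coordinate tables pooled across events are turned into normalized
2D probability surfaces, per-frame ensemble labels (chimeric ap/P-pe/E,
head-tilted, endpoint states), per-ensemble means and standard deviations,
ensemble-average structures, FWHM of circular angle distributions, and
conditional mean curves (e.g. average tilt as a function of head rotation).

Default ensemble boundaries are read off the study's reported ranges:
ap/P-pe/E combines a highly rotated head (phi_head 14-20 deg) with a
partially translocated P-tRNA (R_P-ASL 4-6 A); the head-tilted (HT)
ensemble combines large tilt with a nearly back-rotated head. Standard
deviations use the population (n) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import kabsch_fit
from .structure_io import AtomGroup, Structure, Trajectory


class EnsembleError(ValueError):
    pass


@dataclass
class Histogram2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise EnsembleError("probabilities must sum to 1")
        if np.any(self.probabilities < 0):
            raise EnsembleError("negative probability")


@dataclass
class EnsembleDefinition:
    """A named conjunction of closed-interval constraints on coordinates."""

    name: str
    intervals: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for key, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise EnsembleError(f"{self.name}/{key}: interval not ordered")


def default_ensemble_definitions() -> list[EnsembleDefinition]:
    """Boundaries read off the study's reported ranges (priority-ordered)."""
    return [
        EnsembleDefinition("ap/P-pe/E", {"phi_head": (14.0, 20.0),
                                         "R_P-ASL": (4.0, 6.0)}),
        EnsembleDefinition("HT", {"theta_head": (6.0, np.inf),
                                  "phi_head": (-np.inf, 8.0)}),
        EnsembleDefinition("P/P-E/E", {"R_P-ASL": (0.0, 2.0),
                                       "phi_head": (-3.0, 3.0),
                                       "theta_head": (0.0, 3.0)}),
    ]


def histogram2d(x: np.ndarray, y: np.ndarray, bins: int | tuple = 50,
                filter: np.ndarray | None = None,
                range_: tuple | None = None) -> Histogram2D:
    """Normalized joint histogram over (optionally filtered) samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise EnsembleError("x and y must have equal length")
    if filter is not None:
        x, y = x[filter], y[filter]
    if len(x) == 0:
        raise EnsembleError("no samples left after filtering")
    counts, xe, ye = np.histogram2d(x, y, bins=bins, range=range_)
    return Histogram2D(xe, ye, counts, counts / counts.sum())


def assign_ensembles(series_table: pd.DataFrame,
                     definitions: list[EnsembleDefinition]) -> pd.Series:
    """First-matching-definition label per frame ('unassigned' if none)."""
    labels = pd.Series("unassigned", index=series_table.index, dtype=object)
    unassigned = np.ones(len(series_table), dtype=bool)
    for d in definitions:
        mask = np.ones(len(series_table), dtype=bool)
        for coord, (lo, hi) in d.intervals.items():
            if coord not in series_table.columns:
                raise EnsembleError(
                    f"ensemble {d.name!r} references missing coordinate {coord!r}")
            vals = series_table[coord].to_numpy(dtype=float)
            mask &= (vals >= lo) & (vals <= hi)
        take = mask & unassigned
        labels.iloc[take] = d.name
        unassigned &= ~mask
    return labels


def ensemble_stats(series_table: pd.DataFrame, labels: pd.Series,
                   columns: list[str] | None = None) -> pd.DataFrame:
    """Per-ensemble frame count, mean and population s.d. of each column.

    Singleton ensembles get NaN s.d. Index: ensemble label; columns:
    count plus (mean, sd) per coordinate.
    """
    if columns is None:
        columns = [c for c in series_table.columns if c not in ("frame", "time")]
    rows = {}
    for label, sub in series_table.groupby(labels.to_numpy()):
        row = {"count": len(sub)}
        for c in columns:
            vals = sub[c].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"{c}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{c}_sd"] = vals.std(ddof=0) if len(vals) > 1 else np.nan
        rows[label] = row
    return pd.DataFrame(rows).T


def average_structure(trajectory: Trajectory, labels: pd.Series | np.ndarray,
                      ensemble: str, alignment_group: AtomGroup,
                      parent: Structure) -> Structure:
    """Mean structure of an ensemble's frames after superposition.

    Frames are superposed on ``alignment_group`` to the parent reference
    coordinates, then averaged arithmetically; aligning to a fixed
    reference (rather than to any particular member) makes the result
    independent of frame ordering.
    """
    labels = np.asarray(labels)
    idx = np.nonzero(labels == ensemble)[0]
    if len(idx) == 0:
        raise EnsembleError(f"ensemble {ensemble!r} is empty")
    ref = parent.coords[alignment_group.members]
    acc = np.zeros_like(parent.coords)
    for k in idx:
        frame = trajectory.frames[k]
        fit = kabsch_fit(frame[alignment_group.members], ref)
        acc += fit.apply(frame)
    return parent.with_coords(acc / len(idx))


def rmsd_between(a: Structure, b: Structure, selection: AtomGroup) -> float:
    """Post-superposition RMSD over a selection (Angstrom)."""
    if a.n_atoms != b.n_atoms:
        raise EnsembleError(
            f"atom counts differ: {a.n_atoms} vs {b.n_atoms}")
    sel = selection.members
    return kabsch_fit(a.coords[sel], b.coords[sel]).rmsd


def fwhm(samples: np.ndarray, circular: bool = True, bandwidth: float = 2.0,
         grid_step: float = 0.5) -> float:
    """Full width at half maximum of a smoothed angle density (degrees).

    A fixed-bandwidth Gaussian kernel density is evaluated on a regular
    grid over (-180, 180]; circular data are handled by wrapping the
    kernel. The width is measured between the half-maximum crossings
    bracketing the global peak; a density with no such crossings raises.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if len(samples) < 100:
        raise EnsembleError("fwhm needs at least 100 samples")
    grid = np.arange(-180.0, 180.0 + grid_step / 2, grid_step)
    diff = grid[:, None] - samples[None, :]
    if circular:
        diff = (diff + 180.0) % 360.0 - 180.0
    dens = np.exp(-0.5 * (diff / bandwidth) ** 2).sum(axis=1)
    peak = int(np.argmax(dens))
    half = dens[peak] / 2.0

    def _cross(start: int, step: int) -> float:
        k = start
        while 0 <= k + step < len(grid):
            if dens[k + step] < half <= dens[k]:
                # linear interpolation between grid points
                f = (dens[k] - half) / (dens[k] - dens[k + step])
                return grid[k] + f * (grid[k + step] - grid[k])
            k += step
        raise EnsembleError("density never falls below half maximum; "
                            "FWHM undefined")

    return float(abs(_cross(peak, 1) - _cross(peak, -1)))


def conditional_mean(y: np.ndarray, x: np.ndarray,
                     bins: int | np.ndarray = 20) -> pd.DataFrame:
    """Mean of y per x-bin (e.g. average tilt as a function of rotation).

    Returns columns x_center, y_mean, count; empty bins have NaN mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise EnsembleError("x and y must have equal length")
    edges = (np.histogram_bin_edges(x, bins=bins)
             if np.isscalar(bins) else np.asarray(bins, dtype=float))
    which = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    centers = 0.5 * (edges[:-1] + edges[1:])
    means = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    for b in range(len(centers)):
        mask = which == b
        # samples exactly at the right edge belong to the last bin
        mask &= (x >= edges[0]) & (x <= edges[-1])
        counts[b] = mask.sum()
        if counts[b]:
            means[b] = y[mask].mean()
    return pd.DataFrame({"x_center": centers, "y_mean": means, "count": counts})
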