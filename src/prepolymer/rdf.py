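"""Radial pair distribution function, peak detection, lattice matching.

g(r) is computed between selected marker atoms (by default the C3' sugar
carbons) with minimum-image distances in an orthorhombic periodic box and
the standard three-dimensional shell normalization

    g(r_k) = n_k / (N * rho * V_shell(k)),   rho = (N - 1) / V_box,

where n_k counts ordered pairs in shell k, so g -> 1 at large r for a
homogeneous system.  For quasi-2-D monolayers the same normalization is
kept: peak positions, the quantity of interest, do not depend on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .synthetic import LatticeSpec
from .system import Configuration

__all__ = [
    "RDFResult",
    "PeakSet",
    "LatticeMatch",
    "compute_rdf",
    "find_peaks",
    "lattice_shell_distances",
    "match_lattice",
]


@dataclass(frozen=True)
class RDFResult:
    bin_centers: np.ndarray
    g_values: np.ndarray
    bin_width: float
    r_max: float
    n_particles: int
    raw_counts: np.ndarray  # ordered-pair counts per shell

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"r": self.bin_centers, "g": self.g_values})


@dataclass(frozen=True)
class PeakSet:
    positions: np.ndarray
    prominences: np.ndarray


@dataclass(frozen=True)
class LatticeMatch:
    candidate: Optional[LatticeSpec]
    rms_residual: float
    matched: bool


Selection = Union[str, Callable[[object], bool], None]


def _select_positions(config: Configuration, selection: Selection) -> np.ndarray:
    if selection is None:
        atoms = config.atoms
    elif callable(selection):
        atoms = [a for a in config.atoms if selection(a)]
    else:
        atoms = [a for a in config.atoms if a.name == selection]
    return np.array([a.position for a in atoms], dtype=float).reshape(-1, 3)


def _min_image_pdist(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Condensed minimum-image distance matrix (vectorized, O(n^2) memory)."""
    d = pos[:, None, :] - pos[None, :, :]
    d -= box * np.round(d / box)
    dist = np.linalg.norm(d, axis=-1)
    iu = np.triu_indices(len(pos), k=1)
    return dist[iu]


def compute_rdf(
    config: Configuration,
    selection: Selection = "C3'",
    bin_width: float = 0.1,
    r_max: float = 12.0,
) -> RDFResult:
    """g(r) between the selected atoms under periodic boundary conditions."""
    if config.box is None:
        raise ValueError("compute_rdf requires a periodic box")
    box = np.asarray(config.box, dtype=float)
    if r_max > box.min() / 2 + 1e-9:
        raise ValueError(
            f"r_max={r_max} exceeds half the smallest box edge ({box.min() / 2:.3f})"
        )
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    pos = _select_positions(config, selection)
    n = len(pos)
    if n < 2:
        raise ValueError("need at least two selected atoms")

    n_bins = int(round(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    dists = _min_image_pdist(pos, box)
    counts, _ = np.histogram(dists, bins=edges)
    ordered = 2 * counts.astype(float)

    volume = float(np.prod(box))
    rho = (n - 1) / volume
    shell_vol = (4.0 / 3.0) * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = ordered / (n * rho * shell_vol)

    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(
        bin_centers=centers,
        g_values=g,
        bin_width=bin_width,
        r_max=r_max,
        n_particles=n,
        raw_counts=ordered,
    )


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return y.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(y, kernel, mode="same")


def find_peaks(
    rdf: RDFResult, smoothing_window: int = 3, min_prominence: float = 0.5
) -> PeakSet:
    """Local maxima of the moving-average-smoothed g(r).

    Peaks are positions of bin centers whose smoothed value exceeds the
    prominence threshold; a flat profile yields an empty set.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    smoothed = _moving_average(rdf.g_values, smoothing_window)
    idx, props = _scipy_find_peaks(smoothed, prominence=min_prominence)
    return PeakSet(
        positions=rdf.bin_centers[idx], prominences=props["prominences"]
    )


def lattice_shell_distances(spec: LatticeSpec, n_shells: int = 3) -> np.ndarray:
    """First ``n_shells`` distinct neighbor-shell distances |i*a + j*b|.

    Enumerates integer combinations (i, j) != (0, 0) of the lattice vectors
    and returns the unique sorted distances, grouped to 1e-6 Å.
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    va, vb = spec.vectors
    sin_alpha = math.sin(math.radians(spec.alpha))
    m = n_shells + 2
    while True:
        ii, jj = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
        mask = (ii != 0) | (jj != 0)
        vecs = ii[mask].reshape(-1, 1) * va + jj[mask].reshape(-1, 1) * vb
        d = np.sort(np.linalg.norm(vecs, axis=1))
        uniq = [d[0]]
        for x in d[1:]:
            if x - uniq[-1] > 1e-6:
                uniq.append(x)
            if len(uniq) >= n_shells:
                break
        # any vector outside the +-m index window has norm >= m*min(a,b)*sin(alpha),
        # so the kept shells are complete once that bound exceeds the last one
        if len(uniq) >= n_shells and m * min(spec.a, spec.b) * sin_alpha > uniq[n_shells - 1]:
            return np.array(uniq[:n_shells])
        m *= 2


def match_lattice(
    peaks: PeakSet,
    candidates: Sequence[LatticeSpec],
    tolerance: float = 0.3,
) -> LatticeMatch:
    """Pick the candidate unit cell whose neighbor shells best explain the
    observed g(r) peaks.

    A candidate is eligible when every peak lies within ``tolerance`` of one
    of its shell distances; among eligible candidates the one with the
    smallest RMS |peak - nearest shell| wins, ties broken toward the
    candidate needing fewer shells.  With no eligible candidate a no-match
    result (candidate=None) is returned.
    """
    if not candidates:
        raise ValueError("need at least one candidate lattice")
    pos = np.asarray(peaks.positions, dtype=float)
    if pos.size == 0:
        raise ValueError("need at least one peak")

    best: Optional[tuple[float, int, LatticeSpec]] = None
    for cand in candidates:
        # enough shells to cover the outermost peak
        n_shells = 1
        shells = lattice_shell_distances(cand, n_shells)
        while shells[-1] < pos.max() + tolerance and n_shells < 64:
            n_shells += 1
            shells = lattice_shell_distances(cand, n_shells)
        resid = np.abs(pos[:, None] - shells[None, :]).min(axis=1)
        if np.any(resid > tolerance):
            continue
        used = len({int(np.argmin(np.abs(p - shells))) for p in pos})
        rms = float(np.sqrt(np.mean(resid**2)))
        key = (rms, used)
        if best is None or key < (best[0], best[1]):
            best = (rms, used, cand)

    if best is None:
        return LatticeMatch(candidate=None, rms_residual=float("nan"), matched=False)
    return LatticeMatch(candidate=best[2], rms_residual=best[0], matched=True)
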