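"""Interpolated surface property maps over a substrate slab.

Two map modes share one interpolation rule.  In donor/acceptor mode each
substrate oxygen carrying a bonded hydrogen is a hydrogen-bond donor and
gets a fictitious charge q = +1, each bare oxygen an acceptor with q = -1;
other substrate atoms are ignored.  In charge mode the user-supplied
partial charges are used directly and the mapped values are clipped to
+-0.1 by default.

The value at a map vertex is the inverse-square-distance weighted average

    value = sum_q w(q) * q,   w(q) = s(q) / s,   s(q) = 1 / d(vertex, q)^2,

with s the sum of the s(q) over all sites, so the weights sum to one and
the value is bounded by the charge range.  Vertices form a regular x-y grid
at a fixed normal offset above the topmost substrate atom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .system import Configuration, TopologyAnnotation

__all__ = [
    "ChargeSite",
    "PotentialMap",
    "assign_donor_acceptor",
    "weighted_potential",
    "potential_map",
]

#: vertices closer than this to a site make the 1/d^2 weight singular
EPSILON = 1e-6


@dataclass(frozen=True)
class ChargeSite:
    position: np.ndarray
    q: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not np.isfinite(self.q):
            raise ValueError("charge must be finite")


@dataclass(frozen=True)
class PotentialMap:
    x: np.ndarray  # grid x coordinates (nx,)
    y: np.ndarray  # grid y coordinates (ny,)
    z: float  # probe plane height
    values: np.ndarray  # (ny, nx)
    mode: str
    clip_limits: Optional[tuple[float, float]]

    def to_dataframe(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "value": self.values.ravel()}
        )

    def save_png(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        limit = np.nanmax(np.abs(self.values)) or 1.0
        im = ax.pcolormesh(
            self.x, self.y, self.values, cmap="RdBu_r", vmin=-limit, vmax=limit
        )
        ax.set_xlabel("x (Å)")
        ax.set_ylabel("y (Å)")
        ax.set_title(f"{self.mode} map at z = {self.z:.2f} Å")
        fig.colorbar(im, ax=ax, label="weighted potential")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def assign_donor_acceptor(
    config: Configuration, topo: TopologyAnnotation
) -> list[ChargeSite]:
    """Fictitious +-1 charges for the substrate's donor/acceptor oxygens.

    Substrate oxygens with a bonded hydrogen are donors (+1); bare oxygens
    are acceptors (-1); all other substrate atoms are skipped, so an inert
    (e.g. all-carbon) slab yields an empty site list.
    """
    sites = [
        ChargeSite(position=config.atoms[idx].position, q=+1.0)
        for idx, _hs in topo.substrate_donors
    ]
    sites += [
        ChargeSite(position=config.atoms[idx].position, q=-1.0)
        for idx in sorted(topo.substrate_acceptors)
    ]
    return sites


def weighted_potential(vertex: np.ndarray, sites: Sequence[ChargeSite]) -> float:
    """Inverse-square-distance weighted average of the site charges."""
    if not sites:
        raise ValueError("need at least one charge site")
    vertex = np.asarray(vertex, dtype=float)
    pos = np.array([s.position for s in sites])
    q = np.array([s.q for s in sites])
    d2 = np.sum((pos - vertex) ** 2, axis=1)
    if np.any(d2 < EPSILON**2):
        raise ValueError("vertex coincides with a charge site (singular weight)")
    w = 1.0 / d2
    return float(np.sum(w * q) / np.sum(w))


def _batch_potential(vertices: np.ndarray, sites: Sequence[ChargeSite]) -> np.ndarray:
    pos = np.array([s.position for s in sites])
    q = np.array([s.q for s in sites])
    d2 = np.sum((vertices[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    if np.any(d2 < EPSILON**2):
        raise ValueError("a map vertex coincides with a charge site")
    w = 1.0 / d2
    return np.sum(w * q, axis=1) / np.sum(w, axis=1)


def potential_map(
    config: Configuration,
    topo: Optional[TopologyAnnotation] = None,
    mode: str = "donor_acceptor",
    grid_spacing: float = 1.0,
    probe_offset: float = 1.4,
    clip_limits: tuple[float, float] = (-0.1, 0.1),
) -> PotentialMap:
    """Weighted-average property map on a regular grid above the slab.

    The probe plane sits ``probe_offset`` above the topmost substrate atom
    and spans the substrate's x-y extent.  ``mode='charge'`` interpolates
    user-supplied partial charges (clipped to ``clip_limits``);
    ``mode='donor_acceptor'`` interpolates the fictitious +-1 charges from
    :func:`assign_donor_acceptor` without clipping.
    """
    substrate = config.select("substrate")
    if not substrate:
        raise ValueError("configuration has no substrate atoms")
    if mode not in {"charge", "donor_acceptor"}:
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "charge":
        missing = [a.index for a in substrate if a.partial_charge is None]
        if missing:
            raise ValueError(
                f"{len(missing)} substrate atoms lack partial charges; supply them "
                "via a charge sidecar (CSV of atom index, charge) before mapping"
            )
        sites = [ChargeSite(position=a.position, q=float(a.partial_charge)) for a in substrate]
    else:
        if topo is None:
            raise ValueError("donor_acceptor mode requires a topology annotation")
        sites = assign_donor_acceptor(config, topo)
        if not sites:
            raise ValueError("substrate has no donor or acceptor sites (inert surface)")

    sub_pos = np.array([a.position for a in substrate])
    x0, x1 = sub_pos[:, 0].min(), sub_pos[:, 0].max()
    y0, y1 = sub_pos[:, 1].min(), sub_pos[:, 1].max()
    z = float(sub_pos[:, 2].max() + probe_offset)
    x = np.arange(x0, x1 + grid_spacing / 2, grid_spacing)
    y = np.arange(y0, y1 + grid_spacing / 2, grid_spacing)
    xx, yy = np.meshgrid(x, y)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)])

    values = _batch_potential(vertices, sites).reshape(len(y), len(x))
    clip = None
    if mode == "charge":
        values = np.clip(values, *clip_limits)
        clip = clip_limits
    return PotentialMap(x=x, y=y, z=z, values=values, mode=mode, clip_limits=clip)
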