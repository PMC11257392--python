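"""Deterministic synthetic inputs for metric-extraction and diffusion tests.

These generators build radial profiles and batch states with *known*
crossings or closed-form evolution, so the front-radius extraction and the
finite-volume diffusion operator can be checked against constructed ground
truth rather than against the simulator itself.
"""

from __future__ import annotations

import numpy as np

from .plaque import RadialField, RadialGrid
from .wellmixed import WellMixedState

__all__ = ["step_profile", "gaussian_profile", "batch_snapshot", "make_fixture", "heat_kernel_2d"]


def step_profile(
    grid: RadialGrid,
    crossing: float = 3000.0,
    lawn: float = 1.0 / 400.0,
    phage_level: float | None = None,
    N_stages: int = 10,
) -> RadialField:
    """Lawn destroyed (and phage present) inside ``crossing``, intact
    outside: every front radius sits at ``crossing`` up to one grid cell."""
    r = grid.r
    inside = r < crossing
    phage_level = 2.0 * lawn if phage_level is None else phage_level
    return RadialField(
        grid=grid,
        time=0.0,
        B=np.where(inside, 0.0, lawn),
        n=np.full(grid.M, 0.5),
        phage=np.where(inside, phage_level, 0.0),
        I=np.zeros((N_stages, grid.M)),
    )


def gaussian_profile(
    grid: RadialGrid, sigma: float = 500.0, total: float = 1.0
) -> np.ndarray:
    """Radially symmetric Gaussian with the given integral over the plane,
    evaluated at cell centres; the free-diffusion evolution of this profile
    is the 2-D heat kernel (see :func:`heat_kernel_2d`)."""
    r = grid.r
    prof = total / (2.0 * np.pi * sigma**2) * np.exp(-(r**2) / (2.0 * sigma**2))
    return prof


def heat_kernel_2d(r: np.ndarray, t: float, D: float, sigma0: float, total: float = 1.0) -> np.ndarray:
    """Closed-form evolution of a Gaussian under 2-D diffusion: a Gaussian
    with variance sigma0^2 + 2 D t."""
    s2 = sigma0**2 + 2.0 * D * t
    return total / (2.0 * np.pi * s2) * np.exp(-(r**2) / (2.0 * s2))


def batch_snapshot(
    N_stages: int = 10,
    B: float = 0.0,
    n: float = 0.0,
    R: float = 0.0,
    P: float = 0.0,
) -> WellMixedState:
    """Well-mixed state with empty latency chains; defaults to all-zero."""
    st = WellMixedState.zeros(N_stages)
    st.B, st.n, st.R, st.P = B, n, R, P
    return st


def make_fixture(kind: str, seed: int = 0, **params):
    """Dispatch by fixture kind: ``step_profile``, ``gaussian_profile`` or
    ``batch_snapshot``.  All fixtures are deterministic; ``seed`` is
    accepted for interface uniformity."""
    makers = {
        "step_profile": step_profile,
        "gaussian_profile": gaussian_profile,
        "batch_snapshot": batch_snapshot,
    }
    if kind not in makers:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(makers)}")
    return makers[kind](**params)
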