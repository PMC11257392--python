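"""Front radii of an expanding plaque and plaque-size ratio sweeps.

Four radii characterise the infection front of a radial snapshot:

* ``r_PB0`` — outermost radius where the free phage density equals the
  initial lawn density B0 (one phage per microcolony; the farthest point
  where infection is likely).
* ``r_super`` — outermost radius where free phage equals the *total* cell
  density; inside it secondary adsorptions (and hence lysis inhibition)
  dominate.
* ``r_half`` — outermost radius where the total cell density falls to half
  its value at the undisturbed outer edge: the visible plaque radius.
* ``r_ZOI`` — same as r_half but for uninfected cells only: the zone of
  infection, counting unlysed lysis-inhibited cells as infected.

All radii are located by scanning from the outer boundary inward and
linearly interpolating the first (outermost) sign change, which is robust
to the double-peaked phage profiles produced by delayed LIN bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .plaque import PlaqueParams, PlaqueResult, RadialField, simulate_plaque

__all__ = [
    "PlaqueMetrics",
    "front_radii",
    "metrics_trajectory",
    "plaque_ratio_sweep",
    "PlaqueRatioSweep",
]


@dataclass(frozen=True)
class PlaqueMetrics:
    """The four front radii (µm) of one snapshot; ``None`` marks a radius
    whose defining crossing does not exist in the profile."""

    time: float
    r_PB0: float | None
    r_super: float | None
    r_half: float | None
    r_ZOI: float | None


def _outermost_crossing(r: np.ndarray, diff: np.ndarray) -> float | None:
    """Outermost radius where ``diff`` changes sign, by linear interpolation
    between adjacent cell centres; None when no sign change exists."""
    s = np.sign(diff)
    for j in range(len(r) - 2, -1, -1):
        a, b = diff[j], diff[j + 1]
        if s[j] == 0.0:
            return float(r[j])
        if s[j] * s[j + 1] < 0:
            return float(r[j] + (r[j + 1] - r[j]) * a / (a - b))
    return None


def front_radii(
    snapshot: RadialField, B0: float, half_fraction: float = 0.5
) -> PlaqueMetrics:
    """Extract the four front radii from one radial snapshot.

    Reference densities for r_half and r_ZOI are taken from the outermost
    grid cell of the same snapshot (the undisturbed edge of the lawn), so
    the ongoing growth of the lawn is accounted for automatically.
    ``half_fraction`` is the visibility threshold; 0.5 means the clearing
    is called where the lawn drops to half the edge density.
    """
    if not 0.0 < half_fraction < 1.0:
        raise ValueError("half_fraction must lie in (0, 1)")
    r = snapshot.grid.r
    V = snapshot.phage
    B_tot = snapshot.B_tot
    B = snapshot.B
    return PlaqueMetrics(
        time=snapshot.time,
        r_PB0=_outermost_crossing(r, V - B0),
        r_super=_outermost_crossing(r, V - B_tot),
        r_half=_outermost_crossing(r, B_tot - half_fraction * B_tot[-1]),
        r_ZOI=_outermost_crossing(r, B - half_fraction * B[-1]),
    )


def metrics_trajectory(
    result: PlaqueResult, half_fraction: float = 0.5
) -> pd.DataFrame:
    """Front radii of every sampled snapshot of a plaque run."""
    B0 = result.params.B0
    rows = [front_radii(f, B0, half_fraction) for f in result.fields]
    return pd.DataFrame(
        {
            "time_min": [m.time for m in rows],
            "r_PB0": [m.r_PB0 for m in rows],
            "r_super": [m.r_super for m in rows],
            "r_half": [m.r_half for m in rows],
            "r_ZOI": [m.r_ZOI for m in rows],
        }
    )


@dataclass
class PlaqueRatioSweep:
    """LIN/r-mutant plaque-size ratios over an (f_tau, f_beta) grid."""

    f_tau_grid: np.ndarray
    f_beta_grid: np.ndarray
    r_half_ratio: np.ndarray  #: shape (len(f_tau_grid), len(f_beta_grid))
    r_ZOI_ratio: np.ndarray
    t_eval: float
    reference: PlaqueMetrics  #: the r-mutant metrics the ratios are normalised to
    errors: dict

    def frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = pd.Index(self.f_tau_grid, name="f_tau")
        cols = pd.Index(self.f_beta_grid, name="f_beta")
        return (
            pd.DataFrame(self.r_half_ratio, index=idx, columns=cols),
            pd.DataFrame(self.r_ZOI_ratio, index=idx, columns=cols),
        )


def _metrics_at(params: PlaqueParams, t_eval: float, half_fraction: float) -> PlaqueMetrics:
    res = simulate_plaque(params, sample_times=[0.0, t_eval])
    return front_radii(res.fields[-1], params.B0, half_fraction)


def plaque_ratio_sweep(
    f_tau_grid: Sequence[float],
    f_beta_grid: Sequence[float],
    params: PlaqueParams | None = None,
    t_eval: float = 300.0,
    half_fraction: float = 0.5,
) -> PlaqueRatioSweep:
    """Visible plaque radius and zone-of-infection ratios (LIN phage over
    r-mutant) at ``t_eval`` minutes, over an (f_tau, f_beta) grid.

    The r-mutant reference plaque is simulated once and reused for every
    grid cell.  Cells whose metric is absent (no crossing) or whose
    simulation fails are set to NaN and recorded in ``errors``.
    """
    f_tau_grid = np.asarray(f_tau_grid, dtype=float)
    f_beta_grid = np.asarray(f_beta_grid, dtype=float)
    if f_tau_grid.size == 0 or f_beta_grid.size == 0:
        raise ValueError("sweep grids must be nonempty")

    base = params if params is not None else PlaqueParams.default()
    if base.t_end < t_eval:
        base = dc_replace(base, t_end=t_eval)
    ref_params = dc_replace(
        base, wellmixed=dc_replace(base.wellmixed, model_id="M0", f_tau=1.0, f_beta=1.0)
    )
    ref = _metrics_at(ref_params, t_eval, half_fraction)
    if ref.r_half is None or ref.r_ZOI is None:
        raise ValueError("reference r-mutant plaque has no measurable front")

    shape = (f_tau_grid.size, f_beta_grid.size)
    half = np.full(shape, np.nan)
    zoi = np.full(shape, np.nan)
    errors: dict = {}
    for i, ft in enumerate(f_tau_grid):
        for j, fb in enumerate(f_beta_grid):
            cell = dc_replace(
                base,
                wellmixed=dc_replace(
                    base.wellmixed, model_id="M1", f_tau=ft, f_beta=fb
                ),
            )
            try:
                m = _metrics_at(cell, t_eval, half_fraction)
            except Exception as exc:
                errors[(i, j)] = str(exc)
                continue
            if m.r_half is not None:
                half[i, j] = m.r_half / ref.r_half
            else:
                errors.setdefault((i, j), "r_half absent")
            if m.r_ZOI is not None:
                zoi[i, j] = m.r_ZOI / ref.r_ZOI
            else:
                errors.setdefault((i, j), "r_ZOI absent")
    return PlaqueRatioSweep(
        f_tau_grid=f_tau_grid,
        f_beta_grid=f_beta_grid,
        r_half_ratio=half,
        r_ZOI_ratio=zoi,
        t_eval=t_eval,
        reference=ref,
        errors=errors,
    )
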