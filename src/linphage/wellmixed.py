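"""Well-mixed batch-culture models of phage growth with lysis inhibition.

Three deterministic ODE models share one state layout:

* ``M0`` — rapid-lysis mutant (r-mutant) only: free phage R infects
  uninfected bacteria B; infected cells traverse an N-stage Erlang latency
  chain and burst beta(n) phages.  Free phage adsorb to (and are removed
  by) *all* cells, infected or not.
* ``M1`` — lysis-inhibition (LIN) capable phage P only: identical to M0,
  except a secondary adsorption onto an infected cell moves it into a
  lysis-inhibited chain whose total latency is stretched by f_tau and whose
  burst is amplified by f_beta.
* ``MC1`` — both strains compete in one culture.  The first infection
  determines the progeny strain (superinfection exclusion); secondary
  adsorption of either strain (or, optionally, only of the LIN strain)
  triggers LIN in cells first infected by the LIN phage.

State vector (concentrations per mL):
``[B, n, R, P, I_R(1..N), I_P(1..N), L(1..N)]``;
compartments unused by a model are identically zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .response import NutrientResponseParams, burst_size, growth_rate, stage_rate

__all__ = [
    "WellMixedParams",
    "WellMixedState",
    "TimeSeries",
    "CompetitionOutcome",
    "SweepResult",
    "derivative",
    "simulate_batch",
    "final_phage_ratio_separate",
    "competition_outcome",
    "sweep_lin_grid",
    "default_batch_init",
]

ModelId = Literal["M0", "M1", "MC1"]
TriggerMode = Literal["any_phage", "lin_phage_only"]

#: Table-default initial concentrations (per mL).
DEFAULT_B0 = 1e6
DEFAULT_PHAGE0 = 1e3
DEFAULT_N0 = 1e9


@dataclass(frozen=True)
class WellMixedParams:
    """Full parameter set for one well-mixed model run."""

    response: NutrientResponseParams = field(default_factory=NutrientResponseParams)
    eta: float = 5e-10  #: adsorption rate constant (mL/min)
    f_tau: float = 1.0  #: LIN latency fold-extension (>= 1)
    f_beta: float = 1.0  #: LIN burst fold-increase (>= 1)
    trigger_mode: TriggerMode = "any_phage"
    model_id: ModelId = "M0"

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.f_tau < 1.0:
            raise ValueError(f"f_tau must be >= 1, got {self.f_tau}")
        if self.f_beta < 1.0:
            raise ValueError(f"f_beta must be >= 1, got {self.f_beta}")
        if self.trigger_mode not in ("any_phage", "lin_phage_only"):
            raise ValueError(f"unknown trigger_mode {self.trigger_mode!r}")
        if self.model_id not in ("M0", "M1", "MC1"):
            raise ValueError(f"unknown model_id {self.model_id!r}")


@dataclass
class WellMixedState:
    """Concentrations (per mL) of every compartment at one instant."""

    B: float
    n: float
    R: float
    P: float
    I_R: np.ndarray
    I_P: np.ndarray
    L: np.ndarray

    @classmethod
    def zeros(cls, N: int) -> "WellMixedState":
        return cls(0.0, 0.0, 0.0, 0.0, np.zeros(N), np.zeros(N), np.zeros(N))

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.B, self.n, self.R, self.P], self.I_R, self.I_P, self.L]
        )

    @classmethod
    def from_vector(cls, y: np.ndarray, N: int) -> "WellMixedState":
        y = np.asarray(y, dtype=float)
        if y.size != 4 + 3 * N:
            raise ValueError(f"state vector length {y.size} != {4 + 3 * N}")
        return cls(
            B=float(y[0]),
            n=float(y[1]),
            R=float(y[2]),
            P=float(y[3]),
            I_R=y[4 : 4 + N].copy(),
            I_P=y[4 + N : 4 + 2 * N].copy(),
            L=y[4 + 2 * N : 4 + 3 * N].copy(),
        )

    @property
    def B_tot(self) -> float:
        """Total intact cells: uninfected + infected + lysis-inhibited."""
        return self.B + float(self.I_R.sum() + self.I_P.sum() + self.L.sum())

    def validate(self, N: int, model_id: ModelId | None = None) -> None:
        vec = self.to_vector()
        if np.any(np.isnan(vec)):
            raise ValueError("state contains NaN")
        if np.any(vec < 0):
            raise ValueError("state components must be nonnegative")
        if len(self.I_R) != N or len(self.I_P) != N or len(self.L) != N:
            raise ValueError(f"staged vectors must have length {N}")
        if model_id == "M0" and (self.P > 0 or self.I_P.any() or self.L.any()):
            raise ValueError("M0 carries no LIN-phage compartments (P, I_P, L)")
        if model_id == "M1" and (self.R > 0 or self.I_R.any()):
            raise ValueError("M1 carries no r-mutant compartments (R, I_R)")


def default_batch_init(
    params: WellMixedParams,
    B0: float = DEFAULT_B0,
    R0: float | None = None,
    P0: float | None = None,
    n0: float | None = None,
) -> WellMixedState:
    """Table-default initial state for the given model.

    M0 seeds only R, M1 only P; MC1 seeds both strains at the default phage
    level each unless overridden.
    """
    N = params.response.N_stages
    st = WellMixedState.zeros(N)
    st.B = B0
    st.n = params.response.n_ref if n0 is None else n0
    if params.model_id == "M0":
        st.R = DEFAULT_PHAGE0 if R0 is None else R0
    elif params.model_id == "M1":
        st.P = DEFAULT_PHAGE0 if P0 is None else P0
    else:
        st.R = DEFAULT_PHAGE0 if R0 is None else R0
        st.P = DEFAULT_PHAGE0 if P0 is None else P0
    return st


def _rhs(t: float, y: np.ndarray, p: WellMixedParams) -> np.ndarray:
    """Time derivative of the packed state vector.

    One general right-hand side covers all three models: with the unused
    strain's compartments identically zero the M0/M1 equations are exact
    restrictions of the MC1 system.
    """
    rp = p.response
    N = rp.N_stages
    # Rates are evaluated on the nonnegative part; the integrator may probe
    # slightly negative values near extinction.
    yc = np.maximum(y, 0.0)
    B, n, R, P = yc[0], yc[1], yc[2], yc[3]
    I_R = yc[4 : 4 + N]
    I_P = yc[4 + N : 4 + 2 * N]
    L = yc[4 + 2 * N : 4 + 3 * N]

    g = growth_rate(n, rp)
    k = stage_rate(n, rp, 1.0)  # N / tau(n)
    kL = k / p.f_tau  # N / (f_tau * tau(n))
    beta = burst_size(n, rp)
    eta = p.eta

    phi = R + P  # every free phage infects an uninfected cell on adsorption
    phi_trig = P if p.trigger_mode == "lin_phage_only" else R + P
    B_tot = B + I_R.sum() + I_P.sum() + L.sum()

    dy = np.empty_like(y)
    dy[0] = g * B - eta * phi * B  # division - infection
    dy[1] = -g * B  # nutrient consumed 1:1 with cell production

    dI_R = np.empty(N)
    dI_R[0] = eta * R * B - k * I_R[0]
    dI_R[1:] = k * (I_R[:-1] - I_R[1:])

    dI_P = np.empty(N)
    dI_P[0] = eta * P * B - eta * phi_trig * I_P[0] - k * I_P[0]
    dI_P[1:] = k * (I_P[:-1] - I_P[1:]) - eta * phi_trig * I_P[1:]

    dL = np.empty(N)
    dL[0] = eta * phi_trig * I_P.sum() - kL * L[0]
    dL[1:] = kL * (L[:-1] - L[1:])

    dy[2] = beta * k * I_R[-1] - eta * R * B_tot
    dy[3] = beta * k * I_P[-1] + p.f_beta * beta * kL * L[-1] - eta * P * B_tot
    dy[4 : 4 + N] = dI_R
    dy[4 + N : 4 + 2 * N] = dI_P
    dy[4 + 2 * N :] = dL
    return dy


def derivative(state: WellMixedState, params: WellMixedParams) -> WellMixedState:
    """Instantaneous rate of change of every compartment (per mL per min)."""
    N = params.response.N_stages
    state.validate(N, params.model_id)
    dy = _rhs(0.0, state.to_vector(), params)
    return WellMixedState.from_vector(dy, N)


@dataclass
class TimeSeries:
    """Sampled trajectory of a well-mixed run."""

    times: np.ndarray  #: sample times (min), strictly increasing
    Y: np.ndarray  #: state vectors, shape (len(times), 4 + 3N)
    N: int
    params: WellMixedParams

    def state_at(self, i: int) -> WellMixedState:
        return WellMixedState.from_vector(self.Y[i], self.N)

    @property
    def B(self) -> np.ndarray:
        return self.Y[:, 0]

    @property
    def n(self) -> np.ndarray:
        return self.Y[:, 1]

    @property
    def R(self) -> np.ndarray:
        return self.Y[:, 2]

    @property
    def P(self) -> np.ndarray:
        return self.Y[:, 3]

    @property
    def I_R_total(self) -> np.ndarray:
        return self.Y[:, 4 : 4 + self.N].sum(axis=1)

    @property
    def I_P_total(self) -> np.ndarray:
        return self.Y[:, 4 + self.N : 4 + 2 * self.N].sum(axis=1)

    @property
    def L_total(self) -> np.ndarray:
        return self.Y[:, 4 + 2 * self.N :].sum(axis=1)

    @property
    def B_tot(self) -> np.ndarray:
        return self.B + self.I_R_total + self.I_P_total + self.L_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "B": self.B,
                "n": self.n,
                "R": self.R,
                "P": self.P,
                "I_R_total": self.I_R_total,
                "I_P_total": self.I_P_total,
                "L_total": self.L_total,
                "B_tot": self.B_tot,
            }
        )


class IntegrationError(RuntimeError):
    """Integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time:g} min)")
        self.last_time = last_time


def simulate_batch(
    params: WellMixedParams,
    init: WellMixedState | None = None,
    t_end: float = 1200.0,
    sample_times: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    method: str = "LSODA",
) -> TimeSeries:
    """Integrate a well-mixed model and sample it on a regular grid.

    Parameters
    ----------
    params, init
        Model parameters and initial state (Table defaults if omitted).
    t_end
        End of the run in minutes (default 20 h = 1200 min).
    sample_times
        Output grid; defaults to 1-min resolution from 0 to t_end.
    rtol, atol
        Integrator tolerances (atol in concentration units, per mL).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    N = params.response.N_stages
    if init is None:
        init = default_batch_init(params)
    init.validate(N, params.model_id)
    if sample_times is None:
        sample_times = np.arange(0.0, t_end + 0.5, 1.0)
    sample_times = np.asarray(sample_times, dtype=float)

    sol = solve_ivp(
        _rhs,
        (0.0, float(t_end)),
        init.to_vector(),
        t_eval=sample_times,
        args=(params,),
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(sol.message, last)

    Y = sol.y.T.copy()
    # Sampled states must be nonnegative: clip integrator noise, reject
    # anything clearly below tolerance.
    neg_floor = -max(atol, rtol * np.abs(Y).max())
    if Y.min() < neg_floor:
        raise IntegrationError(
            f"state went negative beyond tolerance (min {Y.min():.3e})", float(sol.t[-1])
        )
    np.clip(Y, 0.0, None, out=Y)
    return TimeSeries(times=sol.t.copy(), Y=Y, N=N, params=params)


def _lin_params(
    base: WellMixedParams | None, f_tau: float, f_beta: float, model_id: ModelId
) -> WellMixedParams:
    base = base if base is not None else WellMixedParams()
    return replace(base, f_tau=f_tau, f_beta=f_beta, model_id=model_id)


def final_phage_ratio_separate(
    f_tau: float,
    f_beta: float,
    params: WellMixedParams | None = None,
    t_end: float = 1200.0,
    B0: float = DEFAULT_B0,
    phage0: float = DEFAULT_PHAGE0,
    n0: float | None = None,
) -> float:
    """Free LIN-phage over free r-mutant phage after growing in *separate*
    cultures started from identical conditions.

    Returns ``inf`` if the r-mutant phage is extinct at ``t_end``.
    """
    p1 = _lin_params(params, f_tau, f_beta, "M1")
    p0 = _lin_params(params, 1.0, 1.0, "M0")
    ts1 = simulate_batch(p1, default_batch_init(p1, B0=B0, P0=phage0, n0=n0), t_end)
    ts0 = simulate_batch(p0, default_batch_init(p0, B0=B0, R0=phage0, n0=n0), t_end)
    P_end = ts1.P[-1]
    R_end = ts0.R[-1]
    if R_end == 0.0:
        return math.inf
    return float(P_end / R_end)


@dataclass
class CompetitionOutcome:
    """Summary of a mixed-culture competition run."""

    ratio: float  #: free P / free R at t_end (inf if R extinct)
    peak_decline: float  #: (max_t R - R(t_end)) / max_t R, 0 if R monotone
    crossing_time: float | None  #: earliest t with total free phage >= B (min)
    series: TimeSeries


def phage_host_crossing_time(ts: TimeSeries) -> float | None:
    """Earliest time at which total free phage reaches the uninfected
    bacteria concentration, by linear interpolation between samples."""
    diff = (ts.R + ts.P) - ts.B
    if diff[0] >= 0:
        return float(ts.times[0])
    idx = np.nonzero(diff >= 0)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    t0, t1 = ts.times[i - 1], ts.times[i]
    d0, d1 = diff[i - 1], diff[i]
    if d1 == d0:
        return float(t1)
    return float(t0 + (t1 - t0) * (-d0) / (d1 - d0))


def competition_outcome(
    f_tau: float,
    f_beta: float,
    params: WellMixedParams | None = None,
    init: WellMixedState | None = None,
    t_end: float = 1200.0,
) -> CompetitionOutcome:
    """Run the mixed-culture competition model and summarise it.

    The peak decline of the free r-mutant phage measures how strongly
    lysis-inhibited cells soak up competitor phage after the host supply is
    exhausted; its global maximum over the sampled grid is used (earliest
    time on ties).
    """
    p = _lin_params(params, f_tau, f_beta, "MC1")
    if init is None:
        init = default_batch_init(p)
    ts = simulate_batch(p, init, t_end)
    R = ts.R
    R_max = R.max()
    if R_max <= 0.0:
        decline = 0.0
        ratio = math.inf if ts.P[-1] > 0 else math.nan
    else:
        decline = float((R_max - R[-1]) / R_max)
        ratio = math.inf if R[-1] == 0.0 else float(ts.P[-1] / R[-1])
    return CompetitionOutcome(
        ratio=ratio,
        peak_decline=decline,
        crossing_time=phage_host_crossing_time(ts),
        series=ts,
    )


@dataclass
class SweepResult:
    """Outcome statistic on an (f_tau, f_beta) grid."""

    f_tau_grid: np.ndarray
    f_beta_grid: np.ndarray
    log10_ratio: np.ndarray  #: shape (len(f_tau_grid), len(f_beta_grid))
    contour: np.ndarray  #: polyline of (f_tau, f_beta) where the ratio is 1
    errors: dict  #: (i, j) -> error message for failed cells
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log10_ratio,
            index=pd.Index(self.f_tau_grid, name="f_tau"),
            columns=pd.Index(self.f_beta_grid, name="f_beta"),
        )


def _ratio_one_contour(
    f_tau_grid: np.ndarray, f_beta_grid: np.ndarray, logmat: np.ndarray
) -> np.ndarray:
    """Interpolate, per f_tau row, the f_beta at which log10(ratio) = 0."""
    pts = []
    for i, ft in enumerate(f_tau_grid):
        row = logmat[i]
        for j in range(len(f_beta_grid) - 1):
            a, b = row[j], row[j + 1]
            if not (np.isfinite(a) and np.isfinite(b)):
                continue
            if a == 0.0:
                pts.append((ft, f_beta_grid[j]))
                break
            if a * b < 0:
                fb = f_beta_grid[j] + (f_beta_grid[j + 1] - f_beta_grid[j]) * (
                    -a / (b - a)
                )
                pts.append((ft, fb))
                break
        else:
            if len(f_beta_grid) and row[-1] == 0.0:
                pts.append((ft, f_beta_grid[-1]))
    return np.array(pts, dtype=float).reshape(-1, 2)


def sweep_lin_grid(
    mode: Literal["separate", "competition"],
    f_tau_grid: Sequence[float],
    f_beta_grid: Sequence[float],
    params: WellMixedParams | None = None,
    t_end: float = 1200.0,
) -> SweepResult:
    """log10 of the final LIN-phage/r-mutant free-phage ratio over an
    (f_tau, f_beta) grid, in separate cultures or head-to-head competition.

    Per-cell simulation failures are recorded in ``errors`` and the cell is
    set to NaN; the run continues.
    """
    if mode not in ("separate", "competition"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    f_tau_grid = np.asarray(f_tau_grid, dtype=float)
    f_beta_grid = np.asarray(f_beta_grid, dtype=float)
    if f_tau_grid.size == 0 or f_beta_grid.size == 0:
        raise ValueError("sweep grids must be nonempty")
    if f_tau_grid.min() < 1.0 or f_beta_grid.min() < 1.0:
        raise ValueError("f_tau and f_beta grids must be >= 1")

    mat = np.full((f_tau_grid.size, f_beta_grid.size), np.nan)
    errors: dict = {}
    for i, ft in enumerate(f_tau_grid):
        for j, fb in enumerate(f_beta_grid):
            try:
                if mode == "separate":
                    ratio = final_phage_ratio_separate(ft, fb, params, t_end)
                else:
                    ratio = competition_outcome(ft, fb, params, t_end=t_end).ratio
                mat[i, j] = np.log10(ratio) if ratio > 0 else -np.inf
            except Exception as exc:  # pragma: no cover - defensive
                errors[(i, j)] = str(exc)
    contour = _ratio_one_contour(f_tau_grid, f_beta_grid, mat)
    return SweepResult(
        f_tau_grid=f_tau_grid,
        f_beta_grid=f_beta_grid,
        log10_ratio=mat,
        contour=contour,
        errors=errors,
        mode=mode,
    )
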