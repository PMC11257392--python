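"""Event-driven stochastic counterpart of the well-mixed models.

A statistically exact (direct-method) simulation of the same reaction
network as the deterministic batch models, at integer copy numbers in a
volume V.  It serves as an independent validation oracle: at matched
concentrations its replicate means must agree with the ODE trajectories,
and the lysis-time distribution of the staged latency chain must be
Erlang(N) with mean tau and relative standard deviation 1/sqrt(N).

Reactions (propensities use the batch rate constants with eta/V scaling):

* division: B -> B+1 consuming one nutrient unit, at g(n/V)·B
* adsorption of each free phage type to each cell class, removing the
  phage and, depending on the class: starting an infection (uninfected),
  triggering lysis inhibition (cell first infected by the LIN phage, when
  the adsorbing strain can trigger), or pure inactivation otherwise
* latency-stage progression and lysis, releasing beta(n) phage (f_beta
  times that for a lysis-inhibited cell), stochastically rounded so the
  mean burst is exact.

Nutrient is an integer pool of cell-equivalents so that conservation of
B + n is exact without phage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .response import burst_size, growth_rate, stage_rate
from .wellmixed import WellMixedParams

__all__ = ["CountState", "EventTrajectory", "simulate_events", "sample_lysis_times"]


@dataclass
class CountState:
    """Integer copy numbers of every compartment in a volume V (mL)."""

    V: float
    B: int = 0
    n: int = 0
    R: int = 0
    P: int = 0
    I_R: np.ndarray = field(default_factory=lambda: np.zeros(10, dtype=np.int64))
    I_P: np.ndarray = field(default_factory=lambda: np.zeros(10, dtype=np.int64))
    L: np.ndarray = field(default_factory=lambda: np.zeros(10, dtype=np.int64))

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError("volume must be positive")
        self.I_R = np.asarray(self.I_R, dtype=np.int64)
        self.I_P = np.asarray(self.I_P, dtype=np.int64)
        self.L = np.asarray(self.L, dtype=np.int64)
        if min(self.B, self.n, self.R, self.P) < 0 or (
            self.I_R.min(initial=0) < 0
            or self.I_P.min(initial=0) < 0
            or self.L.min(initial=0) < 0
        ):
            raise ValueError("counts must be nonnegative")


@dataclass
class EventTrajectory:
    """Counts recorded on a fixed time grid (piecewise-constant sampling)."""

    times: np.ndarray
    counts: np.ndarray  #: shape (len(times), 4 + 3N), columns as in the ODE state
    V: float
    N: int
    n_events: int
    capped: bool  #: True if the event cap was hit before t_end

    def to_frame(self) -> pd.DataFrame:
        """Concentrations (per mL) in the batch TimeSeries CSV schema."""
        c = self.counts / self.V
        N = self.N
        return pd.DataFrame(
            {
                "time_min": self.times,
                "B": c[:, 0],
                "n": c[:, 1],
                "R": c[:, 2],
                "P": c[:, 3],
                "I_R_total": c[:, 4 : 4 + N].sum(axis=1),
                "I_P_total": c[:, 4 + N : 4 + 2 * N].sum(axis=1),
                "L_total": c[:, 4 + 2 * N :].sum(axis=1),
                "B_tot": c[:, 0] + c[:, 4:].sum(axis=1),
            }
        )


def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    """floor(x) plus a Bernoulli on the fractional part: integer burst
    sizes whose mean equals the real-valued ODE burst size exactly."""
    lo = int(np.floor(x))
    return lo + (1 if rng.random() < x - lo else 0)


def simulate_events(
    params: WellMixedParams,
    init: CountState,
    seed: int,
    t_end: float,
    record_times: np.ndarray | None = None,
    max_events: int = 50_000_000,
) -> EventTrajectory:
    """Exact event-driven simulation of one stochastic realisation.

    ``record_times`` defaults to a 1-min grid.  A run that exceeds
    ``max_events`` is truncated and flagged ``capped`` rather than raising,
    so runaway parameter choices surface as data, not crashes.
    """
    rp = params.response
    N = rp.N_stages
    V = init.V
    eta_v = params.eta / V  # per-pair adsorption propensity
    lin_only = params.trigger_mode == "lin_phage_only"
    rng = np.random.default_rng(seed)

    if record_times is None:
        record_times = np.arange(0.0, t_end + 0.5, 1.0)
    record_times = np.asarray(record_times, dtype=float)

    B, n, R, P = init.B, init.n, init.R, init.P
    I_R = init.I_R.astype(np.int64).copy()
    I_P = init.I_P.astype(np.int64).copy()
    L = init.L.astype(np.int64).copy()
    if len(I_R) != N or len(I_P) != N or len(L) != N:
        raise ValueError(f"staged count vectors must have length {N}")

    out = np.zeros((len(record_times), 4 + 3 * N), dtype=np.int64)
    rec = 0

    def snapshot() -> np.ndarray:
        return np.concatenate([[B, n, R, P], I_R, I_P, L])

    t = 0.0
    n_events = 0
    capped = False
    # propensity vector layout:
    # 0: division
    # 1..2: infection of B by R / by P
    # 3..4: adsorption of R / P to I_R cells (inactivation)
    # 5..6: adsorption of R / P to I_P cells (LIN trigger or inactivation)
    # 7..8: adsorption of R / P to L cells (inactivation)
    # 9..8+N: I_R stage progression (last = lysis)
    # 9+N..8+2N: I_P stage progression (last = lysis)
    # 9+2N..8+3N: L stage progression (last = inhibited lysis)
    a = np.zeros(9 + 3 * N)
    while True:
        while rec < len(record_times) and t >= record_times[rec]:
            out[rec] = snapshot()
            rec += 1
        if rec >= len(record_times):
            break

        n_conc = n / V
        g = growth_rate(n_conc, rp)
        k = stage_rate(n_conc, rp, 1.0)
        kL = k / params.f_tau
        sI_R, sI_P, sL = int(I_R.sum()), int(I_P.sum()), int(L.sum())

        a[0] = g * B if n > 0 else 0.0
        a[1] = eta_v * R * B
        a[2] = eta_v * P * B
        a[3] = eta_v * R * sI_R
        a[4] = eta_v * P * sI_R
        a[5] = eta_v * R * sI_P
        a[6] = eta_v * P * sI_P
        a[7] = eta_v * R * sL
        a[8] = eta_v * P * sL
        a[9 : 9 + N] = k * I_R
        a[9 + N : 9 + 2 * N] = k * I_P
        a[9 + 2 * N :] = kL * L
        a_tot = a.sum()
        if a_tot <= 0.0:
            t = np.inf
            continue

        t += rng.exponential(1.0 / a_tot)
        if t >= record_times[-1]:
            continue  # record remaining samples, then exit
        r_idx = int(np.searchsorted(np.cumsum(a), rng.random() * a_tot))
        n_events += 1

        if r_idx == 0:
            B += 1
            n -= 1
        elif r_idx == 1:
            R -= 1
            B -= 1
            I_R[0] += 1
        elif r_idx == 2:
            P -= 1
            B -= 1
            I_P[0] += 1
        elif r_idx in (3, 4):
            if r_idx == 3:
                R -= 1
            else:
                P -= 1
        elif r_idx in (5, 6):
            triggers = r_idx == 6 or not lin_only
            if r_idx == 5:
                R -= 1
            else:
                P -= 1
            if triggers:
                # pick the adsorbed cell's stage proportionally to occupancy
                stage = int(
                    np.searchsorted(np.cumsum(I_P), rng.random() * sI_P)
                )
                I_P[stage] -= 1
                L[0] += 1
        elif r_idx in (7, 8):
            if r_idx == 7:
                R -= 1
            else:
                P -= 1
        elif r_idx < 9 + N:
            stage = r_idx - 9
            I_R[stage] -= 1
            if stage == N - 1:
                R += _stochastic_round(burst_size(n_conc, rp), rng)
            else:
                I_R[stage + 1] += 1
        elif r_idx < 9 + 2 * N:
            stage = r_idx - 9 - N
            I_P[stage] -= 1
            if stage == N - 1:
                P += _stochastic_round(burst_size(n_conc, rp), rng)
            else:
                I_P[stage + 1] += 1
        else:
            stage = r_idx - 9 - 2 * N
            L[stage] -= 1
            if stage == N - 1:
                P += _stochastic_round(
                    params.f_beta * burst_size(n_conc, rp), rng
                )
            else:
                L[stage + 1] += 1

        if n_events >= max_events:
            capped = True
            while rec < len(record_times):
                out[rec] = snapshot()
                rec += 1
            break

    return EventTrajectory(
        times=record_times.copy(),
        counts=out,
        V=V,
        N=N,
        n_events=n_events,
        capped=capped,
    )


def sample_lysis_times(
    params: WellMixedParams,
    n_cells: int,
    seed: int,
    f_tau: float = 1.0,
    n_level: float | None = None,
) -> np.ndarray:
    """Lysis times of independent singly-infected cells at fixed nutrient.

    Direct sampling of the N-stage latency chain (a sum of N exponentials),
    used to verify the Erlang mean f_tau*tau(n) and relative SD 1/sqrt(N).
    """
    rp = params.response
    n_level = rp.n_ref if n_level is None else n_level
    k = stage_rate(n_level, rp, f_tau)
    if k <= 0:
        raise ValueError("stage rate is zero: latency diverges at this nutrient level")
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / k, size=(n_cells, rp.N_stages)).sum(axis=1)
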