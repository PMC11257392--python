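"""Nutrient-dependent host physiology and the latency/burst trade-off.

Bacterial growth follows Monod kinetics, g(n) = g_max * n / (K_n + n).
Phage latency and burst size track the host growth state: as nutrient is
depleted the burst shrinks towards a floor ``r_b * beta0`` and the latent
period stretches towards a ceiling ``tau0 / r_l`` (diverging when r_l = 0,
which arrests lysis under starvation).

The latent period is modelled as an Erlang chain of ``N_stages`` identical
exponential substates, so all latency quantities are exposed in *rate* form
(per-substate progression rate).  This keeps the r_l = 0, n = 0 limit
numerically safe: the rate is simply 0 (arrest), never a division by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutrientResponseParams", "growth_rate", "burst_size", "stage_rate"]


@dataclass(frozen=True)
class NutrientResponseParams:
    """Physiology parameters shared by every model variant.

    Parameters
    ----------
    g_max : float
        Maximum bacterial growth rate (1/min).  Default 0.034/min
        (20-min doubling time).
    K_n : float
        Monod constant: nutrient level at half-maximal growth.  Same units
        as the nutrient variable (per mL in batch, per µm² in plaques).
    beta0 : float
        Maximum burst size (phages released per lysing cell).
    tau0 : float
        Minimum *total* latent period (min), i.e. the mean time from
        infection to burst when nutrient is at the reference level.
    r_l : float
        Ratio of minimum to maximum latency time, in [0, 1].  r_l = 0 makes
        latency diverge as nutrient runs out.
    r_b : float
        Ratio of minimum to maximum burst size, in [0, 1].
    n_ref : float
        Reference nutrient level (the initial nutrient n0) used to
        normalise the growth-rate dependence.
    N_stages : int
        Number of sequential infection substates (Erlang shape parameter).
    """

    g_max: float = 0.034
    K_n: float = 2e8
    beta0: float = 150.0
    tau0: float = 20.0
    r_l: float = 0.5
    r_b: float = 0.1
    n_ref: float = 1e9
    N_stages: int = 10

    def __post_init__(self) -> None:
        if self.g_max <= 0:
            raise ValueError(f"g_max must be positive, got {self.g_max}")
        if self.K_n <= 0:
            raise ValueError(f"K_n must be positive, got {self.K_n}")
        if self.beta0 <= 0:
            raise ValueError(f"beta0 must be positive, got {self.beta0}")
        if self.tau0 <= 0:
            raise ValueError(f"tau0 must be positive, got {self.tau0}")
        if not 0.0 <= self.r_l <= 1.0:
            raise ValueError(f"r_l must lie in [0, 1], got {self.r_l}")
        if not 0.0 <= self.r_b <= 1.0:
            raise ValueError(f"r_b must lie in [0, 1], got {self.r_b}")
        if self.n_ref <= 0:
            raise ValueError(f"n_ref must be positive, got {self.n_ref}")
        if int(self.N_stages) != self.N_stages or self.N_stages < 1:
            raise ValueError(f"N_stages must be a positive integer, got {self.N_stages}")


def _check_nonneg(n) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("nutrient level must be nonnegative")
    return n


def growth_rate(n, p: NutrientResponseParams):
    """Monod growth rate g(n) = g_max * n / (K_n + n), in 1/min.

    Accepts scalars or arrays; negative nutrient raises ``ValueError``.
    """
    n = _check_nonneg(n)
    out = p.g_max * n / (p.K_n + n)
    return out if out.ndim else float(out)


def burst_size(n, p: NutrientResponseParams):
    """Burst size beta(n) = beta0 * (r_b + (1 - r_b) * g(n)/g(n_ref)).

    Equals beta0 at the reference nutrient level and r_b*beta0 under
    complete starvation.
    """
    n = _check_nonneg(n)
    rel = growth_rate(n, p) / growth_rate(p.n_ref, p)
    out = p.beta0 * (p.r_b + (1.0 - p.r_b) * rel)
    return out if np.ndim(out) else float(out)


def stage_rate(n, p: NutrientResponseParams, f_tau: float = 1.0):
    """Per-substate progression rate of the Erlang latency chain (1/min).

    Returns ``(N_stages / (f_tau * tau0)) * (r_l + (1 - r_l) * g(n)/g(n_ref))``,
    i.e. N/tau(n) for a normal infection (f_tau = 1) and N/(f_tau*tau(n))
    for a lysis-inhibited chain, so the mean total latency is always
    ``f_tau * tau(n)``.  Evaluates to exactly 0 when r_l = 0 and n = 0
    (latency diverges: the chain arrests instead of dividing by zero).
    """
    if f_tau < 1.0:
        raise ValueError(f"f_tau must be >= 1, got {f_tau}")
    n = _check_nonneg(n)
    rel = growth_rate(n, p) / growth_rate(p.n_ref, p)
    out = (p.N_stages / (f_tau * p.tau0)) * (p.r_l + (1.0 - p.r_l) * rel)
    return out if np.ndim(out) else float(out)
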