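"""Flat key–value run configuration with table defaults.

Keys are named after the symbols used throughout the model (g_max, K_n,
eta, tau0, beta0, r_l, r_b, N, f_tau, f_beta, B0, R0, P0, n0, delta_a,
D_p, D_n, R_max, dr, ...).  Defaults reproduce the standard batch and
plaque parameter tables exactly; every overridden key is tracked so runs
can log parameter provenance.  Unknown keys are errors, not warnings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .plaque import PlaqueParams
from .response import NutrientResponseParams
from .wellmixed import WellMixedParams, WellMixedState, default_batch_init

__all__ = ["RunConfig", "ConfigError", "load_config"]

SCHEMA_VERSION = 1

_BATCH_MODELS = ("M0", "M1", "MC1")
_PLAQUE_MODELS = ("MP0", "MP1")


class ConfigError(ValueError):
    """A configuration key is unknown or fails validation."""


def _positive(x: float) -> bool:
    return x > 0


def _nonneg(x: float) -> bool:
    return x >= 0


def _unit(x: float) -> bool:
    return 0.0 <= x <= 1.0


def _ge1(x: float) -> bool:
    return x >= 1.0


# key -> (default or None, caster, validator, description)
_SCHEMA: dict[str, tuple[Any, Any, Any, str]] = {
    "model": ("M0", str, lambda v: v in _BATCH_MODELS + _PLAQUE_MODELS, "model id"),
    "g_max": (0.034, float, _positive, "max growth rate (1/min)"),
    "K_n": (None, float, _positive, "Monod constant; default n0/5"),
    "eta": (5e-10, float, _positive, "adsorption rate (mL/min)"),
    "tau0": (20.0, float, _positive, "minimum total latency (min)"),
    "beta0": (150.0, float, _positive, "maximum burst size"),
    "r_l": (None, float, _unit, "latency ratio; 0.5 batch, 0 plaque"),
    "r_b": (0.1, float, _unit, "burst-size ratio"),
    "N": (10, int, lambda v: v >= 1, "latency stages"),
    "f_tau": (1.0, float, _ge1, "LIN latency factor"),
    "f_beta": (1.0, float, _ge1, "LIN burst factor"),
    "trigger_mode": (
        "any_phage",
        str,
        lambda v: v in ("any_phage", "lin_phage_only"),
        "which strain triggers LIN",
    ),
    "B0": (None, float, _nonneg, "initial bacteria; 1e6/mL batch, 1/400/um^2 plaque"),
    "R0": (None, float, _nonneg, "initial r-mutant phage (batch)"),
    "P0": (None, float, _nonneg, "initial LIN phage (batch)"),
    "n0": (None, float, _positive, "initial nutrient; 1e9/mL batch, 0.5/um^2 plaque"),
    "delta_a": (500.0, float, _positive, "soft-agar thickness (um)"),
    "D_p": (240.0, float, _nonneg, "phage diffusivity (um^2/min)"),
    "D_n": (5e4, float, _nonneg, "nutrient diffusivity (um^2/min)"),
    "R_max": (10_000.0, float, _positive, "domain radius (um)"),
    "dr": (20.0, float, _positive, "grid spacing (um)"),
    "t_end": (None, float, _positive, "run length (min); 1200 batch, 400 plaque"),
    "sample_interval": (None, float, _positive, "output grid (min); 1 batch, 10 plaque"),
    "half_fraction": (0.5, float, lambda v: 0 < v < 1, "visibility threshold"),
    "seed": (0, int, lambda v: v >= 0, "RNG seed (stochastic oracle)"),
    "V": (1e-6, float, _positive, "oracle volume (mL)"),
}


@dataclass
class RunConfig:
    """Validated run configuration; ``overrides`` lists every key the user
    set away from its table default."""

    values: dict[str, Any]
    overrides: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    @property
    def is_plaque(self) -> bool:
        return self.values["model"] in _PLAQUE_MODELS

    def _resolved(self) -> dict[str, Any]:
        """Fill context-dependent defaults (batch vs plaque)."""
        v = dict(self.values)
        plaque = self.is_plaque
        if v["n0"] is None:
            v["n0"] = 0.5 if plaque else 1e9
        if v["K_n"] is None:
            v["K_n"] = v["n0"] / 5.0
        if v["r_l"] is None:
            v["r_l"] = 0.0 if plaque else 0.5
        if v["B0"] is None:
            v["B0"] = 1.0 / 400.0 if plaque else 1e6
        if v["t_end"] is None:
            v["t_end"] = 400.0 if plaque else 1200.0
        if v["sample_interval"] is None:
            v["sample_interval"] = 10.0 if plaque else 1.0
        if v["R0"] is None:
            v["R0"] = 0.0 if v["model"] == "M1" else 1e3
        if v["P0"] is None:
            v["P0"] = 0.0 if v["model"] == "M0" else 1e3
        return v

    def response_params(self) -> NutrientResponseParams:
        v = self._resolved()
        return NutrientResponseParams(
            g_max=v["g_max"],
            K_n=v["K_n"],
            beta0=v["beta0"],
            tau0=v["tau0"],
            r_l=v["r_l"],
            r_b=v["r_b"],
            n_ref=v["n0"],
            N_stages=v["N"],
        )

    def wellmixed_params(self) -> WellMixedParams:
        v = self._resolved()
        model = v["model"]
        if model in _PLAQUE_MODELS:
            model = "M0" if model == "MP0" else "M1"
        return WellMixedParams(
            response=self.response_params(),
            eta=v["eta"],
            f_tau=v["f_tau"],
            f_beta=v["f_beta"],
            trigger_mode=v["trigger_mode"],
            model_id=model,
        )

    def batch_init(self) -> WellMixedState:
        v = self._resolved()
        return default_batch_init(
            self.wellmixed_params(), B0=v["B0"], R0=v["R0"], P0=v["P0"], n0=v["n0"]
        )

    def plaque_params(self) -> PlaqueParams:
        if not self.is_plaque:
            raise ConfigError(f"model {self.values['model']} is not a plaque model")
        v = self._resolved()
        return PlaqueParams(
            wellmixed=self.wellmixed_params(),
            delta_a=v["delta_a"],
            D_p=v["D_p"],
            D_n=v["D_n"],
            R_max=v["R_max"],
            dr=v["dr"],
            t_end=v["t_end"],
            B0=v["B0"],
            n0=v["n0"],
        )

    def provenance(self) -> dict[str, Any]:
        """Effective values with a default/override flag per key, for run logs."""
        v = self._resolved()
        return {
            k: {"value": v[k], "source": "override" if k in self.overrides else "default"}
            for k in sorted(v)
        }


def load_config(source: str | Path | Mapping[str, Any] | None = None, **cli_overrides) -> RunConfig:
    """Build a RunConfig from a YAML file and/or keyword overrides.

    CLI overrides (keywords with value ``None`` are ignored) take
    precedence over the file.  Unknown or invalid keys raise
    :class:`ConfigError` naming the offending key.
    """
    raw: dict[str, Any] = {}
    if source is not None:
        if isinstance(source, Mapping):
            raw.update(source)
        else:
            with open(source) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ConfigError("config file must be a flat key-value mapping")
            raw.update(loaded)
    raw.update({k: v for k, v in cli_overrides.items() if v is not None})

    values = {k: default for k, (default, _, _, _) in _SCHEMA.items()}
    overrides: dict[str, Any] = {}
    for key, val in raw.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown configuration key {key!r}")
        _, caster, validator, desc = _SCHEMA[key]
        try:
            val = caster(val)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"key {key!r} ({desc}): {exc}") from None
        if val is not None and not validator(val):
            raise ConfigError(f"key {key!r} ({desc}): invalid value {val!r}")
        values[key] = val
        overrides[key] = val
    return RunConfig(values=values, overrides=overrides)
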