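"""Transition-state-theory kinetics for two- and three-step catalytic cycles.

A catalytic cycle is parameterized by Gibbs free energies (kcal/mol) of its
ground and transition states.  Microscopic rate constants follow the Eyring
form ``k = (k_B T / h) * exp(-dG_barrier / RT)``; composite kinetic
parameters (k_cat, K_M, K_D, catalytic efficiency) are derived from the
steady-state expressions of each mechanism.

Two mechanisms are supported:

``simple``
    E + S <-> ES -> E + P, with rate constants k1, k-1, k2.
``complex``
    E + S <-> ES <-> EP -> E + P, adding k-2 and k3 (acyl-enzyme-style
    cycle with reversible chemistry and irreversible product release).

The same numeric prefactor k_B*T/h is used for the bimolecular binding step
(units M^-1 s^-1) as for unimolecular steps; no diffusion-limit cap is
applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np

__all__ = [
    "ValidationError",
    "FreeEnergyProfile",
    "RateConstantSet",
    "KineticParameters",
    "thermal_prefactor",
    "arrhenius_rate",
    "rates_from_profile",
    "kinetic_parameters",
    "kinetic_parameters_arrays",
    "default_profile",
    "SIMPLE",
    "COMPLEX",
    "STATE_ORDER",
    "RATE_EDGES",
    "RATE_ORDER",
    "PARAM_NAMES",
    "KB_J_PER_K",
    "PLANCK_J_S",
    "R_KCAL_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
]

# CODATA 2018 exact values; R expressed in kcal/(mol K).
KB_J_PER_K = 1.380649e-23
PLANCK_J_S = 6.62607015e-34
R_KCAL_PER_MOL_K = 1.98720425e-3
DEFAULT_TEMPERATURE_K = 298.15

SIMPLE = "simple"
COMPLEX = "complex"

# Canonical state labels.  "*_ts" marks a transition state: "E+S_ts" is the
# binding barrier, "ES_ts" the chemical barrier, "EP_ts" the product-release
# barrier.  The free E + P state never enters a rate and is not represented.
STATE_ORDER: dict[str, tuple[str, ...]] = {
    SIMPLE: ("E+S", "E+S_ts", "ES", "ES_ts"),
    COMPLEX: ("E+S", "E+S_ts", "ES", "ES_ts", "EP", "EP_ts"),
}

# rate constant -> (transition state, ground state) defining its barrier
RATE_EDGES: dict[str, dict[str, tuple[str, str]]] = {
    SIMPLE: {
        "k1": ("E+S_ts", "E+S"),
        "k_minus1": ("E+S_ts", "ES"),
        "k2": ("ES_ts", "ES"),
    },
    COMPLEX: {
        "k1": ("E+S_ts", "E+S"),
        "k_minus1": ("E+S_ts", "ES"),
        "k2": ("ES_ts", "ES"),
        "k_minus2": ("ES_ts", "EP"),
        "k3": ("EP_ts", "EP"),
    },
}

RATE_ORDER: dict[str, tuple[str, ...]] = {
    SIMPLE: ("k1", "k_minus1", "k2"),
    COMPLEX: ("k1", "k_minus1", "k2", "k_minus2", "k3"),
}

PARAM_NAMES = ("kcat", "KM", "KD", "efficiency")

DEFAULT_ENERGIES: dict[str, dict[str, float]] = {
    SIMPLE: {"E+S": 0.0, "E+S_ts": 10.0, "ES": -5.0, "ES_ts": 11.0},
    COMPLEX: {
        "E+S": 0.0,
        "E+S_ts": 10.0,
        "ES": -5.0,
        "ES_ts": 11.0,
        "EP": -9.0,
        "EP_ts": 9.0,
    },
}


class ValidationError(ValueError):
    """Raised when domain inputs violate a contract precondition."""


def _check_mechanism(mechanism: str) -> str:
    if mechanism not in (SIMPLE, COMPLEX):
        raise ValidationError(
            f"unknown mechanism {mechanism!r}; expected 'simple' or 'complex'"
        )
    return mechanism


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Gibbs free energies (kcal/mol) of every state in a catalytic cycle.

    Parameters
    ----------
    mechanism:
        ``"simple"`` or ``"complex"``.
    energies:
        Mapping from state label (see :data:`STATE_ORDER`) to free energy.
    temperature_K:
        Absolute temperature; defaults to 298.15 K.
    """

    mechanism: str
    energies: Mapping[str, float]
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        _check_mechanism(self.mechanism)
        if not (self.temperature_K > 0):
            raise ValidationError(
                f"temperature must be > 0 K, got {self.temperature_K}"
            )
        required = STATE_ORDER[self.mechanism]
        for state in required:
            if state not in self.energies:
                raise ValidationError(
                    f"profile missing required state {state!r} for "
                    f"{self.mechanism} mechanism"
                )
            value = self.energies[state]
            if not math.isfinite(value):
                raise ValidationError(f"energy of state {state!r} is not finite")
        object.__setattr__(
            self, "energies", {s: float(self.energies[s]) for s in required}
        )

    @property
    def states(self) -> tuple[str, ...]:
        return STATE_ORDER[self.mechanism]

    def shifted(self, delta: Mapping[str, float]) -> "FreeEnergyProfile":
        """Return a new profile with per-state offsets added."""
        missing = [s for s in delta if s not in self.energies]
        if missing:
            raise ValidationError(f"unknown states in shift: {missing}")
        energies = {s: g + float(delta.get(s, 0.0)) for s, g in self.energies.items()}
        return FreeEnergyProfile(self.mechanism, energies, self.temperature_K)

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "temperature_K": self.temperature_K,
            "energies": dict(self.energies),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FreeEnergyProfile":
        try:
            return cls(
                mechanism=payload["mechanism"],
                energies=payload["energies"],
                temperature_K=payload.get("temperature_K", DEFAULT_TEMPERATURE_K),
            )
        except KeyError as exc:
            raise ValidationError(f"profile JSON missing field {exc.args[0]!r}") from exc

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FreeEnergyProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_profile(mechanism: str, temperature_K: float = DEFAULT_TEMPERATURE_K) -> FreeEnergyProfile:
    """Built-in wild-type profile for either mechanism.

    The default energies give a positive barrier for every step; this is
    asserted here (defaults only — perturbed profiles may legitimately have
    inverted barriers).
    """
    _check_mechanism(mechanism)
    profile = FreeEnergyProfile(mechanism, DEFAULT_ENERGIES[mechanism], temperature_K)
    for name, (ts, ground) in RATE_EDGES[mechanism].items():
        barrier = profile.energies[ts] - profile.energies[ground]
        if barrier <= 0:
            raise AssertionError(f"default profile has non-positive barrier for {name}")
    return profile


@dataclass(frozen=True)
class RateConstantSet:
    """Microscopic rate constants of one catalytic cycle variant.

    ``k1`` is bimolecular (M^-1 s^-1); the rest are unimolecular (s^-1).
    ``k_minus2`` and ``k3`` are required for (and only for) the complex
    mechanism.  ``k_minus2`` may be exactly zero to represent a cycle whose
    chemical step is treated as irreversible (experimental tables often omit
    it); every other rate constant must be strictly positive.
    """

    mechanism: str
    k1: float
    k_minus1: float
    k2: float
    k_minus2: float | None = None
    k3: float | None = None

    def __post_init__(self) -> None:
        _check_mechanism(self.mechanism)
        for name in ("k1", "k_minus1", "k2"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValidationError(f"{name} must be a positive finite rate, got {value}")
        if self.mechanism == COMPLEX:
            if self.k_minus2 is None or self.k3 is None:
                raise ValidationError("complex mechanism requires k_minus2 and k3")
            if not (self.k_minus2 >= 0 and math.isfinite(self.k_minus2)):
                raise ValidationError(f"k_minus2 must be >= 0, got {self.k_minus2}")
            if not (self.k3 > 0 and math.isfinite(self.k3)):
                raise ValidationError(f"k3 must be a positive finite rate, got {self.k3}")
        elif self.k_minus2 is not None or self.k3 is not None:
            raise ValidationError("simple mechanism takes only k1, k_minus1, k2")

    def as_dict(self) -> dict[str, float]:
        out = {"k1": self.k1, "k_minus1": self.k_minus1, "k2": self.k2}
        if self.mechanism == COMPLEX:
            out["k_minus2"] = self.k_minus2
            out["k3"] = self.k3
        return out


@dataclass(frozen=True)
class KineticParameters:
    """Composite kinetic observables for one variant.

    ``kcat`` in s^-1, ``KM`` and ``KD`` in molar, ``efficiency`` =
    kcat/KM in M^-1 s^-1.
    """

    kcat: float
    KM: float
    KD: float
    efficiency: float

    def __post_init__(self) -> None:
        for name in ("kcat", "KM", "KD", "efficiency"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValidationError(f"{name} must be positive and finite, got {value}")
        if abs(self.efficiency - self.kcat / self.KM) > 1e-10 * self.efficiency:
            raise ValidationError("efficiency inconsistent with kcat/KM")

    def as_dict(self) -> dict[str, float]:
        return {
            "kcat": self.kcat,
            "KM": self.KM,
            "KD": self.KD,
            "efficiency": self.efficiency,
        }


def thermal_prefactor(temperature_K: float) -> float:
    """Eyring frequency factor k_B*T/h for the given temperature.

    The returned number is used unchanged for both unimolecular (s^-1) and
    bimolecular (M^-1 s^-1) steps.  ~6.21e12 at 298.15 K.
    """
    if not (temperature_K > 0):
        raise ValidationError(f"temperature must be > 0 K, got {temperature_K}")
    return KB_J_PER_K * temperature_K / PLANCK_J_S


def arrhenius_rate(
    g_transition: float, g_ground: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Rate constant (k_B T / h) * exp(-(G_ts - G_ground) / RT).

    Energies in kcal/mol.  No diffusion-limit cap is applied; a negative
    barrier simply yields a rate above the prefactor.
    """
    if not (math.isfinite(g_transition) and math.isfinite(g_ground)):
        raise ValidationError("state energies must be finite")
    prefactor = thermal_prefactor(temperature_K)
    barrier = g_transition - g_ground
    return prefactor * math.exp(-barrier / (R_KCAL_PER_MOL_K * temperature_K))


def rates_from_profile(profile: FreeEnergyProfile) -> RateConstantSet:
    """Microscopic rate constants of a free-energy profile.

    Each rate depends only on the difference between its transition state
    and its ground state, so rates are invariant under a uniform shift of
    all state energies.
    """
    rates = {
        name: arrhenius_rate(
            profile.energies[ts], profile.energies[ground], profile.temperature_K
        )
        for name, (ts, ground) in RATE_EDGES[profile.mechanism].items()
    }
    return RateConstantSet(mechanism=profile.mechanism, **rates)


def kinetic_parameters_arrays(
    mechanism: str, rates: Mapping[str, "np.ndarray | float"]
) -> dict[str, np.ndarray]:
    """Vectorized kinetic parameters from arrays (or scalars) of rates.

    Returns a dict with keys ``kcat``, ``KM``, ``KD``, ``efficiency``.
    Shared by the scalar API and the simulation pipeline so both routes use
    identical arithmetic.
    """
    _check_mechanism(mechanism)
    k1 = np.asarray(rates["k1"], dtype=float)
    k_minus1 = np.asarray(rates["k_minus1"], dtype=float)
    k2 = np.asarray(rates["k2"], dtype=float)
    if mechanism == SIMPLE:
        kcat = k2 + np.zeros_like(k1)
        km = (k_minus1 + k2) / k1
        eff = k1 * k2 / (k_minus1 + k2)
    else:
        k_minus2 = np.asarray(rates["k_minus2"], dtype=float)
        k3 = np.asarray(rates["k3"], dtype=float)
        denom = k2 + k_minus2 + k3
        num = k2 * k3 + k_minus1 * k_minus2 + k_minus1 * k3
        kcat = k2 * k3 / denom
        km = num / (k1 * denom)
        eff = k1 * k2 * k3 / num
    kd = k_minus1 / k1
    return {"kcat": kcat, "KM": km, "KD": kd, "efficiency": eff}


def kinetic_parameters(rates: RateConstantSet) -> KineticParameters:
    """Composite kinetic parameters of one variant.

    simple:  kcat = k2;            KM = (k-1 + k2)/k1
    complex: kcat = k2 k3/(k2 + k-2 + k3);
             KM = (k2 k3 + k-1 k-2 + k-1 k3)/(k1 (k2 + k-2 + k3))
    In both: KD = k-1/k1 and efficiency is the algebraic ratio kcat/KM.
    """
    values = kinetic_parameters_arrays(rates.mechanism, rates.as_dict())
    return KineticParameters(
        kcat=float(values["kcat"]),
        KM=float(values["KM"]),
        KD=float(values["KD"]),
        efficiency=float(values["efficiency"]),
    )
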