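"""Separating specific from non-specific epistasis in measured rate constants.

Given microscopic rate constants for wild type, two single mutants, and the
double mutant, the workflow

1. predicts each double-mutant rate constant multiplicatively from the two
   single fold-changes; the observed/expected ratio per rate constant is the
   *specific* epistasis (non-additivity of the free-energy effects);
2. computes kinetic parameters for every variant from its rate constants;
3. forms two double-mutant predictions per kinetic parameter: the *null*
   (wt parameter x the two single parameter folds) and the *corrected null*
   (parameter recomputed from the multiplicatively expected rate constants);
4. reports the non-specific factor (corrected null / null), the apparent
   specific factor (observed / null), and the corrected specific factor
   (observed / corrected null), which satisfy
   apparent = non-specific x corrected exactly.

Measured kinetic parameters, when supplied, are used only to screen the
computed parameters for fold error (>1.5-fold is flagged); they never enter
the epistasis ratios.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

from .mechanism_core import (
    COMPLEX,
    PARAM_NAMES,
    RATE_ORDER,
    KineticParameters,
    RateConstantSet,
    ValidationError,
    kinetic_parameters,
)

__all__ = [
    "VARIANTS",
    "ExperimentalVariantSet",
    "CorrectionReport",
    "fold_error",
    "expected_double_rates",
    "specific_epistasis",
    "correction_report",
]

VARIANTS = ("wt", "mutA", "mutB", "double")
FOLD_ERROR_FLAG = 1.5


@dataclass(frozen=True)
class ExperimentalVariantSet:
    """Rate constants (and optional measured parameters) for a double-mutant cycle.

    ``rates`` maps each of wt/mutA/mutB/double to a :class:`RateConstantSet`
    of one mechanism.  ``measured`` optionally maps variant -> parameter
    name -> measured value (same units as the computed parameters).
    ``bound_flags`` marks rate constants reported only as bounds (e.g. a
    ">=" threshold); these are used at face value but produce a warning in
    the report.
    """

    rates: Mapping[str, RateConstantSet]
    measured: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    bound_flags: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [v for v in VARIANTS if v not in self.rates]
        if missing:
            raise ValidationError(f"variant set missing variants: {missing}")
        kinds = {self.rates[v].mechanism for v in VARIANTS}
        if len(kinds) != 1:
            raise ValidationError(f"variants mix mechanisms: {sorted(kinds)}")

    @property
    def mechanism(self) -> str:
        return self.rates["wt"].mechanism

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ExperimentalVariantSet":
        """Build from the experiment JSON layout.

        Expected shape: ``{"mechanism": ..., "variants": [{"variant": "wt",
        "k1": ..., "k_minus1": ..., "k2": ..., "k_minus2": ..., "k3": ...,
        "is_bound_k3": true, "measured": {"kcat": ...}}, ...]}``.  For the
        complex mechanism a missing ``k_minus2`` is taken as 0 (irreversible
        chemistry as reported); a missing ``k3``/``k_minus2`` pair means the
        simple mechanism unless one is declared.
        """
        try:
            entries = payload["variants"]
        except KeyError as exc:
            raise ValidationError("experiment JSON missing field 'variants'") from exc
        mechanism = payload.get("mechanism")
        if mechanism is None:
            has_k3 = any("k3" in e for e in entries)
            mechanism = COMPLEX if has_k3 else "simple"
        rates: dict[str, RateConstantSet] = {}
        measured: dict[str, dict[str, float]] = {}
        bounds: dict[str, tuple[str, ...]] = {}
        for entry in entries:
            try:
                variant = entry["variant"]
            except KeyError as exc:
                raise ValidationError("variant entry missing field 'variant'") from exc
            if variant not in VARIANTS:
                raise ValidationError(
                    f"unknown variant {variant!r}; expected one of {VARIANTS}"
                )
            kwargs = {"mechanism": mechanism}
            for name in RATE_ORDER[mechanism]:
                if name == "k_minus2" and name not in entry:
                    kwargs[name] = 0.0
                    continue
                if name not in entry:
                    raise ValidationError(
                        f"variant {variant!r} missing rate constant {name!r}"
                    )
                kwargs[name] = float(entry[name])
            rates[variant] = RateConstantSet(**kwargs)
            if "measured" in entry:
                measured[variant] = {k: float(v) for k, v in entry["measured"].items()}
            flagged = tuple(
                name
                for name in RATE_ORDER[mechanism]
                if entry.get(f"is_bound_{name}", False)
            )
            if flagged:
                bounds[variant] = flagged
        return cls(rates=rates, measured=measured, bound_flags=bounds)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ExperimentalVariantSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        entries = []
        for variant in VARIANTS:
            entry: dict = {"variant": variant, **self.rates[variant].as_dict()}
            for name in self.bound_flags.get(variant, ()):
                entry[f"is_bound_{name}"] = True
            if variant in self.measured:
                entry["measured"] = dict(self.measured[variant])
            entries.append(entry)
        return {"mechanism": self.mechanism, "variants": entries}


def fold_error(measured: float, computed: float) -> float:
    """Symmetric fold discrepancy, always >= 1: max of the two ratios."""
    for name, value in (("measured", measured), ("computed", computed)):
        if not (value > 0 and math.isfinite(value)):
            raise ValidationError(f"{name} must be positive and finite, got {value}")
    return max(measured / computed, computed / measured)


def expected_double_rates(
    wt: RateConstantSet, mut_a: RateConstantSet, mut_b: RateConstantSet
) -> RateConstantSet:
    """Multiplicative prediction of the double mutant's rate constants.

    Per rate constant, expected = k_wt * (k_A/k_wt) * (k_B/k_wt); this is
    the no-specific-epistasis expectation (additive free-energy effects).
    """
    kinds = {wt.mechanism, mut_a.mechanism, mut_b.mechanism}
    if len(kinds) != 1:
        raise ValidationError(f"mechanism mismatch among variants: {sorted(kinds)}")
    wt_rates = wt.as_dict()
    a_rates = mut_a.as_dict()
    b_rates = mut_b.as_dict()
    expected = {}
    for name, k_wt in wt_rates.items():
        if name == "k_minus2" and k_wt == 0:
            if a_rates[name] != 0 or b_rates[name] != 0:
                raise ValidationError("k_minus2 zero in wt but nonzero in a mutant")
            expected[name] = 0.0
        else:
            expected[name] = k_wt * (a_rates[name] / k_wt) * (b_rates[name] / k_wt)
    return RateConstantSet(mechanism=wt.mechanism, **expected)


def specific_epistasis(
    observed_double: RateConstantSet, expected_double: RateConstantSet
) -> dict[str, float]:
    """Observed/expected fold per rate constant (1 = perfectly additive)."""
    if observed_double.mechanism != expected_double.mechanism:
        raise ValidationError("mechanism mismatch between observed and expected")
    obs = observed_double.as_dict()
    exp = expected_double.as_dict()
    out = {}
    for name in obs:
        if exp[name] == 0 and obs[name] == 0:
            out[name] = 1.0
        else:
            out[name] = obs[name] / exp[name]
    return out


@dataclass
class CorrectionReport:
    """Per-parameter decomposition of apparent epistasis.

    ``nonspecific[p] * corrected_specific[p] == apparent_specific[p]``
    exactly; ``nonspecific`` is the epistasis the kinetic map would create
    even with perfectly additive rate constants.
    """

    mechanism: str
    rate_specific_epistasis: dict[str, float]
    expected_double_rates: dict[str, float]
    computed_params: dict[str, dict[str, float]]
    null_double: dict[str, float]
    corrected_null_double: dict[str, float]
    nonspecific: dict[str, float]
    apparent_specific: dict[str, float]
    corrected_specific: dict[str, float]
    fold_errors: dict[str, dict[str, float]]
    warnings: list[str]

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "rate_specific_epistasis": self.rate_specific_epistasis,
            "expected_double_rates": self.expected_double_rates,
            "computed_params": self.computed_params,
            "null_double": self.null_double,
            "corrected_null_double": self.corrected_null_double,
            "nonspecific": self.nonspecific,
            "apparent_specific": self.apparent_specific,
            "corrected_specific": self.corrected_specific,
            "fold_errors": self.fold_errors,
            "warnings": self.warnings,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def correction_report(data: ExperimentalVariantSet) -> CorrectionReport:
    """Full correction workflow for one wt / mutA / mutB / double quartet."""
    warnings = [
        f"rate constant {name} of variant {variant!r} is a reported bound, "
        "used at face value"
        for variant, names in data.bound_flags.items()
        for name in names
    ]
    expected = expected_double_rates(data.rates["wt"], data.rates["mutA"], data.rates["mutB"])
    rate_eps = specific_epistasis(data.rates["double"], expected)

    params = {
        variant: kinetic_parameters(data.rates[variant]).as_dict()
        for variant in VARIANTS
    }
    corrected_params = kinetic_parameters(expected).as_dict()

    null = {}
    nonspecific = {}
    apparent = {}
    corrected = {}
    for param in PARAM_NAMES:
        wt = params["wt"][param]
        null[param] = wt * (params["mutA"][param] / wt) * (params["mutB"][param] / wt)
        nonspecific[param] = corrected_params[param] / null[param]
        apparent[param] = params["double"][param] / null[param]
        corrected[param] = params["double"][param] / corrected_params[param]

    fold_errors: dict[str, dict[str, float]] = {}
    for variant, measured in data.measured.items():
        per_variant = {}
        for param, value in measured.items():
            if param not in PARAM_NAMES:
                raise ValidationError(
                    f"unknown measured parameter {param!r} for variant {variant!r}"
                )
            error = fold_error(value, params[variant][param])
            per_variant[param] = error
            if error > FOLD_ERROR_FLAG:
                warnings.append(
                    f"computed {param} of {variant!r} deviates {error:.2f}-fold "
                    f"from the measured value (> {FOLD_ERROR_FLAG}-fold)"
                )
        fold_errors[variant] = per_variant

    return CorrectionReport(
        mechanism=data.mechanism,
        rate_specific_epistasis=rate_eps,
        expected_double_rates=expected.as_dict(),
        computed_params=params,
        null_double=null,
        corrected_null_double=corrected_params,
        nonspecific=nonspecific,
        apparent_specific=apparent,
        corrected_specific=corrected,
        fold_errors=fold_errors,
        warnings=warnings,
    )
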