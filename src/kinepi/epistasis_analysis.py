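"""Epistasis quantification and classification against the multiplicative null.

For a kinetic parameter p, the null prediction of a double mutant is
``p_wt * (p1/p_wt) * (p2/p_wt)`` and the epistasis factor is
``epsilon = p12_observed / p12_null``.  A pair is significant at a fold
threshold t when ``|log epsilon| >= log t``.  Significant pairs are signed
(positive if epsilon > 1) and typed by how many of the two single effects
flip sign between genetic backgrounds: none -> magnitude, one -> sign,
both -> reciprocal sign.

Two flip-detection rules are provided.  The default, ``"thresholded"``,
counts a flip only when the mutation's effect is significant at the same
fold threshold in *both* backgrounds and opposite in sign (i.e. it moves
from significantly beneficial to significantly deleterious or vice versa);
effects inside the threshold band are treated as neutral.  ``"strict"``
counts any sign change of the log fold-change regardless of size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mechanism_core import PARAM_NAMES, ValidationError
from .mutation_simulator import VariantTable

__all__ = [
    "DEFAULT_THRESHOLDS",
    "EpistasisRecord",
    "EpistasisSummary",
    "null_predicted",
    "epsilon",
    "classify",
    "summarize",
    "records_frame",
]

DEFAULT_THRESHOLDS = (1.5, 2.0, 5.0, 10.0)

SIGN_CLASSES = ("positive", "negative")
TYPE_CLASSES = ("magnitude", "sign", "reciprocal_sign")


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not (value > 0 and math.isfinite(value)):
            raise ValidationError(f"{name} must be positive and finite, got {value}")


def null_predicted(p_wt: float, p1: float, p2: float) -> float:
    """Multiplicative-null double-mutant parameter: p_wt * fold1 * fold2."""
    _require_positive(p_wt=p_wt, p1=p1, p2=p2)
    return p_wt * (p1 / p_wt) * (p2 / p_wt)


def epsilon(observed: float, predicted: float) -> float:
    """Epistasis factor: observed double parameter over the null prediction."""
    _require_positive(observed=observed, predicted=predicted)
    return observed / predicted


FLIP_RULES = ("thresholded", "strict")


def _is_flip(effect_wt: float, effect_other_bg: float, log_thr: float, rule: str) -> bool:
    if effect_wt * effect_other_bg >= 0:  # exact zero counts as no flip
        return False
    if rule == "strict":
        return True
    return abs(effect_wt) >= log_thr and abs(effect_other_bg) >= log_thr


def classify(
    p_wt: float,
    p1: float,
    p2: float,
    p12_observed: float,
    threshold: float = 1.5,
    flip_rule: str = "thresholded",
) -> tuple[str, str]:
    """Sign and type of a double mutant's epistasis in one parameter.

    Returns ``(sign, type)`` with sign in {"positive", "negative", "none"}
    and type in {"magnitude", "sign", "reciprocal_sign", "none"}.  A pair is
    typed only if significant: |log epsilon| >= log(threshold).  The type
    counts background-dependent sign flips of each single effect, where
    mutation 1's effects are log(p1/p_wt) (wt background) and log(p12/p2)
    (background of mutation 2); see the module docstring for the two
    ``flip_rule`` options.
    """
    _require_positive(p_wt=p_wt, p1=p1, p2=p2, p12_observed=p12_observed)
    if not threshold > 1:
        raise ValidationError(f"threshold must exceed 1, got {threshold}")
    if flip_rule not in FLIP_RULES:
        raise ValidationError(f"flip_rule must be one of {FLIP_RULES}, got {flip_rule!r}")
    eps = p12_observed / null_predicted(p_wt, p1, p2)
    log_thr = math.log(threshold)
    if abs(math.log(eps)) < log_thr:
        return ("none", "none")
    sign = "positive" if eps > 1 else "negative"
    flips = sum(
        _is_flip(
            math.log(own / p_wt),
            math.log(p12_observed / other),
            log_thr,
            flip_rule,
        )
        for own, other in ((p1, p2), (p2, p1))
    )
    kind = {0: "magnitude", 1: "sign", 2: "reciprocal_sign"}[flips]
    return (sign, kind)


@dataclass
class EpistasisRecord:
    """Epistasis of one pair in one kinetic parameter."""

    pair_id: str
    parameter: str
    observed_fold: float
    predicted_fold: float
    epsilon: float
    significant: dict[float, bool]
    sign: str
    type: str


@dataclass
class EpistasisSummary:
    """Prevalence and class shares of epistasis across a variant table.

    ``prevalence_pct[param][t]`` is the percent of all pairs significant at
    threshold t.  ``class_shares_pct`` (magnitude/sign/reciprocal_sign) are
    percents of *all* pairs at the primary (first) threshold and sum to the
    primary prevalence; ``sign_shares_pct`` (positive/negative) are percents
    of the *significant* pairs at the primary threshold.
    """

    mechanism: str
    n_singles: int
    n_pairs: int
    thresholds: tuple[float, ...]
    prevalence_pct: dict[str, dict[float, float]]
    class_shares_pct: dict[str, dict[str, float]]
    sign_shares_pct: dict[str, dict[str, float]]
    counts: dict[str, dict]

    @property
    def primary_threshold(self) -> float:
        return self.thresholds[0]

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "n_singles": self.n_singles,
            "n_pairs": self.n_pairs,
            "thresholds": list(self.thresholds),
            "parameters": {
                param: {
                    "prevalence_pct": {
                        str(t): self.prevalence_pct[param][t] for t in self.thresholds
                    },
                    "class_shares_pct": self.class_shares_pct[param],
                    "sign_shares_pct": self.sign_shares_pct[param],
                    "counts": self.counts[param],
                }
                for param in PARAM_NAMES
            },
        }


def _pair_analysis(
    table: VariantTable,
    param: str,
    thresholds: Sequence[float],
    flip_rule: str = "thresholded",
) -> dict[str, np.ndarray]:
    """Vectorized epsilon / significance / sign / flip counts for one parameter.

    Flips are evaluated at the primary (first) threshold.
    """
    if flip_rule not in FLIP_RULES:
        raise ValidationError(f"flip_rule must be one of {FLIP_RULES}, got {flip_rule!r}")
    wt = table.wt_params[param]
    p1 = table.single_params[param][table.pair_i]
    p2 = table.single_params[param][table.pair_j]
    obs = table.pair_params[param]
    null = table.pair_null[param]
    eps = obs / null
    log_eps = np.log(eps)
    significant = {
        t: np.abs(log_eps) >= math.log(t) - 1e-12 * math.log(t) for t in thresholds
    }
    log_thr = math.log(thresholds[0])
    e1 = np.log(p1 / wt)
    e1_bg = np.log(obs / p2)
    e2 = np.log(p2 / wt)
    e2_bg = np.log(obs / p1)
    flip1 = e1 * e1_bg < 0
    flip2 = e2 * e2_bg < 0
    if flip_rule == "thresholded":
        flip1 &= (np.abs(e1) >= log_thr) & (np.abs(e1_bg) >= log_thr)
        flip2 &= (np.abs(e2) >= log_thr) & (np.abs(e2_bg) >= log_thr)
    flips = flip1.astype(np.int8) + flip2.astype(np.int8)
    return {
        "epsilon": eps,
        "log_eps": log_eps,
        "significant": significant,
        "flips": flips,
        "observed_fold": obs / wt,
        "predicted_fold": null / wt,
    }


def summarize(
    table: VariantTable,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    flip_rule: str = "thresholded",
) -> EpistasisSummary:
    """Prevalence, class shares, and sign shares per kinetic parameter.

    The first threshold is the primary one used for classification; the
    conventional default is 1.5-fold with 2-, 5-, and 10-fold companions.
    """
    if table.n_pairs < 1:
        raise ValidationError("variant table has no pairs to summarize")
    thresholds = tuple(float(t) for t in thresholds)
    if not thresholds or any(t <= 1 for t in thresholds):
        raise ValidationError(f"thresholds must all exceed 1, got {thresholds}")
    n_pairs = table.n_pairs
    prevalence: dict[str, dict[float, float]] = {}
    class_shares: dict[str, dict[str, float]] = {}
    sign_shares: dict[str, dict[str, float]] = {}
    counts: dict[str, dict] = {}
    for param in PARAM_NAMES:
        res = _pair_analysis(table, param, thresholds, flip_rule)
        sig_counts = {t: int(res["significant"][t].sum()) for t in thresholds}
        prevalence[param] = {t: 100.0 * sig_counts[t] / n_pairs for t in thresholds}
        primary = res["significant"][thresholds[0]]
        n_sig = sig_counts[thresholds[0]]
        flips = res["flips"][primary]
        class_counts = {
            "magnitude": int((flips == 0).sum()),
            "sign": int((flips == 1).sum()),
            "reciprocal_sign": int((flips == 2).sum()),
        }
        positive = int((res["epsilon"][primary] > 1).sum())
        sign_counts = {"positive": positive, "negative": n_sig - positive}
        class_shares[param] = {
            k: 100.0 * v / n_pairs for k, v in class_counts.items()
        }
        sign_shares[param] = {
            k: (100.0 * v / n_sig if n_sig else 0.0) for k, v in sign_counts.items()
        }
        counts[param] = {
            "pairs": n_pairs,
            "significant": {str(t): sig_counts[t] for t in thresholds},
            "classes": class_counts,
            "sign": sign_counts,
        }
    return EpistasisSummary(
        mechanism=table.mechanism,
        n_singles=table.n_singles,
        n_pairs=n_pairs,
        thresholds=thresholds,
        prevalence_pct=prevalence,
        class_shares_pct=class_shares,
        sign_shares_pct=sign_shares,
        counts=counts,
    )


def records_frame(
    table: VariantTable,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    flip_rule: str = "thresholded",
) -> pd.DataFrame:
    """Long-form per-pair epistasis table (one row per pair and parameter)."""
    thresholds = tuple(float(t) for t in thresholds)
    pair_ids = np.array(
        [f"m{i}_m{j}" for i, j in zip(table.pair_i, table.pair_j)], dtype=object
    )
    frames = []
    for param in PARAM_NAMES:
        res = _pair_analysis(table, param, thresholds, flip_rule)
        primary = res["significant"][thresholds[0]]
        sign = np.where(primary, np.where(res["epsilon"] > 1, "positive", "negative"), "none")
        kind = np.where(
            primary,
            np.choose(res["flips"], ["magnitude", "sign", "reciprocal_sign"]),
            "none",
        )
        data = {
            "pair_id": pair_ids,
            "parameter": param,
            "observed_fold": res["observed_fold"],
            "predicted_fold": res["predicted_fold"],
            "epsilon": res["epsilon"],
        }
        for t in thresholds:
            label = f"{t:g}x"
            data[f"significant_{label}"] = res["significant"][t]
        data["sign"] = sign
        data["type"] = kind
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)
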