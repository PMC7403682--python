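"""Line-cross expectations, adaptation strength, and the variance-on-
adaptation regression.

Works on the probability scale of the mean-model predictions: the
midparent is the unweighted mean of the four ecotype means, the additive
F1 expectation equals the midparent, the F4 expectation is the midpoint of
the midparent and the observed F1 mean, and heterosis is the deviation of
an observed hybrid mean from its expectation. All identities are evaluated
per posterior draw so HPD intervals of deviations are HPDs of the per-draw
deviation sequence.

Adaptation strength in a habitat is the native ecotype's predicted fitness
minus the unweighted mean of the three foreign ecotypes'. The regression
of a generation's fitness variance on adaptation strength across the four
habitats is an ordinary least-squares slope computed per posterior draw,
pairing mean-model and character-state draws by index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import hpd_interval, posterior_summary, smallest_hpd_excluding_zero
from .fitmodels import GenerationCovPosterior


@dataclass
class LineCrossExpectation:
    habitat: str
    midparent: dict
    f1_observed: dict
    f1_deviation: dict          # heterosis: F1 - midparent
    f4_expected: dict           # (midparent + F1 observed)/2
    f4_observed: dict
    f4_deviation: dict
    draws: dict = field(default_factory=dict)


@dataclass
class AdaptationSummary:
    habitats: list
    native_map: dict
    strength_draws: np.ndarray   # (S, n_habitats)
    summaries: list


@dataclass
class SlopePosterior:
    generation: str
    slope_draws: np.ndarray
    summary: dict
    fraction_negative: float
    smallest_hpd_excluding_zero: float


def _require(cell_draws: dict, habitat, category) -> np.ndarray:
    try:
        return cell_draws[(habitat, category)]
    except KeyError:
        raise KeyError(f"no posterior draws for category {category!r} in "
                       f"habitat {habitat!r}")


def midparent_expectations(cell_draws: dict, habitat: str, ecotypes: list,
                           f1_categories: list, prob: float = 0.95) -> LineCrossExpectation:
    """Midparent / F1 / F4 expectations and deviations for one habitat.

    ``cell_draws`` maps (habitat, category) to aligned posterior probability
    draws. The observed F1 mean averages the F1 cross-type categories.
    """
    eco = np.stack([_require(cell_draws, habitat, e) for e in ecotypes])
    mid = eco.mean(axis=0)
    f1 = np.stack([_require(cell_draws, habitat, c) for c in f1_categories]).mean(axis=0)
    f4 = _require(cell_draws, habitat, "F4")
    f4_exp = 0.5 * (mid + f1)
    draws = {"midparent": mid, "f1_observed": f1, "f1_deviation": f1 - mid,
             "f4_expected": f4_exp, "f4_observed": f4, "f4_deviation": f4 - f4_exp}
    summ = {k: posterior_summary(v, prob) for k, v in draws.items()}
    return LineCrossExpectation(habitat, summ["midparent"], summ["f1_observed"],
                                summ["f1_deviation"], summ["f4_expected"],
                                summ["f4_observed"], summ["f4_deviation"], draws)


def adaptation_strength(cell_draws: dict, native_map: dict, ecotypes: list,
                        prob: float = 0.95) -> AdaptationSummary:
    """Native minus mean-foreign predicted fitness per habitat, per draw."""
    habitats = sorted({h for h, _ in cell_draws})
    missing = [h for h in habitats if h not in native_map]
    if missing:
        raise ValueError(f"native_map lacks habitats {missing}")
    if len(set(native_map.values())) != len(native_map):
        raise ValueError("native_map assigns one ecotype to several habitats")
    strengths = []
    summaries = []
    for h in habitats:
        native = _require(cell_draws, h, native_map[h])
        foreign = np.stack([_require(cell_draws, h, e)
                            for e in ecotypes if e != native_map[h]]).mean(axis=0)
        s = native - foreign
        strengths.append(s)
        summaries.append({"habitat": h} | posterior_summary(s, prob))
    return AdaptationSummary(habitats, dict(native_map),
                             np.stack(strengths, axis=1), summaries)


def variance_adaptation_regression(adapt: AdaptationSummary,
                                   var_posterior: GenerationCovPosterior,
                                   prob: float = 0.95) -> SlopePosterior:
    """OLS slope of habitat fitness variance on adaptation strength, per draw.

    Strength and variance draws are paired by index (the two models are
    fitted separately, so joint draws do not exist; index pairing preserves
    each marginal posterior).
    """
    if list(adapt.habitats) != list(var_posterior.habitats):
        raise ValueError("habitat sets differ between strength and variance posteriors")
    n_h = len(adapt.habitats)
    if n_h < 3:
        raise ValueError("regression needs at least 3 habitats")
    S = min(adapt.strength_draws.shape[0], var_posterior.draws.shape[0])
    x = adapt.strength_draws[:S]                       # (S, H)
    v = np.einsum("shh->sh", var_posterior.draws[:S])  # diagonal variances
    xc = x - x.mean(axis=1, keepdims=True)
    vc = v - v.mean(axis=1, keepdims=True)
    denom = (xc * xc).sum(axis=1)
    if np.any(denom == 0):
        slopes = np.where(denom == 0, 0.0, (xc * vc).sum(axis=1) / np.where(denom == 0, 1, denom))
    else:
        slopes = (xc * vc).sum(axis=1) / denom
    frac_neg = float((slopes < 0).mean())
    return SlopePosterior(var_posterior.generation, slopes,
                          posterior_summary(slopes, prob), frac_neg,
                          smallest_hpd_excluding_zero(slopes))


def linecross_table(cell_draws: dict, habitats: list, ecotypes: list,
                    f1_categories: list, prob: float = 0.95) -> pd.DataFrame:
    """Fig-3-style table: one row per habitat and quantity, with HPDs."""
    rows = []
    for h in habitats:
        lce = midparent_expectations(cell_draws, h, ecotypes, f1_categories, prob)
        for name in ("midparent", "f1_observed", "f1_deviation",
                     "f4_expected", "f4_observed", "f4_deviation"):
            rows.append({"habitat": h, "quantity": name} | getattr(lce, name))
    return pd.DataFrame(rows)
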