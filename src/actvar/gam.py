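"""Factor-term generalized additive model for per-participant CDI.

The model G(E(CDI)) = beta0 + f_sex(sex) + f_WR(WR) + f_age(age) has an
identity link, Gaussian errors and purely categorical (factor) terms with
no smoothing penalty, so it is exactly an ordinary least-squares fit with
sum-to-zero-coded factors: each factor's level effects sum to zero and a
2-level factor reports symmetric +/- effects.  Goodness of fit is the
likelihood-ratio pseudo-R^2 — the proportional reduction in deviance
(residual vs null), reported as a percentage; for a Gaussian identity-link
model the deviance is the residual sum of squares.  Feature importance is
the drop in pseudo-R^2 when a factor is left out and the model refit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

log = logging.getLogger(__name__)

DEFAULT_FACTORS = ("sex", "wr", "age")


@dataclass
class GamSpec:
    """Response column, factor columns and interaction order (1-3)."""

    response: str = "cdi"
    factors: Sequence[str] = DEFAULT_FACTORS
    interaction_order: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.interaction_order <= 3:
            raise ValueError("interaction_order must be 1, 2 or 3")
        if self.interaction_order > len(self.factors):
            raise ValueError("interaction order exceeds the number of factors")

    def formula(self) -> str:
        mains = [f"C({f}, Sum)" for f in self.factors]
        terms = list(mains)
        for order in range(2, self.interaction_order + 1):
            for combo in itertools.combinations(mains, order):
                terms.append(":".join(combo))
        return f"{self.response} ~ " + " + ".join(terms)


@dataclass
class GamFit:
    """Fitted factor GAM: intercept, per-level effects, fit quality."""

    spec: GamSpec
    beta0: float
    effects: Mapping[str, Mapping[str, float]]
    pseudo_r2: float                 # percent of null deviance explained
    term_pvalues: Mapping[str, float]
    result: object = field(repr=False)

    def predict_cell(self, **levels) -> float:
        """Main-effects prediction beta0 + sum of the cell's level effects."""
        total = self.beta0
        for factor, level in levels.items():
            total += self.effects[factor][level]
        return total

    def phenotype_predictions(self) -> pd.DataFrame:
        """Predictions for every combination of factor levels, ordered
        by predicted value (one row per phenotype cell)."""
        factors = list(self.effects)
        level_lists = [sorted(self.effects[f]) for f in factors]
        rows = []
        for combo in itertools.product(*level_lists):
            cell = dict(zip(factors, combo))
            rows.append({**cell, "predicted": self.predict_cell(**cell)})
        return (pd.DataFrame(rows)
                .sort_values("predicted")
                .reset_index(drop=True))


def _check_table(table: pd.DataFrame, spec: GamSpec) -> None:
    for f in spec.factors:
        if f not in table.columns:
            raise ValueError(f"table lacks factor column {f!r}")
        counts = table[f].value_counts()
        if (counts == 0).any() or counts.empty:
            raise ValueError(f"factor {f!r} has an unobserved level")
    if spec.response not in table.columns:
        raise ValueError(f"table lacks response column {spec.response!r}")


def fit_gam(table: pd.DataFrame, spec: GamSpec | None = None) -> GamFit:
    """Fit the identity-link factor GAM by sum-to-zero-coded least squares."""
    if spec is None:
        spec = GamSpec()
    _check_table(table, spec)
    data = table.copy()
    for f in spec.factors:
        data[f] = data[f].astype(str)
    model = smf.ols(spec.formula(), data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("rank-deficient design: aliased levels among "
                         f"factors {tuple(spec.factors)}")
    result = model.fit()
    pseudo_r2 = 100.0 * (1.0 - result.ssr / result.centered_tss)

    effects: dict[str, dict[str, float]] = {}
    for f in spec.factors:
        levels = sorted(data[f].unique())
        eff = {}
        for lev in levels[:-1]:
            eff[lev] = float(result.params[f"C({f}, Sum)[S.{lev}]"])
        eff[levels[-1]] = -sum(eff.values())
        effects[f] = eff

    with np.errstate(invalid="ignore"):
        aov = anova_lm(result, typ=2)
    term_p = {}
    for f in spec.factors:
        term_p[f] = float(aov.loc[f"C({f}, Sum)", "PR(>F)"])
    return GamFit(spec, float(result.params["Intercept"]), effects,
                  float(pseudo_r2), term_p, result)


def feature_importance(fit: GamFit, table: pd.DataFrame) -> dict[str, float]:
    """Drop in pseudo-R^2 (percentage points) when each factor is left out."""
    out = {}
    for f in fit.spec.factors:
        remaining = [x for x in fit.spec.factors if x != f]
        if remaining:
            reduced = fit_gam(table, GamSpec(fit.spec.response, remaining, 1))
            out[f] = fit.pseudo_r2 - reduced.pseudo_r2
        else:
            out[f] = fit.pseudo_r2
    return out


@dataclass
class ModelSelection:
    """Outcome of the three-model comparison and factor pruning."""

    pseudo_r2_by_order: Mapping[int, float]
    main_term_pvalues: Mapping[str, float]
    dropped: tuple
    chosen: GamSpec
    final_fit: GamFit


def select_model(table: pd.DataFrame, factors: Sequence[str] = ("sex", "wr", "age", "cyclic"),
                 response: str = "cdi", alpha: float = 0.05) -> ModelSelection:
    """Compare main-effects, +2-way and +2&3-way models; prune null factors.

    All three interaction orders are fit and their pseudo-R^2 recorded
    (nesting guarantees it never decreases with order).  Any factor whose
    term is not significantly different from 0 in the main-effects model is
    dropped, and the reduced main-effects model refit and returned.
    """
    r2 = {}
    main_fit = None
    for order in (1, 2, 3):
        try:
            fit = fit_gam(table, GamSpec(response, factors, order))
        except ValueError as exc:
            if order == 1:
                raise
            # empty cells alias interaction levels on small cohorts
            log.warning("order-%d model not estimable (%s); skipped", order, exc)
            continue
        r2[order] = fit.pseudo_r2
        if order == 1:
            main_fit = fit
    dropped = tuple(f for f, p in main_fit.term_pvalues.items() if p >= alpha)
    kept = [f for f in factors if f not in dropped]
    if not kept:
        # no factor clears the bar: report the unpruned main-effects model
        log.warning("no factor term significant at %.2g; keeping all", alpha)
        dropped = ()
        kept = list(factors)
    final_spec = GamSpec(response, kept, 1)
    final_fit = fit_gam(table, final_spec)
    if dropped:
        log.info("dropped factors with null effects: %s", ", ".join(dropped))
    return ModelSelection(r2, dict(main_fit.term_pvalues), dropped,
                          final_spec, final_fit)
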