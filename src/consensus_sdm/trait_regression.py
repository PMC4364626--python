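"""Trait regressions: simple OLS and forward stepwise multiple regression.

Map-correlation and model-performance responses are related to the nine
candidate predictors (latitudinal, thermal, and elevation ranges,
prevalence, specialization, marginality, and the AUC/kappa/TSS accuracy
means) by ordinary least squares. Stepwise selection is bidirectional with
classic entry/removal levels: at each step the candidate with the smallest
partial-F p-value enters if p <= alpha_enter, then any included predictor
whose p-value rises above alpha_remove leaves; iteration stops at a
fixpoint. The procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

CANDIDATE_PREDICTORS = [
    "lat_range", "thermal_range", "elev_range", "prevalence",
    "specialization", "marginality", "auc", "kappa", "tss",
]


@dataclass
class RegressionResult:
    selected_predictors: list[str]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    intercept: float
    r_squared: float
    n: int
    entry_order: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = [{
            "predictor": name,
            "coefficient": self.coefficients[name],
            "std_error": self.std_errors[name],
            "t": self.t_values[name],
            "p_value": self.p_values[name],
            "step_entered": self.entry_order.index(name) + 1
            if name in self.entry_order else 0,
        } for name in self.selected_predictors]
        return pd.DataFrame(rows)


def _ols_result(y: np.ndarray, X: pd.DataFrame, entry_order: list[str]) -> RegressionResult:
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design).fit()
    names = list(X.columns)
    return RegressionResult(
        selected_predictors=names,
        coefficients={n: float(fit.params[n]) for n in names},
        std_errors={n: float(fit.bse[n]) for n in names},
        t_values={n: float(fit.tvalues[n]) for n in names},
        p_values={n: float(fit.pvalues[n]) for n in names},
        intercept=float(fit.params["const"]),
        r_squared=float(fit.rsquared) if names else 0.0,
        n=len(y),
        entry_order=entry_order,
    )


def simple_linreg(y, x, name: str = "x") -> RegressionResult:
    """Ordinary least squares of y on a single predictor."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size:
        raise ValueError("y and x differ in length")
    if y.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope undefined")
    X = pd.DataFrame({name: x})
    return _ols_result(y, X, entry_order=[name])


def forward_stepwise(y, X: pd.DataFrame, alpha_enter: float = 0.05,
                     alpha_remove: float = 0.10,
                     multiplicity: str = "bonferroni") -> RegressionResult:
    """Bidirectional stepwise OLS (forward entry with backward removal).

    The partial-F p-value of adding one predictor to the current model
    equals the two-sided t-test p-value of its coefficient in the augmented
    fit, which is what is used here. Because every step screens several
    candidates at once, the entry test is Bonferroni-adjusted by default
    (the best candidate enters if min(1, p * n_candidates_tested) <=
    alpha_enter); this keeps the per-step false-entry rate near alpha_enter
    regardless of how many noise predictors are offered. Pass
    ``multiplicity="raw"`` for the uncorrected rule. If no predictor ever
    enters, the intercept-only result is returned (not an error).
    """
    if multiplicity not in ("bonferroni", "raw"):
        raise ValueError(f"unknown multiplicity rule {multiplicity!r}")
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y and X differ in length")
    if alpha_remove < alpha_enter:
        raise ValueError("alpha_remove must be >= alpha_enter for termination")
    candidates = [c for c in X.columns
                  if np.ptp(X[c].to_numpy(dtype=float)) > 0]
    included: list[str] = []
    entry_order: list[str] = []
    seen_states: set[tuple[str, ...]] = set()

    while True:
        state = tuple(sorted(included))
        if state in seen_states:
            break
        seen_states.add(state)
        changed = False

        # forward entry: smallest augmented-model p-value
        best_p, best_c = None, None
        n_tested = 0
        for c in candidates:
            if c in included:
                continue
            design = sm.add_constant(X[included + [c]], has_constant="add")
            try:
                fit = sm.OLS(y, design).fit()
            except Exception:
                continue
            p = float(fit.pvalues[c])
            if np.isnan(p):
                continue
            n_tested += 1
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and multiplicity == "bonferroni":
            best_p = min(1.0, best_p * n_tested)
        if best_c is not None and best_p <= alpha_enter:
            included.append(best_c)
            entry_order.append(best_c)
            changed = True

        # backward removal: drop the worst included predictor above the bar
        if included:
            design = sm.add_constant(X[included], has_constant="add")
            fit = sm.OLS(y, design).fit()
            pvals = {c: float(fit.pvalues[c]) for c in included}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] > alpha_remove:
                included.remove(worst)
                changed = True

        if not changed:
            break

    return _ols_result(y, X[included], entry_order=entry_order)


def trait_tables(traits: pd.DataFrame, responses: pd.DataFrame,
                 predictors: list[str] | None = None,
                 alpha_enter: float = 0.05, alpha_remove: float = 0.10,
                 ) -> dict[str, RegressionResult]:
    """Stepwise fit of every response column on the trait predictors.

    ``traits`` holds one row per species with the candidate predictor
    columns; ``responses`` holds, per species (aligned index), response
    columns such as mean map Pearson/kappa per period or mean model
    accuracy. Returns one RegressionResult per response column.
    """
    predictors = list(predictors or [c for c in CANDIDATE_PREDICTORS
                                     if c in traits.columns])
    missing = [p for p in predictors if p not in traits.columns]
    if missing:
        raise ValueError(f"missing trait columns: {missing}")
    if len(traits) < 10:
        raise ValueError("need >= 10 species rows for the trait regressions")
    X = traits[predictors].astype(float)
    out = {}
    for resp in responses.columns:
        y = responses[resp].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            out[resp] = _ols_result(y, X[[]], entry_order=[])
        else:
            out[resp] = forward_stepwise(y, X, alpha_enter=alpha_enter,
                                         alpha_remove=alpha_remove)
    return out
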