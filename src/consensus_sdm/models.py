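"""Niche-model adapters and ensemble calibration.

A :class:`ModelAdapter` gives every presence/absence learner one surface:
``fit(calibration, layers, seed)`` then ``predict(X) -> P(presence)`` in
[0, 1]. The default menu carries eight adapters filling the roles of the
classic niche-modelling algorithm families — GLM, GAM, MARS, MDA, CTA, GBM,
ANN, RF — each backed by a standard scikit-learn learner:

=====  =========================================================
glm    logistic regression on standardized predictors
gam    logistic regression on a small cubic-spline basis
       (a few effective degrees of freedom per predictor)
mars   logistic regression on a degree-1 (hinge) spline basis
mda    linear discriminant analysis with probability outputs
cta    classification tree
gbm    gradient-boosted trees
ann    single-hidden-layer perceptron
rf     random forest
=====  =========================================================

An envelope adapter (``sre``) is also available: probability 1 inside the
presence min-max envelope, 0 outside. Additional classes can be registered
at run time. Fit failures are first-class: they are recorded per key and
excluded by the evaluation filter rather than crashing the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grids import EnvGrid, SpeciesDistribution, ScenarioSet
from .pseudoabsence import Bout, Envelope, fit_sre


class NotFittedError(RuntimeError):
    pass


class FitFailure(RuntimeError):
    """A learner failed to calibrate on this bout."""


@dataclass
class ModelAdapter:
    """Uniform wrapper around one presence/absence learner.

    ``factory(seed)`` must return an unfitted estimator with
    ``predict_proba``; the adapter handles layer bookkeeping, the fitted
    flag, and probability-range checks.
    """

    model_class_id: str
    factory: Callable[[int], object]
    _estimator: object | None = field(default=None, repr=False)
    _layers: list[str] | None = field(default=None, repr=False)

    @property
    def is_fitted(self) -> bool:
        return self._estimator is not None

    def fit(self, calibration: pd.DataFrame, layers: list[str], seed: int = 0) -> "ModelAdapter":
        """Train on the calibration rows (label column: presence/absence)."""
        y = (calibration["label"] == "presence").to_numpy()
        if y.all() or not y.any():
            raise FitFailure(
                f"{self.model_class_id}: calibration data contain one class only"
            )
        X = calibration[layers].to_numpy(dtype=float)
        est = self.factory(seed)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(X, y)
        except Exception as exc:  # numerically failed fit -> recorded upstream
            raise FitFailure(f"{self.model_class_id}: {exc}") from exc
        self._estimator = est
        self._layers = list(layers)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise NotFittedError(f"{self.model_class_id} is not fitted")
        proba = self._estimator.predict_proba(np.asarray(X, dtype=float))
        classes = list(self._estimator.classes_)
        p = proba[:, classes.index(True)]
        return np.clip(p, 0.0, 1.0)

    def project(self, env: EnvGrid) -> "ModelProjection":
        """Per-cell probability of presence on the masked-in cells."""
        if not self.is_fitted:
            raise NotFittedError(f"{self.model_class_id} is not fitted")
        missing = set(self._layers) - set(env.layer_names)
        if missing:
            raise KeyError(
                f"{self.model_class_id}: grid lacks fitted layer(s) {sorted(missing)}"
            )
        rows, cols = np.nonzero(env.mask)
        X = np.column_stack([env.layer(n)[rows, cols] for n in self._layers])
        probs = np.full(env.shape, np.nan)
        probs[rows, cols] = self.predict(X)
        return ModelProjection(probs=probs, model_class=self.model_class_id)


class EnvelopeAdapter:
    """Presence-only envelope model (SRE) under the adapter surface:
    probability exactly 1 inside the calibration-presence envelope, 0
    outside."""

    model_class_id = "sre"

    def __init__(self) -> None:
        self._envelope: Envelope | None = None
        self._layers: list[str] | None = None

    @property
    def is_fitted(self) -> bool:
        return self._envelope is not None

    def fit(self, calibration: pd.DataFrame, layers: list[str], seed: int = 0) -> "EnvelopeAdapter":
        pres = calibration[calibration["label"] == "presence"]
        if len(pres) < 2:
            raise FitFailure("sre: need >= 2 presences")
        self._envelope = Envelope(bounds={
            n: (float(pres[n].min()), float(pres[n].max())) for n in layers
        })
        self._layers = list(layers)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise NotFittedError("sre is not fitted")
        X = np.asarray(X, dtype=float)
        inside = np.ones(X.shape[0], dtype=bool)
        for j, name in enumerate(self._layers):
            lo, hi = self._envelope.bounds[name]
            inside &= (X[:, j] >= lo) & (X[:, j] <= hi)
        return inside.astype(float)

    project = ModelAdapter.project


@dataclass
class ModelProjection:
    """Probability-of-presence grid tagged with its provenance."""

    probs: np.ndarray
    model_class: str
    bout: int | None = None
    scenario: tuple[int, int] | str = "baseline"
    period: str = "baseline"

    def __post_init__(self) -> None:
        finite = self.probs[np.isfinite(self.probs)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("projection probabilities outside [0, 1]")

    @property
    def key(self) -> tuple:
        return (self.model_class, self.bout, self.scenario, self.period)


# -- default adapter menu --------------------------------------------------

def _spline_logistic(degree: int, n_knots: int):
    def factory(seed: int):
        return make_pipeline(
            StandardScaler(),
            SplineTransformer(degree=degree, n_knots=n_knots),
            LogisticRegression(max_iter=500),
        )
    return factory


ADAPTER_FACTORIES: dict[str, Callable[[int], object]] = {
    "glm": lambda seed: make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=500)),
    # cubic splines with few knots: ~3 effective df of smoothing per predictor
    "gam": _spline_logistic(degree=3, n_knots=4),
    # degree-1 splines are piecewise-linear hinge features
    "mars": _spline_logistic(degree=1, n_knots=5),
    "mda": lambda seed: LinearDiscriminantAnalysis(),
    "cta": lambda seed: DecisionTreeClassifier(
        min_samples_leaf=5, random_state=seed),
    "gbm": lambda seed: GradientBoostingClassifier(
        n_estimators=50, max_depth=3, random_state=seed),
    "ann": lambda seed: make_pipeline(
        StandardScaler(),
        MLPClassifier(hidden_layer_sizes=(8,), max_iter=300, random_state=seed)),
    "rf": lambda seed: RandomForestClassifier(
        n_estimators=100, min_samples_leaf=2, random_state=seed),
}

DEFAULT_MENU = list(ADAPTER_FACTORIES)


def register_adapter(model_class_id: str, factory: Callable[[int], object]) -> None:
    """Add a user model class to the menu (factory(seed) -> estimator with
    predict_proba)."""
    ADAPTER_FACTORIES[model_class_id] = factory


def make_adapter(model_class_id: str):
    if model_class_id == "sre":
        return EnvelopeAdapter()
    if model_class_id not in ADAPTER_FACTORIES:
        raise KeyError(
            f"unknown model class {model_class_id!r}; "
            f"registered: {sorted(ADAPTER_FACTORIES)} + ['sre']"
        )
    return ModelAdapter(model_class_id=model_class_id,
                        factory=ADAPTER_FACTORIES[model_class_id])


# -- ensemble calibration --------------------------------------------------

@dataclass
class ProjectionEnsemble:
    """All projections keyed by (model_class, bout, scenario, period), with
    the fitted models and a log of fit failures."""

    projections: dict[tuple, ModelProjection] = field(default_factory=dict)
    models: dict[tuple[str, int], object] = field(default_factory=dict)
    fit_failures: dict[tuple[str, int], str] = field(default_factory=dict)

    def add(self, proj: ModelProjection) -> None:
        if proj.key in self.projections:
            raise KeyError(f"duplicate projection key {proj.key}")
        self.projections[proj.key] = proj

    def subset(self, *, period: str | None = None,
               bout: int | None = None,
               scenario=None,
               model_classes: list[str] | None = None) -> list[ModelProjection]:
        out = []
        for (mc, b, sc, pe), proj in self.projections.items():
            if period is not None and pe != period:
                continue
            if bout is not None and b != bout:
                continue
            if scenario is not None and sc != scenario:
                continue
            if model_classes is not None and mc not in model_classes:
                continue
            out.append(proj)
        return out

    def counts(self) -> dict:
        per_period: dict[str, int] = {}
        for (_, _, _, pe) in self.projections:
            per_period[pe] = per_period.get(pe, 0) + 1
        return {
            "n_models_fitted": len(self.models),
            "n_fit_failures": len(self.fit_failures),
            "n_projections_per_period": per_period,
        }


def calibrate_ensemble(bouts: list[Bout], layers: list[str],
                       scenarios: ScenarioSet,
                       menu: list[str] | None = None,
                       periods: list[str] | None = None,
                       seed: int = 0,
                       filter_keys: set[tuple[str, int]] | None = None,
                       ) -> ProjectionEnsemble:
    """Fit one model per (class, bout) and project baseline plus every
    (gcm, sres) scenario for the requested periods.

    With the full design — 8 classes, 9 bouts, 3x3 scenarios — this yields
    72 fitted models, 72 baseline projections, and 648 projections per
    future period. Failed fits are logged under ``fit_failures`` and simply
    contribute no projections.
    """
    menu = list(menu or DEFAULT_MENU)
    if not menu:
        raise ValueError("empty model menu")
    periods = list(periods if periods is not None else scenarios.periods)
    ens = ProjectionEnsemble()
    for mc_i, mc in enumerate(menu):
        for bout in bouts:
            key = (mc, bout.bout_id)
            adapter = make_adapter(mc)
            child = int(np.random.SeedSequence(
                [seed, mc_i, bout.bout_id]).generate_state(1)[0] % (2**31))
            try:
                adapter.fit(bout.calibration, layers, seed=child)
            except FitFailure as exc:
                warnings.warn(f"fit failure for {key}: {exc}")
                ens.fit_failures[key] = str(exc)
                continue
            ens.models[key] = adapter
            proj = adapter.project(scenarios.baseline)
            proj.bout = bout.bout_id
            ens.add(proj)
            for period in periods:
                for (gcm, sres), grid in scenarios.for_period(period).items():
                    p = adapter.project(grid)
                    p.bout = bout.bout_id
                    p.scenario = (gcm, sres)
                    p.period = period
                    ens.add(p)
    return ens


def evaluate_ensemble(ens: ProjectionEnsemble, bouts: list[Bout],
                      layers: list[str]) -> dict[tuple[str, int], object]:
    """Testing-set scores for every fitted (class, bout); failed fits map to
    None so the filter removes them."""
    from .evaluation import evaluate

    by_bout = {b.bout_id: b for b in bouts}
    scores: dict[tuple[str, int], object] = dict.fromkeys(ens.fit_failures)
    for (mc, bout_id), adapter in ens.models.items():
        test = by_bout[bout_id].testing
        X = test[layers].to_numpy(dtype=float)
        y = (test["label"] == "presence").to_numpy()
        scores[(mc, bout_id)] = evaluate(adapter.predict(X), y)
    return scores
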