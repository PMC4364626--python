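"""Synthetic landscapes, virtual species, and future-climate scenarios.

Every downstream stage of the pipeline is exercised on data generated here:
spatially autocorrelated environmental surfaces, virtual species whose
presence probability is a known function of the environment (so niche
marginality, specialization, and prevalence are controllable by
construction), and future scenarios produced by systematic perturbation of
the baseline climate layers.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import PERIODS, THERMAL_LAYERS, EnvGrid, GridAlignmentError, SpeciesDistribution, ScenarioSet


@dataclass
class LayerSpec:
    """Marginal distribution and spatial structure of one synthetic layer.

    mean, sd : marginal moments of the stochastic field, in layer units.
    autocorr_range : Gaussian smoothing length in cells; 0 gives white noise.
    ns_gradient : optional deterministic north-to-south trend added on top,
        in layer units per row (positive = increases southward). The marginal
        mean/sd describe the stochastic component only.
    """

    mean: float = 0.0
    sd: float = 1.0
    autocorr_range: float = 3.0
    ns_gradient: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.autocorr_range < 0:
            raise ValueError("autocorrelation range must be nonnegative")


@dataclass
class VirtualSpeciesSpec:
    """Niche geometry of a virtual species.

    Suitability at a cell is the product over the selected layers of Gaussian
    kernels exp(-(x - optimum)^2 / (2 breadth^2)), rescaled to [0, 1].
    """

    optimum: dict[str, float]
    breadth: dict[str, float]
    prevalence_target: float = 0.1
    sampling_mode: str = "threshold"  # or "bernoulli"
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.optimum) != set(self.breadth):
            raise ValueError("optimum and breadth must name the same layers")
        if any(b <= 0 for b in self.breadth.values()):
            raise ValueError("breadth must be strictly positive")
        if not 0.0 < self.prevalence_target < 1.0:
            raise ValueError("prevalence_target must be in (0, 1)")
        if self.sampling_mode not in ("threshold", "bernoulli"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")


class PrevalenceError(RuntimeError):
    """Requested prevalence cannot be achieved on this landscape."""


def _autocorrelated_field(rng: np.random.Generator, shape: tuple[int, int],
                          spec: LayerSpec) -> np.ndarray:
    """Gaussian-kernel smoothing of white noise, restandardized post hoc.

    Smoothing shrinks the marginal variance, so the field is re-scaled to the
    requested mean/sd afterwards; the requested moments are then exact up to
    floating point over the full grid.
    """
    noise = rng.standard_normal(shape)
    if spec.autocorr_range > 0:
        noise = gaussian_filter(noise, sigma=spec.autocorr_range, mode="reflect")
    noise = (noise - noise.mean()) / noise.std()
    layer = spec.mean + spec.sd * noise
    if spec.ns_gradient != 0.0:
        layer = layer + spec.ns_gradient * np.arange(shape[0])[:, None]
    return layer


def gen_landscape(rows: int, cols: int, layer_specs: dict[str, LayerSpec],
                  seed: int, cell_size_km: float = 8.0,
                  origin_latlon: tuple[float, float] = (50.0, 100.0),
                  mask: np.ndarray | None = None) -> EnvGrid:
    """Generate an :class:`EnvGrid` of independent autocorrelated layers.

    Layers are drawn in the order of ``layer_specs`` from one seeded
    generator, so the same call with the same seed reproduces the grid
    exactly.
    """
    if rows < 10 or cols < 10:
        raise ValueError("rows and cols must be >= 10")
    if not layer_specs:
        raise ValueError("at least one layer spec required")
    rng = np.random.default_rng(seed)
    values = np.stack([
        _autocorrelated_field(rng, (rows, cols), spec)
        for spec in layer_specs.values()
    ])
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    return EnvGrid(layer_names=list(layer_specs), values=values, mask=mask,
                   cell_size_km=cell_size_km, origin_latlon=origin_latlon)


def default_landscape_specs(include_soil: bool = False) -> dict[str, LayerSpec]:
    """A China-like default layer set: 7 climate variables plus elevation.

    The thermal layers share a north-south gradient (cooling northward,
    i.e. a negative per-row trend since row 0 is the northernmost), which
    couples them the way real temperature surfaces are coupled and gives the
    thermal PCA a dominant first axis. Magnitudes are loosely continental:
    MAT ~ N(8, 6) deg C, TD ~ N(28, 6) deg C, DD ~ N(2500, 900) degree-days,
    precipitation in mm.
    """
    specs = {
        "MAT": LayerSpec(mean=8.0, sd=4.0, autocorr_range=4.0, ns_gradient=0.15),
        "MWMT": LayerSpec(mean=22.0, sd=4.0, autocorr_range=4.0, ns_gradient=0.10),
        "MCMT": LayerSpec(mean=-6.0, sd=5.0, autocorr_range=4.0, ns_gradient=0.25),
        "TD": LayerSpec(mean=28.0, sd=4.0, autocorr_range=4.0, ns_gradient=-0.15),
        "DD": LayerSpec(mean=2500.0, sd=700.0, autocorr_range=4.0, ns_gradient=30.0),
        "MAP": LayerSpec(mean=800.0, sd=300.0, autocorr_range=5.0),
        "MSP": LayerSpec(mean=450.0, sd=180.0, autocorr_range=5.0),
        "ELEV": LayerSpec(mean=1500.0, sd=800.0, autocorr_range=6.0),
    }
    if include_soil:
        specs.update({
            "SOM": LayerSpec(mean=3.0, sd=1.2, autocorr_range=3.0),
            "PH": LayerSpec(mean=6.5, sd=0.8, autocorr_range=3.0),
        })
    return specs


def suitability_surface(env: EnvGrid, spec: VirtualSpeciesSpec) -> np.ndarray:
    """Product-of-Gaussian-kernels suitability, rescaled to max 1 on the mask."""
    missing = set(spec.optimum) - set(env.layer_names)
    if missing:
        raise KeyError(f"species niche names layers absent from grid: {sorted(missing)}")
    log_suit = np.zeros(env.shape)
    for name, opt in spec.optimum.items():
        x = env.layer(name)
        log_suit -= (x - opt) ** 2 / (2.0 * spec.breadth[name] ** 2)
    suit = np.exp(log_suit)
    top = suit[env.mask].max()
    if top > 0:
        suit = suit / top
    return np.where(env.mask, suit, np.nan)


def gen_virtual_species(env: EnvGrid, spec: VirtualSpeciesSpec,
                        ) -> tuple[SpeciesDistribution, np.ndarray]:
    """Realize a virtual species from its suitability surface.

    threshold mode occupies the top round(p * N) cells by suitability (ties
    broken by a seeded jitter), hitting the target prevalence exactly up to
    integer rounding. bernoulli mode scales suitability into occupancy
    probabilities whose mean equals the target and draws cells independently;
    the draw is retried (new substream) if realized prevalence misses the
    target by more than 10% relative, and fails explicitly if the landscape
    cannot support the target at all.

    Returns the realized distribution and the suitability grid.
    """
    suit = suitability_surface(env, spec)
    n = env.n_cells
    target = spec.prevalence_target
    k = int(round(target * n))
    if k < 1 or k > n - 1:
        raise PrevalenceError(
            f"target prevalence {target} needs {k} of {n} cells occupied; "
            "achievable prevalence is in [1/N, (N-1)/N]"
        )
    rng = np.random.default_rng(spec.seed)
    masked_suit = suit[env.mask]
    presence = np.zeros(env.shape, dtype=bool)
    rows, cols = np.nonzero(env.mask)

    if spec.sampling_mode == "threshold":
        jitter = rng.uniform(0, 1e-12, size=n)
        order = np.argsort(masked_suit + jitter)[::-1]
        chosen = order[:k]
        presence[rows[chosen], cols[chosen]] = True
    else:
        probs = _bernoulli_probs(masked_suit, target)
        for attempt in range(10):
            draw = rng.uniform(size=n) < probs
            realized = draw.sum() / n
            if abs(realized - target) <= 0.1 * target and 0 < draw.sum() < n:
                break
        else:
            raise PrevalenceError(
                f"bernoulli draws repeatedly missed target {target}; "
                f"last realized {realized:.4f}"
            )
        presence[rows[draw], cols[draw]] = True

    return SpeciesDistribution(presence=presence, env=env), suit


def _bernoulli_probs(suit: np.ndarray, target: float) -> np.ndarray:
    """Scale suitability to probabilities min(c * suit, 1) with mean target.

    The mean of min(c * suit, 1) is continuous and nondecreasing in c, so c
    is found by bisection. Fails if even c -> inf (all positive-suitability
    cells certain) cannot reach the target.
    """
    attainable = (suit > 0).mean()
    if attainable < target:
        raise PrevalenceError(
            f"only {attainable:.3f} of cells have positive suitability; "
            f"target prevalence {target} is unattainable in bernoulli mode"
        )
    hi = 1.0
    while np.minimum(hi * suit, 1.0).mean() < target:
        hi *= 10.0
        if hi > 1e300:
            raise PrevalenceError("suitability scaling diverged")
    lo = 0.0
    for _ in range(200):
        c = 0.5 * (lo + hi)
        m = np.minimum(c * suit, 1.0).mean()
        if m < target:
            lo = c
        else:
            hi = c
    return np.minimum(hi * suit, 1.0)


@dataclass
class ScenarioDelta:
    """Additive perturbation of selected layers for one future scenario.

    offsets : per-layer uniform additive change (e.g. {"MAT": +2.0}).
    ns_gradients : optional per-layer additive trend in units per row,
        letting scenarios warm the south more than the north (or vice versa).
    """

    offsets: dict[str, float] = field(default_factory=dict)
    ns_gradients: dict[str, float] = field(default_factory=dict)

    def apply(self, baseline: EnvGrid) -> EnvGrid:
        values = baseline.values.copy()
        nrows = baseline.shape[0]
        for name, off in self.offsets.items():
            values[baseline.layer_names.index(name)] += off
        for name, grad in self.ns_gradients.items():
            values[baseline.layer_names.index(name)] += (
                grad * np.arange(nrows)[:, None]
            )
        return baseline.with_values(values)


def gen_scenarios(baseline: EnvGrid,
                  deltas: dict[tuple[int, int, str], ScenarioDelta],
                  ) -> ScenarioSet:
    """Build a :class:`ScenarioSet` by applying additive deltas to baseline.

    ``deltas`` must cover all 9 (gcm, sres) combinations for every period it
    mentions; masks and geometry are preserved by construction.
    """
    by_period: dict[str, set[tuple[int, int]]] = {}
    for gcm, sres, period in deltas:
        by_period.setdefault(period, set()).add((gcm, sres))
    for period, combos in by_period.items():
        if len(combos) != 9:
            raise ValueError(
                f"period {period!r} defines {len(combos)} (gcm, sres) "
                "combinations, need all 9"
            )
    grids = {key: delta.apply(baseline) for key, delta in deltas.items()}
    return ScenarioSet(baseline=baseline, scenario_grids=grids)


def default_scenario_deltas(periods: tuple[str, ...] = PERIODS,
                            ) -> dict[tuple[int, int, str], ScenarioDelta]:
    """Stylized warming ensemble: 3 GCM x 3 SRES per period.

    Emissions intensity (SRES analog) sets the warming rate; GCMs disagree
    by a multiplicative spread. Warming grows with period (2020s < 2050s <
    2080s), precipitation changes a few percent of its mean either way —
    magnitudes in line with the CMIP3-era scenario spread the design mirrors.
    """
    sres_rate = {1: 1.3, 2: 1.0, 3: 0.7}        # A2, A1B, B1 analogs
    gcm_spread = {1: 1.2, 2: 1.0, 3: 0.8}
    period_warming = {"2020s": 1.0, "2050s": 2.0, "2080s": 3.2}
    deltas = {}
    for period in periods:
        for gcm in (1, 2, 3):
            for sres in (1, 2, 3):
                dt = period_warming[period] * sres_rate[sres] * gcm_spread[gcm]
                deltas[(gcm, sres, period)] = ScenarioDelta(offsets={
                    "MAT": dt,
                    "MWMT": dt * 1.1,
                    "MCMT": dt * 1.3,
                    "TD": -dt * 0.2,
                    "DD": dt * 150.0,
                    "MAP": dt * 15.0 * (1 if gcm != 3 else -1),
                    "MSP": dt * 8.0 * (1 if gcm != 3 else -1),
                })
    return deltas
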