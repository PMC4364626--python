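"""End-to-end experiment orchestration.

One :class:`ExperimentConfig` drives the full chain: simulate landscape and
virtual species -> pseudo-absences and split-sample bouts -> calibrate the
model ensemble -> evaluate and filter -> project scenarios -> three
consensus maps -> range metrics -> congruence -> niche traits -> trait
regressions. A single master seed spawns per-stage substreams, so runs are
reproducible end to end and stages can be re-run independently.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import congruence as cg
from . import consensus as cs
from . import evaluation as ev
from . import niche_properties as nprop
from . import range_metrics as rm
from . import trait_regression as tr
from .grids import PERIODS, EnvGrid, SpeciesDistribution, ScenarioSet
from .models import DEFAULT_MENU, ProjectionEnsemble, calibrate_ensemble, evaluate_ensemble
from .pseudoabsence import Bout, bouts_to_csv, fit_sre, make_subsets
from .synthetic import (LayerSpec, VirtualSpeciesSpec, default_landscape_specs,
                        default_scenario_deltas, gen_landscape,
                        gen_scenarios, gen_virtual_species)


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic substream seed for one pipeline stage."""
    h = np.random.SeedSequence([master, zlib.crc32(stage.encode()), index])
    return int(h.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentConfig:
    """Everything one experiment needs; defaults mirror the standard design:
    8 model classes x 9 bouts, 3 GCM x 3 SRES scenarios, AUC/kappa/TSS
    retention thresholds 0.70/0.4/0.4, presence threshold 0.5."""

    rows: int = 50
    cols: int = 50
    cell_size_km: float = 8.0
    n_species: int = 1
    prevalence: float = 0.15
    sampling_mode: str = "threshold"
    menu: list[str] = field(default_factory=lambda: list(DEFAULT_MENU))
    periods: list[str] = field(default_factory=lambda: ["2050s"])
    n_absence_draws: int = 3
    n_splits: int = 3
    absence_fraction: float = 0.7
    split_ratio: float = 0.7
    auc_min: float = ev.AUC_THRESHOLD
    kappa_min: float = ev.KAPPA_THRESHOLD
    tss_min: float = ev.TSS_THRESHOLD
    presence_threshold: float = ev.PRESENCE_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.auc_min <= 1:
            raise ValueError("auc_min outside [0, 1]")
        if not -1 <= self.kappa_min <= 1 or not -1 <= self.tss_min <= 1:
            raise ValueError("kappa/tss thresholds outside [-1, 1]")
        if self.n_absence_draws < 1 or self.n_splits < 1:
            raise ValueError("replication counts must be >= 1")
        unknown = set(self.periods) - set(PERIODS)
        if unknown:
            raise ValueError(f"unknown periods {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def species_cohort(env: EnvGrid, n_species: int, prevalence: float,
                   sampling_mode: str, seed: int,
                   niche_layers: tuple[str, ...] = ("MAT", "MAP"),
                   ) -> list[VirtualSpeciesSpec]:
    """A cohort of virtual species spanning a spread of niche positions and
    breadths on this landscape, so traits vary across species."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_species):
        optimum, breadth = {}, {}
        for name in niche_layers:
            vals = env.layer(name)[env.mask]
            offset_sd = rng.uniform(-1.5, 1.5)
            optimum[name] = float(vals.mean() + offset_sd * vals.std())
            breadth[name] = float(vals.std() * rng.uniform(0.3, 1.5))
        specs.append(VirtualSpeciesSpec(
            optimum=optimum, breadth=breadth, prevalence_target=prevalence,
            sampling_mode=sampling_mode,
            seed=int(rng.integers(2**31)),
        ))
    return specs


def filtered_ensemble(ens: ProjectionEnsemble,
                      retained: list[tuple[str, int]]) -> ProjectionEnsemble:
    """Ensemble restricted to projections of retained (class, bout) models."""
    keep = set(retained)
    out = ProjectionEnsemble(
        models={k: v for k, v in ens.models.items() if k in keep},
        fit_failures=dict(ens.fit_failures),
    )
    for key, proj in ens.projections.items():
        if (key[0], key[1]) in keep:
            out.projections[key] = proj
    return out


@dataclass
class SpeciesRun:
    """All per-species artifacts of one experiment."""

    species_id: int
    species: SpeciesDistribution
    bouts: list[Bout]
    ensemble: ProjectionEnsemble
    retained_ensemble: ProjectionEnsemble
    scores: dict[tuple[str, int], ev.EvaluationScores | None]
    retained: list[tuple[str, int]]
    removed: list[tuple[str, int]]
    consensus: dict[str, dict[str, cs.ConsensusMap]]  # period -> method -> map
    range_changes: pd.DataFrame
    congruence: pd.DataFrame
    traits: nprop.NicheTraits

    def scores_table(self) -> pd.DataFrame:
        rows = []
        for (mc, bout), sc in sorted(self.scores.items()):
            if sc is None:
                rows.append({"species": self.species_id, "model_class": mc,
                             "bout": bout, "auc": np.nan, "kappa": np.nan,
                             "tss": np.nan, "pass": False, "fit_failed": True})
            else:
                rows.append({"species": self.species_id, "model_class": mc,
                             "bout": bout, "auc": sc.auc, "kappa": sc.kappa,
                             "tss": sc.tss,
                             "pass": (mc, bout) in set(self.retained),
                             "fit_failed": False})
        return pd.DataFrame(rows)


def run_species(env: EnvGrid, scenarios: ScenarioSet,
                spec: VirtualSpeciesSpec, species_id: int,
                config: ExperimentConfig) -> SpeciesRun:
    """The full per-species chain. See module docstring for stage order."""
    species, _suit = gen_virtual_species(env, spec)
    envelope = fit_sre(env, species)
    bouts = make_subsets(
        env, species, envelope,
        fraction=config.absence_fraction, ratio=config.split_ratio,
        n_absence_draws=config.n_absence_draws, n_splits=config.n_splits,
        seed=stage_seed(config.seed, "subsets", species_id),
    )
    layers = list(env.layer_names)
    ens = calibrate_ensemble(
        bouts, layers, scenarios, menu=config.menu, periods=config.periods,
        seed=stage_seed(config.seed, "fit", species_id),
    )
    scores = evaluate_ensemble(ens, bouts, layers)
    retained, removed = ev.filter_models(
        scores, auc_min=config.auc_min, kappa_min=config.kappa_min,
        tss_min=config.tss_min,
    )
    kept = filtered_ensemble(ens, retained)

    consensus_maps: dict[str, dict[str, cs.ConsensusMap]] = {}
    for period in ["baseline"] + list(config.periods):
        consensus_maps[period] = cs.consensus_all(
            kept, period, class_order=config.menu,
            threshold=config.presence_threshold,
        )

    range_rows, congruence_rows = [], []
    for period in config.periods:
        for method in ("average", "frequency", "median_pca"):
            summary = rm.summarize_range_change(
                consensus_maps["baseline"][method],
                consensus_maps[period][method], env,
                threshold=config.presence_threshold,
            )
            range_rows.append({
                "species": species_id, "period": period, "method": method,
                "current_area_cells": summary.current_area_cells,
                "future_area_cells": summary.future_area_cells,
                "total_change_pct": summary.total_change_pct,
                "new_habitat_pct": summary.new_habitat_pct,
                "habitat_lost_pct": summary.habitat_lost_pct,
                "shift_km": summary.shift.shift_km,
                "northward_km": summary.shift.northward_km,
                "eastward_km": summary.shift.eastward_km,
                "bearing_deg": summary.shift.bearing_deg,
            })
    for period in ["baseline"] + list(config.periods):
        maps = consensus_maps[period]
        prob = {m: maps[m].probs for m in maps}
        binary = {m: rm.binarize(maps[m], config.presence_threshold)
                  for m in maps}
        summary = cg.pairwise_summary(prob, binary, env.mask)
        ov = cg.overlay([binary[m] for m in ("average", "frequency",
                                             "median_pca")], env.mask)
        row = {
            "species": species_id, "period": period,
            "mean_pearson": summary.mean_pearson,
            "mean_kappa": summary.mean_kappa,
            **{f"pearson_{a}_{b}": v for (a, b), v in summary.pearson_pairs.items()},
            **{f"kappa_{a}_{b}": v for (a, b), v in summary.kappa_pairs.items()},
            **{f"n_{k}": v for k, v in ov.counts.items()},
        }
        try:
            row["consistency_ratio"] = cg.consistency_ratio(ov)
        except ValueError:
            row["consistency_ratio"] = np.nan
        congruence_rows.append(row)

    traits = nprop.species_traits(env, species, bouts[0].calibration)
    return SpeciesRun(
        species_id=species_id, species=species, bouts=bouts, ensemble=ens,
        retained_ensemble=kept, scores=scores, retained=retained,
        removed=removed, consensus=consensus_maps,
        range_changes=pd.DataFrame(range_rows),
        congruence=pd.DataFrame(congruence_rows),
        traits=traits,
    )


@dataclass
class ExperimentResult:
    env: EnvGrid
    scenarios: ScenarioSet
    runs: list[SpeciesRun]
    manifest: dict
    regressions: dict[str, tr.RegressionResult] = field(default_factory=dict)


def run_experiment(config: ExperimentConfig,
                   outdir: str | Path | None = None) -> ExperimentResult:
    """Execute the whole experiment; optionally persist all tables under
    *outdir* (CSV + JSON manifest)."""
    env = gen_landscape(config.rows, config.cols, default_landscape_specs(),
                        seed=stage_seed(config.seed, "landscape"),
                        cell_size_km=config.cell_size_km)
    scenarios = gen_scenarios(env, default_scenario_deltas(tuple(config.periods)))
    specs = species_cohort(env, config.n_species, config.prevalence,
                           config.sampling_mode,
                           seed=stage_seed(config.seed, "cohort"))

    runs = []
    for i, spec in enumerate(specs):
        try:
            runs.append(run_species(env, scenarios, spec, i, config))
        except Exception as exc:
            raise RuntimeError(f"species {i} failed in pipeline: {exc}") from exc

    manifest = {
        "n_species": len(runs),
        "menu": list(config.menu),
        "periods": list(config.periods),
        "per_species": {
            str(r.species_id): {
                **r.ensemble.counts(),
                "n_models_retained": len(r.retained),
                "n_models_removed": len(r.removed),
                "n_median_pca_selected": {
                    period: r.consensus[period]["median_pca"].provenance["n_selected"]
                    for period in r.consensus
                },
            }
            for r in runs
        },
    }

    regressions: dict[str, tr.RegressionResult] = {}
    if len(runs) >= 10:
        traits, responses = cohort_tables(runs)
        regressions = tr.trait_tables(traits, responses)

    result = ExperimentResult(env=env, scenarios=scenarios, runs=runs,
                              manifest=manifest, regressions=regressions)
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def cohort_tables(runs: list[SpeciesRun]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species predictor and response tables for the trait regressions.

    Predictors: the six niche traits plus mean single-model AUC/kappa/TSS
    over retained models. Responses: mean pairwise map Pearson and kappa,
    baseline and future averages.
    """
    t_rows, r_rows = [], []
    for r in runs:
        st = r.scores_table()
        ok = st[st["pass"]]
        t_rows.append({
            "species": r.species_id, **r.traits.as_dict(),
            "auc": ok["auc"].mean(), "kappa": ok["kappa"].mean(),
            "tss": ok["tss"].mean(),
        })
        by_period = r.congruence.set_index("period")
        future = by_period.drop(index="baseline", errors="ignore")
        r_rows.append({
            "pearson_baseline": by_period.loc["baseline", "mean_pearson"],
            "kappa_baseline": by_period.loc["baseline", "mean_kappa"],
            "pearson_future": future["mean_pearson"].mean(),
            "kappa_future": future["mean_kappa"].mean(),
        })
    return pd.DataFrame(t_rows), pd.DataFrame(r_rows)


def write_outputs(result: ExperimentResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.concat([r.scores_table() for r in result.runs],
              ignore_index=True).to_csv(outdir / "model_scores.csv", index=False)
    pd.concat([r.range_changes for r in result.runs],
              ignore_index=True).to_csv(outdir / "range_changes.csv", index=False)
    pd.concat([r.congruence for r in result.runs],
              ignore_index=True).to_csv(outdir / "congruence.csv", index=False)
    traits = pd.DataFrame([
        {"species": r.species_id, **r.traits.as_dict()} for r in result.runs
    ])
    traits.to_csv(outdir / "species_traits.csv", index=False)
    for r in result.runs:
        bouts_to_csv(r.bouts, outdir / f"samplesets_species{r.species_id}.csv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    if result.regressions:
        for resp, reg in result.regressions.items():
            reg.table().to_csv(outdir / f"regression_{resp}.csv", index=False)
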