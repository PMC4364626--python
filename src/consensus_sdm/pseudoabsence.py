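"""Pseudo-absence selection via the surface range envelope (SRE) and the
replicated calibration/testing split.

Presence-only data provide no absences, so candidate absences are certified
environmentally: the rectilinear envelope spanning the min-max of every
predictor over presence sites is fitted, any cell inside it is precluded,
and the remaining cells are treated as true absences. 70% of those are
drawn for model development; presences plus drawn absences are split 7:3
(stratified by class) into calibration and testing data. Both the absence
draw and the split are replicated three times each, crossed, giving nine
split-sample bouts per species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import EnvGrid, GridAlignmentError, SpeciesDistribution


@dataclass
class Envelope:
    """Per-layer (min, max) bounds over presence cells, inclusive."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"layer {name!r}: min {lo} > max {hi}")

    @property
    def layer_names(self) -> list[str]:
        return list(self.bounds)


@dataclass
class Bout:
    """One calibration/testing pair, keyed by (absence draw, split) in 1..3."""

    draw: int
    split: int
    calibration: pd.DataFrame
    testing: pd.DataFrame

    @property
    def bout_id(self) -> int:
        """1..9, row-major over (draw, split)."""
        return (self.draw - 1) * 3 + self.split


SAMPLE_COLUMNS = ["cell_id", "row", "col", "label"]


def fit_sre(env: EnvGrid, species: SpeciesDistribution,
            quantile: float = 0.0) -> Envelope:
    """Fit the environmental envelope over presence cells.

    With ``quantile = 0`` (default) bounds are the exact min/max of each
    layer over presences — the extreme-value envelope. A nonzero quantile
    trims each tail (e.g. 0.025 gives the 2.5th/97.5th percentiles).
    """
    species.env.check_aligned(env)
    pres = species.presence
    if int(pres.sum()) < 2:
        raise ValueError("need at least 2 presence cells to fit an envelope")
    if not 0.0 <= quantile < 0.5:
        raise ValueError("quantile must be in [0, 0.5)")
    bounds = {}
    for name in env.layer_names:
        vals = env.layer(name)[pres]
        if quantile == 0.0:
            bounds[name] = (float(vals.min()), float(vals.max()))
        else:
            bounds[name] = (
                float(np.quantile(vals, quantile)),
                float(np.quantile(vals, 1.0 - quantile)),
            )
    return Envelope(bounds=bounds)


def classify_envelope(env: EnvGrid, envelope: Envelope) -> np.ndarray:
    """Boolean grid: True where every layer value lies within its bounds
    (inclusive). Off-mask cells are False."""
    missing = set(envelope.layer_names) - set(env.layer_names)
    if missing:
        raise GridAlignmentError(
            f"envelope names layers absent from grid: {sorted(missing)}"
        )
    inside = env.mask.copy()
    for name, (lo, hi) in envelope.bounds.items():
        vals = env.layer(name)
        inside &= (vals >= lo) & (vals <= hi)
    return inside


def draw_true_absences(env: EnvGrid, species: SpeciesDistribution,
                       envelope: Envelope, fraction: float = 0.7,
                       seed: int = 0) -> np.ndarray:
    """Sample round(fraction * pool) true-absence cells without replacement.

    The pool is every masked-in, non-presence cell outside the envelope.
    Returns flat cell ids (row-major), sorted.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    species.env.check_aligned(env)
    inside = classify_envelope(env, envelope)
    pool_mask = env.mask & ~species.presence & ~inside
    pool = np.flatnonzero(pool_mask.ravel())
    if pool.size == 0:
        raise RuntimeError(
            "species envelope covers all candidate absences: empty pool"
        )
    n_draw = int(round(fraction * pool.size))
    n_draw = max(n_draw, 1)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n_draw, replace=False)
    return np.sort(chosen)


def _cells_frame(env: EnvGrid, cell_ids: np.ndarray, label: str) -> pd.DataFrame:
    rows, cols = np.divmod(cell_ids, env.shape[1])
    out = pd.DataFrame({
        "cell_id": cell_ids, "row": rows, "col": cols, "label": label,
    })
    for name in env.layer_names:
        out[name] = env.layer(name)[rows, cols]
    return out


def _child_seed(master: int, draw: int, split: int) -> int:
    # fixed arithmetic so adding bouts never reshuffles earlier ones
    return int(np.random.SeedSequence([master, draw, split]).generate_state(1)[0] % (2**31))


def make_subsets(env: EnvGrid, species: SpeciesDistribution,
                 envelope: Envelope, fraction: float = 0.7,
                 ratio: float = 0.7, n_absence_draws: int = 3,
                 n_splits: int = 3, seed: int = 0) -> list[Bout]:
    """Build the replicated calibration/testing bouts.

    For each of ``n_absence_draws`` independent 70% true-absence draws,
    presences plus drawn absences are split ``n_splits`` times into
    calibration and testing at ``ratio`` : (1 - ratio), stratified so the
    presence:absence ratio matches between roles up to integer rounding.
    Draws and splits are crossed: bout (d, s) uses absence draw d and split
    stream s. Deterministic per master seed.
    """
    presence_ids = np.flatnonzero(species.presence.ravel())
    n_pres = presence_ids.size
    if n_pres < 2:
        raise ValueError("too few presences to split into both roles")

    bouts: list[Bout] = []
    for d in range(1, n_absence_draws + 1):
        absences = draw_true_absences(
            env, species, envelope, fraction=fraction,
            seed=_child_seed(seed, d, 0),
        )
        if absences.size < 2:
            raise ValueError("too few true absences to split into both roles")
        pres_df = _cells_frame(env, presence_ids, "presence")
        abs_df = _cells_frame(env, absences, "absence")
        for s in range(1, n_splits + 1):
            rng = np.random.default_rng(_child_seed(seed, d, s))
            cal_parts, test_parts = [], []
            for df in (pres_df, abs_df):
                idx = rng.permutation(len(df))
                n_cal = int(np.floor(ratio * len(df)))
                n_cal = min(max(n_cal, 1), len(df) - 1)
                cal_parts.append(df.iloc[np.sort(idx[:n_cal])])
                test_parts.append(df.iloc[np.sort(idx[n_cal:])])
            cal = pd.concat(cal_parts, ignore_index=True)
            test = pd.concat(test_parts, ignore_index=True)
            for frame, role in ((cal, "calibration"), (test, "testing")):
                frame["role"] = role
                frame["bout"] = (d - 1) * n_splits + s
                frame["draw"] = d
                frame["split"] = s
            bouts.append(Bout(draw=d, split=s, calibration=cal, testing=test))
    return bouts


def bouts_to_csv(bouts: list[Bout], path) -> None:
    """Serialize all bouts to one CSV (columns: cell_id,row,col,label,role,
    bout,draw,split plus one column per environmental layer)."""
    frames = []
    for bout in bouts:
        frames.append(bout.calibration)
        frames.append(bout.testing)
    all_rows = pd.concat(frames, ignore_index=True)
    meta = ["cell_id", "row", "col", "label", "role", "bout", "draw", "split"]
    layers = [c for c in all_rows.columns if c not in meta]
    all_rows[meta + layers].to_csv(path, index=False)
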