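"""Consensus combiners: average, frequency, and the two-step median (PCA).

Average is the cellwise arithmetic mean of all retained projections.
Frequency binarizes each projection at the 0.5 presence threshold and
reports the fraction predicting presence. The median (PCA) approach first
selects, within each (bout, scenario) block, the single model-class
projection most correlated (in absolute value) with the first principal
component of the block's cells-by-models matrix — the consensus axis — and
then takes the cellwise median of the selected projections: 9 bouts x 9
scenarios = 81 for a future period, 9 for the baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .evaluation import PRESENCE_THRESHOLD
from .models import ModelProjection, ProjectionEnsemble


@dataclass
class ConsensusMap:
    """Per-cell consensual probability map with its provenance."""

    probs: np.ndarray
    method: str  # average | frequency | median_pca
    period: str = "baseline"
    provenance: dict = field(default_factory=dict)


def _stack(projections: list[ModelProjection]) -> np.ndarray:
    """Aligned probability stack in a fixed key order, so floating-point
    reductions are byte-identical however the caller ordered the inputs."""
    if not projections:
        raise ValueError("empty projection list")
    projections = sorted(projections, key=lambda p: str(p.key))
    shape = projections[0].probs.shape
    for p in projections:
        if p.probs.shape != shape:
            raise ValueError("projections are not aligned")
    return np.stack([p.probs for p in projections])


def consensus_average(projections: list[ModelProjection],
                      period: str = "baseline") -> ConsensusMap:
    """Cellwise arithmetic mean of all projections."""
    stack = _stack(projections)
    return ConsensusMap(
        probs=stack.mean(axis=0), method="average", period=period,
        provenance={"keys": sorted(str(p.key) for p in projections)},
    )


def consensus_frequency(projections: list[ModelProjection],
                        threshold: float = PRESENCE_THRESHOLD,
                        period: str = "baseline") -> ConsensusMap:
    """Fraction of projections predicting presence (prob > threshold,
    strictly) at each cell; values lie on the lattice {0, 1/k, ..., 1}."""
    stack = _stack(projections)
    with np.errstate(invalid="ignore"):
        freq = (stack > threshold).mean(axis=0)
    freq = np.where(np.isfinite(stack[0]), freq, np.nan)
    return ConsensusMap(
        probs=freq, method="frequency", period=period,
        provenance={"keys": sorted(str(p.key) for p in projections),
                    "threshold": threshold},
    )


def pca_select(projections: list[ModelProjection],
               class_order: list[str] | None = None,
               ) -> tuple[ModelProjection, float]:
    """Select the projection most aligned with the PCA consensus axis.

    Builds the cells x models matrix over masked-in cells, centres each
    column (no variance scaling — probabilities share the [0, 1] scale),
    and extracts first principal-component scores. The PC1 sign is
    indeterminate, so the axis is oriented toward the ensemble majority
    (the sum of column correlations with it is made nonnegative); the
    projection with the largest signed correlation to the oriented axis is
    returned, together with that correlation. Orienting before selecting
    means a projection anti-correlated with the consensus (an anti-signal
    outlier) can never win. Ties break by a fixed model-class order (the
    supplied ``class_order``, else alphabetical), never by list position.
    All-constant blocks fall back to the first projection in class order
    with a warning.
    """
    if not projections:
        raise ValueError("empty projection block")
    order = class_order or sorted({p.model_class for p in projections})
    rank = {mc: i for i, mc in enumerate(order)}
    projections = sorted(projections,
                         key=lambda p: (rank.get(p.model_class, len(order)), str(p.key)))
    if len(projections) == 1:
        return projections[0], 1.0

    mask = np.isfinite(projections[0].probs)
    X = np.column_stack([p.probs[mask] for p in projections])
    Xc = X - X.mean(axis=0)
    col_sd = np.where(np.ptp(X, axis=0) == 0, 0.0, Xc.std(axis=0))
    if np.all(col_sd == 0):
        warnings.warn("all projections constant; PCA selection falls back to "
                      "first projection in class order")
        return projections[0], 0.0
    # PC1 scores via SVD of the centred matrix
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    pc1_sd = pc1.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(
            col_sd > 0,
            (Xc * (pc1 - pc1.mean())[:, None]).mean(axis=0) / (col_sd * pc1_sd),
            0.0,
        )
    if corr.sum() < 0:  # orient the consensus axis toward the majority
        corr = -corr
    best = int(np.argmax(np.round(corr, 12)))  # ties -> lowest class rank
    return projections[best], float(corr[best])


def consensus_median_pca(ensemble: ProjectionEnsemble, period: str,
                         class_order: list[str] | None = None,
                         ) -> ConsensusMap:
    """Two-step median (PCA) consensus for one period.

    Step 1 runs :func:`pca_select` independently in every (bout, scenario)
    block of the retained ensemble; step 2 takes the cellwise median of the
    selected projections (midpoint convention for even counts). A block with
    zero retained projections is skipped with a warning; if every block is
    empty the consensus fails explicitly.
    """
    blocks: dict[tuple, list[ModelProjection]] = {}
    for (mc, bout, scenario, pe), proj in ensemble.projections.items():
        if pe == period:
            blocks.setdefault((bout, scenario), []).append(proj)
    if not blocks:
        raise RuntimeError(f"no projections for period {period!r}")

    selected, prov = [], {}
    for block_key in sorted(blocks, key=str):
        projs = blocks[block_key]
        if not projs:
            warnings.warn(f"block {block_key} has no retained projections; skipped")
            continue
        proj, corr = pca_select(projs, class_order=class_order)
        selected.append(proj)
        prov[str(block_key)] = {"selected": str(proj.key), "pc1_corr": corr}
    if not selected:
        raise RuntimeError("every (bout, scenario) block was empty")

    stack = _stack(selected)
    return ConsensusMap(
        probs=np.median(stack, axis=0), method="median_pca", period=period,
        provenance={"n_selected": len(selected), "blocks": prov},
    )


def consensus_all(ensemble: ProjectionEnsemble, period: str,
                  class_order: list[str] | None = None,
                  threshold: float = PRESENCE_THRESHOLD,
                  ) -> dict[str, ConsensusMap]:
    """All three consensual maps for one period from one retained ensemble."""
    projections = ensemble.subset(period=period)
    return {
        "average": consensus_average(projections, period=period),
        "frequency": consensus_frequency(projections, threshold=threshold,
                                         period=period),
        "median_pca": consensus_median_pca(ensemble, period,
                                           class_order=class_order),
    }
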