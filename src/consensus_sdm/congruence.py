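"""Spatial congruence among the three consensual prediction maps.

The overlay classifies every masked-in cell by how many of the three
binarized consensus maps predict presence: good (all 3), moderate (exactly
2), poor (exactly 1), outside (none). The consistency ratio is incongruent
over congruent area, (moderate + poor) / good. Map similarity is quantified
pairwise by Pearson correlation of the probability maps and Cohen's kappa
of the binary maps, averaged over the three method pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ConfusionCounts, kappa as _cohen_kappa

CATEGORIES = ("good", "moderate", "poor", "outside")
PAIRS = (("average", "frequency"), ("median_pca", "average"),
         ("median_pca", "frequency"))


@dataclass
class OverlayGrid:
    """Per-cell agreement category plus counts. category codes: 3=good,
    2=moderate, 1=poor, 0=outside, -1=off-mask."""

    category: np.ndarray
    counts: dict[str, int]


@dataclass
class CongruenceSummary:
    pearson_pairs: dict[tuple[str, str], float]
    kappa_pairs: dict[tuple[str, str], float]
    mean_pearson: float
    mean_kappa: float


def overlay(maps: list[np.ndarray], mask: np.ndarray) -> OverlayGrid:
    """Overlay three aligned binary maps on the validity mask."""
    if len(maps) != 3:
        raise ValueError("overlay requires exactly three binary maps")
    maps = [np.asarray(m, dtype=bool) for m in maps]
    for m in maps:
        if m.shape != mask.shape:
            raise ValueError("maps are not aligned to the mask")
    agree = sum(m.astype(int) for m in maps)
    category = np.where(mask, agree, -1)
    counts = {
        "good": int(((category == 3)).sum()),
        "moderate": int((category == 2).sum()),
        "poor": int((category == 1).sum()),
        "outside": int((category == 0).sum()),
    }
    return OverlayGrid(category=category, counts=counts)


def consistency_ratio(ov: OverlayGrid) -> float:
    """Incongruent-to-congruent area ratio: (moderate + poor) / good."""
    good = ov.counts["good"]
    if good == 0:
        raise ValueError("zero congruent (good) cells: ratio undefined")
    return (ov.counts["moderate"] + ov.counts["poor"]) / good


def map_pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation of two probability maps over masked-in cells."""
    x = np.asarray(a, dtype=float)[mask]
    y = np.asarray(b, dtype=float)[mask]
    if x.size < 2:
        raise ValueError("need >= 2 masked-in cells")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance map: Pearson correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def map_kappa(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Cohen's kappa of two binary maps over masked-in cells."""
    x = np.asarray(a, dtype=bool)[mask]
    y = np.asarray(b, dtype=bool)[mask]
    cm = ConfusionCounts(
        a=int((x & y).sum()), b=int((x & ~y).sum()),
        c=int((~x & y).sum()), d=int((~x & ~y).sum()),
    )
    return _cohen_kappa(cm)


def pairwise_summary(prob_maps: dict[str, np.ndarray],
                     binary_maps: dict[str, np.ndarray],
                     mask: np.ndarray) -> CongruenceSummary:
    """Three pairwise Pearson (probability) and kappa (binary) similarities
    among {average, frequency, median_pca}, plus their means."""
    missing = {m for pair in PAIRS for m in pair} - set(prob_maps)
    if missing:
        raise ValueError(f"missing consensus maps: {sorted(missing)}")
    pearson, kap = {}, {}
    for pair in PAIRS:
        m1, m2 = pair
        try:
            pearson[pair] = map_pearson(prob_maps[m1], prob_maps[m2], mask)
            kap[pair] = map_kappa(binary_maps[m1], binary_maps[m2], mask)
        except ValueError as exc:
            raise ValueError(f"pair {pair}: {exc}") from exc
    return CongruenceSummary(
        pearson_pairs=pearson,
        kappa_pairs=kap,
        mean_pearson=float(np.mean(list(pearson.values()))),
        mean_kappa=float(np.mean(list(kap.values()))),
    )
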