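"""Species niche and biogeographical traits.

Six per-species traits drive the trait regressions: prevalence (fraction of
presences in the model-training data), latitudinal and elevation ranges
(difference between the mean of the 10% most extreme presence sites at each
end), thermal range (the same 10%-extreme spread measured along the first
axis of a PCA of the five thermal variables), and the two ecological niche
factor analysis (ENFA) summaries — marginality, the standardized departure
of the species' mean environment from the study-area mean, and
specialization, the narrowness of the species' environmental variance
relative to the study area's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import THERMAL_LAYERS, EnvGrid, SpeciesDistribution


@dataclass
class NicheTraits:
    prevalence: float
    latitudinal_range: float
    elevation_range: float
    thermal_range: float
    marginality: float
    specialization: float
    thermal_pca_two_axis_variance: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "prevalence": self.prevalence,
            "lat_range": self.latitudinal_range,
            "elev_range": self.elevation_range,
            "thermal_range": self.thermal_range,
            "marginality": self.marginality,
            "specialization": self.specialization,
            "pca_two_axis_variance": self.thermal_pca_two_axis_variance,
        }


def prevalence(calibration: pd.DataFrame) -> float:
    """Proportion of presences among the model-training rows."""
    if len(calibration) == 0:
        raise ValueError("empty calibration data")
    return float((calibration["label"] == "presence").mean())


def extreme_range(values, fraction: float = 0.10) -> float:
    """Mean of the top ceil(fraction*n) values minus mean of the bottom
    ceil(fraction*n) values. Nonnegative by construction."""
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if n < 10:
        raise ValueError(f"need >= 10 values for 10%-extreme range, got {n}")
    k = int(np.ceil(fraction * n))
    return float(values[-k:].mean() - values[:k].mean())


def _standardize_layers(env: EnvGrid, layers: list[str]) -> np.ndarray:
    """(n_masked_cells, n_layers) matrix, each column z-scored over the
    masked-in cells."""
    cols = []
    for name in layers:
        v = env.layer(name)[env.mask]
        if np.ptp(v) == 0:  # exactly constant layer
            cols.append(np.zeros_like(v))
        else:
            cols.append((v - v.mean()) / v.std())
    return np.column_stack(cols)


def thermal_pca(env: EnvGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the five standardized thermal layers over masked-in cells.

    Returns (scores, explained_variance_ratio, components); scores are the
    masked-cell coordinates on the principal axes.
    """
    missing = [n for n in THERMAL_LAYERS if n not in env.layer_names]
    if missing:
        raise KeyError(f"missing thermal layer(s): {missing}")
    Z = _standardize_layers(env, list(THERMAL_LAYERS))
    Zc = Z - Z.mean(axis=0)
    u, s, vt = np.linalg.svd(Zc, full_matrices=False)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return u * s, ratio, vt


def thermal_range(env: EnvGrid, species: SpeciesDistribution,
                  fraction: float = 0.10, two_axis: bool = False,
                  ) -> tuple[float, float]:
    """Species thermal range along the thermal-PCA synthetic variable.

    Presence-cell scores are ordered along the first principal axis and the
    10%-extreme spread is computed there; the cumulative variance of the
    first two axes is returned alongside. With ``two_axis=True`` the spread
    is the Euclidean distance between the two tail centroids in the
    (PC1, PC2) plane instead.
    """
    species.env.check_aligned(env)
    scores, ratio, _ = thermal_pca(env)
    pres_at_masked = species.presence[env.mask]
    if int(pres_at_masked.sum()) < 10:
        raise ValueError("need >= 10 presences for the thermal range")
    pc1 = scores[pres_at_masked, 0]
    two_axis_var = float(ratio[:2].sum())
    if np.ptp(pc1) == 0:
        return 0.0, two_axis_var
    if not two_axis:
        return extreme_range(pc1, fraction), two_axis_var
    pc12 = scores[pres_at_masked, :2]
    order = np.argsort(pc12[:, 0])
    k = int(np.ceil(fraction * len(order)))
    lo = pc12[order[:k]].mean(axis=0)
    hi = pc12[order[-k:]].mean(axis=0)
    return float(np.linalg.norm(hi - lo)), two_axis_var


def enfa(env: EnvGrid, species: SpeciesDistribution,
         layers: list[str] | None = None) -> tuple[float, float]:
    """Global ENFA marginality and specialization.

    Layers are standardized over all masked-in cells. The marginality vector
    m is the mean standardized environment at presence cells; global
    marginality M = ||m|| / 1.96 (so a species one-sided at ~2 global SD
    scores about 1). Specialization is computed on the subspace orthogonal
    to the marginality axis: with species covariance S_s and global
    covariance S_g projected onto that subspace, the generalized eigenvalues
    of S_g v = lambda S_s v are global-to-species variance ratios along the
    specialization factors, and S = sqrt(mean lambda). A species sampling
    the whole landscape uniformly has M ~ 0 and S ~ 1; narrower niches give
    larger S.
    """
    species.env.check_aligned(env)
    layers = list(layers or env.layer_names)
    if len(layers) < 2:
        raise ValueError("ENFA needs >= 2 environmental layers")
    Z = _standardize_layers(env, layers)
    pres = species.presence[env.mask]
    n_pres = int(pres.sum())
    if n_pres < len(layers) + 1:
        raise ValueError(
            f"{n_pres} presences for {len(layers)} layers: "
            "species covariance would be singular"
        )
    Zs = Z[pres]
    m = Zs.mean(axis=0)
    marginality = float(np.linalg.norm(m) / 1.96)

    cov_s = np.cov(Zs, rowvar=False)
    cov_g = np.cov(Z, rowvar=False)
    if np.linalg.matrix_rank(cov_s) < len(layers):
        raise np.linalg.LinAlgError(
            "singular species covariance; reduce or decorrelate layers"
        )
    # orthonormal basis of the subspace orthogonal to the marginality axis
    norm_m = np.linalg.norm(m)
    if norm_m > 0:
        q, _ = np.linalg.qr(np.column_stack([m / norm_m, np.eye(len(layers))]))
        basis = q[:, 1:len(layers)]
    else:
        basis = np.eye(len(layers))[:, 1:]
    A = basis.T @ cov_s @ basis
    G = basis.T @ cov_g @ basis
    # generalized eigenproblem G v = lambda A v via scipy
    from scipy.linalg import eigh

    lam = eigh(G, A, eigvals_only=True)
    lam = np.clip(lam, 0.0, None)
    specialization = float(np.sqrt(lam.mean()))
    return marginality, specialization


def species_traits(env: EnvGrid, species: SpeciesDistribution,
                   calibration: pd.DataFrame,
                   elevation_layer: str = "ELEV",
                   enfa_layers: list[str] | None = None) -> NicheTraits:
    """All six traits for one species.

    Latitudinal range uses presence-cell latitudes; elevation range uses the
    ``elevation_layer`` values at presences; both apply the 10%-extreme
    definition.
    """
    lat, _ = env.cell_latlon()
    lat_values = lat[species.presence]
    elev_values = env.layer(elevation_layer)[species.presence]
    t_range, two_axis_var = thermal_range(env, species)
    marg, spec = enfa(env, species, layers=enfa_layers)
    return NicheTraits(
        prevalence=prevalence(calibration),
        latitudinal_range=extreme_range(lat_values),
        elevation_range=extreme_range(elev_values),
        thermal_range=t_range,
        marginality=marg,
        specialization=spec,
        thermal_pca_two_axis_variance=two_axis_var,
    )
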