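"""Synthetic tissues with known ground truth.

Two generators cover the regimes the sampling theory distinguishes:

* :func:`generate_hpp_tissue` — each phenotype is an independent homogeneous
  Poisson point process (HPP) at a stated density λ (points per µm²).  For
  such a tissue the probability that r non-overlapping squares of width w
  contain at least one point of a phenotype is exactly 1 − exp(−λrw²), so the
  saturation constant obeys τ = 1/(λw²) and the width exponent is α = 2
  (spatially random mixing).

* :func:`generate_segregated_tissue` — disk-shaped patches of a single
  phenotype over a sparse mixed background.  Phenotypes concentrated in
  patches make wide FoVs unproductive, driving α below 2.

:func:`generate_curve_observations` draws noisy recovery curves directly from
the saturation law, for exercising the curve fits without a tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import SpatialDataset
from .sampling import RecoveryCurve

__all__ = [
    "HppSpec",
    "PatchSpec",
    "generate_hpp_tissue",
    "generate_segregated_tissue",
    "generate_curve_observations",
]


@dataclass
class HppSpec:
    """Homogeneous Poisson tissue: one density λ (points/µm²) per label."""

    densities: Mapping[str, float]
    extent: tuple[float, float, float, float] = (0.0, 0.0, 6000.0, 6000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(lam <= 0 for lam in self.densities.values()):
            raise ValueError("all densities must be positive")
        xmin, ymin, xmax, ymax = self.extent
        if (xmax - xmin) * (ymax - ymin) <= 0:
            raise ValueError("extent area must be positive")


@dataclass
class PatchSpec:
    """Segregated tissue: single-label disk patches over a mixed background.

    ``n_patches`` disk patches of radius ``patch_radius`` (µm) are centered
    uniformly on the extent; each patch receives one label drawn uniformly
    from ``label_pool`` and Poisson(within_patch_density · πR²) points
    uniform on its disk (clipped to the extent).  The background is an HPP
    of total density ``background_density`` with labels mixed uniformly over
    the pool.
    """

    n_patches: int
    patch_radius: float
    within_patch_density: float
    label_pool: Sequence[str]
    background_density: float = 0.0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 4000.0, 4000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")
        if self.patch_radius <= 0:
            raise ValueError("patch_radius must be positive")
        if self.within_patch_density < 0 or self.background_density < 0:
            raise ValueError("densities must be >= 0")
        if len(self.label_pool) < 1:
            raise ValueError("label_pool must not be empty")


def generate_hpp_tissue(spec: HppSpec) -> SpatialDataset:
    """Simulate independent HPPs, one per label, on the extent."""
    xmin, ymin, xmax, ymax = spec.extent
    area = (xmax - xmin) * (ymax - ymin)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    xs, ys, labs = [], [], []
    for label in spec.densities:  # insertion order keeps the draw reproducible
        lam = spec.densities[label]
        n = rng.poisson(lam * area)
        xs.append(rng.uniform(xmin, xmax, n))
        ys.append(rng.uniform(ymin, ymax, n))
        labs.append(np.full(n, str(label), dtype=object))
    if not xs:
        return SpatialDataset(np.empty(0), np.empty(0), np.empty(0, dtype=object),
                              bounds=spec.extent)
    return SpatialDataset(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(labs),
        bounds=spec.extent,
    )


def generate_segregated_tissue(spec: PatchSpec) -> SpatialDataset:
    """Simulate disk patches of identical phenotype over a mixed background."""
    xmin, ymin, xmax, ymax = spec.extent
    area = (xmax - xmin) * (ymax - ymin)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    pool = np.asarray([str(l) for l in spec.label_pool], dtype=object)

    centers_x = rng.uniform(xmin, xmax, spec.n_patches)
    centers_y = rng.uniform(ymin, ymax, spec.n_patches)
    patch_labels = pool[rng.integers(0, pool.size, spec.n_patches)]

    xs, ys, labs = [], [], []
    mean_pts = spec.within_patch_density * np.pi * spec.patch_radius**2
    for cx, cy, lab in zip(centers_x, centers_y, patch_labels):
        n = rng.poisson(mean_pts)
        rad = spec.patch_radius * np.sqrt(rng.uniform(size=n))
        ang = rng.uniform(0.0, 2.0 * np.pi, n)
        px = cx + rad * np.cos(ang)
        py = cy + rad * np.sin(ang)
        keep = (px >= xmin) & (px <= xmax) & (py >= ymin) & (py <= ymax)
        xs.append(px[keep])
        ys.append(py[keep])
        labs.append(np.full(int(keep.sum()), lab, dtype=object))

    n_bg = rng.poisson(spec.background_density * area)
    xs.append(rng.uniform(xmin, xmax, n_bg))
    ys.append(rng.uniform(ymin, ymax, n_bg))
    labs.append(pool[rng.integers(0, pool.size, n_bg)])

    return SpatialDataset(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(labs),
        bounds=spec.extent,
    )


def generate_curve_observations(
    n_observable: int,
    tau: float,
    r_values: Sequence[int],
    reps: int = 50,
    seed: int = 0,
) -> RecoveryCurve:
    """Draw noisy recovery curves from the saturation law.

    At each r the number of recovered phenotypes is Binomial(N_O, p) with
    p = 1 − exp(−r/τ): every one of the N_O phenotypes is recovered
    independently with the saturation probability.  Mean and standard error
    over ``reps`` draws are returned, mimicking the aggregation of a real
    sampling experiment.
    """
    if n_observable <= 0 or tau <= 0:
        raise ValueError("n_observable and tau must be positive")
    r_values = np.asarray(sorted(int(r) for r in r_values), dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = 1.0 - np.exp(-r_values / tau)
    draws = rng.binomial(n_observable, p, size=(reps, r_values.size))
    se = draws.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.zeros(r_values.size)
    return RecoveryCurve(
        r_values=r_values,
        mean_recovered=draws.mean(axis=0),
        se_recovered=se,
        reps=reps,
    )
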