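"""The FoV sampling engine.

Simulates a multiplexed-imaging acquisition on a labeled point pattern:
non-overlapping axis-aligned square fields of view (FoVs) of width ``w`` are
placed by rejection sampling, the cells of each phenotype falling inside the
sampled squares are counted, and a phenotype is *recovered* when its sampled
count passes the recovery threshold ``T``.  Repeating the draw (50 times by
default) and averaging over repetitions yields a recovery curve N(r), the
object the saturation model is fitted to.

Conventions
-----------
* Candidate FoV centers are uniform over the tissue bounds rectangle; squares
  may overhang the tissue edge (edge effects are accepted and documented).
* Two squares overlap when their open interiors intersect; squares sharing
  only an edge do not overlap.
* Point membership uses half-open squares ``[x-w/2, x+w/2) x [y-w/2, y+w/2)``
  so abutting squares can never double-count a point.
* Draws at different r are independent (fresh substream per (r, repetition)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import SpatialDataset

__all__ = [
    "FovSet",
    "RecoveryCurve",
    "FovPlacementError",
    "sample_fovs",
    "count_in_fovs",
    "recovered_set",
    "recovery_curve",
    "sample_counts",
    "kl_divergence",
    "per_phenotype_recovery",
    "cells_per_spot",
    "SpotCountSummary",
]


class FovPlacementError(RuntimeError):
    """Raised when r non-overlapping FoVs cannot be placed."""


@dataclass
class FovSet:
    """One draw of non-overlapping square FoVs.

    ``centers`` is an (r, 2) array of square centers (µm); all squares share
    the width ``width``.
    """

    centers: np.ndarray
    width: float
    draw_seed: int | None = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[1] != 2:
            raise ValueError("centers must be an (r, 2) array")
        self.width = float(self.width)

    @property
    def r(self) -> int:
        return self.centers.shape[0]

    def squares(self) -> list[tuple[float, float, float, float]]:
        """(xmin, ymin, xmax, ymax) per square."""
        h = self.width / 2.0
        return [
            (cx - h, cy - h, cx + h, cy + h) for cx, cy in self.centers
        ]


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _place_centers(
    rng: np.random.Generator,
    bounds: tuple[float, float, float, float],
    r: int,
    w: float,
    max_attempts: int,
) -> np.ndarray:
    xmin, ymin, xmax, ymax = bounds
    cx = np.empty(r)
    cy = np.empty(r)
    placed = 0
    while placed < r:
        rejections = 0
        while True:
            a = rng.uniform(xmin, xmax)
            b = rng.uniform(ymin, ymax)
            # open-interior overlap: both center offsets strictly below w
            if placed and np.any(
                (np.abs(a - cx[:placed]) < w) & (np.abs(b - cy[:placed]) < w)
            ):
                rejections += 1
                if rejections >= max_attempts:
                    raise FovPlacementError(
                        f"cannot place {r} non-overlapping FoVs of width {w} "
                        f"(gave up after {max_attempts} consecutive rejections "
                        f"at square {placed + 1})"
                    )
                continue
            cx[placed] = a
            cy[placed] = b
            placed += 1
            break
    return np.column_stack([cx, cy])


def sample_fovs(
    ds: SpatialDataset,
    r: int,
    w: float,
    seed=None,
    max_attempts: int = 1000,
) -> FovSet:
    """Draw ``r`` non-overlapping square FoVs of width ``w`` (µm).

    Centers are sampled uniformly over the tissue bounds; a candidate whose
    square overlaps a previously accepted square is discarded and redrawn.
    After ``max_attempts`` consecutive rejections for one square a
    :class:`FovPlacementError` is raised.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if w <= 0:
        raise ValueError("width must be positive")
    if r * w * w > ds.area and ds.area > 0:
        raise FovPlacementError(
            f"total FoV area {r * w * w:.0f} um^2 exceeds tissue area {ds.area:.0f} um^2"
        )
    rng = _rng_from(seed)
    centers = _place_centers(rng, ds.bounds, r, w, max_attempts)
    return FovSet(centers, w, draw_seed=seed if isinstance(seed, int) else None)


def _counts_for_centers(
    x: np.ndarray,
    y: np.ndarray,
    codes: np.ndarray,
    n_labels: int,
    centers: np.ndarray,
    w: float,
) -> np.ndarray:
    """Per-label point counts inside the union of half-open squares."""
    h = w / 2.0
    mask = np.zeros(x.shape[0], dtype=bool)
    for cx, cy in centers:
        mask |= (x >= cx - h) & (x < cx + h) & (y >= cy - h) & (y < cy + h)
    return np.bincount(codes[mask], minlength=n_labels)


def count_in_fovs(ds: SpatialDataset, fovs: FovSet) -> pd.Series:
    """Number of points of each phenotype inside the sampled squares.

    Every label of the dataset appears in the index (zero counts included),
    which keeps sampled and full-data proportion vectors aligned.
    """
    codes, uniq = ds.label_codes()
    counts = _counts_for_centers(ds.x, ds.y, codes, uniq.size, fovs.centers, fovs.width)
    return pd.Series(counts, index=uniq, dtype=int)


def recovered_set(counts: pd.Series | dict, T: int, strict: bool = True) -> set[str]:
    """Labels passing the recovery rule: count > T (strict) or >= T."""
    if T < 0:
        raise ValueError("threshold T must be >= 0")
    if not isinstance(counts, pd.Series):
        counts = pd.Series(counts, dtype=float)
    passed = counts > T if strict else counts >= T
    return set(map(str, counts.index[passed]))


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Kullback-Leibler divergence sum P_i ln(P_i / Q_i), with 0 ln 0 := 0.

    ``Q`` must be strictly positive wherever ``P`` is; an all-zero ``P``
    (an empty draw) is signalled with a ValueError so callers can resample.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have equal length")
    if P.sum() == 0:
        raise ValueError("empty sample: P is all zero")
    if not np.allclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("P must sum to 1")
    pos = P > 0
    if np.any(Q[pos] <= 0):
        raise ValueError("Q must be strictly positive on observed labels")
    return float(np.sum(P[pos] * np.log(P[pos] / Q[pos])))


@dataclass
class RecoveryCurve:
    """Aggregated recovery across repeated FoV draws.

    One row per number of FoVs r: the mean and standard error of the number
    of recovered phenotypes over ``reps`` independent draws, and optionally
    the mean KL divergence between sampled and full-tissue proportions.
    """

    r_values: np.ndarray
    mean_recovered: np.ndarray
    se_recovered: np.ndarray
    reps: int
    w: float | None = None
    threshold: int | None = None
    mean_kl: np.ndarray | None = None
    se_kl: np.ndarray | None = None
    kl_rejections: int = 0

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=int)
        self.mean_recovered = np.asarray(self.mean_recovered, dtype=float)
        self.se_recovered = np.asarray(self.se_recovered, dtype=float)
        if np.any(np.diff(self.r_values) <= 0):
            raise ValueError("r_values must be strictly increasing")
        if np.any(self.se_recovered < 0):
            raise ValueError("standard errors must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "r": self.r_values,
                "mean_recovered": self.mean_recovered,
                "se_recovered": self.se_recovered,
            }
        )
        if self.mean_kl is not None:
            df["mean_kl"] = self.mean_kl
            df["se_kl"] = self.se_kl
        if self.w is not None:
            df.insert(0, "w", self.w)
        return df

    def plot(self, ax=None, **kwargs):
        """Errorbar plot of mean recovered clusters versus r."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.r_values, self.mean_recovered, yerr=self.se_recovered,
                    fmt="o", capsize=2, **kwargs)
        ax.set_xlabel("number of FoVs r")
        ax.set_ylabel("mean recovered phenotypes")
        return ax


def sample_counts(
    ds: SpatialDataset,
    r_values: Sequence[int],
    w: float,
    reps: int = 50,
    seed=0,
    max_attempts: int = 1000,
) -> dict[int, np.ndarray]:
    """Per-label sampled counts for every (r, repetition) draw.

    Returns ``{r: counts}`` with ``counts`` of shape (reps, n_labels), using
    an independent random substream per (r, repetition).  This is the shared
    primitive behind recovery curves, per-phenotype recovery and
    threshold-robustness scans: any recovery rule can be applied to the same
    draws afterwards.
    """
    if ds.n_points == 0:
        raise ValueError("dataset is empty")
    r_values = [int(r) for r in r_values]
    codes, uniq = ds.label_codes()
    x, y = ds.x, ds.y
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(r_values) * reps)
    out: dict[int, np.ndarray] = {}
    k = 0
    for r in r_values:
        counts = np.zeros((reps, uniq.size), dtype=int)
        for rep in range(reps):
            rng = np.random.default_rng(children[k]); k += 1
            try:
                centers = _place_centers(rng, ds.bounds, r, w, max_attempts)
            except FovPlacementError as err:
                raise FovPlacementError(f"r={r}: {err}") from err
            counts[rep] = _counts_for_centers(x, y, codes, uniq.size, centers, w)
        out[r] = counts
    return out


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def recovery_curve(
    ds: SpatialDataset,
    r_values: Sequence[int],
    w: float,
    T: int,
    reps: int = 50,
    seed=0,
    strict: bool = True,
    compute_kl: bool = False,
    max_attempts: int = 1000,
) -> RecoveryCurve:
    """Mean (± SE) number of recovered phenotypes per number of FoVs r.

    For each r, ``reps`` independent draws of r non-overlapping squares of
    width ``w`` are taken; a phenotype is recovered in a draw when its
    sampled count passes the threshold rule.  With ``compute_kl`` the KL
    divergence between each draw's proportion vector and the full-data
    proportions is averaged as well; empty draws (no cells sampled) are
    rejected and redrawn, and the tally is reported in ``kl_rejections``.
    """
    counts_by_r = sample_counts(ds, r_values, w, reps=reps, seed=seed,
                                max_attempts=max_attempts)
    Q = None
    if compute_kl:
        codes, uniq = ds.label_codes()
        Q = np.bincount(codes, minlength=uniq.size).astype(float)
        Q /= Q.sum()

    means, ses, kl_means, kl_ses = [], [], [], []
    kl_rejections = 0
    # redraw stream disjoint from the sample_counts substreams
    redraw_children = (
        iter(np.random.SeedSequence(seed, spawn_key=(999,)).spawn(4096))
        if compute_kl
        else None
    )

    for r in counts_by_r:
        counts = counts_by_r[r]
        rec = (counts > T).sum(axis=1) if strict else (counts >= T).sum(axis=1)
        means.append(float(rec.mean()))
        ses.append(_sem(rec.astype(float)))
        if compute_kl:
            kls = []
            for row in counts:
                total = row.sum()
                while total == 0:  # empty draw: reject and redraw
                    kl_rejections += 1
                    rng = np.random.default_rng(next(redraw_children))
                    centers = _place_centers(rng, ds.bounds, r, w, max_attempts)
                    codes, uniq = ds.label_codes()
                    row = _counts_for_centers(ds.x, ds.y, codes, uniq.size, centers, w)
                    total = row.sum()
                kls.append(kl_divergence(row / total, Q))
            kl_means.append(float(np.mean(kls)))
            kl_ses.append(_sem(np.asarray(kls)))

    return RecoveryCurve(
        r_values=np.asarray(list(counts_by_r), dtype=int),
        mean_recovered=np.asarray(means),
        se_recovered=np.asarray(ses),
        reps=reps,
        w=w,
        threshold=T,
        mean_kl=np.asarray(kl_means) if compute_kl else None,
        se_kl=np.asarray(kl_ses) if compute_kl else None,
        kl_rejections=kl_rejections,
    )


def per_phenotype_recovery(
    ds: SpatialDataset,
    r_values: Sequence[int],
    w: float,
    T: int = 0,
    reps: int = 50,
    seed=0,
    strict: bool = True,
    max_attempts: int = 1000,
) -> pd.DataFrame:
    """Per-label recovery probability versus r.

    Returns a DataFrame indexed by label with one column per r: the fraction
    of repetitions in which that label passed the recovery rule.
    """
    counts_by_r = sample_counts(ds, r_values, w, reps=reps, seed=seed,
                                max_attempts=max_attempts)
    _, uniq = ds.label_codes()
    cols = {}
    for r, counts in counts_by_r.items():
        hit = counts > T if strict else counts >= T
        cols[r] = hit.mean(axis=0)
    return pd.DataFrame(cols, index=uniq)


@dataclass
class SpotCountSummary:
    """Distribution of cell counts inside spot-sized squares."""

    counts: np.ndarray
    spot_width: float

    @property
    def median(self) -> float:
        return float(np.median(self.counts))

    @property
    def quartiles(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.counts, [25, 75])
        return float(q1), float(q3)

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))


def cells_per_spot(
    ds: SpatialDataset,
    spot_width: float = 44.0,
    n_draws: int = 1000,
    seed=0,
) -> SpotCountSummary:
    """Cell counts of randomly placed spot-sized squares (default 44 µm).

    Estimates how many single cells one capture spot of a spot-based
    platform aggregates; draws are independent (overlap between draws is
    allowed) with centers uniform over the tissue bounds.
    """
    if ds.n_points == 0:
        raise ValueError("dataset is empty")
    rng = _rng_from(seed)
    xmin, ymin, xmax, ymax = ds.bounds
    h = spot_width / 2.0
    cx = rng.uniform(xmin, xmax, size=n_draws)
    cy = rng.uniform(ymin, ymax, size=n_draws)
    x, y = ds.x, ds.y
    counts = np.empty(n_draws, dtype=int)
    for i in range(n_draws):
        counts[i] = np.count_nonzero(
            (x >= cx[i] - h) & (x < cx[i] + h) & (y >= cy[i] - h) & (y < cy[i] + h)
        )
    return SpotCountSummary(counts=counts, spot_width=spot_width)
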