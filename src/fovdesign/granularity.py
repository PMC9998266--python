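"""Effect of clustering granularity on the sampling constant τ.

Phenotype labels usually come from a clustering whose granularity is a
choice.  To see how τ depends on it, the labels are merged bottom-up along a
hierarchical tree (Ward linkage on Euclidean distances between per-cluster
mean feature profiles); after each merge the spatial sampling analysis is
rerun and the saturation model refitted, tracing τ as a function of the
number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .data import SpatialDataset
from .models import SaturationFit, fit_saturation
from .sampling import recovery_curve

__all__ = ["MergeStep", "MergeTrace", "granularity_analysis"]


@dataclass
class MergeStep:
    """One granularity level: cluster count, relabeling and fitted τ."""

    n_clusters: int
    label_mapping: dict[str, str]
    tau: float
    fit: SaturationFit


@dataclass
class MergeTrace:
    """τ versus cluster count along the merge tree."""

    steps: list[MergeStep]
    linkage_matrix: np.ndarray
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_clusters": [s.n_clusters for s in self.steps],
                "tau": [s.tau for s in self.steps],
                "r_squared": [s.fit.r_squared for s in self.steps],
            }
        )


def cluster_mean_profiles(ds: SpatialDataset) -> pd.DataFrame:
    """Mean feature vector per phenotype label."""
    if ds.features is None:
        raise ValueError("dataset carries no feature matrix")
    df = pd.DataFrame(np.asarray(ds.features))
    df["__label"] = ds.labels.astype(str)
    return df.groupby("__label").mean()


def granularity_analysis(
    ds: SpatialDataset,
    w: float,
    T: int,
    r_values: Sequence[int],
    reps: int = 50,
    seed=0,
    strict: bool = True,
) -> MergeTrace:
    """Merge clusters along the Ward tree and refit τ at each level.

    Starting from the N_total original labels, the two most similar clusters
    (Euclidean distance between mean profiles, Ward's criterion) are merged
    repeatedly; at each level from N_total−1 down to 2 clusters the points
    are relabeled by the tree cut, the recovery curve is recomputed and the
    saturation model refitted.  Merged counts are sums of member counts, so
    recovery can only get easier as clusters merge.
    """
    profiles = cluster_mean_profiles(ds)
    labels = list(profiles.index)
    if len(labels) < 3:
        raise ValueError("granularity analysis needs at least 3 distinct labels")

    Z = linkage(profiles.to_numpy(), method="ward", metric="euclidean")
    steps: list[MergeStep] = []
    children = np.random.SeedSequence(seed).spawn(len(labels) - 2)
    for k, child in zip(range(len(labels) - 1, 1, -1), children):
        assignment = fcluster(Z, t=k, criterion="maxclust")
        mapping = {lab: f"merged_{grp}" for lab, grp in zip(labels, assignment)}
        merged = ds.relabel(mapping)
        curve = recovery_curve(
            merged, r_values, w, T, reps=reps,
            seed=int(child.generate_state(1)[0]), strict=strict,
        )
        fit = fit_saturation(curve)
        steps.append(
            MergeStep(n_clusters=int(k), label_mapping=mapping, tau=fit.tau, fit=fit)
        )
    return MergeTrace(steps=steps, linkage_matrix=Z, labels=labels)
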