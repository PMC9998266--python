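"""Labeled point patterns and their I/O.

The central container is :class:`SpatialDataset`: one record per cell (or
capture spot) with planar coordinates in micrometres and a phenotype label,
optionally accompanied by a non-negative feature matrix (e.g. mean marker
intensities or transcript counts per observation).  All downstream sampling
and model fitting operates on this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpatialDataset",
    "PhenotypeAbundance",
    "SchemaError",
    "CoordinateParseError",
    "load_points",
    "write_points",
    "phenotype_abundances",
    "observable_phenotypes",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class CoordinateParseError(ValueError):
    """A coordinate value could not be interpreted as a finite number."""


@dataclass
class PhenotypeAbundance:
    """Count and proportion of one phenotype within a dataset."""

    label: str
    count: int
    proportion: float


@dataclass
class SpatialDataset:
    """A labeled planar point pattern with rectangular tissue bounds.

    Parameters
    ----------
    x, y
        Point coordinates in micrometres.
    labels
        Phenotype identifier per point (non-empty strings).
    features
        Optional (n_points, n_features) non-negative matrix.
    bounds
        ``(xmin, ymin, xmax, ymax)`` in micrometres.  Defaults to the tight
        bounding rectangle of the points; supply explicitly for tissues that
        do not fill their bounding box.
    unit_note
        Free-text reminder of the coordinate unit; must remain micrometres.
    """

    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray
    features: np.ndarray | None = None
    bounds: tuple[float, float, float, float] | None = None
    unit_note: str = "micrometres"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.labels = np.asarray(self.labels, dtype=object).ravel()
        if self.x.shape != self.y.shape or self.x.shape != self.labels.shape:
            raise ValueError("x, y and labels must have equal length")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y)):
            bad = np.flatnonzero(~(np.isfinite(self.x) & np.isfinite(self.y)))
            raise CoordinateParseError(
                f"non-finite coordinates at rows {bad[:10].tolist()}"
            )
        if self.n_points and any(not isinstance(l, str) or not l for l in self.labels):
            self.labels = np.array([str(l) for l in self.labels], dtype=object)
            if any(not l or l == "nan" for l in self.labels):
                raise ValueError("labels must be non-empty strings")
        if self.bounds is None:
            if self.n_points == 0:
                self.bounds = (0.0, 0.0, 0.0, 0.0)
            else:
                self.bounds = (
                    float(self.x.min()),
                    float(self.y.min()),
                    float(self.x.max()),
                    float(self.y.max()),
                )
        else:
            self.bounds = tuple(float(b) for b in self.bounds)  # type: ignore[assignment]
            xmin, ymin, xmax, ymax = self.bounds
            if xmax < xmin or ymax < ymin:
                raise ValueError("bounds must satisfy xmin <= xmax and ymin <= ymax")
            if self.n_points and (
                self.x.min() < xmin
                or self.x.max() > xmax
                or self.y.min() < ymin
                or self.y.max() > ymax
            ):
                raise ValueError("all points must lie inside the supplied bounds")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.ndim != 2 or self.features.shape[0] != self.n_points:
                raise ValueError("features must be a (n_points, n_features) matrix")
            if np.any(self.features < 0):
                raise ValueError("feature values must be non-negative")

    # -- basic descriptors -------------------------------------------------

    @property
    def n_points(self) -> int:
        return int(self.x.size)

    @property
    def unique_labels(self) -> np.ndarray:
        return np.unique(self.labels.astype(str))

    @property
    def n_total(self) -> int:
        """Number of distinct phenotype labels present (N_total)."""
        return int(self.unique_labels.size)

    @property
    def area(self) -> float:
        """Bounds area in square micrometres."""
        xmin, ymin, xmax, ymax = self.bounds
        return (xmax - xmin) * (ymax - ymin)

    def label_counts(self) -> pd.Series:
        return pd.Series(self.labels.astype(str)).value_counts().sort_index()

    def proportions(self) -> pd.Series:
        """Full-data phenotype proportion vector Q."""
        counts = self.label_counts()
        return counts / counts.sum()

    def label_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer codes per point and the corresponding label order."""
        uniq, codes = np.unique(self.labels.astype(str), return_inverse=True)
        return codes, uniq

    def relabel(self, mapping: Mapping[str, str]) -> "SpatialDataset":
        """Return a copy with labels replaced through ``mapping``."""
        new = np.array([mapping.get(str(l), str(l)) for l in self.labels], dtype=object)
        return SpatialDataset(
            self.x.copy(), self.y.copy(), new,
            features=None if self.features is None else self.features.copy(),
            bounds=self.bounds, unit_note=self.unit_note,
        )

    def crop(self, xmin: float, ymin: float, xmax: float, ymax: float) -> "SpatialDataset":
        """Points inside the half-open window [xmin, xmax) × [ymin, ymax).

        The window becomes the new bounds, so the result can serve as a
        single-FoV dataset (e.g. for the shrinkage estimator of α).
        """
        inside = (
            (self.x >= xmin) & (self.x < xmax) & (self.y >= ymin) & (self.y < ymax)
        )
        return SpatialDataset(
            self.x[inside], self.y[inside], self.labels[inside],
            features=None if self.features is None else self.features[inside],
            bounds=(xmin, ymin, xmax, ymax), unit_note=self.unit_note,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "label": self.labels.astype(str)})

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        x: str = "x",
        y: str = "y",
        label: str = "label",
        features: np.ndarray | None = None,
        bounds: tuple[float, float, float, float] | None = None,
    ) -> "SpatialDataset":
        for col in (x, y, label):
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} not found in table")
        xv = pd.to_numeric(df[x], errors="coerce").to_numpy(dtype=float)
        yv = pd.to_numeric(df[y], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~(np.isfinite(xv) & np.isfinite(yv)))
        if bad.size:
            raise CoordinateParseError(
                f"non-numeric or non-finite coordinate at row(s) {bad[:10].tolist()}"
            )
        return cls(xv, yv, df[label].astype(str).to_numpy(dtype=object),
                   features=features, bounds=bounds)


def load_points(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    bounds: tuple[float, float, float, float] | None = None,
    features_path: str | Path | None = None,
) -> SpatialDataset:
    """Read a delimited point table into a :class:`SpatialDataset`.

    ``column_map`` maps the roles ``x``, ``y`` and ``label`` to column names
    (defaults to those exact names).  A JSON sidecar ``<path>.meta.json``
    written by :func:`write_points` restores bounds and the unit note; an
    explicit ``bounds`` argument wins over the sidecar.  ``features_path``
    optionally points to a MatrixMarket file with one row per point.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = {"x": "x", "y": "y", "label": "label"}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    missing = [c for c in (cmap["x"], cmap["y"], cmap["label"]) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")

    meta_path = path.with_name(path.name + ".meta.json")
    unit_note = "micrometres"
    if bounds is None and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        bounds = tuple(meta["bounds"]) if meta.get("bounds") else None
        unit_note = meta.get("unit_note", unit_note)

    features = None
    if features_path is not None:
        from scipy.io import mmread

        mat = mmread(str(features_path))
        features = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)

    ds = SpatialDataset.from_dataframe(
        df, x=cmap["x"], y=cmap["y"], label=cmap["label"],
        features=features, bounds=bounds,
    )
    ds.unit_note = unit_note
    return ds


def write_points(
    ds: SpatialDataset,
    path: str | Path,
    delimiter: str = ",",
    features_path: str | Path | None = None,
) -> None:
    """Write the point table plus a JSON metadata sidecar (bounds, units)."""
    path = Path(path)
    ds.to_frame().to_csv(path, sep=delimiter, index=False)
    meta = {"bounds": list(ds.bounds), "unit_note": ds.unit_note}
    path.with_name(path.name + ".meta.json").write_text(json.dumps(meta))
    if features_path is not None and ds.features is not None:
        from scipy.io import mmwrite

        mmwrite(str(features_path), np.asarray(ds.features))


def phenotype_abundances(ds: SpatialDataset) -> list[PhenotypeAbundance]:
    """Per-phenotype counts and proportions (the abundance vector p)."""
    if ds.n_points == 0:
        raise ValueError("dataset is empty")
    counts = ds.label_counts()
    total = int(counts.sum())
    return [
        PhenotypeAbundance(label=str(lab), count=int(c), proportion=c / total)
        for lab, c in counts.items()
    ]


def observable_phenotypes(ds: SpatialDataset, T: int, strict: bool = True) -> int:
    """Number of phenotypes whose total count passes the recovery rule (N_O).

    With ``strict`` (default) a phenotype counts if its total exceeds ``T``
    (count > T); with ``strict=False`` the rule is count >= T.  N_O is the
    ceiling of any recovery curve computed at the same threshold.
    """
    if T < 0:
        raise ValueError("threshold T must be >= 0")
    counts = ds.label_counts()
    passed = counts > T if strict else counts >= T
    return int(passed.sum())
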