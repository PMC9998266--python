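"""Experimental-design planning from fitted (α, C) parameters.

Substituting the width law τ(w) = C/w^α into the saturation law gives the
design surface

    fraction(r, w) = 1 − exp(−r·w^α / C),

the expected fraction of observable phenotypes recovered when imaging r
square FoVs of width w (µm).  For α = 2 the surface depends on (r, w) only
through the total imaged area r·w²; for α < 2 splitting a fixed area into
more, smaller FoVs (fragmentation) recovers strictly more phenotypes, while
for α > 2 it would recover fewer.

Widths are in µm throughout; total areas are reported in mm²
(1 mm² = 10⁶ µm²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignEvaluation",
    "DesignRecommendation",
    "recovery_fraction",
    "predict_recovery_surface",
    "fragmentation_analysis",
    "fovs_for_fraction",
    "recommend_design",
]

UM2_PER_MM2 = 1e6


def recovery_fraction(alpha: float, C: float, r, w):
    """Predicted recovered fraction 1 − exp(−r·w^α/C); vectorised."""
    if alpha <= 0 or C <= 0:
        raise ValueError("alpha and C must be positive")
    r = np.asarray(r, dtype=float)
    w = np.asarray(w, dtype=float)
    return 1.0 - np.exp(-r * np.power(w, alpha) / C)


@dataclass
class DesignEvaluation:
    """Predicted recovery over a grid of (r, w) designs."""

    alpha: float
    C: float
    n_observable: float | None
    grid: pd.DataFrame

    def fraction_at(self, r: float, w: float) -> float:
        return float(recovery_fraction(self.alpha, self.C, r, w))


def predict_recovery_surface(
    alpha: float,
    C: float,
    r_grid: Sequence[float],
    w_grid: Sequence[float],
    n_observable: float | None = None,
) -> DesignEvaluation:
    """Evaluate the design surface on a cartesian (r, w) grid.

    The grid carries the total area in mm² and the predicted recovered
    fraction; when ``n_observable`` is given a predicted count column is
    added.  Fraction mode (no N_O) is the default for comparing tissues.
    """
    rows = []
    for r in r_grid:
        for w in w_grid:
            frac = float(recovery_fraction(alpha, C, r, w))
            rows.append(
                {
                    "r": r,
                    "w": float(w),
                    "total_area_mm2": r * w * w / UM2_PER_MM2,
                    "predicted_fraction": frac,
                }
            )
    grid = pd.DataFrame(rows)
    if n_observable is not None:
        grid["predicted_count"] = n_observable * grid["predicted_fraction"]
    return DesignEvaluation(alpha=alpha, C=C, n_observable=n_observable, grid=grid)


def fragmentation_analysis(
    alpha: float,
    C: float,
    total_areas_mm2: Sequence[float] = (1.6, 0.8, 0.32),
    r_values: Sequence[int] = tuple(range(1, 26)),
) -> pd.DataFrame:
    """Recovered fraction when a fixed total area is split into r FoVs.

    For each (area, r) the FoV width is w = sqrt(area/r), keeping r·w²
    constant along each area line.  Rising fractions along r (α < 2) mean
    fragmentation pays; flat lines (α = 2) mean only total area matters.
    """
    rows = []
    for area in total_areas_mm2:
        for r in r_values:
            w = math.sqrt(area * UM2_PER_MM2 / r)
            rows.append(
                {
                    "total_area_mm2": float(area),
                    "r": int(r),
                    "w": w,
                    "predicted_fraction": float(recovery_fraction(alpha, C, r, w)),
                }
            )
    return pd.DataFrame(rows)


def fovs_for_fraction(tau: float, target_fraction: float) -> int:
    """Smallest integer r with predicted fraction ≥ target: r ≥ −τ ln(1−f).

    Inverting the saturation law; e.g. f = 1 − e⁻² needs r = 2τ FoVs.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target fraction must lie strictly between 0 and 1 "
                         "(the asymptote is unreachable)")
    exact = -tau * math.log1p(-target_fraction)
    # snap to an integer before ceiling to absorb representation error
    nearest = round(exact)
    if abs(exact - nearest) < 1e-9:
        return max(int(nearest), 1)
    return max(int(math.ceil(exact)), 1)


@dataclass
class DesignRecommendation:
    """Designs meeting a target recovery fraction under constraints."""

    target_fraction: float
    feasible: bool
    candidates: pd.DataFrame
    minimal_r: pd.Series | None = None
    minimal_area: pd.Series | None = None
    best_achievable_fraction: float | None = None

    def summary(self) -> str:
        lines = [f"Design recommendation (target fraction {self.target_fraction:.3f})"]
        if not self.feasible:
            lines.append(
                "  infeasible under the given constraints; best achievable "
                f"fraction {self.best_achievable_fraction:.3f}"
            )
            return "\n".join(lines)
        for name, row in (("minimal r", self.minimal_r),
                          ("minimal area", self.minimal_area)):
            lines.append(
                f"  {name}: r={int(row['r'])}, w={row['w']:.0f} um, "
                f"area={row['total_area_mm2']:.3f} mm^2, "
                f"fraction={row['predicted_fraction']:.3f}"
            )
        return "\n".join(lines)


def recommend_design(
    alpha: float,
    C: float,
    target_fraction: float,
    max_total_area_mm2: float | None = None,
    max_r: int = 50,
    widths: Sequence[float] | None = None,
    fixed_width: float | None = None,
) -> DesignRecommendation:
    """Enumerate (r, w) designs and pick those meeting the target fraction.

    For every candidate width the minimal integer r is computed by inverting
    the saturation law with τ(w) = C/w^α; candidates violating the area or r
    constraints are dropped.  Returns the minimal-r and minimal-area designs
    among the survivors, or an infeasibility report with the best achievable
    fraction on the constrained grid.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target fraction must lie strictly between 0 and 1")
    if fixed_width is not None:
        widths = [float(fixed_width)]
    elif widths is None:
        widths = np.arange(100.0, 1001.0, 25.0)

    rows = []
    for w in widths:
        tau_w = C / w**alpha
        r_needed = fovs_for_fraction(tau_w, target_fraction)
        rows.append(
            {
                "w": float(w),
                "tau": tau_w,
                "r": r_needed,
                "total_area_mm2": r_needed * w * w / UM2_PER_MM2,
                "predicted_fraction": float(
                    recovery_fraction(alpha, C, r_needed, w)
                ),
            }
        )
    cand = pd.DataFrame(rows)
    ok = pd.Series(True, index=cand.index)
    if max_r is not None:
        ok &= cand["r"] <= max_r
    if max_total_area_mm2 is not None:
        ok &= cand["total_area_mm2"] <= max_total_area_mm2
    cand_ok = cand[ok].reset_index(drop=True)

    if cand_ok.empty:
        # best achievable fraction on the constrained grid
        best = 0.0
        for w in widths:
            r_max_w = max_r if max_r is not None else 10**6
            if max_total_area_mm2 is not None:
                r_area = math.floor(max_total_area_mm2 * UM2_PER_MM2 / (w * w))
                r_max_w = min(r_max_w, r_area)
            if r_max_w >= 1:
                best = max(best, float(recovery_fraction(alpha, C, r_max_w, w)))
        return DesignRecommendation(
            target_fraction=target_fraction,
            feasible=False,
            candidates=cand_ok,
            best_achievable_fraction=best,
        )

    by_r = cand_ok.sort_values(["r", "total_area_mm2"]).iloc[0]
    by_area = cand_ok.sort_values(["total_area_mm2", "r"]).iloc[0]
    return DesignRecommendation(
        target_fraction=target_fraction,
        feasible=True,
        candidates=cand_ok,
        minimal_r=by_r,
        minimal_area=by_area,
    )
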