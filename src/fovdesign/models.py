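"""Models of cell-phenotype recovery and tissue spatial segregation.

Four empirical laws are fitted, each as a small Model class whose ``fit()``
returns a Results object (parameters, fit quality, diagnostics, summary):

* :class:`SaturationModel` — N(r) = N_O (1 − exp(−r/τ)): mean number of
  phenotypes recovered with r FoVs.  τ is the characteristic number of FoVs;
  imaging 2τ FoVs recovers 1 − e⁻² ≈ 86% of the observable phenotypes.
* :class:`PowerLawModel` — τ(w) = C/w^α (width law, exponent α measures
  spatial segregation: 2 = random mixing, below 2 = patchy tissue) and
  τ(p) = A/p^β (abundance law).  Both are ordinary least squares on log10
  scales, as is conventional for power laws.
* :class:`KLDecayModel` — KL(r) = KL_O exp(−(r−1)/θ) + KL_b: decay of the
  divergence between sampled and full-tissue phenotype proportions.
* :class:`ShrinkageAlphaModel` — the single-FoV α estimator: progressively
  shrink one field of view and regress log(recovered clusters) on
  log(effective width); in the sparse-recovery regime (N(1) ≪ N_O) the slope
  estimates α.

Nonlinear fits use Gauss–Newton-class least squares (Levenberg–Marquardt)
with fixed conventional start values; R² is always the squared Pearson
correlation between observed and fitted values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .data import SpatialDataset
from .sampling import RecoveryCurve, recovery_curve, sample_counts

logger = logging.getLogger(__name__)

__all__ = [
    "SaturationModel",
    "SaturationFit",
    "PowerLawModel",
    "PowerLawFit",
    "KLDecayModel",
    "KLFit",
    "ShrinkageAlphaModel",
    "SegregationEstimate",
    "WidthScan",
    "fit_saturation",
    "predict_recovery",
    "fit_tau_vs_width",
    "fit_tau_vs_abundance",
    "fit_kl_model",
    "fit_per_phenotype_tau",
    "fit_alpha_across_widths",
    "alpha_threshold_scan",
    "estimate_alpha_by_shrinkage",
    "transfer_ratio",
    "multinomial_deviance",
]


def _pearson_r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Squared Pearson correlation of observed vs fitted values."""
    if observed.size < 2 or np.std(observed) == 0 or np.std(fitted) == 0:
        return 0.0
    r = np.corrcoef(observed, fitted)[0, 1]
    return float(np.clip(r * r, 0.0, 1.0))


# --------------------------------------------------------------------------
# Saturation model
# --------------------------------------------------------------------------


def _saturation(r, n_o, tau):
    return n_o * (1.0 - np.exp(-r / tau))


@dataclass
class SaturationFit:
    """Results of a saturation-curve fit."""

    n_observable: float
    tau: float
    r_squared: float
    converged: bool
    used_fallback: bool
    start_values: tuple[float, float]
    r: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)

    def predict(self, r) -> np.ndarray | float:
        """Expected recovered count N(r) = N_O (1 − exp(−r/τ)); r ≥ 0."""
        r_arr = np.asarray(r, dtype=float)
        if np.any(r_arr < 0):
            raise ValueError("r must be >= 0")
        out = _saturation(r_arr, self.n_observable, self.tau)
        return float(out) if np.isscalar(r) or r_arr.ndim == 0 else out

    @property
    def params(self) -> pd.Series:
        return pd.Series({"N_O": self.n_observable, "tau": self.tau})

    def summary(self) -> str:
        lines = [
            "Saturation model  N(r) = N_O (1 - exp(-r/tau))",
            f"  N_O  {self.n_observable:12.4f}",
            f"  tau  {self.tau:12.4f}   (2*tau FoVs recover {100*(1-np.exp(-2)):.0f}% of N_O)",
            f"  R^2  {self.r_squared:12.4f}",
            f"  converged: {self.converged}   fallback used: {self.used_fallback}",
            f"  n obs: {self.r.size}   start values: {self.start_values}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.r, self.observed, "o", label="observed", **kwargs)
        dense = np.linspace(0, self.r.max(), 200)
        ax.plot(dense, self.predict(dense), "r--", label="fit")
        ax.set_xlabel("number of FoVs r")
        ax.set_ylabel("recovered phenotypes")
        ax.legend()
        return ax


class SaturationModel:
    """Nonlinear least-squares model of phenotype recovery saturation."""

    def __init__(self, r: Sequence[float], n_recovered: Sequence[float]):
        self.r = np.asarray(r, dtype=float)
        self.n_recovered = np.asarray(n_recovered, dtype=float)
        if self.r.size != self.n_recovered.size:
            raise ValueError("r and n_recovered must have equal length")
        if np.unique(self.r).size < 3:
            raise ValueError("need at least 3 distinct r values")
        if np.allclose(self.n_recovered, self.n_recovered[0]):
            raise ValueError("recovery values are all equal; saturation is undefined")

    @classmethod
    def from_curve(cls, curve: RecoveryCurve) -> "SaturationModel":
        return cls(curve.r_values, curve.mean_recovered)

    def _moment_start(self) -> tuple[float, float]:
        """Data-driven start: asymptote from the curve top, τ from the first point."""
        n0 = float(self.n_recovered.max())
        y1 = float(self.n_recovered[np.argmin(self.r)])
        if n0 > 0 and 0 < y1 < n0:
            tau0 = -float(self.r.min()) / np.log1p(-y1 / n0)
        else:
            tau0 = float(self.r.max()) / 3.0
        tau0 = float(np.clip(tau0, 0.1, 10.0 * self.r.max()))
        return max(n0, 1e-6), tau0

    def fit(self, start_n: float = 20.0, start_tau: float = 5.0) -> SaturationFit:
        params, converged, fallback = _nls_fit(
            _saturation, self.r, self.n_recovered, p0=(start_n, start_tau),
            bounds=((1e-12, 1e-12), (np.inf, np.inf)),
            extra_starts=(self._moment_start(),),
        )
        n_o, tau = params
        fitted = _saturation(self.r, n_o, tau)
        return SaturationFit(
            n_observable=float(n_o),
            tau=float(tau),
            r_squared=_pearson_r2(self.n_recovered, fitted),
            converged=converged,
            used_fallback=fallback,
            start_values=(start_n, start_tau),
            r=self.r,
            observed=self.n_recovered,
        )


def _nls_fit(func, x, y, p0, bounds, extra_starts=()):
    """Multi-start Gauss–Newton least squares.

    Levenberg–Marquardt from the conventional start ``p0`` and from each of
    ``extra_starts`` (data-driven moment initialisers); the lowest-SSE valid
    solution wins, which guards against the step-function local minimum that
    a fixed start can land in when the true scale is far from it.  A
    positivity-bounded TRF fallback triggers only when every unbounded
    attempt diverges.
    """
    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for start in (p0, *extra_starts):
            try:
                params, _ = curve_fit(func, x, y, p0=start, method="lm", maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            if np.all(np.isfinite(params)) and np.all(np.asarray(params) > 0):
                sse = float(np.sum((func(np.asarray(x, float), *params) - y) ** 2))
                candidates.append((sse, params))
        if candidates:
            candidates.sort(key=lambda c: c[0])
            return candidates[0][1], True, False
        logger.info("unbounded fit diverged; retrying with positivity bounds")
        try:
            params, _ = curve_fit(
                func, x, y, p0=np.maximum(p0, 1e-6), bounds=bounds,
                method="trf", maxfev=20000,
            )
            return params, True, True
        except (RuntimeError, ValueError):
            return np.asarray(p0, dtype=float), False, True


# --------------------------------------------------------------------------
# Power-law models (log10-log10 OLS)
# --------------------------------------------------------------------------


@dataclass
class PowerLawFit:
    """Results of a log10–log10 power-law regression y = coef / x^exponent."""

    exponent: float
    log10_coefficient: float
    r_squared: float
    xname: str
    yname: str
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def slope(self) -> float:
        """Slope of the log10 regression (−exponent)."""
        return -self.exponent

    @property
    def coefficient(self) -> float:
        return float(10.0**self.log10_coefficient)

    def predict(self, x) -> np.ndarray | float:
        x_arr = np.asarray(x, dtype=float)
        out = 10.0 ** (self.log10_coefficient + self.slope * np.log10(x_arr))
        return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out

    def summary(self) -> str:
        return "\n".join(
            [
                f"Power law  {self.yname}({self.xname}) = "
                f"{self.coefficient:.4g} / {self.xname}^{self.exponent:.4f}",
                f"  exponent      {self.exponent:12.4f}",
                f"  log10(coef)   {self.log10_coefficient:12.4f}",
                f"  R^2           {self.r_squared:12.4f}",
                f"  n obs: {self.x.size}",
            ]
        )


class PowerLawModel:
    """OLS on log10-transformed data for τ–width and τ–abundance laws."""

    def __init__(self, x: Sequence[float], y: Sequence[float],
                 xname: str = "x", yname: str = "y"):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.size != self.y.size:
            raise ValueError("x and y must have equal length")
        if self.x.size < 3:
            raise ValueError("need at least 3 observations")
        if np.any(self.x <= 0) or np.any(self.y <= 0):
            raise ValueError("power-law regression requires strictly positive data")
        self.xname = xname
        self.yname = yname

    def fit(self) -> PowerLawFit:
        lx = np.log10(self.x)
        ly = np.log10(self.y)
        res = sm.OLS(ly, sm.add_constant(lx)).fit()
        intercept, slope = res.params
        return PowerLawFit(
            exponent=float(-slope),
            log10_coefficient=float(intercept),
            r_squared=float(res.rsquared),
            xname=self.xname,
            yname=self.yname,
            x=self.x,
            y=self.y,
        )


# --------------------------------------------------------------------------
# KL decay model
# --------------------------------------------------------------------------


def _kl_decay(r, kl_o, kl_b, theta):
    return kl_o * np.exp(-(r - 1.0) / theta) + kl_b


@dataclass
class KLFit:
    """Results of the KL-divergence decay fit."""

    kl_o: float
    kl_b: float
    theta: float
    r_squared: float
    converged: bool
    used_fallback: bool
    r: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)

    def predict(self, r) -> np.ndarray | float:
        r_arr = np.asarray(r, dtype=float)
        out = _kl_decay(r_arr, self.kl_o, self.kl_b, self.theta)
        return float(out) if np.isscalar(r) or r_arr.ndim == 0 else out

    def summary(self) -> str:
        return "\n".join(
            [
                "KL decay  KL(r) = KL_O exp(-(r-1)/theta) + KL_b",
                f"  KL_O   {self.kl_o:12.5f}   (mean KL with one FoV: {self.kl_o + self.kl_b:.5f})",
                f"  KL_b   {self.kl_b:12.5f}   (baseline divergence)",
                f"  theta  {self.theta:12.4f}",
                f"  R^2    {self.r_squared:12.4f}",
                f"  converged: {self.converged}   fallback used: {self.used_fallback}",
            ]
        )


class KLDecayModel:
    """Exponential-decay model of proportion-recovery KL divergence."""

    def __init__(self, r: Sequence[float], kl: Sequence[float]):
        self.r = np.asarray(r, dtype=float)
        self.kl = np.asarray(kl, dtype=float)
        if self.r.size != self.kl.size:
            raise ValueError("r and kl must have equal length")
        if np.unique(self.r).size < 4:
            raise ValueError("need at least 4 distinct r values")

    @classmethod
    def from_curve(cls, curve: RecoveryCurve) -> "KLDecayModel":
        if curve.mean_kl is None:
            raise ValueError("curve carries no KL values")
        return cls(curve.r_values, curve.mean_kl)

    def fit(self, start_theta: float = 2.0, start_klo: float = 1.0,
            start_klb: float = 0.01) -> KLFit:
        # data-driven moment start: amplitude and floor from the curve ends
        klo0 = max(float(self.kl.max() - self.kl.min()), 1e-6)
        klb0 = max(float(self.kl.min()), 1e-6)
        theta0 = max(float(self.r.max() - self.r.min()) / 3.0, 0.5)
        params, converged, fallback = _nls_fit(
            _kl_decay, self.r, self.kl, p0=(start_klo, start_klb, start_theta),
            bounds=((0.0, 0.0, 1e-12), (np.inf, np.inf, np.inf)),
            extra_starts=((klo0, klb0, theta0),),
        )
        kl_o, kl_b, theta = params
        fitted = _kl_decay(self.r, kl_o, kl_b, theta)
        return KLFit(
            kl_o=float(kl_o), kl_b=float(kl_b), theta=float(theta),
            r_squared=_pearson_r2(self.kl, fitted),
            converged=converged, used_fallback=fallback,
            r=self.r, observed=self.kl,
        )


# --------------------------------------------------------------------------
# Single-FoV shrinkage estimator of alpha
# --------------------------------------------------------------------------

DEFAULT_SHRINK_FACTORS = (1.1, 1.2, 1.5, 1.8, 2.2, 2.5, 3.0)


@dataclass
class SegregationEstimate:
    """Segregation exponent from single-FoV shrinkage."""

    alpha: float
    r_squared: float
    passed_quality: bool
    shrink_factors: tuple[float, ...]
    effective_widths: np.ndarray = field(repr=False)
    recovered_counts: np.ndarray = field(repr=False)

    def summary(self) -> str:
        return "\n".join(
            [
                "Shrinkage estimate  log N(1) ~ alpha log(w) + const",
                f"  alpha  {self.alpha:10.4f}",
                f"  R^2    {self.r_squared:10.4f}   quality (R^2 >= 0.9): {self.passed_quality}",
                f"  widths used: {np.round(self.effective_widths, 1).tolist()}",
                f"  recovered:   {self.recovered_counts.tolist()}",
            ]
        )


class ShrinkageAlphaModel:
    """Estimate α from one field of view by progressive shrinkage.

    The FoV (the dataset's bounds) is shrunk about its center by each factor
    f, the phenotypes recovered inside the reduced window are counted, and
    log(count) is regressed on log(effective width).  Combining the
    saturation and width laws for a single FoV gives
    log N(1) ≈ α log w + const when N(1) ≪ N_O, so the slope estimates α.
    Factors yielding zero recovered phenotypes are dropped; estimates with
    regression R² < 0.9 carry ``passed_quality=False`` and should be
    excluded from cohort aggregation.
    """

    def __init__(
        self,
        ds: SpatialDataset,
        shrink_factors: Sequence[float] = DEFAULT_SHRINK_FACTORS,
        T: int = 20,
        strict: bool = True,
    ):
        if ds.n_points == 0:
            raise ValueError("dataset is empty")
        self.ds = ds
        self.shrink_factors = tuple(float(f) for f in shrink_factors)
        if any(f < 1 for f in self.shrink_factors):
            raise ValueError("shrink factors must be >= 1")
        self.T = int(T)
        self.strict = strict

    def _recovered_in_window(self, factor: float) -> tuple[float, int]:
        xmin, ymin, xmax, ymax = self.ds.bounds
        cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
        hw = (xmax - xmin) / (2.0 * factor)
        hh = (ymax - ymin) / (2.0 * factor)
        inside = (
            (self.ds.x >= cx - hw) & (self.ds.x < cx + hw)
            & (self.ds.y >= cy - hh) & (self.ds.y < cy + hh)
        )
        codes, uniq = self.ds.label_codes()
        counts = np.bincount(codes[inside], minlength=uniq.size)
        hit = counts > self.T if self.strict else counts >= self.T
        eff_width = float(np.sqrt((2 * hw) * (2 * hh)))  # geometric mean side
        return eff_width, int(hit.sum())

    def fit(self) -> SegregationEstimate:
        widths, counts = [], []
        for f in self.shrink_factors:
            w_eff, n_rec = self._recovered_in_window(f)
            if n_rec > 0:
                widths.append(w_eff)
                counts.append(n_rec)
        if not counts:
            raise ValueError(
                "all shrink factors recovered zero phenotypes; alpha is not estimable"
            )
        if len(counts) < 4:
            raise ValueError(
                f"only {len(counts)} shrink factors recovered any phenotype; "
                "need at least 4 for the regression"
            )
        widths_arr = np.asarray(widths)
        counts_arr = np.asarray(counts)
        res = sm.OLS(np.log(counts_arr), sm.add_constant(np.log(widths_arr))).fit()
        slope = float(res.params[1])
        r2 = float(res.rsquared)
        return SegregationEstimate(
            alpha=slope,
            r_squared=r2,
            passed_quality=r2 >= 0.9,
            shrink_factors=self.shrink_factors,
            effective_widths=widths_arr,
            recovered_counts=counts_arr,
        )


# --------------------------------------------------------------------------
# Spec-level convenience wrappers and end-to-end helpers
# --------------------------------------------------------------------------


def fit_saturation(curve: RecoveryCurve, start_n: float = 20.0,
                   start_tau: float = 5.0) -> SaturationFit:
    """Fit N(r) = N_O (1 − exp(−r/τ)) to a recovery curve."""
    return SaturationModel.from_curve(curve).fit(start_n=start_n, start_tau=start_tau)


def predict_recovery(fit: SaturationFit, r) -> np.ndarray | float:
    """Expected recovered count at r FoVs under a fitted saturation model."""
    return fit.predict(r)


def fit_tau_vs_width(taus: Sequence[float], widths: Sequence[float]) -> PowerLawFit:
    """Fit τ(w) = C/w^α by log10–log10 OLS; the exponent is α."""
    return PowerLawModel(widths, taus, xname="w", yname="tau").fit()


def fit_tau_vs_abundance(taus: Sequence[float],
                         proportions: Sequence[float]) -> PowerLawFit:
    """Fit τ(p) = A/p^β; phenotypes with zero abundance are excluded."""
    taus = np.asarray(taus, dtype=float)
    p = np.asarray(proportions, dtype=float)
    if np.any(p > 1):
        raise ValueError("proportions must lie in (0, 1]")
    keep = p > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} phenotype(s) with zero abundance",
            stacklevel=2,
        )
    return PowerLawModel(p[keep], taus[keep], xname="p", yname="tau").fit()


def fit_kl_model(curve: RecoveryCurve | tuple, start_theta: float = 2.0,
                 start_klo: float = 1.0, start_klb: float = 0.01) -> KLFit:
    """Fit KL(r) = KL_O exp(−(r−1)/θ) + KL_b to a mean-KL curve."""
    if isinstance(curve, RecoveryCurve):
        model = KLDecayModel.from_curve(curve)
    else:
        r, kl = curve
        model = KLDecayModel(r, kl)
    return model.fit(start_theta=start_theta, start_klo=start_klo, start_klb=start_klb)


def fit_per_phenotype_tau(recovery_prob: pd.DataFrame,
                          start_tau: float = 2.0) -> pd.Series:
    """Per-phenotype τ from individual recovery probabilities.

    Fits the single-phenotype saturation law p(r) = 1 − exp(−r/τ) (the
    saturation model with N_O fixed to one) to each row of the probability
    table produced by :func:`fovdesign.sampling.per_phenotype_recovery`.
    Phenotypes never recovered (all-zero rows) yield NaN.
    """
    r = recovery_prob.columns.to_numpy(dtype=float)
    out = {}
    for label, row in recovery_prob.iterrows():
        y = row.to_numpy(dtype=float)
        if np.all(y == 0):
            out[label] = np.nan
            continue
        params, converged, _ = _nls_fit(
            lambda rr, tau: 1.0 - np.exp(-rr / tau), r, y, p0=(start_tau,),
            bounds=((1e-12,), (np.inf,)),
        )
        out[label] = float(params[0]) if converged else np.nan
    return pd.Series(out, name="tau")


def transfer_ratio(fit: PowerLawFit, taus: Sequence[float],
                   proportions: Sequence[float]) -> float:
    """Mean observed/predicted τ ratio when transferring an abundance fit.

    Applies a τ(p) power law fitted on one tissue to the phenotype
    abundances of another and reports mean(observed τ / predicted τ); values
    far from 1 mean composition alone does not transfer across tissues.
    """
    taus = np.asarray(taus, dtype=float)
    p = np.asarray(proportions, dtype=float)
    pred = fit.predict(p)
    return float(np.mean(taus / pred))


@dataclass
class WidthScan:
    """Per-width saturation fits and the resulting width power law."""

    widths: np.ndarray
    curves: dict
    saturation_fits: dict
    power_law: PowerLawFit

    @property
    def alpha(self) -> float:
        return self.power_law.exponent

    @property
    def taus(self) -> pd.Series:
        return pd.Series(
            {w: self.saturation_fits[w].tau for w in self.widths}, name="tau"
        )

    def summary(self) -> str:
        lines = ["Width scan"]
        for w in self.widths:
            f = self.saturation_fits[w]
            lines.append(f"  w={w:6.0f} um  tau={f.tau:8.3f}  R^2={f.r_squared:.4f}")
        lines.append(f"  alpha = {self.alpha:.4f}  (log10 C = "
                     f"{self.power_law.log10_coefficient:.4f}, "
                     f"R^2 = {self.power_law.r_squared:.4f})")
        return "\n".join(lines)


def fit_alpha_across_widths(
    ds: SpatialDataset,
    widths: Sequence[float],
    r_values: Sequence[int] | dict,
    T: int,
    reps: int = 50,
    seed=0,
    strict: bool = True,
) -> WidthScan:
    """End-to-end α: recovery curves per width → saturation fits → width law.

    ``r_values`` is either one grid of FoV numbers shared by all widths or a
    mapping ``{width: r_values}``; per-width grids let wide FoVs stop at the
    packing density their width allows while narrow FoVs extend far enough
    to resolve their larger τ.
    """
    widths = np.asarray(sorted(float(w) for w in widths))
    curves, fits = {}, {}
    children = np.random.SeedSequence(seed).spawn(widths.size)
    for w, child in zip(widths, children):
        rv = r_values[w] if isinstance(r_values, dict) else r_values
        curve = recovery_curve(ds, rv, w, T, reps=reps,
                               seed=int(child.generate_state(1)[0]), strict=strict)
        curves[w] = curve
        fits[w] = fit_saturation(curve)
    power = fit_tau_vs_width([fits[w].tau for w in widths], widths)
    return WidthScan(widths=widths, curves=curves, saturation_fits=fits,
                     power_law=power)


def alpha_threshold_scan(
    ds: SpatialDataset,
    widths: Sequence[float],
    r_values: Sequence[int],
    T_values: Sequence[int],
    reps: int = 50,
    seed=0,
    strict: bool = True,
) -> pd.Series:
    """Fitted α per recovery threshold, on shared sampling draws.

    The FoV draws and per-label counts are computed once per width and every
    threshold is applied to the same counts (recovery is a pure function of
    the counts), so differences between thresholds reflect the threshold
    alone rather than fresh sampling noise.
    """
    widths = np.asarray(sorted(float(w) for w in widths))
    r_values = [int(r) for r in r_values]
    children = np.random.SeedSequence(seed).spawn(widths.size)
    counts = {
        w: sample_counts(ds, r_values, w, reps=reps,
                         seed=int(child.generate_state(1)[0]))
        for w, child in zip(widths, children)
    }
    alphas = {}
    for T in T_values:
        taus = []
        for w in widths:
            means = [
                ((counts[w][r] > T) if strict else (counts[w][r] >= T))
                .sum(axis=1).mean()
                for r in r_values
            ]
            fit = SaturationModel(np.asarray(r_values, dtype=float),
                                  np.asarray(means)).fit()
            taus.append(fit.tau)
        alphas[int(T)] = fit_tau_vs_width(taus, widths).exponent
    return pd.Series(alphas, name="alpha")


def estimate_alpha_by_shrinkage(
    ds: SpatialDataset,
    shrink_factors: Sequence[float] = DEFAULT_SHRINK_FACTORS,
    T: int = 20,
    strict: bool = True,
) -> SegregationEstimate:
    """Single-FoV shrinkage estimate of α (see :class:`ShrinkageAlphaModel`)."""
    return ShrinkageAlphaModel(ds, shrink_factors=shrink_factors, T=T,
                               strict=strict).fit()


def multinomial_deviance(x: Sequence[float]) -> float:
    """Gene-selection deviance D(x) = Σ xᵢ ln(xᵢ) + n ln(n), n = Σ xᵢ.

    Computed exactly as conventionally printed for this selection step, with
    0·ln 0 := 0 and D(all-zero) := 0.  Note this omits the expected-count
    terms of a textbook multinomial deviance; it is a ranking score for
    picking high-information genes, not a calibrated statistic.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("x must be non-negative integer counts")
    n = x.sum()
    if n == 0:
        return 0.0
    pos = x > 0
    return float(np.sum(x[pos] * np.log(x[pos])) + n * np.log(n))
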