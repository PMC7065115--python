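"""Fetal-fraction distributions conditional on maternal BMI and fetal ploidy.

The model has three fitted ingredients:

1. a pooled beta fit to euploid FF, whose concentration ``nu = alpha + beta``
   is taken as BMI-invariant (the distribution shape is roughly conserved
   across BMI classes; only the location moves);
2. ordinary least-squares linear fits of FF on BMI, per ploidy, which move
   the beta mean: at BMI ``x`` the euploid FF law is
   ``Beta(mu*nu, (1-mu)*nu)`` with ``mu = m_eu * x + b_eu``;
3. a percentile-shift density ``g`` per trisomy: each aneuploid sample's FF
   is ranked within the euploid distribution for its own BMI
   (``u = F_eu(ff | bmi)``), and a beta law on [0, 1] is fitted to the
   ranks.  Uniform ``g`` means the trisomy's FF behaves like euploid FF;
   mass at low ``u`` (T13, T18) means systematically lower FF, mass at high
   ``u`` (T21) higher FF.

The conditional FF law of a trisomy at BMI ``x`` is then the euploid beta
reweighted by ``g`` in rank space, discretized on a fixed FF grid in 0.1%
steps and renormalized over the requested FF window.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .cohort import PatientRecord, TRISOMIES, ff_mean

__all__ = [
    "BMI_CLASSES",
    "BetaParams",
    "LinearFit",
    "PercentileDensity",
    "FFGrid",
    "ConditionalFFModel",
    "bmi_from_height_weight",
    "classify_bmi",
    "method_of_moments_beta",
    "fit_beta",
    "fit_linear_ff_bmi",
    "euploid_beta_at_bmi",
    "compute_percentile_shift",
    "conditional_ff_pdf",
]

# Half-open BMI class intervals [lo, hi); a BMI of exactly 25 is overweight.
BMI_CLASSES: tuple[tuple[str, float, float], ...] = (
    ("normal", 0.0, 25.0),
    ("overweight", 25.0, 30.0),
    ("obese_I", 30.0, 35.0),
    ("obese_II", 35.0, 40.0),
    ("obese_III", 40.0, float("inf")),
)


def classify_bmi(bmi: float) -> str:
    # snap binary-float artifacts (64.0 / 1.60**2 = 24.999...96) onto the
    # class boundaries before comparing
    bmi = round(bmi, 9)
    for label, lo, hi in BMI_CLASSES:
        if lo <= bmi < hi:
            return label
    raise ValueError(f"BMI {bmi} not classifiable")


def bmi_from_height_weight(height: float, weight: float) -> float:
    """BMI in kg/m^2 from height (m) and weight (kg).

    Out-of-range inputs raise, flagging a suspected unit mix-up (heights in
    cm or weights in lb are the common ones).
    """
    if not 1.0 < height < 2.5:
        raise ValueError(f"height {height} m outside (1.0, 2.5); height in cm?")
    if not 30.0 < weight < 350.0:
        raise ValueError(f"weight {weight} kg outside (30, 350); weight in lb?")
    return weight / height**2


@dataclass(frozen=True)
class BetaParams:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("non-finite beta parameters")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def concentration(self) -> float:
        return self.alpha + self.beta


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of FF (fraction) on BMI for one ploidy class."""

    slope: float
    intercept: float
    ploidy: str
    slope_se: float = float("nan")
    intercept_se: float = float("nan")
    n: int = 0


@dataclass(frozen=True)
class PercentileDensity:
    """Density of aneuploid FF ranks within the BMI-matched euploid law."""

    ploidy: str
    grid: np.ndarray
    density: np.ndarray
    params: BetaParams

    def __post_init__(self) -> None:
        g = np.asarray(self.density, float)
        if (g < 0).any():
            raise ValueError("negative percentile density")
        area = np.trapezoid(g, self.grid)
        if abs(area - 1.0) > 1e-6:
            raise ValueError(f"percentile density integrates to {area}, not 1")

    @property
    def mean_rank(self) -> float:
        return self.params.mean


@dataclass(frozen=True)
class FFGrid:
    """Inclusive FF grid in steps of 0.001 (0.1% FF)."""

    start: float = 0.0
    stop: float = 0.40
    step: float = 0.001

    def points(self, lo: float | None = None, hi: float | None = None) -> np.ndarray:
        lo = self.start if lo is None else lo
        hi = self.stop if hi is None else hi
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"empty or invalid FF window [{lo}, {hi}]")
        n = int(round((hi - lo) / self.step))
        return np.round(lo + self.step * np.arange(n + 1), 9)


def method_of_moments_beta(values: np.ndarray) -> BetaParams:
    """Closed-form beta moments estimate, population (ddof=0) variance."""
    values = np.asarray(values, float)
    m = values.mean()
    s2 = values.var()
    if s2 <= 0 or s2 >= m * (1 - m):
        return BetaParams(1.0, 1.0)
    c = m * (1 - m) / s2 - 1.0
    return BetaParams(m * c, (1 - m) * c)


def fit_beta(ff_values) -> BetaParams:
    """Maximum-likelihood beta fit, started from the moments estimate.

    Values at exactly 0 or 1 are clipped into (0, 1) with a warning; fewer
    than 10 values is an error.
    """
    values = np.asarray(list(ff_values), dtype=float)
    if len(values) < 10:
        raise ValueError(f"need >= 10 values to fit a beta, got {len(values)}")
    if ((values < 0) | (values > 1)).any():
        raise ValueError("values outside [0, 1]")
    if ((values == 0) | (values == 1)).any():
        warnings.warn("values at 0/1 clipped into (0, 1) for beta fitting", stacklevel=2)
        values = np.clip(values, 1e-6, 1 - 1e-6)
    start = method_of_moments_beta(values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a, b, _, _ = stats.beta.fit(values, start.alpha, start.beta, floc=0, fscale=1)
    return BetaParams(float(a), float(b))


def fit_linear_ff_bmi(records: list[PatientRecord], ploidy: str) -> LinearFit:
    """OLS of FF on BMI over the records of one ploidy class."""
    sub = [r for r in records if r.ploidy == ploidy]
    bmi = np.array([r.bmi for r in sub])
    if len(sub) < 2 or np.unique(bmi).size < 2:
        raise ValueError(f"too few records with distinct BMI to fit ploidy {ploidy!r}")
    ff = np.array([r.ff for r in sub])
    res = stats.linregress(bmi, ff)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ploidy=ploidy,
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        n=len(sub),
    )


@dataclass
class ConditionalFFModel:
    """Machinery producing p(FF | BMI, ploidy) on the discrete FF grid."""

    euploid_fit: LinearFit
    ploidy_fits: dict[str, LinearFit]
    pooled_beta: BetaParams
    percentile_densities: dict[str, PercentileDensity] = field(default_factory=dict)
    grid: FFGrid = field(default_factory=FFGrid)
    provenance: dict = field(default_factory=dict)

    @classmethod
    def fit(
        cls,
        records: list[PatientRecord],
        grid: FFGrid | None = None,
        min_aneuploid: int = 20,
        provenance: dict | None = None,
    ) -> "ConditionalFFModel":
        """Fit all ingredients from a cohort.

        Trisomies with fewer than ``min_aneuploid`` records are left without
        a percentile density (their conditional pdf cannot be requested).
        """
        euploid_fit = fit_linear_ff_bmi(records, "euploid")
        pooled = fit_beta([r.ff for r in records if r.ploidy == "euploid"])
        ploidy_fits = {}
        for t in TRISOMIES:
            try:
                ploidy_fits[t] = fit_linear_ff_bmi(records, t)
            except ValueError:
                pass
        model = cls(
            euploid_fit=euploid_fit,
            ploidy_fits=ploidy_fits,
            pooled_beta=pooled,
            grid=grid or FFGrid(),
            provenance=provenance or {},
        )
        model.percentile_densities = compute_percentile_shift(
            records, model, min_records=min_aneuploid
        )
        return model

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        def fit_dict(f: LinearFit) -> dict:
            return {
                "slope": f.slope, "intercept": f.intercept, "ploidy": f.ploidy,
                "slope_se": f.slope_se, "intercept_se": f.intercept_se, "n": f.n,
            }

        doc = {
            "euploid_fit": fit_dict(self.euploid_fit),
            "ploidy_fits": {k: fit_dict(v) for k, v in self.ploidy_fits.items()},
            "pooled_beta": {"alpha": self.pooled_beta.alpha, "beta": self.pooled_beta.beta},
            "percentile_densities": {
                k: {
                    "grid": d.grid.tolist(),
                    "density": d.density.tolist(),
                    "alpha": d.params.alpha,
                    "beta": d.params.beta,
                }
                for k, d in self.percentile_densities.items()
            },
            "grid": {"start": self.grid.start, "stop": self.grid.stop, "step": self.grid.step},
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConditionalFFModel":
        doc = json.loads(Path(path).read_text())

        def fit_obj(d: dict) -> LinearFit:
            return LinearFit(**d)

        return cls(
            euploid_fit=fit_obj(doc["euploid_fit"]),
            ploidy_fits={k: fit_obj(v) for k, v in doc["ploidy_fits"].items()},
            pooled_beta=BetaParams(**doc["pooled_beta"]),
            percentile_densities={
                k: PercentileDensity(
                    ploidy=k,
                    grid=np.array(d["grid"]),
                    density=np.array(d["density"]),
                    params=BetaParams(d["alpha"], d["beta"]),
                )
                for k, d in doc["percentile_densities"].items()
            },
            grid=FFGrid(**doc["grid"]),
            provenance=doc.get("provenance", {}),
        )


def euploid_beta_at_bmi(model: ConditionalFFModel, bmi: float) -> BetaParams:
    """Euploid FF law at a BMI: linear mean, pooled concentration.

    The mean slides along the euploid OLS fit (clipped to a valid beta
    mean); the concentration stays at the pooled euploid fit.
    """
    if model.euploid_fit is None or model.pooled_beta is None:
        raise ValueError("model is not fitted")
    mu = float(ff_mean(bmi, model.euploid_fit.slope, model.euploid_fit.intercept))
    nu = model.pooled_beta.concentration
    return BetaParams(mu * nu, (1.0 - mu) * nu)


def compute_percentile_shift(
    records: list[PatientRecord],
    model: ConditionalFFModel,
    n_grid: int = 101,
    min_records: int = 20,
) -> dict[str, PercentileDensity]:
    """Fit the rank density ``g`` of each trisomy's FF within euploid FF.

    Ranks are pooled across BMI (each sample is ranked against the euploid
    law for its own BMI, which removes the BMI effect before pooling).  A
    beta law is fitted to the ranks — boundary-safe where a histogram or KDE
    would leak mass outside [0, 1] — and tabulated on ``n_grid`` points.
    """
    out: dict[str, PercentileDensity] = {}
    u_grid = np.linspace(0.0, 1.0, n_grid)
    for t in TRISOMIES:
        sub = [r for r in records if r.ploidy == t]
        if len(sub) < min_records:
            continue
        bmi = np.array([r.bmi for r in sub])
        ff = np.array([r.ff for r in sub])
        mu = ff_mean(bmi, model.euploid_fit.slope, model.euploid_fit.intercept)
        nu = model.pooled_beta.concentration
        u = stats.beta.cdf(ff, mu * nu, (1.0 - mu) * nu)
        u = np.clip(u, 1e-6, 1 - 1e-6)
        params = fit_beta(u)
        dens = stats.beta.pdf(np.clip(u_grid, 1e-9, 1 - 1e-9), params.alpha, params.beta)
        dens = np.minimum(dens, 1e12)
        dens = dens / np.trapezoid(dens, u_grid)
        out[t] = PercentileDensity(ploidy=t, grid=u_grid, density=dens, params=params)
    return out


def conditional_ff_pdf(
    model: ConditionalFFModel,
    bmi: float,
    ploidy: str,
    ff_lo: float = 0.0,
    ff_hi: float = 0.40,
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete p(FF | BMI, ploidy) on the FF grid over ``[ff_lo, ff_hi]``.

    Returns ``(grid_points, probabilities)`` with the probabilities summing
    to 1 over the window.  Each grid point carries the probability mass of
    its half-step cell, computed exactly through the rank-space CDF:
    for a trisomy the cell mass is ``G(F(hi)) - G(F(lo))`` where ``F`` is
    the euploid CDF at this BMI and ``G`` the fitted rank-beta CDF (``G`` =
    identity for euploid).  This is the integral of "euploid density times
    g(rank)" over the cell, so no boundary singularity can occur.
    """
    points = model.grid.points(ff_lo, ff_hi)
    eu = euploid_beta_at_bmi(model, bmi)
    half = model.grid.step / 2.0
    edges = np.clip(np.concatenate([points - half, [points[-1] + half]]), 0.0, 1.0)
    f_edges = stats.beta.cdf(edges, eu.alpha, eu.beta)
    if ploidy == "euploid":
        g_edges = f_edges
    else:
        if ploidy not in model.percentile_densities:
            raise ValueError(f"no percentile density fitted for ploidy {ploidy!r}")
        gp = model.percentile_densities[ploidy].params
        g_edges = stats.beta.cdf(f_edges, gp.alpha, gp.beta)
    mass = np.diff(g_edges)
    total = mass.sum()
    if total <= 0:
        raise ValueError(f"no FF probability mass in window [{ff_lo}, {ff_hi}]")
    return points, mass / total
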