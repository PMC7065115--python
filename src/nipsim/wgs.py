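"""Simulation of WGS-based aneuploidy calling and its sensitivity.

Calling model: reads are spread over equally sized bins tiling the autosomal
genome with per-bin expected depth ``lambda = effective_reads / total_bins``.
A trisomic chromosome's bins are elevated to ``lambda * (1 + ff/2)`` (fetal
dosage).  A per-chromosome summary statistic (median bin count by default,
mean as the analytically tractable alternative) is standardized against a
simulated euploid reference panel, and a sample is called positive when the
one-sided z score reaches the cutoff (default 3).

Depth calibration: raw sequencing counts are overdispersed; dividing by a
single scale factor — the index of dispersion of the bin counts — maps them
onto a Poisson regime.  The Poisson simulation is therefore run at
``effective_reads = raw_reads / c``, never at the raw depth.

Implementation note: the per-chromosome statistic is drawn without
materializing bins.  The mean of ``B`` iid Poisson bins is
``Poisson(B * lambda) / B`` exactly, and the median is drawn through the
order-statistic quantile transform (the middle order statistic of ``B``
uniforms is Beta-distributed; pushing it through the Poisson quantile
function reproduces the binned median's distribution exactly, including its
half-integer lattice for even ``B``).  This keeps Monte Carlo sensitivity
curves and large null-rate estimates cheap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BinnedReadCounts
from .genome import TRISOMY_CHROMOSOME, GenomeModel

__all__ = [
    "EffectiveDepthCalibration",
    "ZReference",
    "SensitivityCurve",
    "calibrate_effective_depth",
    "build_z_reference",
    "simulate_sample_z",
    "sensitivity_at_ff",
    "build_sensitivity_curve",
    "false_positive_rate",
]

DEFAULT_EFFECTIVE_READS = 1.0e7
DEFAULT_Z_CUTOFF = 3.0


@dataclass(frozen=True)
class EffectiveDepthCalibration:
    """Single-number scale mapping raw bin counts onto a Poisson regime."""

    scale: float
    raw_reads: float
    effective_reads: float
    gof: float


@dataclass(frozen=True)
class ZReference:
    """Euploid reference moments of the per-chromosome statistic."""

    mu_ref: dict[str, float]
    sigma_ref: dict[str, float]
    statistic: str
    z_cutoff: float = DEFAULT_Z_CUTOFF
    effective_reads: float = DEFAULT_EFFECTIVE_READS
    n_reference: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma_ref.values()):
            raise ValueError("sigma_ref must be positive")
        if self.statistic not in ("median", "mean"):
            raise ValueError("statistic must be 'median' or 'mean'")


@dataclass(frozen=True)
class SensitivityCurve:
    """AS(trisomy, reads, FF) tabulated on the FF grid."""

    trisomy: str
    reads: float
    ff: np.ndarray
    sensitivity: np.ndarray
    mc_se: np.ndarray
    n_reps: int
    seed: int | None = None
    statistic: str = "median"

    def __post_init__(self) -> None:
        s = np.asarray(self.sensitivity, float)
        if ((s < 0) | (s > 1)).any():
            raise ValueError("sensitivity outside [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"ff": self.ff, "sensitivity": self.sensitivity, "mc_se": self.mc_se}).to_csv(
            path, sep="\t", index=False, float_format="%.8g"
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "trisomy": self.trisomy,
                    "reads": self.reads,
                    "ff": self.ff.tolist(),
                    "sensitivity": self.sensitivity.tolist(),
                    "mc_se": self.mc_se.tolist(),
                    "n_reps": self.n_reps,
                    "seed": self.seed,
                    "statistic": self.statistic,
                },
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SensitivityCurve":
        doc = json.loads(Path(path).read_text())
        for k in ("ff", "sensitivity", "mc_se"):
            doc[k] = np.array(doc[k])
        return cls(**doc)


def calibrate_effective_depth(
    counts: list[BinnedReadCounts],
    genome: GenomeModel | None = None,
    raw_reads: float | None = None,
) -> EffectiveDepthCalibration:
    """Estimate the Poisson scale factor from pooled bin counts.

    The scale is the index of dispersion (variance/mean) of the pooled
    counts, floored at 1; ``effective_reads = raw_reads / scale``.  When
    ``raw_reads`` is not given it is inferred from the mean bin count and
    the genome bin total.  The goodness-of-fit statistic is the total
    variation distance between the histogram of rescaled counts and the
    matched Poisson law (0 = perfect fit).
    """
    genome = genome or GenomeModel()
    pooled = np.concatenate([np.asarray(c.counts, float) for c in counts])
    if pooled.size < 1000:
        raise ValueError(f"need >= 1000 pooled bins, got {pooled.size}")
    mean = pooled.mean()
    if mean <= 0:
        raise ValueError("zero mean bin count")
    scale = max(1.0, pooled.var(ddof=1) / mean)
    if raw_reads is None:
        raw_reads = mean * genome.total_bins

    rescaled = np.round(pooled / scale).astype(int)
    lam = mean / scale
    lo, hi = int(stats.poisson.ppf(1e-6, lam)), int(stats.poisson.ppf(1 - 1e-6, lam))
    support = np.arange(lo, hi + 1)
    observed = np.bincount(np.clip(rescaled - lo, 0, hi - lo), minlength=hi - lo + 1)
    # total variation distance between the rescaled histogram and the
    # matched Poisson pmf: 0 = perfect fit, 1 = disjoint
    gof = float(
        0.5 * np.abs(observed / rescaled.size - stats.poisson.pmf(support, lam)).sum()
        + 0.5 * stats.poisson.sf(hi, lam)
        + 0.5 * stats.poisson.cdf(lo - 1, lam)
    )
    return EffectiveDepthCalibration(
        scale=float(scale), raw_reads=float(raw_reads), effective_reads=float(raw_reads / scale), gof=gof
    )


def _sample_statistic(
    rng: np.random.Generator, lam: float, n_bins: int, size: int, statistic: str
) -> np.ndarray:
    """Draw the per-chromosome statistic of ``n_bins`` iid Poisson bins."""
    if statistic == "mean":
        return rng.poisson(lam * n_bins, size=size) / n_bins
    if statistic == "median":
        if n_bins % 2 == 1:
            k = (n_bins + 1) // 2
            u = rng.beta(k, k, size=size)
            return stats.poisson.ppf(u, lam)
        k = n_bins // 2
        v = rng.beta(k + 1, k, size=size)  # U_(k+1)
        u = v * rng.random(size) ** (1.0 / k)  # U_(k) | U_(k+1)
        return 0.5 * (stats.poisson.ppf(u, lam) + stats.poisson.ppf(v, lam))
    raise ValueError(f"unknown statistic {statistic!r}")


def build_z_reference(
    genome: GenomeModel,
    effective_reads: float = DEFAULT_EFFECTIVE_READS,
    n_reference: int = 10_000,
    statistic: str = "median",
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    seed: int | None = None,
) -> ZReference:
    """Simulate a euploid reference panel and record statistic moments."""
    if n_reference < 100:
        raise ValueError("n_reference must be >= 100")
    lam = genome.mean_depth(effective_reads)
    if lam < 1:
        warnings.warn(
            f"per-bin depth {lam:.3g} < 1: too shallow for the normal approximation",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    mu, sigma = {}, {}
    for chrom in genome.chromosomes:
        draws = _sample_statistic(rng, lam, genome.n_bins(chrom), n_reference, statistic)
        mu[chrom] = float(draws.mean())
        sigma[chrom] = float(draws.std(ddof=1))
    return ZReference(
        mu_ref=mu,
        sigma_ref=sigma,
        statistic=statistic,
        z_cutoff=z_cutoff,
        effective_reads=effective_reads,
        n_reference=n_reference,
        seed=seed,
    )


def _target_chromosome(trisomy: str) -> str:
    try:
        return TRISOMY_CHROMOSOME[trisomy]
    except KeyError:
        raise ValueError(f"trisomy must be one of {sorted(TRISOMY_CHROMOSOME)}, got {trisomy!r}") from None


def simulate_sample_z(
    genome: GenomeModel,
    ref: ZReference,
    effective_reads: float,
    ff: float,
    trisomy: str,
    seed: int | None = None,
) -> float:
    """Simulate one trisomic sample and return its z score.

    Bins of the target chromosome are drawn at ``lambda * (1 + ff/2)`` and
    summarized by the reference's statistic; ``z = (stat - mu_ref) / sigma_ref``.
    """
    if not 0.0 <= ff <= 0.40:
        raise ValueError(f"ff {ff} outside [0, 0.40]")
    chrom = _target_chromosome(trisomy)
    rng = np.random.default_rng(seed)
    lam = genome.mean_depth(effective_reads) * (1.0 + ff / 2.0)
    bins = rng.poisson(lam, size=genome.n_bins(chrom))
    stat = float(np.median(bins)) if ref.statistic == "median" else float(bins.mean())
    return (stat - ref.mu_ref[chrom]) / ref.sigma_ref[chrom]


def _z_exceedance(
    genome: GenomeModel,
    ref: ZReference,
    effective_reads: float,
    chrom: str,
    dosage: float,
    n_reps: int,
    rng: np.random.Generator,
) -> float:
    lam = genome.mean_depth(effective_reads) * dosage
    draws = _sample_statistic(rng, lam, genome.n_bins(chrom), n_reps, ref.statistic)
    z = (draws - ref.mu_ref[chrom]) / ref.sigma_ref[chrom]
    return float((z >= ref.z_cutoff).mean())


def sensitivity_at_ff(
    genome: GenomeModel,
    ref: ZReference,
    effective_reads: float,
    trisomy: str,
    ff: float,
    n_reps: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte Carlo analytical sensitivity at one FF, with binomial SE."""
    if not 0.0 <= ff <= 0.40:
        raise ValueError(f"ff {ff} outside [0, 0.40]")
    chrom = _target_chromosome(trisomy)
    rng = np.random.default_rng(seed)
    as_ = _z_exceedance(genome, ref, effective_reads, chrom, 1.0 + ff / 2.0, n_reps, rng)
    se = float(np.sqrt(max(as_ * (1 - as_), 1.0 / n_reps) / n_reps))
    return as_, se


def build_sensitivity_curve(
    genome: GenomeModel,
    ref: ZReference,
    effective_reads: float,
    trisomy: str,
    ff_grid: np.ndarray,
    n_reps: int = 2000,
    seed: int | None = None,
) -> SensitivityCurve:
    """Tabulate AS over an FF grid (raw Monte Carlo values, no smoothing)."""
    chrom = _target_chromosome(trisomy)
    ff_grid = np.asarray(ff_grid, float)
    streams = np.random.SeedSequence(seed).spawn(len(ff_grid))
    as_vals = np.empty(len(ff_grid))
    for i, ff in enumerate(ff_grid):
        rng = np.random.default_rng(streams[i])
        as_vals[i] = _z_exceedance(
            genome, ref, effective_reads, chrom, 1.0 + ff / 2.0, n_reps, rng
        )
    se = np.sqrt(np.maximum(as_vals * (1 - as_vals), 1.0 / n_reps) / n_reps)
    return SensitivityCurve(
        trisomy=trisomy,
        reads=effective_reads,
        ff=ff_grid,
        sensitivity=as_vals,
        mc_se=se,
        n_reps=n_reps,
        seed=seed,
    )


def false_positive_rate(
    genome: GenomeModel,
    ref: ZReference,
    effective_reads: float,
    chromosome: str,
    n_reps: int = 200_000,
    seed: int | None = None,
) -> float:
    """Fraction of simulated euploid samples called positive (z >= cutoff)."""
    if chromosome not in genome.chromosomes:
        raise KeyError(f"unknown chromosome label: {chromosome!r}")
    rng = np.random.default_rng(seed)
    return _z_exceedance(genome, ref, effective_reads, chromosome, 1.0, n_reps, rng)
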