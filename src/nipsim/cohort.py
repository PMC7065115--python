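"""Synthetic screening cohorts and binned read-count fixtures.

The study population this generator emulates is a prenatal-screening cohort
in which each pregnancy carries a maternal BMI (drawn from an
ethnicity-dependent mixture), a fetal ploidy call (euploid or one of the
common autosomal trisomies), and a measured cell-free DNA fetal fraction
(FF).  FF is modelled as beta-distributed around a ploidy-specific linear
trend in BMI: mean FF = m * BMI + b, with a common concentration
``nu = alpha + beta`` controlling biological scatter at fixed BMI.

Read-count fixtures emulate shallow WGS depth profiles: per-bin counts with
genome-wide mean ``reads / total_bins``, elevated by the fetal dosage factor
``1 + ff/2`` on a trisomic chromosome (the fetal compartment contributes a
3/2 copy ratio weighted by FF), and overdispersed via a gamma-Poisson
mixture with index of dispersion ``phi``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import TRISOMY_CHROMOSOME, GenomeModel

PLOIDIES = ("euploid", "T13", "T18", "T21")
TRISOMIES = ("T13", "T18", "T21")

ETHNICITY_CODES = ("af", "aj", "co", "ea", "hi", "me", "na", "ne", "sa", "se", "so", "uk")

# FF ~ BMI linear trends per ploidy: (slope per BMI unit, intercept), FF as a
# fraction.  Euploid pregnancies sit lowest in intercept; T18/T21 higher, and
# the trisomy slopes are slightly steeper.
DEFAULT_PLOIDY_FITS: dict[str, tuple[float, float]] = {
    "euploid": (-0.0024, 0.156),
    "T13": (-0.0030, 0.156),
    "T18": (-0.0033, 0.165),
    "T21": (-0.0025, 0.164),
}

# Ethnicity BMI mixture: code -> (mixture weight, lognormal median BMI,
# lognormal sigma).  Weights and locations are qualitative: obesity rates are
# highest for African, Native American and Hispanic patients and lowest for
# East/Southeast Asian patients, with Caucasian/Other the largest stratum.
DEFAULT_BMI_MIXTURE: dict[str, tuple[float, float, float]] = {
    "co": (0.35, 26.0, 0.20),
    "hi": (0.18, 28.0, 0.20),
    "ne": (0.12, 26.0, 0.20),
    "af": (0.08, 29.0, 0.22),
    "ea": (0.06, 22.5, 0.15),
    "sa": (0.05, 24.0, 0.17),
    "uk": (0.05, 26.0, 0.20),
    "se": (0.04, 22.5, 0.16),
    "aj": (0.02, 24.5, 0.18),
    "me": (0.02, 26.5, 0.19),
    "so": (0.02, 26.5, 0.19),
    "na": (0.01, 29.0, 0.22),
}

# Clip for the linear FF mean: FF is a fraction, the linear trend is not.
FF_MEAN_LO = 0.001
FF_MEAN_HI = 0.5

_COHORT_COLUMNS = ["id", "bmi", "ethnicity", "ploidy", "ff"]
_COUNT_COLUMNS = ["sample_id", "chromosome", "bin_index", "count"]


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is invalid."""


@dataclass(frozen=True)
class PatientRecord:
    """One screened pregnancy."""

    id: str
    bmi: float
    ethnicity: str
    ploidy: str
    ff: float

    def __post_init__(self) -> None:
        if not 10.0 < self.bmi < 80.0:
            raise ValueError(f"bmi {self.bmi} outside (10, 80)")
        if not 0.0 < self.ff < 1.0:
            raise ValueError(f"ff {self.ff} outside (0, 1)")
        if self.ploidy not in PLOIDIES:
            raise ValueError(f"unknown ploidy {self.ploidy!r}")


@dataclass(frozen=True)
class BinnedReadCounts:
    """Per-bin read counts of one chromosome of one sample."""

    sample_id: str
    chromosome: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if (counts < 0).any():
            raise ValueError("negative bin counts")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``trisomy_prevalence`` defaults approximate population screening
    prevalences (T13 1/4000, T18 1/1500, T21 1/500); ``beta_concentration``
    is the FF beta concentration ``nu = alpha + beta`` at fixed BMI;
    ``dispersion`` is the variance/mean index of raw bin counts (1 = Poisson).
    """

    n_patients: int
    seed: int
    trisomy_prevalence: dict[str, float] = field(
        default_factory=lambda: {"T13": 1 / 4000, "T18": 1 / 1500, "T21": 1 / 500}
    )
    ploidy_fits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLOIDY_FITS)
    )
    beta_concentration: float = 30.0
    bmi_mixture: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BMI_MIXTURE)
    )
    read_depth: float = 1.8e7
    dispersion: float = 1.8

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        scalars = [self.beta_concentration, self.read_depth, self.dispersion]
        scalars += [p for p in self.trisomy_prevalence.values()]
        for m, b in self.ploidy_fits.values():
            scalars += [m, b]
        for w, med, sig in self.bmi_mixture.values():
            scalars += [w, med, sig]
        if not all(math.isfinite(v) for v in scalars):
            raise ConfigurationError("non-finite value in cohort configuration")
        for ploidy, p in self.trisomy_prevalence.items():
            if ploidy not in TRISOMIES:
                raise ConfigurationError(f"unknown trisomy {ploidy!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence of {ploidy} outside [0, 1]")
        if sum(self.trisomy_prevalence.values()) > 1.0:
            raise ConfigurationError("trisomy prevalences sum to more than 1")
        if self.beta_concentration <= 0:
            raise ConfigurationError("beta_concentration must be > 0")
        if self.dispersion < 1.0:
            raise ConfigurationError("dispersion must be >= 1")
        missing = set(PLOIDIES) - set(self.ploidy_fits)
        if missing:
            raise ConfigurationError(f"ploidy_fits missing {sorted(missing)}")

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        raw = dict(raw)
        if "ploidy_fits" in raw:
            raw["ploidy_fits"] = {k: tuple(v) for k, v in raw["ploidy_fits"].items()}
        if "bmi_mixture" in raw:
            raw["bmi_mixture"] = {k: tuple(v) for k, v in raw["bmi_mixture"].items()}
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Load a config from YAML or JSON (seed is mandatory in the file)."""
        text = Path(path).read_text()
        raw = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if "seed" not in raw:
            raise ConfigurationError("config file must set a seed")
        return cls.from_dict(raw)


def ff_mean(bmi: np.ndarray | float, slope: float, intercept: float) -> np.ndarray:
    """Linear FF mean ``m * BMI + b``, clipped to a valid beta mean."""
    return np.clip(slope * np.asarray(bmi, dtype=float) + intercept, FF_MEAN_LO, FF_MEAN_HI)


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a synthetic cohort of :class:`PatientRecord`.

    BMI comes from the ethnicity-specific lognormal mixture, ploidy from the
    prevalence table, and FF from ``Beta(mu*nu, (1-mu)*nu)`` with
    ``mu = m_ploidy * BMI + b_ploidy``.  Fixed seed gives identical output.
    """
    n = config.n_patients
    if n == 0:
        return []
    rng = np.random.default_rng(config.seed)

    codes = list(config.bmi_mixture)
    weights = np.array([config.bmi_mixture[c][0] for c in codes], dtype=float)
    weights = weights / weights.sum()
    eth_idx = rng.choice(len(codes), size=n, p=weights)
    med = np.array([config.bmi_mixture[c][1] for c in codes])[eth_idx]
    sig = np.array([config.bmi_mixture[c][2] for c in codes])[eth_idx]
    bmi = np.clip(rng.lognormal(np.log(med), sig), 12.0, 75.0)

    p_tri = np.array([config.trisomy_prevalence[t] for t in TRISOMIES])
    probs = np.concatenate([[1.0 - p_tri.sum()], p_tri])
    ploidy_idx = rng.choice(4, size=n, p=probs)
    ploidies = np.array(PLOIDIES)[ploidy_idx]

    nu = config.beta_concentration
    mu = np.empty(n)
    for ploidy in PLOIDIES:
        mask = ploidies == ploidy
        m, b = config.ploidy_fits[ploidy]
        mu[mask] = ff_mean(bmi[mask], m, b)
    ff = rng.beta(mu * nu, (1.0 - mu) * nu)
    ff = np.clip(ff, 1e-6, 1.0 - 1e-6)

    width = max(6, len(str(n)))
    return [
        PatientRecord(
            id=f"P{i:0{width}d}",
            bmi=float(bmi[i]),
            ethnicity=codes[eth_idx[i]],
            ploidy=str(ploidies[i]),
            ff=float(ff[i]),
        )
        for i in range(n)
    ]


def generate_bin_counts(
    genome: GenomeModel,
    reads: float,
    ff: float,
    ploidy: str,
    dispersion: float = 1.0,
    seed: int | None = None,
) -> list[BinnedReadCounts]:
    """Simulate per-bin counts for the individually modelled chromosomes.

    Per-bin mean is ``reads / total_bins`` genome-wide; the trisomic
    chromosome is elevated by ``1 + ff/2``.  For ``dispersion > 1`` counts
    are gamma-Poisson (negative binomial) with variance ``dispersion * mean``.
    """
    if reads <= 0:
        raise ValueError("reads must be positive")
    if dispersion < 1.0:
        raise ValueError("dispersion must be >= 1")
    if ploidy not in PLOIDIES:
        raise ValueError(f"unknown ploidy {ploidy!r}")
    target = TRISOMY_CHROMOSOME.get(ploidy)
    if target is not None and target not in genome.chromosomes:
        raise KeyError(f"unknown chromosome label: {target!r}")
    rng = np.random.default_rng(seed)
    lam = genome.mean_depth(reads)
    out = []
    for chrom in genome.chromosomes:
        n_bins = genome.n_bins(chrom)
        mean = lam * (1.0 + ff / 2.0) if chrom == target else lam
        if dispersion > 1.0:
            shape = mean / (dispersion - 1.0)
            rate = rng.gamma(shape, dispersion - 1.0, size=n_bins)
            counts = rng.poisson(rate)
        else:
            counts = rng.poisson(mean, size=n_bins)
        out.append(BinnedReadCounts(sample_id="S0", chromosome=chrom, counts=counts))
    return out


# ---------------------------------------------------------------------------
# TSV round-tripping (tab-delimited, UTF-8, header row, '.' decimal)

def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.id, r.bmi, r.ethnicity, r.ploidy, r.ff) for r in records],
        columns=_COHORT_COLUMNS,
    )


def write_cohort(records: list[PatientRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort TSV; FF values outside (0, 1) are rejected, not clipped."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns {sorted(missing)}")
    bad = df[(df["ff"] <= 0) | (df["ff"] >= 1)]
    if len(bad):
        raise ValueError(f"{len(bad)} records with FF outside (0, 1); first id {bad['id'].iloc[0]}")
    return [
        PatientRecord(id=row.id, bmi=row.bmi, ethnicity=row.ethnicity, ploidy=row.ploidy, ff=row.ff)
        for row in df.itertuples(index=False)
    ]


def write_bin_counts(counts: list[BinnedReadCounts], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "sample_id": c.sample_id,
                "chromosome": c.chromosome,
                "bin_index": np.arange(len(c.counts)),
                "count": c.counts,
            }
        )
        for c in counts
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_bin_counts(path: str | Path) -> list[BinnedReadCounts]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"bin-count file missing columns {sorted(missing)}")
    out = []
    for (sample, chrom), grp in df.groupby(["sample_id", "chromosome"], sort=False):
        grp = grp.sort_values("bin_index")
        out.append(BinnedReadCounts(sample_id=sample, chromosome=chrom, counts=grp["count"].to_numpy()))
    return out
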