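"""Genome substrate for the binned read-depth simulation.

The whole-genome-sequencing caller operates on counts of reads falling in
equally sized bins tiling each autosome.  Only the three clinically relevant
trisomy chromosomes (13, 18, 21) are represented individually; the remaining
autosomal sequence matters only through the total number of bins, which sets
the per-bin expected depth ``lambda = reads / total_bins``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# GRCh38-derived chromosome lengths (bp)
CHR13_LENGTH = 114_364_328
CHR18_LENGTH = 80_373_285
CHR21_LENGTH = 46_709_983
AUTOSOME_TOTAL_LENGTH = 2_875_001_522

DEFAULT_BIN_SIZE = 50_000

TRISOMY_CHROMOSOME = {"T13": "chr13", "T18": "chr18", "T21": "chr21"}


@dataclass(frozen=True)
class GenomeModel:
    """Bin layout of the autosomal genome.

    Parameters
    ----------
    chromosome_lengths
        Lengths in bp of the individually modelled chromosomes.
    autosome_total_length
        Total autosomal length in bp; reads are spread uniformly over all
        autosomal bins.
    bin_size
        Width of the tiling bins in bp.
    """

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr13": CHR13_LENGTH,
            "chr18": CHR18_LENGTH,
            "chr21": CHR21_LENGTH,
        }
    )
    autosome_total_length: int = AUTOSOME_TOTAL_LENGTH
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name, length in self.chromosome_lengths.items():
            if length // self.bin_size < 1:
                raise ValueError(f"{name}: bin_size larger than chromosome")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.chromosome_lengths)

    def n_bins(self, chromosome: str) -> int:
        """Number of bins tiling ``chromosome``."""
        try:
            length = self.chromosome_lengths[chromosome]
        except KeyError:
            raise KeyError(f"unknown chromosome label: {chromosome!r}") from None
        return length // self.bin_size

    @property
    def total_bins(self) -> int:
        """Bins tiling the whole autosomal genome."""
        return self.autosome_total_length // self.bin_size

    def mean_depth(self, reads: float) -> float:
        """Expected reads per bin when ``reads`` are spread genome-wide."""
        return reads / self.total_bins
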