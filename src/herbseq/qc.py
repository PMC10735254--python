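"""Library quality-control statistics.

Covers the three QC quantities the analysis reports: the molar fraction of
long (>1 kb) fragments from electrophoresis region tables, the duplication
level of sample-assigned reads, and a method-of-moments estimator of the
per-nucleotide fragmentation rate from observed fragment lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedProfileError


def phred_to_accuracy(phred: float) -> float:
    """Per-base accuracy (percent) implied by a Phred score: Phred 40 -> 99.99 %."""
    return 100.0 * (1.0 - 10.0 ** (-phred / 10.0))


@dataclass
class FragmentSizeProfile:
    """Electrophoresis region table for one sample at one protocol step.

    ``regions`` are (lower bp, upper bp, molarity nmol/L) rows as exported by
    Tapestation-style instruments; ``step`` labels the protocol stage
    (e.g. 'a' post-extraction ... 'd' after the last size selection).
    """

    sample_id: str
    step: str
    regions: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self):
        for lo, hi, mol in self.regions:
            if hi <= lo:
                raise ValueError(f"region ({lo}, {hi}) has non-positive width")
            if mol < 0:
                raise ValueError("molarity must be non-negative")
        spans = sorted((lo, hi) for lo, hi, _ in self.regions)
        for (lo1, hi1), (lo2, _) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise ValueError("regions must be non-overlapping")

    @property
    def total_molarity(self) -> float:
        return sum(m for _, _, m in self.regions)

    @classmethod
    def from_csv(cls, path, sample_id: str = "", step: str = "") -> "FragmentSizeProfile":
        """Load a `from_bp,to_bp,conc_nmol_l` CSV region table."""
        df = pd.read_csv(path)
        required = {"from_bp", "to_bp", "conc_nmol_l"}
        if not required.issubset(df.columns):
            raise ValueError(f"region CSV must have columns {sorted(required)}")
        regions = [
            (float(r.from_bp), float(r.to_bp), float(r.conc_nmol_l))
            for r in df.itertuples()
        ]
        return cls(sample_id=sample_id, step=step, regions=regions)


def profile_from_lengths(
    lengths,
    sample_id: str = "",
    step: str = "",
    bin_edges=(0, 200, 500, 700, 1000, 2000, 4000, 10000, 100000),
) -> FragmentSizeProfile:
    """Synthetic region table from a fragment-length pool.

    Molar concentration counts molecules, so each region's molarity is
    proportional to the number of fragments falling in it.
    """
    lengths = np.asarray(lengths)
    regions = []
    for lo, hi in zip(bin_edges, bin_edges[1:]):
        n = int(((lengths >= lo) & (lengths < hi)).sum())
        if n:
            regions.append((float(lo), float(hi), float(n)))
    return FragmentSizeProfile(sample_id=sample_id, step=step, regions=regions)


def long_fragment_fraction(
    profile: FragmentSizeProfile,
    threshold: float = 1000.0,
    whole_region: bool = False,
    mass_weighted: bool = False,
) -> float:
    """Percent of total molarity in regions above ``threshold`` bp.

    By default a region straddling the threshold contributes pro-rata by
    length; ``whole_region=True`` instead counts only regions whose lower
    bound clears the threshold (the convention of summing whole instrument
    regions).  ``mass_weighted=True`` weights each region by its mean
    fragment length, approximating a mass rather than molar fraction.
    """
    if profile.total_molarity <= 0:
        raise UndefinedProfileError(
            f"profile {profile.sample_id!r}/{profile.step!r} has zero total molarity"
        )

    def weight(lo: float, hi: float, mol: float) -> float:
        return mol * (lo + hi) / 2.0 if mass_weighted else mol

    total = sum(weight(lo, hi, m) for lo, hi, m in profile.regions)
    above = 0.0
    for lo, hi, m in profile.regions:
        w = weight(lo, hi, m)
        if lo >= threshold:
            above += w
        elif hi > threshold and not whole_region:
            above += w * (hi - threshold) / (hi - lo)
    return 100.0 * above / total


def duplication_level(reads, duplicate_flags) -> float:
    """Percent of sample-assigned reads flagged as duplicates.

    ``duplicate_flags`` may be a mapping read_id -> truthy (duplicate) or an
    iterable of booleans aligned with ``reads``.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("empty read set")
    if isinstance(duplicate_flags, dict):
        n_dup = sum(1 for r in reads if duplicate_flags.get(r.read_id))
    else:
        flags = list(duplicate_flags)
        if len(flags) != len(reads):
            raise ValueError("flag list length must match read count")
        n_dup = sum(bool(f) for f in flags)
    return 100.0 * n_dup / len(reads)


@dataclass(frozen=True)
class RateEstimate:
    """Estimated per-nucleotide fragmentation rate (breaks/nt/year)."""

    rate: float
    se: float
    n_fragments: int
    age: float


def estimate_fragmentation_rate(
    fragment_lengths, age: float, min_observable: float = 1.0
) -> RateEstimate:
    """Method-of-moments rate estimate from a left-truncated geometric sample.

    Under independent bond breakage, fragment lengths are geometric with
    parameter p = 1 - exp(-rate * age).  Observing only fragments of length
    >= ``min_observable`` (e.g. after size selection), the memorylessness of
    the geometric gives p_hat = 1 / (mean(L) - min_observable + 1), hence
    rate_hat = -ln(1 - p_hat) / age.  The standard error follows by the
    delta method.
    """
    if age <= 0:
        raise ValueError("age must be positive to estimate a rate")
    lengths = np.asarray(fragment_lengths, dtype=float)
    if lengths.size < 2:
        raise ValueError("need at least two fragments")
    mean = lengths.mean()
    if mean <= min_observable:
        raise ValueError(
            f"mean fragment length ({mean:.1f}) must exceed min_observable ({min_observable})"
        )
    p_hat = 1.0 / (mean - min_observable + 1.0)
    rate = -math.log(1.0 - p_hat) / age
    # d(rate)/d(mean) = p_hat^2 / ((1 - p_hat) * age); Var(mean) = s^2 / n
    se_mean = lengths.std(ddof=1) / math.sqrt(lengths.size)
    se = p_hat**2 / ((1.0 - p_hat) * age) * se_mean
    return RateEstimate(rate=rate, se=se, n_fragments=int(lengths.size), age=age)
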