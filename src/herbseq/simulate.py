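"""Synthetic herbarium target-capture read sets with per-read truth.

The generator reproduces the statistical structure the downstream analysis
assumes: a set of target loci, a section-structured reference database,
age-dependent random fragmentation, terminal cytosine deamination, logistic
bead size selection, length-biased PCR duplication, chimera formation,
congeneric cross-contamination, barcode/flank tagging and a flat-quality
point-error model.  Every emitted read carries a truth row (class, source,
pre-error sequence) so each pipeline stage can be scored against the truth.

Defaults encode the study conditions this package models: 48 target loci
totalling 104 kb, a per-nucleotide breakage rate of 1.66e-4 per year,
within-section divergence of ~0.4-0.9 % against ~3.8-7.9 % between sections,
size-selection midpoints at 500/900/1000 bp, 25 PCR cycles and CCS-grade
per-base accuracy (Phred 40).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import revcomp
from .errors import ConfigError
from .records import ReadRecord

# Study conditions (see docs/methods.md for provenance and rationale).
BREAKAGE_RATE_PER_NT_YEAR = 1.66e-4
TARGET_N_LOCI = 48
TARGET_TOTAL_LENGTH = 104_000
SIZE_MIDPOINTS = (500, 900, 1000)
PCR_CYCLES = 25
PCR_EFFICIENCY = 0.8
PCR_LENGTH_BIAS = 1e-4          # per-bp duplication penalty
ERROR_RATE = 1e-4               # Phred 40 per-base substitution rate
CHIMERA_RATE = 0.02
WITHIN_DIVERGENCE = 0.0065      # mean within-section K80 target
BETWEEN_DIVERGENCE = 0.055      # mean between-section K80 target
DEAM_WINDOW = 25
_DEAM_RATE_PER_YEAR = 0.005     # terminal deamination accumulation rate
_DEAM_DECAY_BP = 10.0           # positional e-folding of the damage profile

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T (byte codes)


def substream(seed: int, *labels) -> np.random.Generator:
    """Named, reproducible RNG substream derived from one run seed."""
    keys = [zlib.crc32(str(l).encode()) for l in labels]
    return np.random.default_rng([int(seed)] + keys)


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class LocusSet:
    """The target loci: (locus_id, sequence) pairs."""

    loci: tuple[tuple[str, str], ...]

    def __post_init__(self):
        ids = [lid for lid, _ in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids must be unique")
        if any(not seq for _, seq in self.loci):
            raise ValueError("locus sequences must be non-empty")

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def as_dict(self) -> dict[str, str]:
        return dict(self.loci)


@dataclass
class DegradationModel:
    """Age-dependent strand breakage plus terminal deamination.

    ``breakage_rate`` is in breaks per nucleotide per year; each
    internucleotide bond fails independently with p = 1 - exp(-rate * age).
    ``deam_rate_5p``/``deam_rate_3p`` give per-position C->T (5') and G->A
    (3') probabilities over the terminal 25 bp.
    """

    breakage_rate: float = BREAKAGE_RATE_PER_NT_YEAR
    age: float = 0.0
    deam_rate_5p: np.ndarray = field(default_factory=lambda: np.zeros(DEAM_WINDOW))
    deam_rate_3p: np.ndarray = field(default_factory=lambda: np.zeros(DEAM_WINDOW))

    def __post_init__(self):
        self.deam_rate_5p = np.asarray(self.deam_rate_5p, dtype=float)
        self.deam_rate_3p = np.asarray(self.deam_rate_3p, dtype=float)
        if self.breakage_rate < 0 or self.age < 0:
            raise ValueError("breakage_rate and age must be non-negative")
        for vec in (self.deam_rate_5p, self.deam_rate_3p):
            if vec.shape != (DEAM_WINDOW,):
                raise ValueError(f"damage vectors must have length {DEAM_WINDOW}")
            if ((vec < 0) | (vec > 1)).any():
                raise ValueError("damage probabilities must lie in [0, 1]")

    @property
    def break_probability(self) -> float:
        return 1.0 - math.exp(-self.breakage_rate * self.age)

    @classmethod
    def for_age(
        cls,
        age: float,
        breakage_rate: float = BREAKAGE_RATE_PER_NT_YEAR,
        deam_amplitude: float | None = None,
    ) -> "DegradationModel":
        """Study-condition model for a specimen of the given age.

        The terminal damage amplitude saturates with age,
        amp = 1 - exp(-0.005 * age), and decays into the read with a 10-bp
        e-folding, which reproduces the observed contrast between young
        (<= 0.15) and old (approaching 1 at the ends) specimens.
        """
        if deam_amplitude is None:
            deam_amplitude = 1.0 - math.exp(-_DEAM_RATE_PER_YEAR * age)
        pos = np.arange(DEAM_WINDOW)
        vec = deam_amplitude * np.exp(-pos / _DEAM_DECAY_BP)
        return cls(breakage_rate=breakage_rate, age=age,
                   deam_rate_5p=vec, deam_rate_3p=vec.copy())


@dataclass(frozen=True)
class SizeSelectionStep:
    """Logistic bead size selection: retention 0.5 at ``midpoint`` bp.

    Default sharpness puts retention at 5 % at 0.8 x midpoint, emulating
    the nominal "fragments >= X bp" bead cutoffs without a hard edge.
    """

    midpoint: float
    sharpness: float | None = None

    def __post_init__(self):
        if self.midpoint <= 0:
            raise ValueError("midpoint must be positive")
        if self.sharpness is not None and self.sharpness <= 0:
            raise ValueError("sharpness must be positive")

    @property
    def slope(self) -> float:
        if self.sharpness is not None:
            return self.sharpness
        return math.log(19.0) / (0.2 * self.midpoint)

    def retention_probability(self, length: float) -> float:
        z = self.slope * (length - self.midpoint)
        if z > 700:
            return 1.0
        if z < -700:
            return 0.0
        return 1.0 / (1.0 + math.exp(-z))


@dataclass
class ContaminationPlan:
    """Donor -> recipient cross-contamination rates (fraction of the
    recipient's reads that originate from the donor's library)."""

    rates: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for (donor, recipient), rate in self.rates.items():
            if donor == recipient:
                raise ValueError(f"self-contamination entry for {donor!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {donor}->{recipient} outside [0, 1]")

    def donors_for(self, recipient: str) -> list[tuple[str, float]]:
        return [
            (donor, rate)
            for (donor, rec), rate in self.rates.items()
            if rec == recipient and rate > 0
        ]

    def samples(self) -> set[str]:
        return {s for pair in self.rates for s in pair}


@dataclass(frozen=True)
class BarcodeScheme:
    """Per-sample 6-nt barcodes with fixed 3-nt flanks.

    The barcode adapter is ligated at both ends so that forward reads start
    with GAT-<barcode>-GTG while reverse reads start with CAC-<barcode>-ATC
    (the same six bases between complementary flanks).  Equivalently, the
    forward-oriented molecule carries GAT-<barcode>-GTG at its 5' end and
    GAT-<rc barcode>-GTG at its 3' end; the asymmetric flanks make read
    orientation unambiguous.
    """

    barcodes: dict[str, str]
    flank_left: str = "GAT"
    flank_right: str = "GTG"

    def __post_init__(self):
        seen = {}
        for sample, bc in self.barcodes.items():
            if len(bc) != 6 or any(c not in "ACGT" for c in bc):
                raise ValueError(f"barcode for {sample!r} must be 6 nt of ACGT")
            if bc in seen:
                raise ValueError(f"barcode {bc} reused by {seen[bc]!r} and {sample!r}")
            seen[bc] = sample

    def tag(self, sample: str) -> str:
        """The 12-nt motif at the 5' end of a forward-oriented read."""
        return self.flank_left + self.barcodes[sample] + self.flank_right

    def tag_end(self, sample: str) -> str:
        """The motif at the 3' end of a forward-oriented read
        (GAT-<rc barcode>-GTG; reads as CAC-<barcode>-ATC on the reverse
        strand, the motif the demultiplexer quotes for reverse reads)."""
        return self.flank_left + revcomp(self.barcodes[sample]) + self.flank_right

    def reverse_start_motif(self, sample: str) -> str:
        """What the first 12 nt of a reverse read look like (CAC-<bc>-ATC)."""
        return revcomp(self.tag_end(sample))

    def min_pairwise_distance(self) -> int:
        tags = [self.tag(s) for s in self.barcodes]
        best = len(tags[0]) if tags else 0
        for i in range(len(tags)):
            for j in range(i + 1, len(tags)):
                d = sum(a != b for a, b in zip(tags[i], tags[j]))
                best = min(best, d)
        return best

    @classmethod
    def generate(cls, samples: list[str], seed: int, min_distance: int = 3) -> "BarcodeScheme":
        """Random barcodes at pairwise Hamming distance >= min_distance."""
        rng = substream(seed, "barcodes")
        chosen: list[str] = []
        attempts = 0
        while len(chosen) < len(samples):
            bc = "".join(chr(b) for b in rng.choice(_BASES, size=6))
            if all(sum(a != b for a, b in zip(bc, other)) >= min_distance for other in chosen):
                chosen.append(bc)
            attempts += 1
            if attempts > 100_000:
                raise ConfigError("could not generate a separated barcode set")
        return cls(barcodes=dict(zip(samples, chosen)))


@dataclass
class SampleSpec:
    """One specimen: its section, age in years and sequencing depth."""

    name: str
    section: str
    age: float
    depth: int
    genome_copies: int = 80
    end_resection_mean: float = 40.0  # bp nibbled per fragment end (geometric)
    size_midpoints: tuple[float, ...] = SIZE_MIDPOINTS
    pcr_cycles: int = PCR_CYCLES
    pcr_efficiency: float = PCR_EFFICIENCY
    pcr_length_bias: float = PCR_LENGTH_BIAS
    chimera_rate: float = CHIMERA_RATE


@dataclass
class Molecule:
    """A distinct library molecule (post-damage, post-selection insert)."""

    mol_id: str
    seq: str
    locus: str
    section: str
    sample: str
    count: int = 1  # post-PCR copy number


# ---------------------------------------------------------------------------
# Elementary generative operations


def _random_seq(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    draw = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
    return draw.tobytes().decode()


def generate_locus_set(
    n_loci: int = TARGET_N_LOCI,
    total_length: int = TARGET_TOTAL_LENGTH,
    gc_fraction: float = 0.4,
    seed: int = 0,
) -> LocusSet:
    """Random target loci whose lengths sum to ``total_length``."""
    if n_loci < 1 or total_length < n_loci:
        raise ValueError("need n_loci >= 1 and total_length >= n_loci")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = substream(seed, "loci")
    lengths = rng.multinomial(total_length - n_loci, [1.0 / n_loci] * n_loci) + 1
    loci = tuple(
        (f"locus{idx:03d}", _random_seq(rng, int(L), gc_fraction))
        for idx, L in enumerate(lengths, start=1)
    )
    return LocusSet(loci=loci)


def mutate_sequence(
    seq: str, rate: float, rng: np.random.Generator, transition_bias: float = 2.0
) -> str:
    """Substitute each site independently with probability ``rate``.

    Among substitutions, transitions (A<->G, C<->T) are ``transition_bias``
    times as likely as each class of change being a transition vs either
    transversion jointly (bias/(bias+1) of substitutions are transitions).
    """
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size == 0:
        return seq
    p_ts = transition_bias / (transition_bias + 1.0)
    is_ts = rng.random(hit.size) < p_ts
    for pos, ts in zip(hit, is_ts):
        base = arr[pos]
        if base not in _TRANSITION:
            continue
        if ts:
            arr[pos] = _TRANSITION[base]
        else:
            # one of the two transversion partners, uniformly
            options = [b for b in (65, 67, 71, 84) if b != base and b != _TRANSITION[base]]
            arr[pos] = options[int(rng.integers(2))]
    return arr.tobytes().decode()


def diverge_sections(
    locus_set: LocusSet,
    n_sections: int = 4,
    within_divergence=WITHIN_DIVERGENCE,
    between_divergence: float = BETWEEN_DIVERGENCE,
    members_per_section: int = 4,
    seed: int = 0,
    transition_bias: float = 2.0,
    section_names: list[str] | None = None,
):
    """Hierarchical substitution process producing a section-level database.

    Each section ancestor is mutated from the root loci at
    (between_divergence - mean within)/2 and each member from its ancestor
    at within_divergence/2; a cross-section pair then accumulates two
    ancestor branches plus two member branches, so realized mean pairwise
    K80 distances approximate ``within_divergence`` inside sections and
    ``between_divergence`` across them.  ``within_divergence`` may be a
    single proportion or one per section.
    """
    from .decontam import DbEntry, SectionDatabase

    within = (
        list(within_divergence)
        if hasattr(within_divergence, "__len__")
        else [within_divergence] * n_sections
    )
    if len(within) != n_sections:
        raise ValueError("per-section within_divergence needs one value per section")
    if not all(0 <= w < between_divergence for w in within):
        raise ValueError(
            "need 0 <= within_divergence < between_divergence for a usable distance gap"
        )
    if section_names is None:
        section_names = [f"sec{chr(ord('A') + i)}" for i in range(n_sections)]
    if len(section_names) != n_sections:
        raise ValueError("section_names length must equal n_sections")
    rng = substream(seed, "sections")
    ancestor_rate = max(between_divergence - float(np.mean(within)), 0.0) / 2.0
    entries = []
    for section, w in zip(section_names, within):
        ancestors = {
            lid: mutate_sequence(seq, ancestor_rate, rng, transition_bias)
            for lid, seq in locus_set.loci
        }
        for m in range(members_per_section):
            sample = f"{section}_ref{m + 1}"
            for lid, _ in locus_set.loci:
                member_seq = mutate_sequence(
                    ancestors[lid], w / 2.0, rng, transition_bias
                )
                entries.append(DbEntry(section=section, sample=sample, locus=lid, seq=member_seq))
    return SectionDatabase(entries=entries)


def fragment_sequence(
    sequence: str, model: DegradationModel, seed: int | np.random.Generator = 0
) -> list[str]:
    """Break a sequence by independent Bernoulli bond failure.

    Each of the len-1 internucleotide bonds breaks with
    p = 1 - exp(-rate * age); fragments are the maximal unbroken runs, in
    order, so fragment lengths are geometric with parameter p.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "frag")
    p = model.break_probability
    if p <= 0 or len(sequence) == 1:
        return [sequence]
    breaks = np.flatnonzero(rng.random(len(sequence) - 1) < p) + 1
    if breaks.size == 0:
        return [sequence]
    out = []
    prev = 0
    for b in breaks:
        out.append(sequence[prev:b])
        prev = int(b)
    out.append(sequence[prev:])
    return out


def apply_damage(
    fragment: str, model: DegradationModel, seed: int | np.random.Generator = 0
) -> str:
    """Plant terminal deamination: C->T over the first 25 positions (5') and
    G->A over the last 25 (3'), per-position probabilities from the model."""
    if not fragment:
        raise ValueError("fragment must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "damage")
    arr = np.frombuffer(fragment.encode(), dtype=np.uint8).copy()
    n = arr.size
    w5 = min(DEAM_WINDOW, n)
    draws5 = rng.random(w5)
    for i in range(w5):
        if arr[i] == 67 and draws5[i] < model.deam_rate_5p[i]:  # C -> T
            arr[i] = 84
    w3 = min(DEAM_WINDOW, n)
    draws3 = rng.random(w3)
    for j in range(w3):
        pos = n - 1 - j
        if arr[pos] == 71 and draws3[j] < model.deam_rate_3p[j]:  # G -> A
            arr[pos] = 65
    return arr.tobytes().decode()


def size_select(
    fragments: list[str],
    step: SizeSelectionStep,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Retain each fragment with the step's logistic probability."""
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "select")
    draws = rng.random(len(fragments))
    return [
        f for f, u in zip(fragments, draws) if u < step.retention_probability(len(f))
    ]


@dataclass(frozen=True)
class AmplifiedFragment:
    seq: str
    parent: int  # index into the input pool
    is_duplicate: bool


def amplify_counts(
    lengths,
    cycles: int,
    efficiency: float,
    length_bias: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Post-PCR copy number per molecule.

    Per cycle every existing copy of molecule m duplicates with probability
    efficiency * exp(-length_bias * L_m), i.e. a length-biased branching
    process; only the counts are tracked.
    """
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    lengths = np.asarray(lengths, dtype=float)
    p = np.clip(efficiency * np.exp(-length_bias * lengths), 0.0, 1.0)
    counts = np.ones(lengths.size, dtype=np.int64)
    for _ in range(cycles):
        counts = counts + rng.binomial(counts, p)
    return counts


def amplify(
    fragments: list[str],
    cycles: int,
    efficiency: float = PCR_EFFICIENCY,
    length_bias: float = PCR_LENGTH_BIAS,
    seed: int | np.random.Generator = 0,
    max_molecules: int = 2_000_000,
) -> list[AmplifiedFragment]:
    """Materialized PCR: every output molecule carries its parent index.

    Copies beyond the first per parent are flagged duplicates.  Raises if the
    pool would exceed ``max_molecules`` (use :func:`amplify_counts` to work
    with copy numbers instead).
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "pcr")
    counts = amplify_counts([len(f) for f in fragments], cycles, efficiency, length_bias, rng)
    if counts.sum() > max_molecules:
        raise ConfigError(
            f"amplified pool ({int(counts.sum())}) exceeds max_molecules={max_molecules}"
        )
    out = []
    for idx, (frag, c) in enumerate(zip(fragments, counts)):
        out.append(AmplifiedFragment(seq=frag, parent=idx, is_duplicate=False))
        out.extend(AmplifiedFragment(seq=frag, parent=idx, is_duplicate=True) for _ in range(int(c) - 1))
    return out


@dataclass(frozen=True)
class ChimeraEvent:
    parent_a: int
    parent_b: int
    breakpoint_a: int
    breakpoint_b: int


def make_chimeras(
    pool: list[str],
    rate: float,
    seed: int | np.random.Generator = 0,
    breakpoint: int | None = None,
) -> tuple[list[str], dict[int, ChimeraEvent]]:
    """Convert a Binomial(n, rate) subset of the pool into two-parent chimeras.

    A selected read i is replaced by pool[i][:b_i] + pool[j][b_j:] for a
    uniformly chosen partner j != i and uniform interior breakpoints (or the
    forced ``breakpoint`` on both parents).  Returns the new pool and a map
    from output index to the chimera's provenance.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "chimera")
    n = len(pool)
    out = list(pool)
    events: dict[int, ChimeraEvent] = {}
    if n < 2 or rate == 0.0:
        return out, events
    selected = np.flatnonzero(rng.random(n) < rate)
    for i in selected:
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        a, b = pool[int(i)], pool[j]
        if len(a) < 2 or len(b) < 2:
            continue
        ba = breakpoint if breakpoint is not None else int(rng.integers(1, len(a)))
        bb = breakpoint if breakpoint is not None else int(rng.integers(1, len(b)))
        ba = min(max(ba, 1), len(a) - 1)
        bb = min(max(bb, 1), len(b) - 1)
        out[int(i)] = a[:ba] + b[bb:]
        events[int(i)] = ChimeraEvent(parent_a=int(i), parent_b=j, breakpoint_a=ba, breakpoint_b=bb)
    return out, events


# ---------------------------------------------------------------------------
# Whole-sample generation


def error_rate_to_phred(error_rate: float) -> int:
    return int(round(-10.0 * math.log10(error_rate))) if error_rate > 0 else 93


def _apply_point_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < error_rate)
    for pos in hit:
        options = [b for b in (65, 67, 71, 84) if b != arr[pos]]
        arr[pos] = options[int(rng.integers(3))]
    return arr.tobytes().decode()


def resect_ends(
    fragments: list[str], mean_per_end: float, rng: np.random.Generator
) -> list[str]:
    """Trim a geometric number of bases (mean ``mean_per_end``) off each
    fragment end, emulating bead cleanup / end-repair nibbling.  This also
    keeps unfragmented copies of the same locus from being byte-identical
    molecules, which no real library contains (genomic breakpoints fall in
    flanking DNA that is not modelled here)."""
    if mean_per_end <= 0:
        return list(fragments)
    p = 1.0 / (mean_per_end + 1.0)
    out = []
    trims = rng.geometric(p, size=2 * len(fragments)) - 1
    for i, frag in enumerate(fragments):
        lo, hi = int(trims[2 * i]), int(trims[2 * i + 1])
        if lo + hi >= len(frag):
            continue  # fragment consumed
        out.append(frag[lo : len(frag) - hi])
    return out


def build_molecule_pool(
    genome: dict[str, str], spec: SampleSpec, seed: int
) -> list[Molecule]:
    """The sample's library molecules: fragment -> resect -> select -> damage
    -> PCR.

    ``genome_copies`` haploid genome equivalents enter extraction; each copy
    fragments independently.  Returns distinct molecules with post-PCR copy
    numbers (duplicates are materialized only at read sampling).
    """
    model = DegradationModel.for_age(spec.age)
    rng = substream(seed, spec.name, "pool")
    molecules: list[Molecule] = []
    steps = [SizeSelectionStep(midpoint=m) for m in spec.size_midpoints]
    for locus, seq in genome.items():
        for copy in range(spec.genome_copies):
            frags = fragment_sequence(seq, model, rng)
            frags = resect_ends(frags, spec.end_resection_mean, rng)
            # Cheap pre-screen: the hardest cutoff makes tiny fragments
            # hopeless; skip damaging them.
            floor = 0.5 * min(spec.size_midpoints) if spec.size_midpoints else 0
            frags = [f for f in frags if len(f) >= floor]
            for step in steps:
                frags = size_select(frags, step, rng)
            for k, frag in enumerate(frags):
                damaged = apply_damage(frag, model, rng)
                molecules.append(
                    Molecule(
                        mol_id=f"{spec.name}:{locus}:c{copy}:f{k}",
                        seq=damaged,
                        locus=locus,
                        section=spec.section,
                        sample=spec.name,
                    )
                )
    if molecules:
        counts = amplify_counts(
            [len(m.seq) for m in molecules],
            spec.pcr_cycles,
            spec.pcr_efficiency,
            spec.pcr_length_bias,
            rng,
        )
        for mol, c in zip(molecules, counts):
            mol.count = int(c)
    return molecules


def _draw_molecules(
    pool: list[Molecule], n: int, rng: np.random.Generator
) -> list[Molecule]:
    counts = np.array([m.count for m in pool], dtype=float)
    probs = counts / counts.sum()
    idx = rng.choice(len(pool), size=n, p=probs)
    return [pool[int(i)] for i in idx]


def build_sample(
    db,
    spec: SampleSpec,
    plan: ContaminationPlan,
    scheme: BarcodeScheme,
    error_rate: float = ERROR_RATE,
    seed: int = 0,
    donor_pools: dict[str, list[Molecule]] | None = None,
    own_pool: list[Molecule] | None = None,
    genome: dict[str, str] | None = None,
    genome_divergence: float = WITHIN_DIVERGENCE,
    id_prefix: str | None = None,
    label_duplicates: bool = True,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Generate one sample's tagged, error-bearing reads plus the truth table.

    The generative chain is fragment -> resect -> size-select -> damage ->
    amplify -> sample reads -> chimerize -> cross-contaminate -> tag with
    barcode/flanks -> point errors (applied once per distinct molecule so
    PCR duplicates stay exact copies) -> flat Phred qualities.  The truth
    table records class (endogenous / duplicate / chimera /
    cross_contaminant), parents, source section/locus, insert length and the
    pre-error sequence.  ``label_duplicates=False`` defers duplicate-class
    labelling to the caller (used when reads are pooled and shuffled across
    samples, where first-seen order changes).
    """
    rng = substream(seed, spec.name, "reads")
    donor_pools = donor_pools or {}
    donors = plan.donors_for(spec.name)
    for donor, _ in donors:
        if donor not in donor_pools:
            raise ConfigError(
                f"contamination plan names donor {donor!r} with no molecule pool"
            )
    if own_pool is None:
        if genome is None:
            genome = sample_genome(db, spec, seed, divergence=genome_divergence)
        own_pool = build_molecule_pool(genome, spec, seed)

    # How many reads come from which library.
    n_contam = {
        donor: int(rng.binomial(spec.depth, rate)) for donor, rate in donors
    }
    n_own = spec.depth - sum(n_contam.values())
    drawn: list[tuple[Molecule, str]] = []
    if own_pool and n_own > 0:
        drawn += [(m, "endogenous") for m in _draw_molecules(own_pool, n_own, rng)]
    for donor, n in n_contam.items():
        if n > 0 and donor_pools[donor]:
            drawn += [
                (m, "cross_contaminant")
                for m in _draw_molecules(donor_pools[donor], n, rng)
            ]
    order = rng.permutation(len(drawn))
    drawn = [drawn[int(i)] for i in order]

    # Chimera conversion on the sampled reads.
    inserts = [m.seq for m, _ in drawn]
    inserts, chim_events = make_chimeras(inserts, spec.chimera_rate, rng)

    tag = scheme.tag(spec.name)
    tag_end = scheme.tag_end(spec.name)
    phred_char = chr(33 + error_rate_to_phred(error_rate))
    prefix = id_prefix if id_prefix is not None else f"{spec.name}_r"

    reads: list[ReadRecord] = []
    rows = []
    errored_cache: dict[str, str] = {}
    for i, (mol, base_class) in enumerate(drawn):
        read_id = f"{prefix}{i:06d}"
        seg_a = seg_b = None
        if i in chim_events:
            ev = chim_events[i]
            partner_mol = drawn[ev.parent_b][0]
            cls = "chimera"
            mol_key = f"chim:{read_id}"
            parents = f"{mol.mol_id};{partner_mol.mol_id}"
            locus = f"{mol.locus}|{partner_mol.locus}"
            section = mol.section
            seg_a = ev.breakpoint_a
            seg_b = len(drawn[ev.parent_b][0].seq) - ev.breakpoint_b
        else:
            cls = base_class
            mol_key = mol.mol_id
            parents = mol.mol_id
            locus = mol.locus
            section = mol.section
        insert = inserts[i]
        tagged = tag + insert + tag_end
        if mol_key in errored_cache:
            errored = errored_cache[mol_key]
        else:
            errored = _apply_point_errors(tagged, error_rate, rng)
            errored_cache[mol_key] = errored
        errored_insert = errored[len(tag): len(errored) - len(tag_end)]
        orientation = "forward" if rng.random() < 0.5 else "reverse"
        bases = errored if orientation == "forward" else revcomp(errored)
        reads.append(
            ReadRecord(
                read_id=read_id,
                bases=bases,
                qualities=phred_char * len(bases),
                orientation=orientation,
            )
        )
        rows.append(
            {
                "read_id": read_id,
                "sample": spec.name,
                "class": cls,
                "parent_ids": parents,
                "section": section,
                "locus": locus,
                "truth_length": len(insert),
                "truth_seq": tagged,
                "truth_insert": errored_insert,
                "orientation": orientation,
                "chim_seg_a": seg_a,
                "chim_seg_b": seg_b,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "sample", "class", "parent_ids", "section", "locus",
            "truth_length", "truth_seq", "truth_insert", "orientation",
            "chim_seg_a", "chim_seg_b",
        ],
    ).astype({"chim_seg_a": "float64", "chim_seg_b": "float64"})
    if label_duplicates:
        label_duplicate_truth(reads, truth)
    return reads, truth


def label_duplicate_truth(reads: list[ReadRecord], truth: pd.DataFrame) -> pd.DataFrame:
    """Mark exact-copy reads as class 'duplicate' of the first-seen copy.

    Two reads of one sample are exact duplicates when their (post-error,
    forward-oriented) inserts are identical -- the same distinct library
    molecule sequenced twice.  ``reads`` defines the first-seen order (the
    order the demultiplexer will see); later copies get class 'duplicate'
    and their parent set to the representative's read id.  Modifies
    ``truth`` in place and returns it.
    """
    idx = truth.set_index("read_id")
    samples = idx["sample"].to_dict()
    inserts = idx["truth_insert"].to_dict()
    classes = idx["class"].to_dict()
    parents = idx["parent_ids"].to_dict()
    seen: dict[tuple[str, str], str] = {}
    for r in reads:
        rid = r.read_id
        if rid not in samples:
            continue
        key = (samples[rid], inserts[rid])
        first = seen.get(key)
        if first is None:
            seen[key] = rid
        else:
            classes[rid] = "duplicate"
            parents[rid] = first
    truth["class"] = truth["read_id"].map(classes)
    truth["parent_ids"] = truth["read_id"].map(parents)
    return truth


def sample_genome(db, spec: SampleSpec, seed: int, divergence: float = WITHIN_DIVERGENCE):
    """The specimen's own haplotype: a fresh member of its section, derived
    from the section's first database entry at within-section divergence."""
    rng = substream(seed, spec.name, "genome")
    entries = [e for e in db.entries if e.section == spec.section]
    if not entries:
        raise ConfigError(f"sample {spec.name!r}: section {spec.section!r} not in database")
    ref_sample = entries[0].sample
    return {
        e.locus: mutate_sequence(e.seq, divergence / 2.0, rng)
        for e in entries
        if e.sample == ref_sample
    }


# ---------------------------------------------------------------------------
# Run-level configuration and orchestration


def study_sample_specs(depth: int = 400, genome_copies: int = 80) -> list[SampleSpec]:
    """The study's 12-specimen design: four sections, collection years 1932
    to 2019 (ages relative to the 2021 sequencing run)."""
    table = [
        ("2019_acaulis", "Siphonomorpha", 2019),
        ("2019_burchellii", "Silene", 2019),
        ("2018_noctiflora", "Elisanthe", 2018),
        ("2017_sachalinensis", "Physolychnis", 2017),
        ("1994_acaulis", "Siphonomorpha", 1994),
        ("1987_burchellii", "Silene", 1987),
        ("1981_noctiflora", "Elisanthe", 1981),
        ("1979_involucrata", "Physolychnis", 1979),
        ("1969_acaulis", "Siphonomorpha", 1969),
        ("1959_uralensis", "Physolychnis", 1959),
        ("1948_burchellii", "Silene", 1948),
        ("1932_rigens", "Elisanthe", 1932),
    ]
    return [
        SampleSpec(name=name, section=section, age=2021 - year, depth=depth,
                   genome_copies=genome_copies)
        for name, section, year in table
    ]


@dataclass
class SimConfig:
    """Full synthetic-run configuration; defaults are the study conditions."""

    n_loci: int = TARGET_N_LOCI
    total_length: int = TARGET_TOTAL_LENGTH
    gc_fraction: float = 0.4
    n_sections: int = 4
    within_divergence: float = WITHIN_DIVERGENCE
    between_divergence: float = BETWEEN_DIVERGENCE
    members_per_section: int = 4
    samples: list[SampleSpec] = field(default_factory=study_sample_specs)
    contamination: ContaminationPlan = field(default_factory=ContaminationPlan)
    error_rate: float = ERROR_RATE
    genome_divergence: float = WITHIN_DIVERGENCE

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "samples" in d:
            d["samples"] = [
                s if isinstance(s, SampleSpec) else SampleSpec(**s) for s in d["samples"]
            ]
        if "contamination" in d and not isinstance(d["contamination"], ContaminationPlan):
            rates = {
                (c["donor"], c["recipient"]): float(c["rate"]) for c in d["contamination"]
            }
            d["contamination"] = ContaminationPlan(rates=rates)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimResult:
    reads: list[ReadRecord]         # pooled, shuffled, unassigned
    truth: pd.DataFrame
    db: object                      # SectionDatabase
    locus_set: LocusSet
    scheme: BarcodeScheme
    config: SimConfig
    pools: dict[str, list[Molecule]]
    genomes: dict[str, dict[str, str]]


def simulate_run(config: SimConfig, seed: int = 0, outdir=None) -> SimResult:
    """Generate the whole multiplexed run: database, per-sample libraries,
    cross-contamination, pooled shuffled FASTQ and the truth table."""
    names = [s.name for s in config.samples]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate sample names")
    unknown = config.contamination.samples() - set(names)
    if unknown:
        raise ConfigError(f"contamination plan references unknown samples: {sorted(unknown)}")
    sections = sorted({s.section for s in config.samples})
    extra = [f"sec{chr(ord('A') + i)}" for i in range(len(sections), config.n_sections)]
    section_names = sections + extra

    locus_set = generate_locus_set(
        config.n_loci, config.total_length, config.gc_fraction, seed
    )
    db = diverge_sections(
        locus_set,
        n_sections=len(section_names),
        within_divergence=config.within_divergence,
        between_divergence=config.between_divergence,
        members_per_section=config.members_per_section,
        seed=seed,
        section_names=section_names,
    )
    scheme = BarcodeScheme.generate(names, seed)

    genomes = {
        s.name: sample_genome(db, s, seed, divergence=config.genome_divergence)
        for s in config.samples
    }
    pools = {s.name: build_molecule_pool(genomes[s.name], s, seed) for s in config.samples}

    all_reads: list[ReadRecord] = []
    truths = []
    for i, spec in enumerate(config.samples):
        reads, truth = build_sample(
            db, spec, config.contamination, scheme,
            error_rate=config.error_rate, seed=seed,
            donor_pools=pools, own_pool=pools[spec.name],
            id_prefix=f"s{i:02d}_",
            label_duplicates=False,
        )
        all_reads.extend(reads)
        truths.append(truth)
    non_empty = [t for t in truths if not t.empty]
    truth = (
        pd.concat(non_empty, ignore_index=True)
        if non_empty
        else pd.DataFrame(columns=["read_id", "sample", "class"])
    )

    rng = substream(seed, "pooling")
    order = rng.permutation(len(all_reads))
    all_reads = [all_reads[int(i)] for i in order]
    if not truth.empty:
        label_duplicate_truth(all_reads, truth)

    result = SimResult(
        reads=all_reads, truth=truth, db=db, locus_set=locus_set,
        scheme=scheme, config=config, pools=pools, genomes=genomes,
    )
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: SimResult, outdir) -> None:
    import os

    from .records import to_fastq

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "reads.fastq"), "w") as fh:
        to_fastq(result.reads, fh)
    result.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    result.db.to_fasta(os.path.join(outdir, "section_db.fasta"))
    with open(os.path.join(outdir, "target_loci.fasta"), "w") as fh:
        for lid, seq in result.locus_set.loci:
            fh.write(f">{lid}\n{seq}\n")
    with open(os.path.join(outdir, "barcodes.tsv"), "w") as fh:
        fh.write("sample\tbarcode\n")
        for sample, bc in result.scheme.barcodes.items():
            fh.write(f"{sample}\t{bc}\n")
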