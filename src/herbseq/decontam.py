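"""Cross-contaminant screening against a section-level reference database.

Congeneric cross-contamination -- reads from a related sample co-processed in
the lab -- is invisible to conventional contamination screens and is detected
here purely by sequence divergence: every read is aligned against a database
of target-locus sequences grouped by taxonomic section, and reads whose best
hit lands in the wrong section are flagged.  The approach requires a genetic
distance gap between sections, which :func:`validate_database` checks with
Kimura two-parameter (K80) distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._align import KmerIndex, LocalHit, ScoreScheme, local_align, revcomp
from .errors import DatabaseValidationError, SaturationError

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class DbEntry:
    section: str
    sample: str
    locus: str
    seq: str


@dataclass
class SectionDatabase:
    """Target-locus reference sequences grouped by taxonomic section.

    FASTA round-trips use the ``>section|sample|locus`` header dialect.
    """

    entries: list[DbEntry]
    distance_summary: "DistanceSummary | None" = None
    _index: KmerIndex | None = field(default=None, repr=False, compare=False)

    def sections(self) -> list[str]:
        out = []
        for e in self.entries:
            if e.section not in out:
                out.append(e.section)
        return out

    def loci(self) -> list[str]:
        out = []
        for e in self.entries:
            if e.locus not in out:
                out.append(e.locus)
        return out

    def index(self) -> KmerIndex:
        if self._index is None or self._index.n_targets != len(self.entries):
            self._index = KmerIndex([e.seq for e in self.entries])
        return self._index

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.section}|{e.sample}|{e.locus}\n{e.seq}\n")

    @classmethod
    def from_fasta(cls, path) -> "SectionDatabase":
        entries = []
        header, chunks = None, []
        def flush():
            if header is not None:
                section, sample, locus = header.split("|", 2)
                entries.append(DbEntry(section, sample, locus, "".join(chunks).upper()))
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    flush()
                    header, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        flush()
        return cls(entries=entries)


@dataclass(frozen=True)
class K80Distance:
    """Kimura two-parameter distance: transition proportion P, transversion
    proportion Q and d = -0.5 ln(1-2P-Q) - 0.25 ln(1-2Q)."""

    P: float
    Q: float
    d: float
    n_sites: int


def k80_distance(seq_a: str, seq_b: str) -> K80Distance:
    """K80 distance between two aligned sequences.

    Columns where either sequence has a gap or ambiguity code are dropped
    pairwise.  Raises :class:`SaturationError` when the observed divergence
    puts either logarithm argument at or below zero.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    valid = np.isin(a, codes) & np.isin(b, codes)
    n = int(valid.sum())
    purine = np.frombuffer(b"AG", dtype=np.uint8)
    diff = valid & (a != b)
    same_class = np.isin(a, purine) == np.isin(b, purine)
    transitions = int((diff & same_class).sum())
    transversions = int((diff & ~same_class).sum())
    if n == 0:
        raise ValueError("no comparable (ungapped, unambiguous) columns")
    P = transitions / n
    Q = transversions / n
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError(
            f"K80 distance undefined at P={P:.4f}, Q={Q:.4f} (saturated)"
        )
    d = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    return K80Distance(P=P, Q=Q, d=d, n_sites=n)


@dataclass
class DistanceSummary:
    """Realized distance structure of a section database.

    Distances are substitutions/site; ``within`` maps section -> mean
    within-section K80 distance (unweighted mean over loci of the per-locus
    mean pairwise distance, mirroring per-locus alignment followed by
    averaging), ``between`` maps (section_a, section_b) -> mean distance.
    """

    within: dict[str, float]
    between: dict[tuple[str, str], float]

    @property
    def max_within(self) -> float:
        return max(self.within.values()) if self.within else 0.0

    @property
    def min_between(self) -> float:
        return min(self.between.values()) if self.between else 0.0

    @property
    def mean_within(self) -> float:
        return float(np.mean(list(self.within.values()))) if self.within else 0.0

    @property
    def mean_between(self) -> float:
        return float(np.mean(list(self.between.values()))) if self.between else 0.0


def _align_group(seqs: list[str], aligner=None) -> list[str]:
    """Per-locus alignment hook: equal-length inputs pass through, anything
    else goes to the pluggable aligner (default: mafft on PATH)."""
    if len({len(s) for s in seqs}) == 1:
        return seqs
    if aligner is None:
        aligner = align_with_mafft
    return aligner(seqs)


def align_with_mafft(seqs: list[str]) -> list[str]:
    import subprocess
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        for i, s in enumerate(seqs):
            fh.write(f">s{i}\n{s}\n")
        path = fh.name
    res = subprocess.run(
        ["mafft", "--auto", "--quiet", path], capture_output=True, text=True, check=True
    )
    out: dict[str, list[str]] = {}
    key = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            key = line[1:]
            out[key] = []
        elif key:
            out[key].append(line.strip())
    return ["".join(out[f"s{i}"]).upper() for i in range(len(seqs))]


def validate_database(
    db: SectionDatabase, min_gap_ratio: float = 2.0, aligner=None
) -> DistanceSummary:
    """Compute the within/between-section K80 distance structure and require
    a gap: min between-section distance >= min_gap_ratio x max within.

    Pairwise distances are computed per locus (sequences of one locus are
    aligned together), then averaged unweighted across loci.  Saturated
    pairs are skipped.  Raises :class:`DatabaseValidationError` naming the
    closest section pair when the gap requirement fails; the summary is also
    stored on the database.
    """
    sections = db.sections()
    if len(sections) < 2:
        raise ValueError("need at least two sections")
    within_acc: dict[str, list[float]] = {s: [] for s in sections}
    between_acc: dict[tuple[str, str], list[float]] = {}
    for locus in db.loci():
        entries = [e for e in db.entries if e.locus == locus]
        aligned = _align_group([e.seq for e in entries], aligner)
        w_loc: dict[str, list[float]] = {}
        b_loc: dict[tuple[str, str], list[float]] = {}
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                try:
                    d = k80_distance(aligned[i], aligned[j]).d
                except SaturationError:
                    continue
                si, sj = entries[i].section, entries[j].section
                if si == sj:
                    w_loc.setdefault(si, []).append(d)
                else:
                    key = tuple(sorted((si, sj)))
                    b_loc.setdefault(key, []).append(d)
        for s, vals in w_loc.items():
            within_acc[s].append(float(np.mean(vals)))
        for key, vals in b_loc.items():
            between_acc.setdefault(key, []).append(float(np.mean(vals)))
    summary = DistanceSummary(
        within={s: float(np.mean(v)) for s, v in within_acc.items() if v},
        between={k: float(np.mean(v)) for k, v in between_acc.items()},
    )
    if summary.between:
        closest = min(summary.between, key=summary.between.get)
        if summary.min_between < min_gap_ratio * summary.max_within or (
            summary.max_within == 0 and summary.min_between == 0
        ):
            raise DatabaseValidationError(
                f"no usable distance gap: sections {closest[0]!r} vs {closest[1]!r} "
                f"are {summary.min_between:.4f} apart while within-section "
                f"distances reach {summary.max_within:.4f} "
                f"(required ratio {min_gap_ratio})",
                section_pair=closest,
            )
    db.distance_summary = summary
    return summary


@dataclass(frozen=True)
class HitRecord:
    """Best database hit for one read."""

    read_id: str
    section: str
    sample: str
    locus: str
    length: int          # alignment columns, gaps included
    identity: float      # matches / alignment columns
    score: float
    strand: str


@dataclass(frozen=True)
class HitClassification:
    read_id: str
    label: str  # clean | possible_cross_contaminant | ambiguous | no_hit
    evidence: HitRecord | None


CLASS_LABELS = ("clean", "possible_cross_contaminant", "ambiguous", "no_hit")


def best_hit(
    read_bases: str,
    db: SectionDatabase,
    read_id: str = "",
    min_score: float = 40.0,
    max_candidates: int = 4,
    scheme: ScoreScheme = ScoreScheme(),
) -> HitRecord | None:
    """Single best local alignment of the read (both strands) over the database.

    Candidate entries are shortlisted by shared k-mers (all entries are
    scanned when the shortlist is empty or the database is small), then
    scored by local alignment.  Deterministic tie-break: higher score, then
    database entry order, then forward strand.  Returns None (no hit) when
    the best score is below ``min_score``.
    """
    rc = revcomp(read_bases)
    if len(db.entries) <= 32:
        cand = list(range(len(db.entries)))
    else:
        index = db.index()
        cand = sorted(set(index.candidates(read_bases, max_candidates))
                      | set(index.candidates(rc, max_candidates)))
        if not cand:
            cand = list(range(len(db.entries)))
    best: tuple[float, int, int, LocalHit] | None = None  # (-score, entry, strand_rank, hit)
    # Banded first pass; the rare read no candidate explains within the band
    # gets an unbounded rescan so weak local cores are still found.
    for max_div in (0.35, None):
        for c in cand:
            target = db.entries[c].seq
            for strand_rank, (strand, q) in enumerate((("+", read_bases), ("-", rc))):
                hit = local_align(q, target, scheme, max_divergence=max_div)
                if hit is None:
                    continue
                hit.strand = strand
                key = (-hit.score, c, strand_rank)
                if best is None or key < best[:3]:
                    best = (*key, hit)
        if best is not None:
            break
    if best is None or best[3].score < min_score:
        return None
    entry = db.entries[best[1]]
    hit = best[3]
    return HitRecord(
        read_id=read_id, section=entry.section, sample=entry.sample,
        locus=entry.locus, length=hit.columns, identity=hit.identity,
        score=hit.score, strand=hit.strand,
    )


def classify_read(
    hit: HitRecord | None,
    expected_section: str,
    read_id: str = "",
    min_identity: float = 0.95,
    min_length: int = 600,
    keep_low_identity: bool = False,
) -> HitClassification:
    """Apply the cross-contaminant rule to one read's best hit.

    clean: best hit in the expected section (any length/identity), or
    no_hit: no alignment (retained; the on-target mapping filters later).
    possible_cross_contaminant: wrong section, alignment longer than
    ``min_length`` and identity at least ``min_identity``.
    ambiguous: any other wrong-section hit -- shorter than or equal to
    ``min_length``, or long but below the identity floor (the conservative
    default; ``keep_low_identity=True`` instead keeps those long low-identity
    hits as clean).
    """
    rid = read_id or (hit.read_id if hit else "")
    if hit is None:
        return HitClassification(read_id=rid, label="no_hit", evidence=None)
    if hit.section == expected_section:
        return HitClassification(read_id=rid, label="clean", evidence=hit)
    if hit.length > min_length:
        if hit.identity >= min_identity:
            return HitClassification(
                read_id=rid, label="possible_cross_contaminant", evidence=hit
            )
        label = "clean" if keep_low_identity else "ambiguous"
        return HitClassification(read_id=rid, label=label, evidence=hit)
    return HitClassification(read_id=rid, label="ambiguous", evidence=hit)


def screen_reads(
    reads,
    db: SectionDatabase,
    expected_section: str,
    min_score: float = 40.0,
    **classify_kwargs,
) -> dict[str, HitClassification]:
    """best_hit + classify_read over a read set."""
    out = {}
    for read in reads:
        hit = best_hit(read.bases, db, read_id=read.read_id, min_score=min_score)
        out[read.read_id] = classify_read(
            hit, expected_section, read_id=read.read_id, **classify_kwargs
        )
    return out


@dataclass
class RemovalReport:
    counts: dict[str, int]
    total: int

    @property
    def contamination_percent(self) -> float:
        return 100.0 * self.counts.get("possible_cross_contaminant", 0) / self.total

    @property
    def ambiguous_percent(self) -> float:
        return 100.0 * self.counts.get("ambiguous", 0) / self.total


def remove_flagged(reads, classifications) -> tuple[list, RemovalReport]:
    """Drop possible_cross_contaminant and ambiguous reads (the conservative
    policy); clean and no_hit reads pass through.  Every read must have a
    classification."""
    reads = list(reads)
    counts = {label: 0 for label in CLASS_LABELS}
    kept = []
    for read in reads:
        cls = classifications.get(read.read_id)
        if cls is None:
            raise KeyError(f"read {read.read_id!r} has no classification")
        counts[cls.label] += 1
        if cls.label in ("clean", "no_hit"):
            kept.append(read)
    return kept, RemovalReport(counts=counts, total=len(reads))
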