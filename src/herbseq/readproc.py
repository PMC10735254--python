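"""Demultiplexing, flank trimming, exact-duplicate removal and chimera flagging.

These are deliberately simple, fully-specified equivalents of the adapter
trimmer, deduplicator and chimera screen used on the real data: barcode
identification uses the 12-nt GAT-<barcode>-GTG motif (and its reverse
complement at the 3' end), deduplication is exact-sequence collapse keeping
the first-seen read, and the chimera test asks whether splitting a read at
some breakpoint lets two distinct parents each explain their segment clearly
better than any single parent explains the whole read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import KmerIndex, infix_identity, revcomp
from .errors import ConfigError
from .records import ReadRecord


@dataclass(frozen=True)
class BarcodeMatch:
    sample: str
    strand: str          # '+' read as given, '-' matched on reverse complement
    start: int           # motif start offset on the oriented read
    mismatches: int


@dataclass
class DemuxResult:
    assigned: dict[str, list[ReadRecord]]
    unassigned: list[ReadRecord]
    matches: dict[str, BarcodeMatch] = field(default_factory=dict)

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())


def _sliding_mismatches(window: str, patterns: np.ndarray) -> np.ndarray:
    """Mismatch counts of every pattern at every offset of window.

    patterns: (n_patterns, 12) uint8.  Returns (n_patterns, n_offsets).
    """
    arr = np.frombuffer(window.encode(), dtype=np.uint8)
    m = patterns.shape[1]
    if arr.size < m:
        return np.empty((patterns.shape[0], 0), dtype=np.int64)
    view = np.lib.stride_tricks.sliding_window_view(arr, m)
    return (view[None, :, :] != patterns[:, None, :]).sum(axis=2)


def demultiplex(
    reads,
    scheme,
    max_mismatch: int = 1,
    search_window: int = 100,
) -> DemuxResult:
    """Assign reads to samples by their barcode motif and trim the flanks.

    The first ``search_window`` bases of the read and of its reverse
    complement are scanned for every sample's GAT-<barcode>-GTG motif; the
    single best match with at most ``max_mismatch`` substitutions wins, ties
    between different samples leave the read unassigned.  Scanning the
    reverse complement catches reverse reads (which start CAC-<barcode>-ATC
    as given).  Assigned reads are re-oriented to forward, the matched
    prefix is trimmed through the flank, and the sample's 3' tag
    (GAT-<rc barcode>-GTG) near the end is trimmed too.  Trimmed affixes are
    retained on the record so the operation is reversible.
    """
    samples = list(scheme.barcodes)
    if scheme.min_pairwise_distance() <= 2 * max_mismatch:
        raise ConfigError(
            f"barcode tags closer than {2 * max_mismatch + 1} mismatches cannot "
            f"be demultiplexed at max_mismatch={max_mismatch}"
        )
    tags = np.stack([
        np.frombuffer(scheme.tag(s).encode(), dtype=np.uint8) for s in samples
    ])
    out = DemuxResult(assigned={s: [] for s in samples}, unassigned=[])
    for read in reads:
        best: tuple[int, int, str, int] | None = None  # (mism, strand_idx, sample, start)
        tied = False
        for strand_idx, seq in enumerate((read.bases, revcomp(read.bases))):
            mm = _sliding_mismatches(seq[:search_window], tags)
            if mm.size == 0:
                continue
            for si, sample in enumerate(samples):
                pos = int(mm[si].argmin())
                val = int(mm[si, pos])
                cand = (val, strand_idx, sample, pos)
                if best is None or val < best[0]:
                    best, tied = cand, False
                elif val == best[0] and sample != best[2]:
                    tied = True
        if best is None or best[0] > max_mismatch or tied:
            out.unassigned.append(read)
            continue
        mism, strand_idx, sample, start = best
        if strand_idx == 0:
            bases, quals = read.bases, read.qualities
        else:
            bases, quals = revcomp(read.bases), read.qualities[::-1]
        tag_len = tags.shape[1]
        cut = start + tag_len
        prefix = bases[:cut]
        bases_t, quals_t = bases[cut:], quals[cut:]
        # Trim the reverse-complement motif near the 3' end, if present.
        suffix = ""
        tail_from = max(len(bases_t) - (search_window + tag_len), 0)
        tail = bases_t[tail_from:]
        rc_tag = np.frombuffer(scheme.tag_end(sample).encode(), dtype=np.uint8)[None, :]
        mm_tail = _sliding_mismatches(tail, rc_tag)
        if mm_tail.size:
            pos = int(mm_tail[0].argmin())
            if int(mm_tail[0, pos]) <= max_mismatch:
                cut3 = tail_from + pos
                suffix = bases_t[cut3:]
                bases_t, quals_t = bases_t[:cut3], quals_t[:cut3]
        rec = read.copy(
            bases=bases_t,
            qualities=quals_t,
            sample=sample,
            orientation="forward" if strand_idx == 0 else "reverse",
            trimmed_prefix=prefix,
            trimmed_suffix=suffix,
        )
        out.assigned[sample].append(rec)
        out.matches[read.read_id] = BarcodeMatch(
            sample=sample,
            strand="+" if strand_idx == 0 else "-",
            start=start,
            mismatches=mism,
        )
    return out


def reattach_tag(read: ReadRecord) -> str:
    """Reconstruct the oriented pre-trim sequence of a demultiplexed read."""
    return read.trimmed_prefix + read.bases + read.trimmed_suffix


def remove_duplicates(reads, k: int = 31) -> tuple[list[ReadRecord], dict[str, str | None]]:
    """Collapse exact-sequence duplicates, keeping the first-seen read.

    With maximum edits 0 this is exact-match deduplication keyed by the read
    sequence; ``k`` is only a seeding/bucketing parameter in the tool being
    emulated and does not change the result here.  Returns the kept reads and
    a map read_id -> id of the retained representative (None for kept reads).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kept: list[ReadRecord] = []
    flags: dict[str, str | None] = {}
    seen: dict[str, str] = {}
    for read in reads:
        first = seen.get(read.bases)
        if first is None:
            seen[read.bases] = read.read_id
            flags[read.read_id] = None
            kept.append(read)
        else:
            flags[read.read_id] = first
    return kept, flags


@dataclass(frozen=True)
class ChimeraEvidence:
    breakpoint: int
    parent_a: str
    parent_b: str
    identity_a: float
    identity_b: float
    whole_identity: float


def flag_chimeras(
    reads,
    reference_pool,
    min_segment: int = 300,
    improvement_margin: float = 0.02,
    breakpoint_stride: int = 50,
    max_candidates: int = 6,
) -> dict[str, ChimeraEvidence | None]:
    """Two-parent breakpoint-improvement chimera test.

    A read is flagged when some breakpoint splits it into two segments (each
    >= ``min_segment``) whose best-parent identities both exceed the whole
    read's best single-parent identity by at least ``improvement_margin``,
    with the two parents distinct.  ``reference_pool`` is a list of
    (name, sequence) parents -- typically the reference database, or the
    read set itself for a de-novo screen.

    Candidate parents are shortlisted by shared k-mers; breakpoints are
    scanned on a ``breakpoint_stride`` grid.  Reads whose best whole-read
    identity is already within ``improvement_margin`` of 1 cannot be
    improved upon and are cleared without a scan.
    """
    if not reference_pool:
        raise ValueError("reference pool must be non-empty")
    names = [n for n, _ in reference_pool]
    seqs = [s for _, s in reference_pool]
    index = KmerIndex(seqs)
    flags: dict[str, ChimeraEvidence | None] = {}
    for read in reads:
        # Candidate parents from the whole read plus each end: a chimera's
        # shorter parent can be crowded out of the whole-read shortlist, but
        # a terminal window at least min_segment long is pure parent.
        cand = sorted(
            set(index.candidates(read.bases, max_n=max_candidates))
            | set(index.candidates(read.bases[:min_segment], max_n=max_candidates // 2 or 1))
            | set(index.candidates(read.bases[-min_segment:], max_n=max_candidates // 2 or 1))
        )
        if not cand:
            cand = list(range(len(seqs)))
        # Exclude the read itself when screening against the read set.
        cand = [c for c in cand if names[c] != read.read_id]
        if not cand:
            flags[read.read_id] = None
            continue
        whole = [(infix_identity(read.bases, seqs[c]), c) for c in cand]
        whole_best, _ = max(whole)
        flags[read.read_id] = None
        if whole_best + improvement_margin > 1.0:
            continue
        L = len(read.bases)
        breakpoints = range(min_segment, L - min_segment + 1, breakpoint_stride)
        best_ev: ChimeraEvidence | None = None
        for b in breakpoints:
            left, right = read.bases[:b], read.bases[b:]
            id_a, pa = max((infix_identity(left, seqs[c]), c) for c in cand)
            id_b, pb = max(
                (infix_identity(right, seqs[c]), c) for c in cand if c != pa
            ) if len(cand) > 1 else (0.0, None)
            if pb is not None and id_a >= whole_best + improvement_margin and \
               id_b >= whole_best + improvement_margin:
                ev = ChimeraEvidence(
                    breakpoint=b, parent_a=names[pa], parent_b=names[pb],
                    identity_a=id_a, identity_b=id_b, whole_identity=whole_best,
                )
                # Keep the best-supported breakpoint (highest weaker-segment
                # identity), not the first passing one.
                if best_ev is None or min(ev.identity_a, ev.identity_b) > \
                   min(best_ev.identity_a, best_ev.identity_b):
                    best_ev = ev
        flags[read.read_id] = best_ev
    return flags
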