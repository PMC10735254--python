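"""De-novo reference building, iterative mapping and on-target statistics.

The analysis defines its on-target reads operationally: reads are assembled
de novo into per-sample reference contigs, contigs are matched to the target
loci, and the cleaned reads are then mapped iteratively against those
references (consensus rebuilt each round, up to 25 rounds); whatever maps at
the end is on-target.  The assembler here is a deterministic greedy
overlap-consensus layout and the mapper a per-read best-placement aligner --
documented, pluggable stand-ins for the production assemblers whose decision
rules (overlap/identity thresholds, iteration cap, majority consensus) are
what matters for the statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._align import LocalHit, local_align
from .records import ReadRecord

_BASE_ORDER = "ACGT"


@dataclass
class ReferenceContig:
    sample: str
    contig_id: str
    consensus: str
    locus: str | None = None
    n_reads: int = 0


@dataclass(frozen=True)
class MappingConfig:
    """Iterative-mapping parameters (25 medium-sensitivity rounds)."""

    iterations: int = 25
    min_identity: float = 0.85
    min_overlap: int = 100
    allow_extension: bool = True

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class Placement:
    """One read's accepted placement on a reference."""

    read_id: str
    ref_index: int
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    ops: list[tuple[str, int]]
    identity: float
    columns: int
    score: float
    left_ext: int = 0   # read bases protruding past the reference 5' end
    right_ext: int = 0


def _placement_from_hit(
    read: ReadRecord, hit: LocalHit, ref_index: int, ref_len: int
) -> Placement:
    left_ext = hit.query_start if hit.target_start == 0 else 0
    right_ext = (len(read.bases) - hit.query_end) if hit.target_end == ref_len else 0
    return Placement(
        read_id=read.read_id, ref_index=ref_index,
        ref_start=hit.target_start, ref_end=hit.target_end,
        read_start=hit.query_start, read_end=hit.query_end,
        ops=hit.ops or [], identity=hit.identity, columns=hit.columns,
        score=hit.score, left_ext=left_ext, right_ext=right_ext,
    )


def _snap_to_ends(read_bases: str, ref: str, hit: LocalHit, cap: int = 100) -> LocalHit:
    """Extend a local hit diagonally to the reference boundaries.

    A dovetailing read can have part of its true overlap swallowed by a
    co-optimal gap placement in the underlying edit path, leaving the
    alignment stopping just short of the reference end and masking the
    overhang.  When the hit ends within ``cap`` columns of a reference
    boundary and the read has enough leftover sequence, the gap-free
    diagonal continuation is appended (exact for substitution-only reads);
    the segment must look like sequence (>= 50 % identity) to be accepted.
    """
    def diag(q_from: int, t_from: int, n: int) -> tuple[list[tuple[str, int]], int]:
        ops: list[tuple[str, int]] = []
        matches = 0
        for i in range(n):
            op = "=" if read_bases[q_from + i] == ref[t_from + i] else "X"
            if op == "=":
                matches += 1
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + 1)
            else:
                ops.append((op, 1))
        return ops, matches

    t0, t1 = hit.target_start, hit.target_end
    if 0 < t0 <= cap and hit.query_start >= t0:
        ops, matches = diag(hit.query_start - t0, 0, t0)
        if matches >= 0.5 * t0:
            hit.ops = ops + (hit.ops or [])
            hit.matches += matches
            hit.columns += t0
            hit.score += 2.0 * matches - 3.0 * (t0 - matches)
            hit.query_start -= t0
            hit.target_start = 0
    tail = len(ref) - t1
    if 0 < tail <= cap and len(read_bases) - hit.query_end >= tail:
        ops, matches = diag(hit.query_end, t1, tail)
        if matches >= 0.5 * tail:
            hit.ops = (hit.ops or []) + ops
            hit.matches += matches
            hit.columns += tail
            hit.score += 2.0 * matches - 3.0 * (tail - matches)
            hit.query_end += tail
            hit.target_end = len(ref)
    return hit


def _diagonal_overlap(read_bases: str, ref: str, k: int = 14) -> LocalHit | None:
    """Gap-free dovetail overlap via the modal shared-k-mer diagonal.

    A short dovetail overlap is invisible to a unit-cost edit aligner (the
    cheapest way to absorb a long overhang is to smear the query across the
    reference), so overlaps are recovered directly: shared k-mers vote for a
    diagonal, and the full gap-free overlap run along the winning diagonal
    is scored.  Exact for substitution-only overlaps.
    """
    ref_kmers: dict[str, int] = {}
    for j in range(len(ref) - k + 1):
        ref_kmers.setdefault(ref[j : j + k], j)
    diagonals: Counter[int] = Counter()
    for i in range(0, max(len(read_bases) - k + 1, 0), 2):
        j = ref_kmers.get(read_bases[i : i + k])
        if j is not None:
            diagonals[j - i] += 1
    if not diagonals:
        return None
    d = sorted(diagonals.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
    q0 = max(0, -d)
    q1 = min(len(read_bases), len(ref) - d)
    if q1 - q0 < k:
        return None
    a = np.frombuffer(read_bases[q0:q1].encode(), dtype=np.uint8)
    b = np.frombuffer(ref[q0 + d : q1 + d].encode(), dtype=np.uint8)
    eq = a == b
    matches = int(eq.sum())
    cols = q1 - q0
    ops: list[tuple[str, int]] = []
    run_op, run_len = None, 0
    for is_eq in eq:
        op = "=" if is_eq else "X"
        if op == run_op:
            run_len += 1
        else:
            if run_op is not None:
                ops.append((run_op, run_len))
            run_op, run_len = op, 1
    ops.append((run_op, run_len))
    return LocalHit(
        score=2.0 * matches - 3.0 * (cols - matches),
        matches=matches, columns=cols,
        query_start=q0, query_end=q1,
        target_start=q0 + d, target_end=q1 + d,
        ops=ops,
    )


def place_read(
    read: ReadRecord,
    ref: str,
    ref_index: int,
    min_identity: float,
    min_overlap: int,
) -> Placement | None:
    """Best placement of a read on one reference, or None.

    Accepts the alignment when its identity clears ``min_identity`` and the
    aligned span reaches ``min_overlap`` columns (or ninety percent of the
    read, whichever is less, so short reads can still map to a reference
    they are fully contained in).  Contained reads are placed by the edit
    aligner; dovetail overlaps the edit aligner cannot see are rescued by
    the shared-k-mer diagonal.
    """
    hit = local_align(read.bases, ref, max_divergence=0.35)
    if hit is not None:
        hit = _snap_to_ends(read.bases, ref, hit)
    need = min(min_overlap, max(int(0.9 * len(read.bases)), 1))
    if hit is None or hit.identity < min_identity or hit.columns < need:
        rescue = _diagonal_overlap(read.bases, ref)
        if rescue is not None:
            rescue = _snap_to_ends(read.bases, ref, rescue)
        hit = rescue
    if hit is None or hit.identity < min_identity or hit.columns < need:
        return None
    return _placement_from_hit(read, hit, ref_index, len(ref))


class _KmerLookup:
    """Append-only k-mer -> target-index map for candidate shortlisting.

    Targets may grow (backbone extension): ``extend`` re-indexes a target's
    new sequence under the same index, deduplicated per target.
    """

    def __init__(self, k: int = 14, stride: int = 4):
        self.k = k
        self.stride = stride
        self._map: dict[str, list[int]] = {}
        self._seen: list[set] = []
        self.n = 0

    def add(self, seq: str) -> int:
        idx = self.n
        self.n += 1
        self._seen.append(set())
        self.extend(idx, seq)
        return idx

    def extend(self, idx: int, seq: str) -> None:
        seen = self._seen[idx]
        for i in range(0, max(len(seq) - self.k + 1, 0), self.stride):
            kmer = seq[i : i + self.k]
            if kmer not in seen:
                seen.add(kmer)
                self._map.setdefault(kmer, []).append(idx)

    def candidates(self, seq: str, max_n: int = 3) -> list[int]:
        # Query stride 1: the target side is strided, so a strided query
        # would alias against the target phase and miss hits.
        counts: Counter[int] = Counter()
        for i in range(0, max(len(seq) - self.k + 1, 0), 1):
            hit = self._map.get(seq[i : i + self.k])
            if hit:
                counts.update(hit)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [idx for idx, _ in ranked[:max_n]]


def _vote(
    consensus: str,
    placements: list[tuple[ReadRecord, Placement]],
    allow_extension: bool,
) -> str:
    """Majority-vote consensus over the placed reads; columns with no votes
    keep the previous consensus base.  Reads protruding past either end
    extend the consensus when extension is enabled."""
    L = len(consensus)
    votes = np.zeros((L, 4), dtype=np.int32)
    left_votes: dict[int, Counter] = {}
    right_votes: dict[int, Counter] = {}
    for read, pl in placements:
        q, t = pl.read_start, pl.ref_start
        for op, n in pl.ops:
            if op in ("=", "X"):
                for i in range(n):
                    base = read.bases[q + i]
                    bi = _BASE_ORDER.find(base)
                    if bi >= 0:
                        votes[t + i, bi] += 1
                q += n
                t += n
            elif op == "I":
                q += n
            else:  # D
                t += n
        if allow_extension and pl.left_ext:
            seg = read.bases[pl.read_start - pl.left_ext : pl.read_start]
            for off, base in enumerate(seg):
                left_votes.setdefault(off - len(seg), Counter())[base] += 1
        if allow_extension and pl.right_ext:
            seg = read.bases[pl.read_end : pl.read_end + pl.right_ext]
            for off, base in enumerate(seg):
                right_votes.setdefault(L + off, Counter())[base] += 1

    core = list(consensus)
    covered = votes.sum(axis=1) > 0
    winners = votes.argmax(axis=1)
    for pos in np.flatnonzero(covered):
        core[pos] = _BASE_ORDER[winners[pos]]

    def majority(counter: Counter) -> str:
        return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]

    left = "".join(
        majority(left_votes[pos]) for pos in sorted(left_votes)
    )
    right = "".join(
        majority(right_votes[pos]) for pos in sorted(right_votes)
    )
    return left + "".join(core) + right


def build_references(
    reads: list[ReadRecord],
    min_overlap: int = 100,
    min_identity: float = 0.85,
    sample: str = "",
) -> list[ReferenceContig]:
    """Greedy overlap-layout-consensus assembly into per-sample references.

    Reads are taken longest-first; each read joins the best existing cluster
    it overlaps by >= ``min_overlap`` columns at >= ``min_identity``
    (extending the cluster backbone when it protrudes) or founds a new
    cluster.  Cluster consensus is a majority vote of the members against
    the final backbone.  Singleton clusters become single-read contigs.
    """
    if not reads:
        raise ValueError("cannot assemble an empty read set")
    ordered = sorted(reads, key=lambda r: (-len(r.bases), r.read_id))
    lookup = _KmerLookup()
    backbones: list[str] = []
    members: list[list[ReadRecord]] = []
    for read in ordered:
        cand = lookup.candidates(read.bases)
        best: tuple[float, int, Placement] | None = None
        for c in cand:
            pl = place_read(read, backbones[c], c, min_identity, min_overlap)
            if pl is not None and (best is None or pl.score > best[0]):
                best = (pl.score, c, pl)
        if best is None:
            idx = lookup.add(read.bases)
            backbones.append(read.bases)
            members.append([read])
        else:
            _, c, pl = best
            members[c].append(read)
            if pl.left_ext or pl.right_ext:
                left = read.bases[pl.read_start - pl.left_ext : pl.read_start]
                right = read.bases[pl.read_end : pl.read_end + pl.right_ext]
                backbones[c] = left + backbones[c] + right
                lookup.extend(c, backbones[c])

    contigs = []
    for i, (backbone, group) in enumerate(zip(backbones, members)):
        placements = []
        for read in group:
            pl = place_read(read, backbone, i, min_identity, min_overlap)
            if pl is not None:
                placements.append((read, pl))
        consensus = _vote(backbone, placements, allow_extension=False) if placements else backbone
        contigs.append(
            ReferenceContig(
                sample=sample, contig_id=f"{sample or 'sample'}_ctg{i + 1:03d}",
                consensus=consensus, n_reads=len(group),
            )
        )
    return contigs


def assign_loci(
    contigs: list[ReferenceContig],
    locus_sequences: dict[str, str],
    min_identity: float = 0.8,
    min_columns: int = 100,
) -> list[ReferenceContig]:
    """Label each contig with its best-matching target locus (in place).

    The contig is aligned locally against every locus (both strands); the
    top-scoring locus wins if its identity clears ``min_identity`` over at
    least ``min_columns`` columns, otherwise the contig stays unassigned.
    """
    from ._align import local_align_both_strands

    items = list(locus_sequences.items())
    for contig in contigs:
        best: tuple[float, str] | None = None
        for lid, seq in items:
            hit = local_align_both_strands(contig.consensus, seq)
            if hit is None or hit.identity < min_identity or hit.columns < min_columns:
                continue
            if best is None or hit.score > best[0]:
                best = (hit.score, lid)
        contig.locus = best[1] if best else None
    return contigs


@dataclass
class MappingResult:
    references: list[ReferenceContig]
    placements: dict[str, Placement]          # read_id -> final placement
    reads: dict[str, ReadRecord]
    n_iterations: int

    @property
    def on_target_ids(self) -> set[str]:
        return set(self.placements)

    def reads_for_ref(self, ref_index: int) -> list[str]:
        return [rid for rid, pl in self.placements.items() if pl.ref_index == ref_index]


def iterative_map(
    reads: list[ReadRecord],
    references: list[ReferenceContig],
    config: MappingConfig = MappingConfig(),
) -> MappingResult:
    """Map all reads to the references, rebuild the majority consensus, and
    repeat until the mapped set stabilizes or the iteration cap is reached.
    The reads mapped after the final round are the on-target set."""
    if not references:
        raise ValueError("references must be non-empty")
    refs = [r.consensus for r in references]
    read_list = sorted(reads, key=lambda r: r.read_id)
    prev_mapped: set[str] | None = None
    placements: dict[str, Placement] = {}
    iteration = 0
    for iteration in range(1, config.iterations + 1):
        lookup = _KmerLookup()
        for seq in refs:
            lookup.add(seq)
        placements = {}
        for read in read_list:
            cand = lookup.candidates(read.bases) or range(len(refs))
            best: Placement | None = None
            for c in cand:
                pl = place_read(read, refs[c], c, config.min_identity, config.min_overlap)
                if pl is None:
                    continue
                if best is None or (pl.score, -pl.ref_index) > (best.score, -best.ref_index):
                    best = pl
            if best is not None:
                placements[read.read_id] = best
        mapped = set(placements)
        by_ref: dict[int, list] = {}
        reads_by_id = {r.read_id: r for r in read_list}
        for rid, pl in placements.items():
            by_ref.setdefault(pl.ref_index, []).append((reads_by_id[rid], pl))
        new_refs = list(refs)
        for ri, group in by_ref.items():
            new_refs[ri] = _vote(refs[ri], group, config.allow_extension)
        if mapped == prev_mapped and new_refs == refs:
            break
        refs = new_refs
        prev_mapped = mapped

    # Final pass against the settled consensus so placements are consistent.
    lookup = _KmerLookup()
    for seq in refs:
        lookup.add(seq)
    placements = {}
    reads_by_id = {r.read_id: r for r in read_list}
    for read in read_list:
        cand = lookup.candidates(read.bases) or range(len(refs))
        best = None
        for c in cand:
            pl = place_read(read, refs[c], c, config.min_identity, config.min_overlap)
            if pl is None:
                continue
            if best is None or (pl.score, -pl.ref_index) > (best.score, -best.ref_index):
                best = pl
        if best is not None:
            placements[read.read_id] = best

    out_refs = []
    for contig, seq in zip(references, refs):
        out_refs.append(
            ReferenceContig(
                sample=contig.sample, contig_id=contig.contig_id,
                consensus=seq, locus=contig.locus, n_reads=contig.n_reads,
            )
        )
    for ri, contig in enumerate(out_refs):
        contig.n_reads = sum(1 for pl in placements.values() if pl.ref_index == ri)
    return MappingResult(
        references=out_refs, placements=placements,
        reads=reads_by_id, n_iterations=iteration,
    )


@dataclass
class AssemblyStats:
    """Per-sample on-target sequencing-success metrics."""

    sample: str
    input_reads: int
    on_target_reads: int
    on_target_ratio: float          # percent of input reads that mapped
    loci_recovered: int
    n_target_loci: int
    mean_depth: float               # aligned bases / total contig length
    coverage_by_locus: dict[str, float]
    depth_by_locus: dict[str, float]
    reads_by_locus: dict[str, int]
    total_contig_length: int
    read_length_mean: float
    read_length_median: float
    reads_gt_1kb: int


def _depth_array(ref_len: int, group: list[tuple[ReadRecord, Placement]]) -> np.ndarray:
    depth = np.zeros(ref_len, dtype=np.int32)
    for _, pl in group:
        t = pl.ref_start
        for op, n in pl.ops:
            if op in ("=", "X"):
                depth[t : t + n] += 1
                t += n
            elif op == "D":
                t += n
    return depth


def compute_stats(
    result: MappingResult,
    input_read_count: int,
    target_loci,
    sample: str = "",
) -> AssemblyStats:
    """Depth, coverage and recovery metrics from the final mapping.

    mean depth = total aligned bases / reference length; coverage = percent
    of reference positions with depth >= 1; a locus is recovered when at
    least one read maps to a contig assigned to it; on-target ratio =
    mapped / input reads x 100.
    """
    locus_ids = (
        [lid for lid, _ in target_loci.loci]
        if hasattr(target_loci, "loci")
        else list(target_loci)
    )
    by_ref: dict[int, list] = {}
    for rid, pl in result.placements.items():
        by_ref.setdefault(pl.ref_index, []).append((result.reads[rid], pl))

    # per-locus accumulators: aligned bases, covered positions, length, reads
    acc: dict[str, list[float]] = {}
    nreads: dict[str, int] = {}
    total_len = 0
    total_aligned = 0
    for ri, contig in enumerate(result.references):
        group = by_ref.get(ri, [])
        if not group:
            continue
        depth = _depth_array(len(contig.consensus), group)
        total_len += len(contig.consensus)
        total_aligned += int(depth.sum())
        locus = contig.locus
        if locus is not None:
            a = acc.setdefault(locus, [0.0, 0.0, 0.0])
            a[0] += float(depth.sum())
            a[1] += float((depth > 0).sum())
            a[2] += float(len(contig.consensus))
            nreads[locus] = nreads.get(locus, 0) + len(group)
    coverage_by_locus = {
        locus: 100.0 * covered / length
        for locus, (_, covered, length) in acc.items()
        if length > 0
    }
    depth_by_locus = {
        locus: aligned / length
        for locus, (aligned, _, length) in acc.items()
        if length > 0
    }

    mapped_lengths = [len(result.reads[rid].bases) for rid in result.placements]
    on_target = len(result.placements)
    recovered = sum(1 for lid in locus_ids if nreads.get(lid, 0) > 0)
    return AssemblyStats(
        sample=sample,
        input_reads=input_read_count,
        on_target_reads=on_target,
        on_target_ratio=(100.0 * on_target / input_read_count) if input_read_count else 0.0,
        loci_recovered=recovered,
        n_target_loci=len(locus_ids),
        mean_depth=(total_aligned / total_len) if total_len else 0.0,
        coverage_by_locus=coverage_by_locus,
        depth_by_locus=depth_by_locus,
        reads_by_locus=nreads,
        total_contig_length=total_len,
        read_length_mean=float(np.mean(mapped_lengths)) if mapped_lengths else 0.0,
        read_length_median=float(np.median(mapped_lengths)) if mapped_lengths else 0.0,
        reads_gt_1kb=sum(1 for L in mapped_lengths if L > 1000),
    )


def write_sam(result: MappingResult, path, sample: str = "") -> None:
    """Emit the final placements as SAM with one @SQ line per reference."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig in result.references:
            fh.write(f"@SQ\tSN:{contig.contig_id}\tLN:{len(contig.consensus)}\n")
        for rid in sorted(result.placements):
            pl = result.placements[rid]
            read = result.reads[rid]
            contig = result.references[pl.ref_index]
            cigar = []
            if pl.read_start:
                cigar.append(f"{pl.read_start}S")
            for op, n in pl.ops:
                cigar.append(f"{n}{'M' if op in '=X' else op}")
            tail = len(read.bases) - pl.read_end
            if tail:
                cigar.append(f"{tail}S")
            fh.write(
                "\t".join(
                    [
                        rid, "0", contig.contig_id, str(pl.ref_start + 1), "60",
                        "".join(cigar), "*", "0", "0", read.bases, read.qualities,
                    ]
                )
                + "\n"
            )
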