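"""Shared pairwise-alignment primitives.

All read-vs-reference comparisons in the package go through this module.  The
workhorse is edlib's banded semi-global ("infix") aligner, which places a full
query inside a target.  For local (Smith-Waterman-like) scoring the infix
alignment path is rescored with an affine gap scheme and trimmed to its
maximum-scoring sub-path, so terminal junk on either sequence never drags the
reported identity down.  Gap columns count as mismatches in every identity
reported here.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def expand_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse an edlib-style cigar into (op, length) runs.

    Ops: '=' match, 'X' mismatch, 'I' consumes query only, 'D' consumes
    target only (edlib convention, query vs target).
    """
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


@dataclass(frozen=True)
class ScoreScheme:
    """blastn-like scoring used for local hit ranking."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass
class LocalHit:
    """A scored, locally-trimmed alignment of a query against a target."""

    score: float
    matches: int
    columns: int        # alignment length, gap columns included
    query_start: int    # 0-based, on the query as given
    query_end: int      # exclusive
    target_start: int
    target_end: int
    strand: str = "+"
    ops: list[tuple[str, int]] | None = None  # ops covering the trimmed region

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _edlib_infix(query: str, target: str, k: int = -1):
    res = edlib.align(query, target, mode="HW", task="path", k=k)
    if res["editDistance"] < 0 or res["cigar"] is None:
        return None
    return res


def infix_identity(query: str, target: str, max_divergence: float = 0.6) -> float:
    """Identity of the best whole-query placement inside target (0 if none).

    Distance-only edlib call with a banded search capped at
    ``max_divergence`` x query length; identity is 1 - distance / |query|,
    a tight lower bound on the column-wise identity for near-substring
    queries (placements worse than the cap report 0).
    """
    if not query:
        return 0.0
    k = max(int(max_divergence * len(query)), 8)
    res = edlib.align(query, target, mode="HW", task="distance", k=k)
    dist = res["editDistance"]
    if dist < 0:
        return 0.0
    return max(1.0 - dist / len(query), 0.0)


def local_align(
    query: str,
    target: str,
    scheme: ScoreScheme = ScoreScheme(),
    max_divergence: float | None = None,
) -> LocalHit | None:
    """Best locally-trimmed alignment of query against target (forward strand).

    The full query is first placed inside the target with edlib; the aligned
    path is then rescored column-by-column with ``scheme`` and trimmed to the
    maximum-scoring contiguous sub-path (gap runs are kept atomic so affine
    costs stay exact).  The trimmed path is itself a valid local alignment,
    so its score never exceeds the Smith-Waterman optimum; for noisy
    substrings at the low divergences the pipeline operates at it equals it
    (tests verify both against a brute-force aligner).
    """
    if not query or not target:
        return None
    k = -1 if max_divergence is None else max(int(max_divergence * len(query)), 16)
    res = _edlib_infix(query, target, k=k)
    if res is None:
        return None
    t_start = res["locations"][0][0]
    ops = expand_cigar(res["cigar"])

    # Atomic events, one per cigar run: every run scores uniformly positive
    # ('=') or negative (X/I/D), so the maximum-scoring sub-path always
    # starts and ends on a run boundary and run-level Kadane is exact.
    # Each event: (score, d_query, d_target, d_columns, d_matches)
    events: list[tuple[float, int, int, int, int]] = []
    for op, n in ops:
        if op == "=":
            events.append((scheme.match * n, n, n, n, n))
        elif op == "X":
            events.append((scheme.mismatch * n, n, n, n, 0))
        elif op == "I":
            events.append((scheme.gap_open + scheme.gap_extend * (n - 1), n, 0, n, 0))
        elif op == "D":
            events.append((scheme.gap_open + scheme.gap_extend * (n - 1), 0, n, n, 0))

    # Kadane over events, tracking coordinates.
    best = (0.0, -1, -1)  # (score, start_event, end_event_exclusive)
    run_score, run_start = 0.0, 0
    for i, ev in enumerate(events):
        if run_score <= 0:
            run_score, run_start = ev[0], i
        else:
            run_score += ev[0]
        if run_score > best[0]:
            best = (run_score, run_start, i + 1)
    if best[1] < 0:
        return None
    score, s, e = best

    q_pos, t_pos = 0, t_start
    q0 = t0 = None
    matches = columns = 0
    trimmed_ops: list[tuple[str, int]] = []
    for i, (ev_score, dq, dt, dc, dm) in enumerate(events):
        if i == s:
            q0, t0 = q_pos, t_pos
        if s <= i < e:
            matches += dm
            columns += dc
            if dq and dt:
                trimmed_ops.append(("=" if dm else "X", dq))
            elif dq:
                trimmed_ops.append(("I", dq))
            else:
                trimmed_ops.append(("D", dt))
        q_pos += dq
        t_pos += dt
        if i == e - 1:
            q1, t1 = q_pos, t_pos
    return LocalHit(
        score=score, matches=matches, columns=columns,
        query_start=q0, query_end=q1, target_start=t0, target_end=t1,
        ops=trimmed_ops,
    )


def local_align_both_strands(
    query: str, target: str, scheme: ScoreScheme = ScoreScheme()
) -> LocalHit | None:
    """Best local hit over both query strands; coordinates refer to the
    strand actually aligned (``strand`` records which one)."""
    fwd = local_align(query, target, scheme)
    rev = local_align(revcomp(query), target, scheme)
    if rev is not None:
        rev.strand = "-"
    if fwd is None:
        return rev
    if rev is None or fwd.score >= rev.score:
        return fwd
    return rev


class KmerIndex:
    """Minimal k-mer hit counter used to shortlist alignment candidates.

    Exact k-mer sharing is a crude but effective prefilter at the divergences
    this package deals with (<= ~10 %).  ``candidates`` returns target indices
    ranked by shared-k-mer count; callers fall back to scanning everything
    when the index returns nothing.
    """

    def __init__(self, targets: list[str], k: int = 14, stride: int = 4):
        self.k = k
        self.stride = stride
        self.n_targets = len(targets)
        self._index: dict[str, list[int]] = {}
        for idx, seq in enumerate(targets):
            seen = set()
            for i in range(0, max(len(seq) - k + 1, 0), stride):
                kmer = seq[i : i + k]
                if kmer not in seen:
                    seen.add(kmer)
                    self._index.setdefault(kmer, []).append(idx)

    def candidates(self, seq: str, max_n: int = 4, query_stride: int = 1) -> list[int]:
        # Query stride must be 1: the target index is strided, so sampling the
        # query too would alias against the target phase and miss every hit.
        k = self.k
        counts: Counter[int] = Counter()
        for i in range(0, max(len(seq) - k + 1, 0), query_stride):
            hit = self._index.get(seq[i : i + k])
            if hit:
                counts.update(hit)
        # Deterministic: by hit count desc, then target order.
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [idx for idx, _ in ranked[:max_n]]
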