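"""Terminal deamination profiling from mapped reads.

Post-mortem cytosine deamination shows up as C->T mismatches at the 5' end of
reads and the complementary G->A at the 3' end -- the classical degraded-DNA
authentication signal.  This module tallies those mismatch frequencies over
the first/last 25 aligned positions of each read against its reference,
strand-aware, with per-position denominators (reference C respectively G
counts) so low-coverage positions are reported as missing rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WINDOW = 25
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class DamageProfile:
    """Positional C->T (5') and G->A (3') mismatch counts for one sample.

    ``counts_5p``/``counts_3p`` are (25, 5) matrices over read-base
    categories A, C, G, T, other at reference-C respectively reference-G
    sites; frequencies divide by the per-position denominator and are NaN
    where the denominator is zero.
    """

    sample: str
    counts_5p: np.ndarray
    counts_3p: np.ndarray

    @property
    def denom_5p(self) -> np.ndarray:
        return self.counts_5p.sum(axis=1)

    @property
    def denom_3p(self) -> np.ndarray:
        return self.counts_3p.sum(axis=1)

    @property
    def freq_5p(self) -> np.ndarray:
        """C->T frequency by 5' position (NaN where no reference C seen)."""
        denom = self.denom_5p.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.counts_5p[:, _BASE_IDX["T"]] / denom, np.nan)

    @property
    def freq_3p(self) -> np.ndarray:
        """G->A frequency by 3' position (NaN where no reference G seen)."""
        denom = self.denom_3p.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.counts_3p[:, _BASE_IDX["A"]] / denom, np.nan)

    def low_coverage_positions(self, min_denominator: int = 10) -> dict[str, list[int]]:
        """Positions whose frequency rests on fewer than ``min_denominator``
        reference bases; flagged rather than interpreted."""
        return {
            "5p": [int(i) for i in np.flatnonzero(self.denom_5p < min_denominator)],
            "3p": [int(i) for i in np.flatnonzero(self.denom_3p < min_denominator)],
        }

    def is_empty(self) -> bool:
        return int(self.denom_5p.sum() + self.denom_3p.sum()) == 0

    def to_table(self):
        import pandas as pd

        rows = []
        for i in range(WINDOW):
            rows.append(("5p", i, "C>T", self.freq_5p[i], int(self.denom_5p[i])))
            rows.append(("3p", i, "G>A", self.freq_3p[i], int(self.denom_3p[i])))
        return pd.DataFrame(rows, columns=["end", "position", "pattern", "frequency", "denominator"])


def error_floor(error_rate: float) -> float:
    """Expected mismatch floor from sequencing error alone: a reference C is
    misread as T in one of the three error outcomes."""
    return error_rate / 3.0


@dataclass(frozen=True)
class AlignedRead:
    """Per-base read/reference correspondence for one mapped read.

    ``pairs`` are (read_pos, ref_pos) for aligned (non-gap) columns, with
    read_pos on the read as stored; ``strand`` '-' means the stored read is
    the reverse complement of the sequenced molecule, so terminal windows
    and patterns are complemented internally.
    """

    read_seq: str
    ref_id: str
    pairs: tuple
    strand: str = "+"


def aligned_pairs_from_ops(ops, read_start: int, ref_start: int) -> tuple:
    """Expand edlib-style ops into (read_pos, ref_pos) match columns."""
    q, t = read_start, ref_start
    out = []
    for op, n in ops:
        if op in ("=", "X", "M"):
            out.extend((q + i, t + i) for i in range(n))
            q += n
            t += n
        elif op == "I":
            q += n
        else:
            t += n
    return tuple(out)


def profile_damage(
    alignments, references: dict[str, str], sample: str = ""
) -> DamageProfile:
    """Tally terminal C->T / G->A mismatch frequencies over mapped reads.

    ``alignments`` is an iterable of :class:`AlignedRead`; ``references``
    maps ref_id to sequence.  Position i (0-based) from the molecule's 5'
    end contributes to the 5' C->T profile when the reference base is C;
    position j from the 3' end to the G->A profile when the reference is G.
    Reads mapped on the reverse strand contribute through the complementary
    pattern.  No alignments yield an empty (all-zero) profile.
    """
    counts_5p = np.zeros((WINDOW, 5), dtype=np.int64)
    counts_3p = np.zeros((WINDOW, 5), dtype=np.int64)
    for aln in alignments:
        ref = references[aln.ref_id]
        n = len(aln.read_seq)
        for q, t in aln.pairs:
            read_base = aln.read_seq[q]
            ref_base = ref[t]
            if aln.strand == "-":
                # molecule coordinates: flip position and complement bases
                pos5 = n - 1 - q
                read_b = _COMP.get(read_base, "N")
                ref_b = _COMP.get(ref_base, "N")
            else:
                pos5 = q
                read_b = read_base
                ref_b = ref_base
            pos3 = n - 1 - pos5
            if pos5 < WINDOW and ref_b == "C":
                counts_5p[pos5, _BASE_IDX.get(read_b, 4)] += 1
            if pos3 < WINDOW and ref_b == "G":
                counts_3p[pos3, _BASE_IDX.get(read_b, 4)] += 1
    return DamageProfile(sample=sample, counts_5p=counts_5p, counts_3p=counts_3p)


def profile_damage_sam(sam_path, reference_fasta, sample: str = "") -> DamageProfile:
    """Profile damage from a SAM file plus its reference FASTA (via pysam)."""
    import pysam

    refs: dict[str, str] = {}
    with open(reference_fasta) as fh:
        name = None
        chunks: list[str] = []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    refs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
        if name is not None:
            refs[name] = "".join(chunks)

    alignments = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            pairs = tuple(
                (q, t)
                for q, t in rec.get_aligned_pairs(matches_only=True)
            )
            alignments.append(
                AlignedRead(
                    read_seq=rec.query_sequence,
                    ref_id=rec.reference_name,
                    pairs=pairs,
                    strand="-" if rec.is_reverse else "+",
                )
            )
    return profile_damage(alignments, refs, sample=sample)


def profile_from_mapping(result, sample: str = "") -> DamageProfile:
    """Profile damage directly from an in-memory iterative-mapping result."""
    refs = {c.contig_id: c.consensus for c in result.references}
    alignments = []
    for rid, pl in result.placements.items():
        read = result.reads[rid]
        contig = result.references[pl.ref_index]
        alignments.append(
            AlignedRead(
                read_seq=read.bases,
                ref_id=contig.contig_id,
                pairs=aligned_pairs_from_ops(pl.ops, pl.read_start, pl.ref_start),
            )
        )
    return profile_damage(alignments, refs, sample=sample)


@dataclass
class ProfileComparison:
    delta_5p: np.ndarray
    delta_3p: np.ndarray
    mean_terminal_excess_5p: float  # mean of delta over the first 5 positions
    mean_terminal_excess_3p: float


def compare_profiles(a: DamageProfile, b: DamageProfile) -> ProfileComparison:
    """Positionwise frequency differences (a minus b) and the mean excess
    over the five terminal positions at each end."""
    if a.is_empty() or b.is_empty():
        raise ValueError("cannot compare empty damage profiles")
    d5 = a.freq_5p - b.freq_5p
    d3 = a.freq_3p - b.freq_3p
    return ProfileComparison(
        delta_5p=d5,
        delta_3p=d3,
        mean_terminal_excess_5p=float(np.nanmean(d5[:5])),
        mean_terminal_excess_3p=float(np.nanmean(d3[:5])),
    )
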