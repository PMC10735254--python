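"""K80 distances, database validation and the cross-contaminant classifier."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from herbseq import decontam, readproc, simulate
from herbseq._align import revcomp
from herbseq.decontam import (
    DbEntry,
    HitRecord,
    SectionDatabase,
    best_hit,
    classify_read,
    k80_distance,
    remove_flagged,
    screen_reads,
    validate_database,
)
from herbseq.errors import DatabaseValidationError, SaturationError
from herbseq.records import ReadRecord


def _read(rid, bases):
    return ReadRecord(read_id=rid, bases=bases, qualities="I" * len(bases))


class TestK80Distance:
    def test_identical_sequences(self):
        r = k80_distance("ACGTACGT", "ACGTACGT")
        assert r.d == 0.0 and r.P == 0.0 and r.Q == 0.0

    def test_closed_form_at_p01_q005(self):
        """d = -0.5 ln(1-2P-Q) - 0.25 ln(1-2Q) at P=0.1, Q=0.05 evaluates to
        0.17018 (independent closed-form evaluation)."""
        # 20 sites: 2 transitions (A<->G), 1 transversion (A<->C)
        a = "A" * 20
        b = "G" * 2 + "C" * 1 + "A" * 17
        r = k80_distance(a, b)
        assert r.P == pytest.approx(0.1)
        assert r.Q == pytest.approx(0.05)
        assert r.d == pytest.approx(0.17018, abs=5e-6)

    def test_frozen_value_matches_ape_dist_dna(self):
        """Frozen oracle: the same pair fed to R ape's dist.dna (model K80)
        returns 0.1673576635."""
        a = "ACGTACGTACGTACGTACGT"
        b = "GCGTACGTACGAACGTACTT"
        assert k80_distance(a, b).d == pytest.approx(0.1673576635, abs=1e-9)

    def test_gap_and_ambiguity_columns_dropped_pairwise(self):
        a = "AC-TACGTNCGT"
        b = "ACGTAC-TACGT"
        r = k80_distance(a, b)
        assert r.n_sites == 9

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k80_distance("A" * 30, "G" * 30)

    def test_dominates_p_distance(self):
        """Jensen: the K80 correction can only stretch the raw mismatch
        proportion."""
        rng = np.random.default_rng(0)
        root = simulate._random_seq(rng, 2000, 0.45)
        for rate in (0.01, 0.05, 0.15):
            other = simulate.mutate_sequence(root, rate, rng)
            r = k80_distance(root, other)
            p_dist = (r.P * r.n_sites + r.Q * r.n_sites) / r.n_sites
            assert r.d >= p_dist - 1e-12

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            k80_distance("ACGT", "ACG")


class TestValidateDatabase:
    def test_study_like_gap_passes(self, section_db):
        summary = validate_database(section_db, min_gap_ratio=2.0)
        assert summary.min_between > 2.0 * summary.max_within
        assert 0.003 < summary.mean_within < 0.012
        assert summary.mean_between > 0.038

    def test_identical_sequences_fail(self, locus_set):
        entries = [
            DbEntry(section=s, sample=f"{s}{m}", locus=lid, seq=seq)
            for s in ("secA", "secB")
            for m in (1, 2)
            for lid, seq in locus_set.loci
        ]
        with pytest.raises(DatabaseValidationError):
            validate_database(SectionDatabase(entries=entries))

    def test_narrow_gap_fails_and_names_pair(self, locus_set):
        db = simulate.diverge_sections(
            locus_set, 2, within_divergence=0.01, between_divergence=0.012,
            members_per_section=2, seed=3,
        )
        with pytest.raises(DatabaseValidationError) as err:
            validate_database(db, min_gap_ratio=2.0)
        assert err.value.section_pair is not None

    def test_fasta_roundtrip(self, section_db, tmp_path):
        path = tmp_path / "db.fasta"
        section_db.to_fasta(path)
        back = SectionDatabase.from_fasta(path)
        assert [(e.section, e.sample, e.locus, e.seq) for e in back.entries] == [
            (e.section, e.sample, e.locus, e.seq) for e in section_db.entries
        ]


@pytest.fixture(scope="module")
def toy_db():
    rng = np.random.default_rng(8)
    seqs = [simulate._random_seq(rng, 900, 0.4) for _ in range(3)]
    return SectionDatabase(
        entries=[
            DbEntry(section=f"sec{i}", sample=f"s{i}", locus=f"loc{i}", seq=s)
            for i, s in enumerate(seqs)
        ]
    )


class TestBestHit:
    def test_exact_substring_hit(self, toy_db):
        query = toy_db.entries[1].seq[50:850]
        hit = best_hit(query, toy_db, read_id="r")
        assert hit.sample == "s1"
        assert hit.identity == 1.0
        assert hit.length == 800
        assert hit.strand == "+"

    def test_agrees_with_brute_force_on_toy_reads(self, toy_db):
        """Score and chosen subject match an exhaustive Smith-Waterman scan
        of every entry on both strands."""
        from test_align import gotoh_local

        rng = np.random.default_rng(9)
        for _ in range(10):
            src = int(rng.integers(3))
            start = int(rng.integers(0, 840))
            query = toy_db.entries[src].seq[start : start + 60]
            query = "".join(
                c if rng.random() > 0.05 else "ACGT"[int(rng.integers(4))] for c in query
            )
            hit = best_hit(query, toy_db, min_score=10)
            oracle = max(
                (max(gotoh_local(q, e.seq) for q in (query, revcomp(query))), i)
                for i, e in enumerate(toy_db.entries)
            )
            assert hit.score == pytest.approx(oracle[0])
            assert hit.sample == f"s{oracle[1]}"

    def test_reverse_complement_strand_symmetry(self, toy_db):
        query = toy_db.entries[2].seq[100:800]
        fwd = best_hit(query, toy_db)
        rev = best_hit(revcomp(query), toy_db)
        assert rev.sample == fwd.sample
        assert rev.identity == pytest.approx(fwd.identity)
        assert rev.strand == "-"

    def test_no_hit_below_min_score(self, toy_db):
        assert best_hit("ACGT" * 5, toy_db, min_score=60) is None


def _hit(section, length, identity):
    return HitRecord(
        read_id="r", section=section, sample="s", locus="l",
        length=length, identity=identity, score=100.0, strand="+",
    )


class TestClassifyRead:
    def test_rule_lattice_exhaustive(self):
        """Exhaustive enumeration over the threshold lattice matches the
        rule: wrong section & length>600 & identity>=0.95 -> contaminant;
        wrong section otherwise -> ambiguous; expected section -> clean."""
        for length, identity, wrong in itertools.product(
            (599, 600, 601), (0.949, 0.95, 0.951), (False, True)
        ):
            hit = _hit("other" if wrong else "home", length, identity)
            got = classify_read(hit, expected_section="home").label
            if not wrong:
                assert got == "clean"
            elif length > 600 and identity >= 0.95:
                assert got == "possible_cross_contaminant"
            else:
                assert got == "ambiguous"

    def test_no_hit_retained_as_no_hit(self):
        assert classify_read(None, "home", read_id="r").label == "no_hit"

    def test_keep_low_identity_flag(self):
        hit = _hit("other", 700, 0.90)
        assert classify_read(hit, "home").label == "ambiguous"
        assert classify_read(hit, "home", keep_low_identity=True).label == "clean"


class TestRemoveFlagged:
    def test_no_flags_passthrough(self):
        reads = [_read(f"r{i}", "ACGT" * 30) for i in range(4)]
        cls = {
            r.read_id: classify_read(_hit("home", 700, 0.99), "home", read_id=r.read_id)
            for r in reads
        }
        kept, report = remove_flagged(reads, cls)
        assert kept == reads
        assert report.counts["clean"] == 4

    def test_counts_and_percentages(self):
        reads = [_read(f"r{i}", "ACGT" * 30) for i in range(100)]
        cls = {}
        for i, r in enumerate(reads):
            if i < 2:
                c = classify_read(_hit("other", 700, 0.99), "home", read_id=r.read_id)
            elif i < 5:
                c = classify_read(_hit("other", 400, 0.99), "home", read_id=r.read_id)
            else:
                c = classify_read(_hit("home", 700, 0.99), "home", read_id=r.read_id)
            cls[r.read_id] = c
        kept, report = remove_flagged(reads, cls)
        assert len(kept) == 95
        assert report.contamination_percent == pytest.approx(2.0)
        assert report.ambiguous_percent == pytest.approx(3.0)
        assert sum(report.counts.values()) == 100

    def test_missing_classification_rejected(self):
        reads = [_read("r0", "ACGT" * 30)]
        with pytest.raises(KeyError):
            remove_flagged(reads, {})

    def test_never_removes_clean_or_no_hit(self):
        reads = [_read("a", "ACGT" * 30), _read("b", "ACGT" * 30)]
        cls = {
            "a": classify_read(None, "home", read_id="a"),
            "b": classify_read(_hit("home", 100, 0.8), "home", read_id="b"),
        }
        kept, _ = remove_flagged(reads, cls)
        assert [r.read_id for r in kept] == ["a", "b"]


class TestPlantedContaminantRecovery:
    def test_screen_recovers_planted_contaminants(self, small_sim):
        """>= 95 % of planted cross-contaminants with long database
        alignments are flagged; endogenous reads are essentially never
        flagged (the sections are separated by a wide distance gap)."""
        demux = readproc.demultiplex(small_sim.reads, small_sim.scheme)
        truth = small_sim.truth.set_index("read_id")
        kept, _ = readproc.remove_duplicates(demux.assigned["young"])
        classifications = screen_reads(kept, small_sim.db, "Siphonomorpha")
        tp = fn = 0
        endo = false_flag = 0
        for r in kept:
            row = truth.loc[r.read_id]
            c = classifications[r.read_id]
            if row["class"] == "cross_contaminant":
                ev = c.evidence
                if ev is not None and ev.length > 600:
                    if c.label == "possible_cross_contaminant":
                        tp += 1
                    else:
                        fn += 1
            elif row["class"] == "endogenous":
                endo += 1
                false_flag += c.label in ("possible_cross_contaminant", "ambiguous")
        assert tp >= 1, "fixture must plant detectable contaminants"
        assert tp / (tp + fn) >= 0.95
        assert false_flag / endo <= 0.001
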