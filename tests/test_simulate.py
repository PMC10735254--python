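"""The synthetic-data generator: elementary operations against closed-form
oracles, and the whole generative chain against its truth table."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from herbseq import simulate
from herbseq.decontam import k80_distance
from herbseq.errors import ConfigError


class TestGenerateLocusSet:
    @pytest.mark.parametrize(
        "n_loci,total",
        [(48, 104_000), (1, 100), (4, 10)],
    )
    def test_partition_properties(self, n_loci, total):
        ls = simulate.generate_locus_set(n_loci, total, 0.4, seed=7)
        assert len(ls) == n_loci
        assert ls.total_length == total
        assert all(len(seq) >= 1 for _, seq in ls.loci)

    def test_reproducible_and_seed_sensitive(self):
        a = simulate.generate_locus_set(5, 5000, 0.4, seed=3)
        b = simulate.generate_locus_set(5, 5000, 0.4, seed=3)
        c = simulate.generate_locus_set(5, 5000, 0.4, seed=4)
        assert a.loci == b.loci
        assert a.loci != c.loci

    def test_gc_content_tracks_request(self):
        ls = simulate.generate_locus_set(2, 40_000, 0.62, seed=1)
        seq = "".join(s for _, s in ls.loci)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.62, abs=0.01)

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            simulate.generate_locus_set(0, 100, 0.4, 1)
        with pytest.raises(ValueError):
            simulate.generate_locus_set(10, 5, 0.4, 1)


class TestDivergeSections:
    def test_zero_within_divergence_gives_identical_members(self, locus_set):
        db = simulate.diverge_sections(
            locus_set, 4, within_divergence=0.0, between_divergence=0.05,
            members_per_section=3, seed=1,
        )
        for section in db.sections():
            for locus in db.loci():
                seqs = {e.seq for e in db.entries if e.section == section and e.locus == locus}
                assert len(seqs) == 1

    def test_realized_k80_distances_near_targets(self, locus_set):
        db = simulate.diverge_sections(
            locus_set, 4, within_divergence=0.007, between_divergence=0.06,
            members_per_section=4, seed=1,
        )
        within, between = [], []
        for locus in db.loci():
            entries = [e for e in db.entries if e.locus == locus]
            for i in range(len(entries)):
                for j in range(i + 1, len(entries)):
                    d = k80_distance(entries[i].seq, entries[j].seq).d
                    (within if entries[i].section == entries[j].section else between).append(d)
        assert np.mean(within) == pytest.approx(0.007, rel=0.3)
        assert np.mean(between) == pytest.approx(0.06, rel=0.3)

    def test_rejects_no_gap(self, locus_set):
        with pytest.raises(ValueError):
            simulate.diverge_sections(
                locus_set, 2, within_divergence=0.05, between_divergence=0.04,
                members_per_section=2, seed=1,
            )


class TestFragmentSequence:
    def test_age_zero_returns_input_untouched(self):
        model = simulate.DegradationModel.for_age(0)
        assert simulate.fragment_sequence("ACGT" * 100, model, 1) == ["ACGT" * 100]

    @pytest.mark.parametrize("age,expected_mean", [(30, 201.3), (60, 100.9)])
    def test_mean_fragment_length_matches_geometric_oracle(self, age, expected_mean):
        """p = 1 - exp(-rate*age); mean fragment length = 1/p."""
        model = simulate.DegradationModel.for_age(age)
        rng = np.random.default_rng(0)
        seq = simulate._random_seq(rng, 1_000_000, 0.4)
        frags = simulate.fragment_sequence(seq, model, seed=5)
        mean = np.mean([len(f) for f in frags])
        assert mean == pytest.approx(expected_mean, rel=0.05)

    def test_fragments_reassemble_to_input(self):
        model = simulate.DegradationModel.for_age(50)
        rng = np.random.default_rng(2)
        seq = simulate._random_seq(rng, 20_000, 0.4)
        frags = simulate.fragment_sequence(seq, model, seed=9)
        assert "".join(frags) == seq

    def test_lengths_fit_geometric_distribution(self):
        """Kolmogorov-Smirnov against Geom(p) does not reject at alpha=0.01
        on 1e5 fragments.  The randomized probability-integral transform
        makes the continuous KS test exact for this discrete distribution
        (naive KS on tied integer data inflates the statistic)."""
        model = simulate.DegradationModel.for_age(30)
        rng = np.random.default_rng(0)
        seq = simulate._random_seq(rng, 22_000_000, 0.4)
        lengths = np.array([len(f) for f in simulate.fragment_sequence(seq, model, seed=8)])
        assert lengths.size > 1e5
        p = model.break_probability
        v = np.random.default_rng(123).random(lengths.size)
        u = stats.geom.cdf(lengths - 1, p) + v * stats.geom.pmf(lengths, p)
        res = stats.kstest(u, "uniform")
        assert res.pvalue > 0.01


class TestApplyDamage:
    def test_zero_rates_leave_fragment_unchanged(self):
        model = simulate.DegradationModel(age=10)
        frag = "ACGTACGTCCGGTTAA" * 10
        assert simulate.apply_damage(frag, model, 3) == frag

    def test_saturating_rates_convert_terminal_window(self):
        model = simulate.DegradationModel(
            age=10, deam_rate_5p=np.ones(25), deam_rate_3p=np.zeros(25)
        )
        out = simulate.apply_damage("C" * 50, model, 3)
        assert out[:25] == "T" * 25
        assert out[25:] == "C" * 25

    def test_planted_rate_recovered_at_position_zero(self):
        rate5 = np.zeros(25)
        rate5[0] = 0.1
        model = simulate.DegradationModel(age=10, deam_rate_5p=rate5)
        rng = np.random.default_rng(4)
        converted = total = 0
        for _ in range(10_000):
            frag = "C" + simulate._random_seq(rng, 49, 0.4)
            out = simulate.apply_damage(frag, model, rng)
            total += 1
            converted += out[0] == "T"
        assert converted / total == pytest.approx(0.1, abs=0.01)


class TestSizeSelect:
    def test_hard_cutoff_limit(self, rng):
        step = simulate.SizeSelectionStep(midpoint=1000, sharpness=1e6)
        frags = ["A" * L for L in (10, 500, 999, 1000, 1500, 3000)]
        kept = simulate.size_select(frags, step, 1)
        assert sorted(len(f) for f in kept) == [1000, 1500, 3000]

    def test_midpoint_retention_is_half(self):
        step = simulate.SizeSelectionStep(midpoint=800)
        assert step.retention_probability(800) == pytest.approx(0.5)
        # design rule: at most 5 % retention at 0.8x midpoint
        assert step.retention_probability(640) <= 0.05 + 1e-12
        # monotone
        probs = [step.retention_probability(L) for L in range(100, 3000, 50)]
        assert all(a <= b for a, b in zip(probs, probs[1:]))

    def test_selection_enriches_long_fraction(self):
        from herbseq.qc import long_fragment_fraction, profile_from_lengths

        rng = np.random.default_rng(7)
        lengths = rng.geometric(1.0 / 700.0, size=20_000)
        frags = ["A" * int(L) for L in lengths]
        step = simulate.SizeSelectionStep(midpoint=1000)
        kept = simulate.size_select(frags, step, 2)
        before = long_fragment_fraction(profile_from_lengths([len(f) for f in frags]))
        after = long_fragment_fraction(profile_from_lengths([len(f) for f in kept]))
        assert after > before


class TestAmplify:
    def test_zero_cycles_is_identity(self):
        out = simulate.amplify(["ACGT" * 30], cycles=0, seed=1)
        assert len(out) == 1 and not out[0].is_duplicate

    def test_perfect_doubling(self):
        out = simulate.amplify(["A" * 100], cycles=3, efficiency=1.0, length_bias=0.0, seed=1)
        assert len(out) == 8
        assert sum(f.is_duplicate for f in out) == 7

    def test_length_bias_favours_short_molecules(self):
        rng = np.random.default_rng(3)
        pool = ["A" * int(L) for L in rng.integers(200, 3000, size=300)]
        out = simulate.amplify(pool, cycles=6, efficiency=0.6, length_bias=5e-4, seed=2)
        dup_lengths = [len(f.seq) for f in out if f.is_duplicate]
        pool_mean = np.mean([len(s) for s in pool])
        assert np.mean(dup_lengths) < pool_mean


class TestMakeChimeras:
    def test_zero_rate_no_chimeras(self):
        pool = ["ACGT" * 100, "TTTT" * 100]
        out, events = simulate.make_chimeras(pool, 0.0, 1)
        assert out == pool and events == {}

    def test_forced_breakpoint_construction(self):
        a, b = "A" * 1000, "G" * 1000
        out, events = simulate.make_chimeras([a, b], rate=1.0, seed=1, breakpoint=500)
        for idx, ev in events.items():
            chim = out[idx]
            assert len(chim) == 1000
            assert chim[:500] in (a[:500], b[:500])
            assert chim[500:] in (a[500:], b[500:])
            assert chim[:500] != chim[500:]

    def test_binomial_chimera_count(self):
        rng = np.random.default_rng(0)
        pool = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(10_000)]
        _, events = simulate.make_chimeras(pool, rate=0.05, seed=3)
        sd = math.sqrt(10_000 * 0.05 * 0.95)
        assert abs(len(events) - 500) <= 3 * sd


class TestBarcodeScheme:
    def test_generated_barcodes_are_separated(self):
        scheme = simulate.BarcodeScheme.generate([f"s{i}" for i in range(12)], seed=5)
        assert scheme.min_pairwise_distance() >= 3

    def test_flank_structure(self):
        scheme = simulate.BarcodeScheme(barcodes={"x": "ACGTAC"})
        assert scheme.tag("x") == "GATACGTACGTG"
        assert scheme.reverse_start_motif("x") == "CACACGTACATC"

    def test_duplicate_barcode_rejected(self):
        with pytest.raises(ValueError):
            simulate.BarcodeScheme(barcodes={"a": "ACGTAC", "b": "ACGTAC"})


class TestBuildSample:
    def test_zero_contamination_plan_means_no_contaminant_truth(self, small_sim):
        truth = small_sim.truth
        clean_samples = {"donor", "mid", "old"}
        sub = truth[truth["sample"].isin(clean_samples)]
        assert (sub["class"] != "cross_contaminant").all()

    def test_planted_contaminant_count_is_binomial(self, small_sim):
        truth = small_sim.truth
        n = (truth["sample"] == "young").sum()
        observed = (
            (truth["sample"] == "young") & (truth["class"] == "cross_contaminant")
        ).sum()
        # classes are assigned before duplicate relabelling, so count the
        # duplicates of contaminants too via parent lookup
        expect = 300 * 0.01
        sd = math.sqrt(300 * 0.01 * 0.99)
        assert abs(observed - expect) <= 4 * sd + 1

    def test_mismatch_rate_matches_error_model(self, small_sim):
        truth = small_sim.truth.set_index("read_id")
        reads = {r.read_id: r for r in small_sim.reads}
        mismatches = bases = 0
        for rid, row in truth.iterrows():
            read = reads[rid]
            expected = row["truth_seq"]
            observed = read.bases if row["orientation"] == "forward" else _rc(read.bases)
            assert len(observed) == len(expected)
            mismatches += sum(a != b for a, b in zip(observed, expected))
            bases += len(expected)
        assert mismatches / bases == pytest.approx(1e-4, rel=0.35)

    def test_truth_class_counts_within_binomial_bands(self, small_sim):
        truth = small_sim.truth
        for sample in ("young", "donor"):
            sub = truth[truth["sample"] == sample]
            n = len(sub)
            n_chim = (sub["class"] == "chimera").sum()
            rate = 0.05 if sample == "young" else simulate.CHIMERA_RATE
            sd = math.sqrt(n * rate * (1 - rate))
            assert abs(n_chim - n * rate) <= 4 * sd + 1

    def test_unknown_contamination_donor_rejected(self, section_db):
        spec = simulate.SampleSpec(name="s1", section="secA", age=5, depth=10)
        plan = simulate.ContaminationPlan(rates={("ghost", "s1"): 0.1})
        scheme = simulate.BarcodeScheme.generate(["s1"], seed=1)
        with pytest.raises(ConfigError):
            simulate.build_sample(section_db, spec, plan, scheme, seed=1)

    def test_bit_reproducible_for_fixed_seed(self):
        cfg = simulate.SimConfig(
            n_loci=3, total_length=4500, members_per_section=2,
            samples=[simulate.SampleSpec(name="a", section="secA", age=10,
                                         depth=50, genome_copies=30)],
        )
        r1 = simulate.simulate_run(cfg, seed=9)
        r2 = simulate.simulate_run(cfg, seed=9)
        assert [x.bases for x in r1.reads] == [x.bases for x in r2.reads]
        assert r1.truth.equals(r2.truth)


def _rc(seq):
    from herbseq._align import revcomp

    return revcomp(seq)


def test_rate_recovery_roundtrip_across_regimes():
    """Planted breakage rates are recovered within 10 % relative error for
    rate*age in [0.001, 0.02] at n >= 1e4 fragments."""
    from herbseq.qc import estimate_fragmentation_rate

    rng = np.random.default_rng(0)
    for lam_age in (0.001, 0.005, 0.02):
        age = 30.0
        lam = lam_age / age
        model = simulate.DegradationModel(breakage_rate=lam, age=age)
        seq_len = int(1.5e4 / lam_age)  # ~1.5e4 expected fragments
        seq = simulate._random_seq(rng, seq_len, 0.4)
        frags = simulate.fragment_sequence(seq, model, seed=6)
        assert len(frags) >= 1e4
        est = estimate_fragmentation_rate([len(f) for f in frags], age=age)
        assert est.rate == pytest.approx(lam, rel=0.1)
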