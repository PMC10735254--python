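"""End-to-end orchestration: simulate -> QC -> read processing ->
decontamination -> assembly -> damage profiling, with a per-sample summary
table.

Stage order follows the analysis design: reads are demultiplexed, exact
duplicates and chimeras are removed, cross-contaminants are screened against
the section database, the cleaned reads build per-sample de-novo references,
iterative mapping defines the on-target set, and terminal damage is profiled
from the final alignments.  Read counts are conserved at every stage
(input = output + removed, per category) and asserted by the report writer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from . import assemble, damage, decontam, qc, readproc, simulate
from .errors import StageError
from .records import ReadRecord

SUMMARY_COLUMNS = [
    "sample", "barcoded_reads", "duplicates_pct", "chimeras",
    "contaminants_pct", "ambiguous_pct", "cleaned_reads", "on_target_reads",
    "on_target_ratio_pct", "on_target_gt_1kb", "on_target_len_mean",
    "on_target_len_median", "loci_recovered", "mean_depth",
    "total_contig_length",
]


@dataclass
class RunConfig:
    """Thresholds for every stage plus the simulation block."""

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    demux_max_mismatch: int = 1
    demux_search_window: int = 100
    dedup_k: int = 31
    chimera_min_segment: int = 300
    chimera_margin: float = 0.02
    decontam_min_score: float = 40.0
    decontam_min_identity: float = 0.95
    decontam_min_length: int = 600
    decontam_keep_low_identity: bool = False
    db_min_gap_ratio: float = 2.0
    assemble_min_overlap: int = 100
    assemble_min_identity: float = 0.85
    mapping: assemble.MappingConfig = field(default_factory=assemble.MappingConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = simulate.SimConfig.from_dict(d["sim"])
        if "mapping" in d and not isinstance(d["mapping"], assemble.MappingConfig):
            d["mapping"] = assemble.MappingConfig(**d["mapping"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SampleResult:
    name: str
    reads: list[ReadRecord]
    dedup_flags: dict
    chimera_flags: dict
    classifications: dict
    removal_report: decontam.RemovalReport | None
    cleaned: list[ReadRecord]
    contigs: list
    mapping: assemble.MappingResult | None
    stats: assemble.AssemblyStats | None
    damage_profile: damage.DamageProfile | None


@dataclass
class RunResult:
    summary: pd.DataFrame
    samples: dict[str, SampleResult]
    sim: simulate.SimResult
    distance_summary: decontam.DistanceSummary
    unassigned: int
    stage_counts: dict

    def summary_tsv(self) -> str:
        return self.summary.to_csv(sep="\t", index=False, float_format="%.4f")


def _empty_stats(sample: str, n_loci: int) -> assemble.AssemblyStats:
    return assemble.AssemblyStats(
        sample=sample, input_reads=0, on_target_reads=0, on_target_ratio=0.0,
        loci_recovered=0, n_target_loci=n_loci, mean_depth=0.0,
        coverage_by_locus={}, depth_by_locus={}, reads_by_locus={},
        total_contig_length=0, read_length_mean=0.0, read_length_median=0.0,
        reads_gt_1kb=0,
    )


def run(config: RunConfig, seed: int = 0, outdir=None) -> RunResult:
    """Execute the full pipeline on a synthetic run; deterministic per seed."""
    sim = simulate.simulate_run(config.sim, seed, outdir=os.path.join(outdir, "sim") if outdir else None)
    try:
        distance_summary = decontam.validate_database(sim.db, config.db_min_gap_ratio)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError("validate_database", "-", str(exc)) from exc

    demux = readproc.demultiplex(
        sim.reads, sim.scheme,
        max_mismatch=config.demux_max_mismatch,
        search_window=config.demux_search_window,
    )
    db_pool = [
        (f"{e.section}|{e.sample}|{e.locus}", e.seq) for e in sim.db.entries
    ]
    locus_seqs = sim.locus_set.as_dict()
    spec_by_name = {s.name: s for s in config.sim.samples}

    rows = []
    samples: dict[str, SampleResult] = {}
    stage_counts: dict[str, dict] = {}
    for name, reads in demux.assigned.items():
        spec = spec_by_name[name]
        counts = {"barcoded": len(reads)}
        if not reads:
            stats = _empty_stats(name, len(locus_seqs))
            samples[name] = SampleResult(
                name=name, reads=[], dedup_flags={}, chimera_flags={},
                classifications={}, removal_report=None, cleaned=[],
                contigs=[], mapping=None, stats=stats, damage_profile=None,
            )
            rows.append(_summary_row(name, 0, 0.0, 0, None, 0, stats))
            stage_counts[name] = counts
            continue

        kept, dup_flags = readproc.remove_duplicates(reads, k=config.dedup_k)
        dup_pct = qc.duplication_level(reads, {rid: v is not None for rid, v in dup_flags.items()})
        counts["after_dedup"] = len(kept)
        assert len(kept) + sum(v is not None for v in dup_flags.values()) == len(reads)

        chim_flags = readproc.flag_chimeras(
            kept, db_pool,
            min_segment=config.chimera_min_segment,
            improvement_margin=config.chimera_margin,
        )
        no_chim = [r for r in kept if chim_flags.get(r.read_id) is None]
        n_chim = len(kept) - len(no_chim)
        counts["after_chimera"] = len(no_chim)

        classifications = decontam.screen_reads(
            no_chim, sim.db, spec.section,
            min_score=config.decontam_min_score,
            min_identity=config.decontam_min_identity,
            min_length=config.decontam_min_length,
            keep_low_identity=config.decontam_keep_low_identity,
        )
        cleaned, report = decontam.remove_flagged(no_chim, classifications)
        counts["cleaned"] = len(cleaned)
        assert report.total == len(no_chim)
        assert sum(report.counts.values()) == len(no_chim)

        if cleaned:
            contigs = assemble.build_references(
                cleaned,
                min_overlap=config.assemble_min_overlap,
                min_identity=config.assemble_min_identity,
                sample=name,
            )
            assemble.assign_loci(contigs, locus_seqs)
            mapping = assemble.iterative_map(cleaned, contigs, config.mapping)
            stats = assemble.compute_stats(mapping, len(cleaned), sim.locus_set, sample=name)
            dmg = damage.profile_from_mapping(mapping, sample=name)
        else:
            contigs, mapping, dmg = [], None, None
            stats = _empty_stats(name, len(locus_seqs))
        counts["on_target"] = stats.on_target_reads

        samples[name] = SampleResult(
            name=name, reads=reads, dedup_flags=dup_flags,
            chimera_flags=chim_flags, classifications=classifications,
            removal_report=report, cleaned=cleaned, contigs=contigs,
            mapping=mapping, stats=stats, damage_profile=dmg,
        )
        rows.append(_summary_row(name, len(reads), dup_pct, n_chim, report, len(cleaned), stats))
        stage_counts[name] = counts

    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS).sort_values("sample").reset_index(drop=True)
    result = RunResult(
        summary=summary, samples=samples, sim=sim,
        distance_summary=distance_summary,
        unassigned=len(demux.unassigned), stage_counts=stage_counts,
    )
    if outdir is not None:
        _write_artifacts(result, outdir)
    return result


def _summary_row(name, n_barcoded, dup_pct, n_chim, report, n_cleaned, stats):
    # contamination quoted as percent of the sample-assigned (barcoded)
    # reads, the convention used for the per-sample contamination levels
    def _pct_of_barcoded(count):
        return round(100.0 * count / n_barcoded, 4) if n_barcoded else 0.0

    return {
        "sample": name,
        "barcoded_reads": n_barcoded,
        "duplicates_pct": round(dup_pct, 4),
        "chimeras": n_chim,
        "contaminants_pct": _pct_of_barcoded(
            report.counts["possible_cross_contaminant"] if report else 0
        ),
        "ambiguous_pct": _pct_of_barcoded(report.counts["ambiguous"] if report else 0),
        "cleaned_reads": n_cleaned,
        "on_target_reads": stats.on_target_reads,
        "on_target_ratio_pct": round(stats.on_target_ratio, 4),
        "on_target_gt_1kb": stats.reads_gt_1kb,
        "on_target_len_mean": round(stats.read_length_mean, 2),
        "on_target_len_median": round(stats.read_length_median, 2),
        "loci_recovered": stats.loci_recovered,
        "mean_depth": round(stats.mean_depth, 4),
        "total_contig_length": stats.total_contig_length,
    }


def _write_artifacts(result: RunResult, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "summary.tsv"), "w") as fh:
        fh.write(result.summary_tsv())
    for name, sr in result.samples.items():
        if sr.mapping is None:
            continue
        sample_dir = os.path.join(outdir, name)
        os.makedirs(sample_dir, exist_ok=True)
        assemble.write_sam(sr.mapping, os.path.join(sample_dir, "on_target.sam"), sample=name)
        with open(os.path.join(sample_dir, "contigs.fasta"), "w") as fh:
            for c in sr.mapping.references:
                fh.write(f">{c.contig_id} locus={c.locus or 'unassigned'} reads={c.n_reads}\n")
                fh.write(c.consensus + "\n")
        if sr.damage_profile is not None:
            sr.damage_profile.to_table().to_csv(
                os.path.join(sample_dir, "damage.tsv"), sep="\t", index=False
            )
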