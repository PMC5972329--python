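"""End-to-end orchestration: germline -> mutations -> mutability -> motifs.

``run_pipeline`` executes the full clone-set analysis and writes a
deterministic report bundle: a clone-set summary table (clones, surveyed bp,
events, events/1,000 bp, replacement/silent, Ti/Tv, frameshifts), mono/di/
trinucleotide mutability tables, a motif summary, windowed mutation-frequency
tracks, optional genotype calls, and a run-metadata file from which the
bundle is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from shmprof import germline as gl
from shmprof import motifs as mt
from shmprof import mutability as mb
from shmprof import mutations as mu
from shmprof import seqio
from shmprof._util import truncate


@dataclass
class RunConfig:
    clones_path: Optional[str] = None
    regions_path: Optional[str] = None
    out_dir: str = "shmprof_out"
    allele_threshold: float = 0.3
    identity_threshold: float = 0.75
    window: int = 20
    masked_spans: tuple = ()
    motif_classes: tuple = tuple(mt.MOTIF_PATTERNS)
    seed: int = 0

    def as_metadata(self) -> dict:
        return {
            "clones_path": self.clones_path or "",
            "regions_path": self.regions_path or "",
            "allele_threshold": self.allele_threshold,
            "identity_threshold": self.identity_threshold,
            "window": self.window,
            "masked_spans": ";".join(f"{s}-{e}" for s, e in self.masked_spans),
            "motif_classes": ",".join(self.motif_classes),
            "seed": self.seed,
        }


@dataclass
class ReportBundle:
    germline: gl.GermlineReference
    partition: gl.SubgroupPartition
    records: list
    summaries: dict            # individual_id (or "Total") -> MutationSummary
    summary_table: pd.DataFrame
    mutability: dict           # k -> DataFrame
    motif_hits: list
    motif_summary: pd.DataFrame
    windows: pd.DataFrame
    chimeras: list = field(default_factory=list)
    written: list = field(default_factory=list)


def summary_table(summaries: dict) -> pd.DataFrame:
    """Clone-set summary in the canonical column order; frequencies and
    ratios truncated to two decimals as in printed reports."""
    rows = []
    for name, s in summaries.items():
        rows.append({
            "individual": name, "clones": s.n_clones, "bp": s.n_bp,
            "mut": s.n_events, "mut_per_1000bp": truncate(s.freq_per_kb, 2),
            "repl": s.replacement, "silent": s.silent,
            "transition": s.transitions, "transversion": s.transversions,
            "frameshift": s.frameshifts,
            "rs_ratio": None if s.rs_ratio is None else truncate(s.rs_ratio, 2),
        })
    return pd.DataFrame(rows)


def run_pipeline(clones: Sequence, config: Optional[RunConfig] = None,
                 region_map=None) -> ReportBundle:
    """Run the full analysis on a clone set (optionally already in memory).

    Stages: germline inference with allelic-position detection, subgroup
    splitting, per-subgroup mutation calling (allelic positions excluded),
    per-individual and pooled summaries, mutability tables at k = 1, 2, 3,
    motif scanning/linkage on the germline, and windowed frequency tracks.
    """
    config = config or RunConfig()
    if isinstance(clones, (str, Path)):
        clones = seqio.read_fasta(clones)
    clones = list(clones)
    if region_map is None and config.regions_path:
        region_map = seqio.read_region_map(config.regions_path)

    reference = gl.infer_germline(clones, allele_threshold=config.allele_threshold,
                                  frame_offset=region_map.frame_offset if region_map else 0)
    partition = gl.split_subgroups(clones, reference)

    # PCR-jumping chimeras between exactly two haplotypes: flagged clones are
    # excluded from all statistics and reported separately
    chimeras: list = []
    if len(partition.groups) == 2:
        ref_a, ref_b = (sg.reference for sg in partition)
        chimeric_ids = {c.clone_id for c in clones
                        if gl.flag_chimeras(c, (ref_a, ref_b)) == "chimera"}
        if chimeric_ids:
            chimeras = sorted(chimeric_ids)
            for subgroup in partition:
                subgroup.clones = [c for c in subgroup.clones
                                   if c.clone_id not in chimeric_ids]

    records: list = []
    bp_by_individual: dict = {}
    clones_by_individual: dict = {}
    for subgroup in partition:
        for clone in subgroup.clones:
            recs = mu.call_mutations(clone, subgroup.reference, region_map,
                                     masked_spans=config.masked_spans)
            records.extend(recs)
            ind = clone.individual_id or "pooled"
            bp_by_individual[ind] = bp_by_individual.get(ind, 0) + mu.surveyed_bases(
                clone, subgroup.reference, masked_spans=config.masked_spans)
            clones_by_individual.setdefault(ind, []).append(clone.clone_id)

    summaries = {}
    for ind in sorted(bp_by_individual):
        ids = set(clones_by_individual[ind])
        ind_records = [r for r in records if r.clone_id in ids]
        summaries[ind] = mu.summarize(ind_records, n_clones=len(ids),
                                      n_bp=bp_by_individual[ind])
    total_bp = sum(bp_by_individual.values())
    n_assigned = sum(len(v) for v in clones_by_individual.values())
    summaries["Total"] = mu.summarize(records, n_clones=n_assigned, n_bp=total_bp)

    mutability = {
        k: mb.mutability_table(records, reference.sequence, k,
                               masked_spans=config.masked_spans)
        for k in (1, 2, 3)
    }

    hits = mt.scan_motifs(reference.sequence, classes=config.motif_classes)
    mt.annotate_motif_flags(records, hits)
    overlap = mt.motif_overlap(records, hits)
    motif_rows = []
    for cls in config.motif_classes:
        motif_rows.append({
            "class": cls,
            "hits": sum(1 for h in hits if h.motif_class == cls),
            "density_per_100bp": mt.motif_density(reference.sequence, cls,
                                                  masked_spans=config.masked_spans),
            "linked_mutations": overlap[cls]["linked"],
            "mutation_fraction": overlap[cls]["fraction"],
        })
    motif_summary = pd.DataFrame(motif_rows)

    windows = mu.window_profile(records, n_clones=n_assigned,
                                length=len(reference.sequence),
                                window=config.window,
                                masked_spans=config.masked_spans)

    return ReportBundle(
        germline=reference, partition=partition, records=records,
        summaries=summaries, summary_table=summary_table(summaries),
        mutability=mutability, motif_hits=hits, motif_summary=motif_summary,
        windows=windows, chimeras=chimeras,
    )


def write_bundle(bundle: ReportBundle, config: RunConfig) -> list:
    """Write the report bundle to config.out_dir (deterministic TSV/BED)."""
    results = {
        "summary": bundle.summary_table,
        "mutations": bundle.records,
        "mutability_mono": bundle.mutability[1],
        "mutability_di": bundle.mutability[2],
        "mutability_tri": bundle.mutability[3],
        "motif_summary": bundle.motif_summary,
        "windows": bundle.windows,
        "motifs.bed": [
            ("germline", h.window_start, h.window_end, h.motif_class, 0, "+",
             h.mutable_position, h.mutable_position + 1)
            for h in bundle.motif_hits
        ],
        "metadata": {**config.as_metadata(),
                     "chimeric_clones": ";".join(bundle.chimeras)},
    }
    written = seqio.write_tables(results, config.out_dir)
    bundle.written = written
    return written
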