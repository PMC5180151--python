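"""End-to-end orchestration: demux -> filter -> cluster -> taxonomy ->
community table -> ecology -> habitat classification.

Every stage logs record counts into a machine-readable manifest so that
count conservation can be audited (reads binned + discarded = reads in;
uniques retained + discarded per rule = uniques in). Negative-control
samples (``control=True`` in the metadata) must retain zero sequences for
a run to be marked clean; violations warn rather than abort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from edna import __version__
from edna.cluster import objective_cluster, threshold_scan
from edna.ecology import (
    build_motu_table,
    chao2,
    ice,
    incidence_summary,
    pairwise_dissimilarity,
)
from edna.filters import dereplicate, run_filters
from edna.habitat import assign_habitat, compare_groups, sample_dissimilarities
from edna.seqio import demultiplex, load_tag_map, read_sequences, trim_primers
from edna.taxonomy import assign_all, assignments_frame, load_refdb

__all__ = ["PipelineConfig", "run_pipeline", "run_reads_pipeline"]


@dataclass
class PipelineConfig:
    """Serialisable parameter set for a full run."""

    reads: str = "reads.fastq"
    tag_map: str = "tags.tsv"
    refdb: str = "refs.fasta"
    metadata: str = "metadata.tsv"
    out_dir: str = "edna_out"
    expected_length: int = 313
    length_tolerance: int = 0
    max_primer_mismatches: int = 2
    prune_max_edit: int = 1
    prune_abundance_ratio: float = 10.0
    min_identity: float = 0.80
    min_replicates: int = 3
    n_replicates: int = 5
    cluster_threshold: float = 0.03
    scan_thresholds: tuple[float, ...] = (0.02, 0.03, 0.04)
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
        if "scan_thresholds" in kwargs:
            kwargs["scan_thresholds"] = tuple(kwargs["scan_thresholds"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["scan_thresholds"] = list(self.scan_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, reason: str):
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage


def run_reads_pipeline(
    reads,
    tag_lookup: dict,
    refdb: list,
    meta: pd.DataFrame,
    config: PipelineConfig | None = None,
):
    """Run the full analysis on in-memory reads.

    ``reads`` is an iterable of (read_id, sequence); ``tag_lookup`` maps
    (fwd_tag, rev_tag) -> (sample, replicate). Returns a dict of stage
    outputs plus a manifest of per-stage record counts.
    """
    cfg = config or PipelineConfig()
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}

    reads = list(reads)
    demux = demultiplex(reads, tag_lookup)
    manifest["stages"]["demux"] = {
        "reads_in": len(reads),
        "binned": demux.n_binned,
        "discarded": demux.n_discarded,
    }

    trimmed_bins: dict = {}
    n_trimmed = n_trim_rejected = 0
    for key, bin_reads in demux.bins.items():
        kept = []
        for read in bin_reads:
            insert = trim_primers(
                read.sequence, max_mismatches=cfg.max_primer_mismatches
            )
            if insert is None:
                n_trim_rejected += 1
            else:
                kept.append(insert)
                n_trimmed += 1
        trimmed_bins[key] = kept
    manifest["stages"]["trim"] = {
        "reads_in": demux.n_binned,
        "trimmed": n_trimmed,
        "rejected": n_trim_rejected,
    }

    table = dereplicate(trimmed_bins)
    manifest["stages"]["dereplicate"] = {
        "reads_in": n_trimmed,
        "uniques": table.shape[0],
    }

    if table.shape[0] == 0:
        raise StageError("filter", "no sequences after dereplication")
    table, retained, report = run_filters(
        table,
        refdb,
        expected_length=cfg.expected_length,
        length_tolerance=cfg.length_tolerance,
        max_edit=cfg.prune_max_edit,
        abundance_ratio=cfg.prune_abundance_ratio,
        min_identity=cfg.min_identity,
        min_replicates=cfg.min_replicates,
        n_replicates=cfg.n_replicates,
    )
    manifest["stages"]["filter"] = {
        "uniques_in": report.n_input,
        "retained": report.n_retained,
        "discarded": dict(report.discarded),
    }
    if not report.check_conservation():
        raise StageError("filter", "record counts not conserved")

    controls = (
        set(meta.index[meta["control"].astype(bool)])
        if "control" in meta.columns
        else set()
    )
    dirty = {s for s in controls if retained.get(s)}
    manifest["clean_controls"] = not dirty
    if dirty:
        warnings.warn(f"negative controls retained sequences: {sorted(dirty)}")

    seqs = list(table.index)
    if not seqs:
        raise StageError("cluster", "no sequences retained")
    totals = table.sum(axis=1).to_dict()
    partition = objective_cluster(seqs, cfg.cluster_threshold, counts=totals)
    scan = threshold_scan(seqs, list(cfg.scan_thresholds), counts=totals)
    manifest["stages"]["cluster"] = {
        "sequences": len(seqs),
        "motus": partition.n_motus,
        "scan": {str(t): c for t, c in scan.items()},
    }

    assignments = assign_all(partition, refdb)
    n_species = sum(a.level == "species" for a in assignments.values())
    manifest["stages"]["taxonomy"] = {
        "motus": len(assignments),
        "species_level": n_species,
    }

    analysis_meta = meta.drop(index=[c for c in controls if c in meta.index])
    # zero out counts outside each sample's retained set before aggregating
    masked = table.copy()
    control_cols = [c for c in masked.columns if c[0] in controls]
    if control_cols:
        masked = masked.drop(columns=control_cols)
    for sample in masked.columns.get_level_values(0).unique():
        keep = retained.get(sample, set())
        cols = [c for c in masked.columns if c[0] == sample]
        drop_rows = [s for s in masked.index if s not in keep]
        masked.loc[drop_rows, cols] = 0
    motu_table = build_motu_table(partition, masked, analysis_meta)
    manifest["stages"]["motu_table"] = {
        "motus": motu_table.counts.shape[0],
        "samples": motu_table.counts.shape[1],
    }

    results = {
        "manifest": manifest,
        "demux": demux,
        "unique_table": table,
        "filter_report": report,
        "partition": partition,
        "threshold_scan": scan,
        "assignments": assignments,
        "motu_table": motu_table,
    }

    habitats = motu_table.habitats
    if len(habitats) >= 2 and motu_table.counts.shape[1] >= 3:
        per_habitat = {}
        for hab in habitats:
            cols = motu_table.samples_of(hab)
            inc = motu_table.incidence[cols]
            summ = incidence_summary(inc)
            per_habitat[hab] = {
                "s_obs": summ.s_obs,
                "chao2": chao2(summ),
                "ice": ice(summ),
            }
        dissim = sample_dissimilarities(motu_table)
        calls = assign_habitat(dissim)
        truth = motu_table.meta.loc[calls.index, "habitat"]
        own = [dissim.loc[s, truth[s]] for s in dissim.index]
        other = [
            dissim.loc[s, h]
            for s in dissim.index
            for h in dissim.columns
            if h != truth[s]
        ]
        results["richness"] = per_habitat
        results["habitat_dissimilarities"] = dissim
        results["habitat_calls"] = calls
        results["habitat_accuracy"] = float((calls == truth).mean())
        results["group_comparison"] = compare_groups(own, other)
        manifest["stages"]["habitat"] = {
            "accuracy": results["habitat_accuracy"],
            "p": results["group_comparison"]["p"],
        }
    return results


def run_pipeline(config: PipelineConfig) -> Path:
    """File-based front end: read inputs, run the analysis, write artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        reads = list(read_sequences(config.reads))
    except OSError as exc:
        raise StageError("input", str(exc)) from exc
    tag_lookup = load_tag_map(config.tag_map)
    refdb = load_refdb(config.refdb)
    meta = pd.read_csv(config.metadata, sep="\t", index_col=0)

    results = run_reads_pipeline(reads, tag_lookup, refdb, meta, config)

    results["filter_report"].to_frame().to_csv(out / "filter_report.tsv", sep="\t",
                                               index=False)
    partition = results["partition"]
    pd.DataFrame(
        [
            {
                "sequence": s,
                "motu_id": m,
                "representative": int(partition.representatives[m] == s),
            }
            for s, m in sorted(partition.labels.items(), key=lambda kv: (kv[1], kv[0]))
        ]
    ).to_csv(out / "motus.tsv", sep="\t", index=False)
    assignments_frame(results["assignments"]).to_csv(out / "assignments.tsv", sep="\t")
    mt = results["motu_table"]
    mt.counts.to_csv(out / "motu_table.tsv", sep="\t")
    pairwise_dissimilarity(mt.incidence.astype(int), "jaccard").to_csv(
        out / "jaccard.tsv", sep="\t"
    )
    if "habitat_dissimilarities" in results:
        results["habitat_dissimilarities"].to_csv(out / "habitat_dissim.tsv", sep="\t")
        results["habitat_calls"].to_frame("call").to_csv(
            out / "habitat_calls.tsv", sep="\t"
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(results["manifest"], fh, indent=2, sort_keys=True)
    return out
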