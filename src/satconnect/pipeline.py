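"""End-to-end orchestration: merge -> screen -> cluster -> graph.

The stage order follows the discovery workflow: paired reads are merged
into fragments, screened for satellite content against the clone library,
clustered at one or more identity thresholds, and summarised as a
similarity network with a minimum spanning tree and species-mixing
statistics.  A run report records counts at every stage so that the
monotonicity retained <= merged <= 2 x input reads is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .errors import PipelineError
from .merge import (
    DEFAULT_MAX_MISMATCH_RATE,
    DEFAULT_MIN_OVERLAP,
    MergedRead,
    merge_pairs,
)
from .repeatscreen import (
    DEFAULT_MIN_LOCAL_IDENTITY,
    DEFAULT_RETENTION_THRESHOLD,
    filter_reads,
)
from .satcluster import (
    CLUSTER_THRESHOLDS,
    DEFAULT_LENGTH_DIFF_CUTOFF,
    Cluster,
    summarize_clusters,
    cluster_greedy,
)
from .satgraph import ClusterGraph, build_graph, mixing_summary
from .seqio import ReadPair, SequenceRecord, pair_reads, read_sequences


@dataclass
class RunConfig:
    """Parameters for one pipeline run; round-trips through YAML."""

    reads1: str | None = None
    reads2: str | None = None
    library: str | None = None
    sources: str | None = None  # optional TSV (read_id, source), e.g. truth.tsv
    min_overlap: int = DEFAULT_MIN_OVERLAP
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE
    retention_threshold: float = DEFAULT_RETENTION_THRESHOLD
    min_local_identity: float = DEFAULT_MIN_LOCAL_IDENTITY
    thresholds: tuple[float, ...] = CLUSTER_THRESHOLDS
    length_diff_cutoff: float = DEFAULT_LENGTH_DIFF_CUTOFF
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in data and data["thresholds"] is not None:
            data["thresholds"] = tuple(float(t) for t in data["thresholds"])
        return cls(**data)


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    version: str
    seed: int
    input_pairs: int
    merged: int
    retained: int
    clusters_per_threshold: dict[float, int]
    mixing_per_threshold: dict[float, tuple[float, float]]
    sources: list[str]
    output_paths: dict[str, str] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = [
            {"metric": "input_pairs", "value": self.input_pairs},
            {"metric": "merged_reads", "value": self.merged},
            {"metric": "retained_reads", "value": self.retained},
        ]
        for thr, n in sorted(self.clusters_per_threshold.items()):
            rows.append({"metric": f"clusters_at_{thr:g}", "value": n})
        for thr, (frac, h) in sorted(self.mixing_per_threshold.items()):
            rows.append({"metric": f"multi_source_fraction_at_{thr:g}",
                         "value": round(frac, 6)})
            rows.append({"metric": f"weighted_shannon_h_at_{thr:g}",
                         "value": round(h, 6)})
        return rows


@dataclass
class PipelineResult:
    """Report plus the in-memory products of every stage."""

    report: RunReport
    merged_reads: list[MergedRead]
    retained_reads: list[MergedRead]
    clusters: dict[float, list[Cluster]]
    graphs: dict[float, ClusterGraph]


def run_pipeline_from_records(
    pairs: Sequence[ReadPair],
    library: Sequence[SequenceRecord],
    config: RunConfig | None = None,
    source_of: Mapping[str, str] | None = None,
    initial_totals: Mapping[str, int] | None = None,
) -> PipelineResult:
    """Run merge -> screen -> cluster -> graph on in-memory records.

    ``source_of`` maps merged-read ids to their originating library; when
    omitted it is taken from each read's ``source`` attribute.
    """
    config = config or RunConfig()
    if not pairs:
        raise PipelineError("no input read pairs", stage="merge")

    merged, merge_stats = merge_pairs(
        pairs, config.min_overlap, config.max_mismatch_rate
    )
    if not merged:
        raise PipelineError("no pairs merged", stage="merge")

    if not library:
        raise PipelineError("empty satellite library", stage="screen")
    retained, screen_stats = filter_reads(
        merged, library, config.retention_threshold, config.min_local_identity
    )
    if not retained:
        raise PipelineError("no reads passed the repeat filter", stage="screen")

    if source_of is None:
        source_of = {
            r.id: (r.source or "unknown") for r in merged
        }
    if initial_totals is None:
        initial_totals = {}
        for pair in pairs:
            label = source_of.get(pair.id, pair.fwd.source or "unknown")
            initial_totals[label] = initial_totals.get(label, 0) + 1
    filtered_totals: dict[str, int] = {}
    for read in retained:
        label = source_of.get(read.id, "unknown")
        filtered_totals[label] = filtered_totals.get(label, 0) + 1

    clusters: dict[float, list[Cluster]] = {}
    graphs: dict[float, ClusterGraph] = {}
    clusters_per_threshold: dict[float, int] = {}
    mixing_per_threshold: dict[float, tuple[float, float]] = {}
    for threshold in config.thresholds:
        cl = cluster_greedy(
            retained, threshold, config.length_diff_cutoff, assignment="best"
        )
        summarize_clusters(cl, source_of, initial_totals, filtered_totals)
        graph = build_graph(cl)
        clusters[threshold] = cl
        graphs[threshold] = graph
        clusters_per_threshold[threshold] = len(cl)
        mixing_per_threshold[threshold] = mixing_summary(graph)

    report = RunReport(
        version=__version__,
        seed=config.seed,
        input_pairs=len(pairs),
        merged=merge_stats.merged,
        retained=screen_stats.retained,
        clusters_per_threshold=clusters_per_threshold,
        mixing_per_threshold=mixing_per_threshold,
        sources=sorted(set(source_of.values())),
    )
    return PipelineResult(
        report=report,
        merged_reads=merged,
        retained_reads=retained,
        clusters=clusters,
        graphs=graphs,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based entry point: reads mate FASTQs and the clone library."""
    if not config.reads1 or not config.reads2 or not config.library:
        raise PipelineError("reads1, reads2 and library paths are required",
                            stage="input")
    for path in (config.reads1, config.reads2, config.library):
        if not Path(path).exists():
            raise PipelineError(f"input not found: {path}", stage="input")
    fwd = read_sequences(config.reads1, "fastq")
    rev = read_sequences(config.reads2, "fastq")
    if not fwd:
        raise PipelineError("empty FASTQ input", stage="merge")
    pairs = pair_reads(fwd, rev)
    library = read_sequences(config.library, "fasta")
    source_of = None
    if config.sources:
        import pandas as pd

        table = pd.read_csv(config.sources, sep="\t")
        source_of = dict(zip(table["read_id"].astype(str),
                             table["source"].astype(str)))
    return run_pipeline_from_records(pairs, library, config,
                                     source_of=source_of)
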