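"""End-to-end convenience layer: files in, feature matrix out.

Chains the individual stages (read inputs -> scan peaks -> filter loops ->
label sites -> assemble features) with the default parameters of each;
the CLI and the examples are thin wrappers over this.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import features, io, labeling, motif


@dataclass
class PipelineResult:
    genome: io.Genome
    peaks: list[io.NarrowPeakRecord]
    hits: list[motif.MotifHit]
    anchors: list[io.GenomicInterval]
    sites: list[labeling.LabeledSite]
    rows: list[features.FeatureRow]


def build_feature_rows(
    fasta_path,
    narrowpeak_path,
    loops_path,
    pwm_path,
    fdr_threshold: float = labeling.DEFAULT_FDR_THRESHOLD,
    pseudocount: float = motif.DEFAULT_PSEUDOCOUNT,
    flank: int = features.DEFAULT_FLANK,
) -> PipelineResult:
    """Run the full labeling + featurization pipeline on the four input files."""
    genome = io.read_fasta(fasta_path)
    peaks = io.read_narrowpeak(narrowpeak_path)
    loops = io.read_loops(loops_path)
    pwm = motif.pwm_from_counts(motif.read_counts(pwm_path), pseudocount)

    hits = motif.scan_peaks(pwm, genome, peaks)
    anchors = labeling.collect_anchors(labeling.filter_loops(loops, fdr_threshold))
    sites = labeling.label_sites(hits, anchors)
    rows = features.assemble_matrix(sites, genome, peaks, flank=flank)
    return PipelineResult(genome, peaks, hits, anchors, sites, rows)
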