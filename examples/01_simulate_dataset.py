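"""Generate a synthetic CTCF dataset and look at what it contains.

The generator writes the four files the pipeline consumes — a genome FASTA,
ChIP-seq peaks (narrowPeak), ChIA-PET-style loops (TSV) and a PWM count
matrix — with a known ground truth: every peak holds a motif sampled from
the PWM, a chosen fraction of sites are true loop anchors, and anchors get
both a higher binding intensity and a tilted flanking-sequence composition.
"""

from loopanchor import default_strong_config, read_loops, simulate

config = default_strong_config(seed=7)
result = simulate(config, "example_output/dataset")

truth = result.truth
loops = read_loops(result.loops_path)
print(f"genome:     {result.fasta_path}")
print(f"peaks:      {result.narrowpeak_path}")
print(f"loops:      {result.loops_path} ({len(loops)} records, "
      f"{sum(lp.fdr < 0.05 for lp in loops)} below FDR 0.05)")
print(f"PWM:        {result.pwm_path} (width {config.pwm_width})")
print(f"sites:      {len(truth.sites)} total, {truth.n_positive} true anchors")
print(f"intensity:  positives ~ 2^N({config.intensity_mu_pos}, "
      f"{config.intensity_sigma}), negatives ~ 2^N({config.intensity_mu_neg}, "
      f"{config.intensity_sigma})")
# Loops whose FDR is >= 0.05 are decoys: the labeling stage must discard
# them, so only the sub-threshold loops define the positive class.
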