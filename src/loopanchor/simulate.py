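"""Self-contained synthetic dataset generator.

Emits exactly the four file types the pipeline consumes — genome FASTA,
narrowPeak peaks, loop TSV, PWM counts — with a known ground truth, so every
pipeline stage runs end to end with no external download.

What the simulation emulates (and what it does not): each binding site is a
motif sampled from an informative PWM planted in an i.i.d. uniform
background; a chosen fraction of sites are true anchors. Positive sites get
(i) higher binding intensity — signalValue = 2**N(mu_pos, sigma), so the
log2-normalized intensities are exactly normal and group tests are
analytically checkable — and (ii) flanks drawn with a per-position base
preference of strength ``flank_bias``, mimicking the flank-sequence signal
around anchor motifs. Loops are generated anchor-first from the positive
sites' peak intervals (FDR drawn below 0.05), with decoy loops above the
FDR cutoff always present so the loop filter is exercised. No chromatin
physics, read-level noise, or genome-composition realism is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    GenomicInterval,
    LoopRecord,
    NarrowPeakRecord,
    SequenceRecord,
    write_fasta,
    write_loops,
    write_narrowpeak,
)
from .motif import PWM, PWM_BASES, reverse_complement, uniform_background, write_counts_jaspar

_CHROM_MARGIN = 300  # site-free leading/trailing bases per chromosome
_PEAK_PAD = 50       # peak extends this far beyond the planted motif
_SLOT = 400          # per-site slot; keeps peaks of neighbouring sites disjoint


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 4
    n_sites: int = 2000
    positive_fraction: float = 0.45
    pwm_width: int = 19
    flank: int = 20
    intensity_mu_pos: float = 4.0
    intensity_mu_neg: float = 2.0
    intensity_sigma: float = 1.0
    flank_bias: float = 0.15
    consensus_prob: float = 0.85
    loop_fdr_range: tuple[float, float] = (0.001, 0.049)
    decoy_fdr_range: tuple[float, float] = (0.05, 0.5)
    decoy_fraction: float = 0.1

    def __post_init__(self):
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.intensity_sigma <= 0:
            raise ValueError("intensity_sigma must be > 0")
        if not (0.0 <= self.flank_bias <= 0.75):
            raise ValueError("flank_bias must be in [0, 0.75]")
        if self.pwm_width + 2 * _PEAK_PAD >= _SLOT:
            raise ValueError("pwm_width too large for the site slot size")

    @property
    def sites_per_chromosome(self) -> int:
        return -(-self.n_sites // self.n_chromosomes)  # ceil

    @property
    def chrom_length(self) -> int:
        return 2 * _CHROM_MARGIN + self.sites_per_chromosome * _SLOT


def default_strong_config(seed: int = 0) -> SimConfig:
    """Separable conditions: a 2-unit log2 intensity shift (one sd = 1) plus
    a 0.15 flank base-preference tilt at every flank position."""
    return SimConfig(seed=seed)


def default_null_config(seed: int = 0) -> SimConfig:
    """No signal anywhere: equal intensity distributions, unbiased flanks."""
    return SimConfig(
        seed=seed,
        intensity_mu_pos=3.0,
        intensity_mu_neg=3.0,
        flank_bias=0.0,
    )


@dataclass(frozen=True)
class GroundTruthSite:
    site_id: str
    interval: GenomicInterval  # planted motif location, stranded
    label: int
    signal_value: float
    window: str  # motif-oriented window (flank + core + flank)


@dataclass(frozen=True)
class GroundTruth:
    sites: tuple[GroundTruthSite, ...]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.sites], dtype=int)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


@dataclass(frozen=True)
class SimResult:
    config: SimConfig
    fasta_path: Path
    narrowpeak_path: Path
    loops_path: Path
    pwm_path: Path
    truth: GroundTruth
    pwm: PWM = field(repr=False, default=None)


def _random_pwm(rng: np.random.Generator, width: int, consensus_prob: float) -> PWM:
    consensus = rng.integers(0, 4, size=width)
    probs = np.full((width, 4), (1.0 - consensus_prob) / 3.0)
    probs[np.arange(width), consensus] = consensus_prob
    return PWM(probs=probs, background=uniform_background())


def _sample_codes(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """One base code per row of a (L, 4) probability matrix."""
    cum = probs.cumsum(axis=1)
    u = rng.random(probs.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(PWM_BASES[c] for c in codes)


def simulate(config: SimConfig, outdir) -> SimResult:
    """Generate the four input files plus ground truth; byte-identical for a
    fixed config (seed included)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    width, flank = config.pwm_width, config.flank

    pwm = _random_pwm(rng, width, config.consensus_prob)

    # per-flank-position preferred bases for positive sites
    n_flank_pos = 2 * flank
    preferred = rng.integers(0, 4, size=n_flank_pos)
    flank_probs = np.full((n_flank_pos, 4), (0.75 - config.flank_bias) / 3.0)
    flank_probs[np.arange(n_flank_pos), preferred] = 0.25 + config.flank_bias
    uniform_flank = np.full((n_flank_pos, 4), 0.25)

    # labels: exactly round(n_sites * positive_fraction) positives, shuffled
    n_pos = int(round(config.n_sites * config.positive_fraction))
    labels = np.zeros(config.n_sites, dtype=int)
    labels[:n_pos] = 1
    labels = labels[rng.permutation(config.n_sites)]

    # background genomes
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genomes = {
        c: rng.integers(0, 4, size=config.chrom_length) for c in chrom_names
    }

    sites: list[GroundTruthSite] = []
    peaks: list[NarrowPeakRecord] = []
    offset_lo, offset_hi = _PEAK_PAD, _SLOT - width - _PEAK_PAD
    for i in range(config.n_sites):
        chrom = chrom_names[i % config.n_chromosomes]
        slot = i // config.n_chromosomes
        slot_start = _CHROM_MARGIN + slot * _SLOT
        motif_start = slot_start + int(rng.integers(offset_lo, offset_hi + 1))
        label = int(labels[i])
        strand = "+" if rng.random() < 0.5 else "-"

        core = _codes_to_str(_sample_codes(rng, pwm.probs))
        fp = flank_probs if label == 1 else uniform_flank
        flank_bases = _codes_to_str(_sample_codes(rng, fp))
        window = flank_bases[:flank] + core + flank_bases[flank:]
        planted = window if strand == "+" else reverse_complement(window)
        # plant the full window so the flank signal is on the genome too
        win_start = motif_start - flank
        codes = np.frombuffer(planted.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.int64)
        for ci, b in enumerate(PWM_BASES):
            lut[ord(b)] = ci
        genomes[chrom][win_start : win_start + len(planted)] = lut[codes]

        mu = config.intensity_mu_pos if label == 1 else config.intensity_mu_neg
        signal = float(2.0 ** rng.normal(mu, config.intensity_sigma))
        interval = GenomicInterval(chrom, motif_start, motif_start + width, strand)
        sites.append(
            GroundTruthSite(
                site_id=f"site{i:05d}", interval=interval, label=label,
                signal_value=signal, window=window,
            )
        )
        peaks.append(
            NarrowPeakRecord(
                interval=GenomicInterval(
                    chrom, motif_start - _PEAK_PAD, motif_start + width + _PEAK_PAD
                ),
                name=f"peak{i:05d}",
                score=0,
                signal_value=signal,
            )
        )

    # loops: anchor-first from positive sites' peak intervals, cyclic within
    # each chromosome so shared anchors (and hence duplicates) occur
    loops: list[LoopRecord] = []
    pos_by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        if s.label == 1:
            pos_by_chrom.setdefault(s.interval.chrom, []).append(i)
    lo, hi = config.loop_fdr_range
    for chrom, idxs in pos_by_chrom.items():
        for j, i in enumerate(idxs):
            a = peaks[i].interval.unstranded()
            if len(idxs) > 1:
                b = peaks[idxs[(j + 1) % len(idxs)]].interval.unstranded()
            else:
                b = GenomicInterval(chrom, 0, 100)  # site-free margin
            loops.append(LoopRecord(a, b, float(rng.uniform(lo, hi))))
    # decoy loops above the FDR cutoff, anchored on negative sites
    neg_idx = [i for i, s in enumerate(sites) if s.label == 0]
    n_decoy = max(1, int(round(config.decoy_fraction * len(neg_idx))))
    dlo, dhi = config.decoy_fdr_range
    for i in neg_idx[:n_decoy]:
        a = peaks[i].interval.unstranded()
        b = GenomicInterval(a.chrom, 0, 100)
        loops.append(LoopRecord(a, b, float(rng.uniform(dlo, dhi))))

    fasta_path = outdir / "genome.fa"
    narrowpeak_path = outdir / "peaks.narrowPeak"
    loops_path = outdir / "loops.tsv"
    pwm_path = outdir / "ctcf_pwm.jaspar"
    write_fasta(
        [SequenceRecord(c, _codes_to_str(genomes[c])) for c in chrom_names],
        fasta_path,
    )
    write_narrowpeak(peaks, narrowpeak_path)
    write_loops(loops, loops_path)
    write_counts_jaspar(np.round(pwm.probs * 1000), pwm_path, name="synthetic_ctcf")

    return SimResult(
        config=config,
        fasta_path=fasta_path,
        narrowpeak_path=narrowpeak_path,
        loops_path=loops_path,
        pwm_path=pwm_path,
        truth=GroundTruth(sites=tuple(sites)),
        pwm=pwm,
    )
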