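"""PWM construction and log-odds motif scanning.

Each ChIP-seq peak is scanned on both strands with a position weight matrix
(19 bp for CTCF) and the single best-scoring occurrence is kept, together
with its strand — the strand later orients the 59-bp feature window so that
all sites are read in motif direction.

Scores are log2 odds against a background base distribution: the score of a
window is ``sum_i log2(p_i[b_i] / bg[b_i])``. The logarithm base is a pure
rescaling and does not affect any downstream ranking or group comparison.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .io import FormatError, Genome, GenomicInterval

logger = logging.getLogger(__name__)

#: channel order used by PWMs and scanning (standard alphabetical order;
#: distinct from the one-hot feature order, which is A,T,C,G — see features)
PWM_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(PWM_BASES)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.8


def reverse_complement(bases: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    if not set(bases) <= set("ACGTN"):
        raise ValueError(f"non-ACGTN characters in {bases!r}")
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: width x 4 probabilities (A,C,G,T) plus a
    background distribution (uniform by default)."""

    probs: np.ndarray
    background: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError(f"probs must be width x 4, got {probs.shape}")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if np.any(probs <= 0):
            raise ValueError("PWM probabilities must be strictly positive "
                             "(apply a pseudocount)")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """width x 4 matrix of log2(p / background)."""
        return np.log2(self.probs / self.background[None, :])

    def consensus(self) -> str:
        return "".join(PWM_BASES[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    """Best motif occurrence in one peak: stranded interval, matching score,
    index of the source peak (for intensity lookup)."""

    interval: GenomicInterval
    score: float
    peak_index: int

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError("MotifHit interval must be stranded")


def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def pwm_from_counts(
    counts, pseudocount: float = DEFAULT_PSEUDOCOUNT, background=None
) -> PWM:
    """Build a PWM from a width x 4 count matrix (columns A,C,G,T).

    ``probs[i][b] = (counts[i][b] + pseudocount) / (rowsum + 4 * pseudocount)``
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError(f"counts must be width x 4, got {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    denom = counts.sum(axis=1) + 4.0 * pseudocount
    if np.any(denom == 0):
        raise ValueError("all-zero count row with pseudocount 0")
    probs = (counts + pseudocount) / denom[:, None]
    bg = uniform_background() if background is None else np.asarray(background, float)
    return PWM(probs=probs, background=bg)


def encode_bases(bases: str) -> np.ndarray:
    """Integer-encode a sequence: A,C,G,T -> 0..3, N -> 4."""
    return np.frombuffer(
        bases.upper().translate(str.maketrans("ACGTN", "\x00\x01\x02\x03\x04"))
        .encode("latin-1"),
        dtype=np.uint8,
    ).astype(np.int64)


def score_window(pwm: PWM, window: str, strand: str = "+") -> float:
    """Log2-odds score of one window; "-" scores its reverse complement.

    Any N in the window gives -inf (an N carries no base identity to score).
    """
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != PWM width {pwm.width}"
        )
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    if strand == "-":
        window = reverse_complement(window)
    codes = encode_bases(window)
    if np.any(codes == 4):
        return float("-inf")
    return float(pwm.log_odds[np.arange(pwm.width), codes].sum())


def _sliding_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Scores of all + strand offsets of an integer-encoded region; windows
    containing N score -inf. Vectorized over offsets."""
    w = pwm.width
    n = codes.size - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)  # n x w
    has_n = (windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    scores = pwm.log_odds[np.arange(w)[None, :], safe].sum(axis=1)
    scores[has_n] = -np.inf
    return scores[:n]


def scan_region(pwm: PWM, genome: Genome, region: GenomicInterval,
                peak_index: int = -1) -> MotifHit | None:
    """Best-scoring motif occurrence over all offsets of both strands.

    Ties break toward the smaller start, then + before -. Returns None (the
    no-hit sentinel) when every window contains an N.
    """
    if len(region) < pwm.width:
        raise ValueError(
            f"region length {len(region)} shorter than PWM width {pwm.width}"
        )
    seq = genome.fetch(region.chrom, region.start, region.end)
    codes = encode_bases(seq)
    fwd = _sliding_scores(pwm, codes)
    # scoring the reverse complement of each window == scanning the
    # reverse-complemented region and mapping offsets back
    rev_codes = encode_bases(reverse_complement(seq))
    rev = _sliding_scores(pwm, rev_codes)[::-1]  # align to forward offsets
    best = float(max(fwd.max(), rev.max()))
    if best == float("-inf"):
        return None
    # tie-break: smallest start first, + preferred at equal start
    for off in range(fwd.size):
        if fwd[off] == best:
            strand, offset = "+", off
            break
        if rev[off] == best:
            strand, offset = "-", off
            break
    start = region.start + offset
    return MotifHit(
        interval=GenomicInterval(region.chrom, start, start + pwm.width, strand),
        score=best,
        peak_index=peak_index,
    )


def scan_peaks(pwm: PWM, genome: Genome, peaks) -> list[MotifHit]:
    """One best hit per peak; peaks that are too short, off-chromosome, or
    all-N are dropped and the dropped count is logged."""
    hits: list[MotifHit] = []
    dropped = 0
    for i, peak in enumerate(peaks):
        iv = peak.interval
        try:
            if iv.chrom not in genome or len(iv) < pwm.width:
                dropped += 1
                continue
            chrom_len = len(genome[iv.chrom])
            clipped = GenomicInterval(
                iv.chrom, max(0, iv.start), min(chrom_len, iv.end), iv.strand
            )
            if len(clipped) < pwm.width:
                dropped += 1
                continue
            hit = scan_region(pwm, genome, clipped, peak_index=i)
        except (KeyError, IndexError):
            dropped += 1
            continue
        if hit is None:
            dropped += 1
            continue
        hits.append(hit)
    if dropped:
        logger.info("scan_peaks: dropped %d of %d peaks with no usable hit",
                    dropped, len(list(peaks)) if not hasattr(peaks, "__len__") else len(peaks))
    return hits


# ---------------------------------------------------------------------------
# count-matrix file formats
# ---------------------------------------------------------------------------

_JASPAR_ROW = re.compile(r"^([ACGT])\s*\[?\s*([\d.\s]*?)\s*\]?\s*$")


def read_counts(path) -> np.ndarray:
    """Read a motif count matrix: JASPAR-style ("A [ 1 2 ... ]" rows, with
    or without brackets / a ">" header) or a plain width x 4 TSV (columns
    A,C,G,T). Returns a width x 4 array."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError("empty count-matrix file", path, 1)
    body = [ln for ln in lines if not ln.startswith(">")]
    jaspar_rows = {}
    for ln in body:
        m = _JASPAR_ROW.match(ln.strip())
        if m and m.group(2).strip():
            jaspar_rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    if set(jaspar_rows) == set("ACGT"):
        widths = {len(v) for v in jaspar_rows.values()}
        if len(widths) != 1:
            raise FormatError("JASPAR rows have unequal widths", path)
        return np.array([jaspar_rows[b] for b in PWM_BASES], dtype=float).T
    # fall back to width x 4 TSV (optional header naming the bases)
    rows = []
    for lineno, ln in enumerate(body, start=1):
        fields = ln.split("\t") if "\t" in ln else ln.split()
        if lineno == 1 and not _is_numeric(fields[0]):
            continue
        if len(fields) != 4:
            raise FormatError(
                f"count row has {len(fields)} columns, expected 4", path, lineno
            )
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise FormatError(f"bad count row: {exc}", path, lineno) from exc
    if not rows:
        raise FormatError("no count rows found", path)
    return np.array(rows, dtype=float)


def write_counts_jaspar(counts: np.ndarray, path, name: str = "motif") -> None:
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i, base in enumerate(PWM_BASES):
            vals = " ".join(f"{v:g}" for v in counts[:, i])
            fh.write(f"{base} [ {vals} ]\n")


def write_hits_tsv(hits, path) -> None:
    """Stage product of scanning: one stranded hit per line."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tscore\tpeak_index\n")
        for h in hits:
            iv = h.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                     f"{h.score!r}\t{h.peak_index}\n")


def read_hits_tsv(path) -> list[MotifHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise FormatError("missing hits header", path, 1)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 6:
                raise FormatError(f"hit line has {len(f)} columns, expected 6",
                                  path, lineno)
            hits.append(
                MotifHit(
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2]), f[3]),
                    score=float(f[4]),
                    peak_index=int(f[5]),
                )
            )
    return hits


def _is_numeric(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
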