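"""Feature construction: strand-oriented 59-bp windows, one-hot encoding,
log2-normalized binding intensity.

The one-hot channel order is A, T, C, G — deliberately NOT alphabetical.
This matches the published encoding convention (A=(1,0,0,0), T=(0,1,0,0),
C=(0,0,1,0), G=(0,0,0,1)) and every consumer of the feature matrix in this
package assumes it. N encodes as all zeros.

A feature row is: 4 * window_length one-hot values (236 for the default
19 + 2*20 window), then the log2 intensity, then the 0/1 anchor label.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import Genome, NarrowPeakRecord
from .labeling import LabeledSite
from .motif import MotifHit, reverse_complement

logger = logging.getLogger(__name__)

#: one-hot channel order (the published convention; not alphabetical)
ONEHOT_BASES = "ATCG"
_CHANNEL = {b: i for i, b in enumerate(ONEHOT_BASES)}

DEFAULT_FLANK = 20


@dataclass
class FeatureRow:
    """One classifier input: site id, one-hot block, intensity, label."""

    site_id: str
    onehot: np.ndarray
    intensity: float
    label: int

    def __post_init__(self):
        self.onehot = np.asarray(self.onehot, dtype=np.int8)
        if self.onehot.ndim != 1 or self.onehot.size % 4:
            raise ValueError("onehot must be a flat vector of length 4*positions")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def features(self) -> np.ndarray:
        """One-hot block with the intensity appended (model input order)."""
        return np.concatenate([self.onehot.astype(float), [self.intensity]])


def feature_names(window_length: int = 59) -> list[str]:
    """Column names: pos00_A ... pos58_G then intensity (position-major,
    channel order A,T,C,G)."""
    names = [
        f"pos{p:02d}_{b}" for p in range(window_length) for b in ONEHOT_BASES
    ]
    names.append("intensity")
    return names


def extract_window(hit: MotifHit, genome: Genome, flank: int = DEFAULT_FLANK) -> str:
    """Motif-oriented sequence window: the hit extended by ``flank`` bases on
    each side; minus-strand hits are reverse-complemented so the 5' flank of
    the motif always comes first.

    Raises IndexError when the window runs past a chromosome end (callers
    drop such sites; no sequence is invented by padding).
    """
    iv = hit.interval
    seq = genome.fetch(iv.chrom, iv.start - flank, iv.end + flank)
    if iv.strand == "-":
        seq = reverse_complement(seq)
    return seq


def one_hot(window: str) -> np.ndarray:
    """Position-major one-hot vector, channel order A,T,C,G; N -> all-zero."""
    out = np.zeros(4 * len(window), dtype=np.int8)
    for i, base in enumerate(window.upper()):
        if base == "N":
            continue
        try:
            out[4 * i + _CHANNEL[base]] = 1
        except KeyError:
            raise ValueError(f"invalid base {base!r} at position {i}") from None
    return out


def decode_one_hot(vec: np.ndarray) -> str:
    """Inverse of :func:`one_hot` (all-zero positions decode to N)."""
    vec = np.asarray(vec).reshape(-1, 4)
    return "".join(
        "N" if row.sum() == 0 else ONEHOT_BASES[int(row.argmax())] for row in vec
    )


def normalize_intensity(signal_value: float) -> float:
    """log2 of the ChIP-seq signalValue; requires a strictly positive value."""
    if signal_value <= 0:
        raise ValueError(f"signal_value must be > 0, got {signal_value}")
    return math.log2(signal_value)


def assemble_matrix(
    sites: list[LabeledSite],
    genome: Genome,
    peaks: list[NarrowPeakRecord],
    flank: int = DEFAULT_FLANK,
) -> list[FeatureRow]:
    """One FeatureRow per retained site.

    The intensity comes from each hit's source peak (``peak_index``). Sites
    whose window crosses a chromosome boundary are dropped, and the dropped
    count is logged — padding would invent sequence.
    """
    rows: list[FeatureRow] = []
    dropped = 0
    for j, site in enumerate(sites):
        hit = site.hit
        try:
            window = extract_window(hit, genome, flank=flank)
        except (IndexError, KeyError):
            dropped += 1
            continue
        peak = peaks[hit.peak_index]
        iv = hit.interval
        rows.append(
            FeatureRow(
                site_id=f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})",
                onehot=one_hot(window),
                intensity=normalize_intensity(peak.signal_value),
                label=site.label,
            )
        )
    if dropped:
        logger.info("assemble_matrix: dropped %d of %d boundary sites",
                    dropped, len(sites))
    return rows


def design_matrix(rows: list[FeatureRow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack rows into (X, y): X has the one-hot block first and the
    intensity as the last column."""
    X = np.stack([r.features for r in rows])
    y = np.array([r.label for r in rows], dtype=int)
    return X, y
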