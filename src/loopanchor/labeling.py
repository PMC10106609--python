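"""Positive/negative set construction.

Loops passing the FDR cutoff define the anchor universe; a motif site is a
positive example (label 1) iff its interval shares at least one base with
any anchor under half-open arithmetic. Anchors are unstranded and
exact-coordinate duplicates (one anchor joining many loops) are removed.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

from .io import GenomicInterval, LoopRecord
from .motif import MotifHit

DEFAULT_FDR_THRESHOLD = 0.05


@dataclass(frozen=True)
class LabeledSite:
    hit: MotifHit
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def filter_loops(loops, fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> list[LoopRecord]:
    """Keep loops with fdr strictly below the threshold (default 0.05)."""
    return [lp for lp in loops if lp.fdr < fdr_threshold]


def collect_anchors(loops) -> list[GenomicInterval]:
    """Pool both anchors of every loop, drop exact-coordinate duplicates,
    preserve first-seen order."""
    seen = set()
    out: list[GenomicInterval] = []
    for lp in loops:
        for anchor in (lp.anchor_a, lp.anchor_b):
            a = anchor.unstranded()
            key = (a.chrom, a.start, a.end)
            if key not in seen:
                seen.add(key)
                out.append(a)
    return out


class _AnchorIndex:
    """Sorted-anchor overlap index, one per chromosome.

    Anchors are sorted by start; a query interval [qs, qe) can only overlap
    anchors with start < qe, and among those we need any with end > qs.
    A running prefix-max of ends answers that in O(log m).
    """

    def __init__(self, anchors):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for a in anchors:
            by_chrom.setdefault(a.chrom, []).append((a.start, a.end))
        self._starts: dict[str, list[int]] = {}
        self._max_end_prefix: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = [s for s, _ in ivs]
            prefix = []
            running = 0
            for _, e in ivs:
                running = max(running, e)
                prefix.append(running)
            self._starts[chrom] = starts
            self._max_end_prefix[chrom] = prefix

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        starts = self._starts.get(iv.chrom)
        if not starts:
            return False
        k = bisect_right(starts, iv.end - 1)  # anchors with start < iv.end
        return k > 0 and self._max_end_prefix[iv.chrom][k - 1] > iv.start


def label_sites(hits, anchors) -> list[LabeledSite]:
    """Label each hit 1 iff it overlaps (>= 1 bp, strand ignored) any anchor."""
    index = _AnchorIndex(anchors)
    return [
        LabeledSite(hit=h, label=int(index.overlaps_any(h.interval))) for h in hits
    ]


def write_labeled_tsv(sites, path) -> None:
    """Stage product of labeling: hit coordinates plus the 0/1 label."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tscore\tpeak_index\tlabel\n")
        for s in sites:
            iv = s.hit.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                     f"{s.hit.score!r}\t{s.hit.peak_index}\t{s.label}\n")


def read_labeled_tsv(path) -> list[LabeledSite]:
    from .io import FormatError

    sites = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise FormatError("missing labeled-sites header", path, 1)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 7:
                raise FormatError(
                    f"labeled line has {len(f)} columns, expected 7", path, lineno
                )
            sites.append(
                LabeledSite(
                    hit=MotifHit(
                        interval=GenomicInterval(f[0], int(f[1]), int(f[2]), f[3]),
                        score=float(f[4]),
                        peak_index=int(f[5]),
                    ),
                    label=int(f[6]),
                )
            )
    return sites


def label_sites_bruteforce(hits, anchors) -> list[LabeledSite]:
    """All-pairs reference implementation; used as the oracle in tests."""
    return [
        LabeledSite(
            hit=h,
            label=int(any(h.interval.overlaps(a) for a in anchors)),
        )
        for h in hits
    ]
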