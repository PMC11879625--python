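"""Windowed runs-of-homozygosity caller.

A window-based ROH rule: a fixed-width window (default 25 kbp) is part of a
run of homozygosity when the individual shows no heterozygous genotype in it
and at least 80% of its sites are genotyped (20+ kbp genotyped in a 25 kbp
window).  Consecutive qualifying windows merge into maximal segments; any
non-qualifying window, for whatever reason, terminates a run unless
``bridge_missing`` allows data-poor windows to be skipped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import List, Optional

from .diversity_metrics import GenomeWindow


class WindowReason(str, enum.Enum):
    PASS = "pass"
    HAS_HET = "has_het"
    INSUFFICIENT_GENOTYPED = "insufficient_genotyped"
    PARTIAL_WINDOW = "partial_window"


@dataclass
class ROHWindowCall:
    window: GenomeWindow
    qualifies: bool
    reason: WindowReason


@dataclass
class ROHSegment:
    """A maximal run of consecutive qualifying windows (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_windows: int


@dataclass
class ROHSummary:
    sample: str
    n_segments: int
    n_qualifying_windows: int
    total_length: int
    f_roh: float


def call_roh_windows(
    windows: List[GenomeWindow],
    min_frac: float = 0.8,
) -> List[ROHWindowCall]:
    """Classify every window; ``qualifies`` iff the window is full-width,
    has zero heterozygous sites and >= ``min_frac`` of its span genotyped.

    Partial terminal windows never qualify — the rule is defined on full
    windows.  Reasons are assigned with partiality checked first, then
    genotyping support, then heterozygosity.
    """
    calls: List[ROHWindowCall] = []
    for w in windows:
        if w.is_partial:
            calls.append(ROHWindowCall(w, False, WindowReason.PARTIAL_WINDOW))
        elif w.n_genotyped < min_frac * w.width:
            calls.append(ROHWindowCall(w, False, WindowReason.INSUFFICIENT_GENOTYPED))
        elif w.n_het > 0:
            calls.append(ROHWindowCall(w, False, WindowReason.HAS_HET))
        else:
            calls.append(ROHWindowCall(w, True, WindowReason.PASS))
    return calls


def merge_segments(
    calls: List[ROHWindowCall],
    bridge_missing: bool = False,
) -> List[ROHSegment]:
    """Merge maximal runs of consecutive qualifying windows into segments.

    Chromosome boundaries always terminate a run.  With ``bridge_missing``,
    windows failing only the genotyping-support rule are skipped without
    terminating the run (they contribute no length); by default they break
    it, the conservative reading.
    """
    # ordering check: windows must be genome-sorted, chromosomes contiguous
    seen = []
    prev_chrom: Optional[str] = None
    prev_start = -1
    for c in calls:
        w = c.window
        if w.chrom != prev_chrom:
            if w.chrom in seen:
                raise ValueError("window calls not ordered: chromosome repeats")
            seen.append(w.chrom)
            prev_start = -1
        elif w.start <= prev_start:
            raise ValueError(f"window calls not ordered at {w.chrom}:{w.start}")
        prev_chrom, prev_start = w.chrom, w.start

    segments: List[ROHSegment] = []
    cur: Optional[ROHSegment] = None
    cur_chrom: Optional[str] = None
    for c in calls:
        w = c.window
        if w.chrom != cur_chrom:
            cur = None
            cur_chrom = w.chrom
        if c.qualifies:
            if cur is None:
                cur = ROHSegment(w.chrom, w.start, w.end, 1)
                segments.append(cur)
            else:
                cur.end = w.end
                cur.n_windows += 1
        elif bridge_missing and c.reason == WindowReason.INSUFFICIENT_GENOTYPED:
            continue  # bridge: neither extend nor terminate
        else:
            cur = None
    return segments


def summarize_roh(
    segments: List[ROHSegment],
    callable_length: int,
    sample: str = "",
    width: Optional[int] = None,
) -> ROHSummary:
    """Summarise segment count, qualifying-window count, total length and
    the ROH fraction of the callable genome."""
    if callable_length <= 0:
        raise ValueError("callable length must be positive to define f_roh")
    n_windows = sum(s.n_windows for s in segments)
    if width is not None:
        total = width * n_windows
    else:
        total = sum(s.end - s.start for s in segments)
    return ROHSummary(
        sample=sample,
        n_segments=len(segments),
        n_qualifying_windows=n_windows,
        total_length=int(total),
        f_roh=total / callable_length,
    )


def write_segments_bed(segments: List[ROHSegment], path: str) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.n_windows}\n")
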