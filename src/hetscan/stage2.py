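"""Stage 2: regions of increased heterozygosity (RIH).

Each chromosome's H track is partitioned into maximal rise-then-fall runs:
successive differences of consecutive H values are scanned, zero differences
are skipped, and a segment extends from the variant where H starts rising,
through the local maximum ``H_max``, to the variant where H stops falling.
Variants in strictly monotone stretches outside any rise-then-fall run (a
falling prefix or rising suffix of a chromosome, or plateaus between
segments) belong to no segment; a target variant that lands there cannot be
given a Stage-2 rank.

When two consecutive segments would share their boundary valley variant, the
valley is assigned to the earlier segment so that segment index ranges stay
pairwise disjoint; this affects membership only, never any ``H_max``.

A target variant is scored by the competition rank of its containing
segment's ``H_max`` among all segments' ``H_max`` values, optionally after
discarding segments shorter than 1/4, 1/2 or 1x the mean segment length
``w`` (ranks ``rank2``/``rank3``/``rank4``; a length cut can discard the
target's own segment, in which case that rank is reported absent).  The
estimated disease-variant position is the position attaining ``H_max`` in
the containing segment, and ``d`` is its absolute distance to the target in
bp.
"""
from __future__ import annotations

import bisect
import dataclasses
import logging
from pathlib import Path

import numpy as np

from ._util import competition_rank
from .io import VariantSite
from .stage1 import HTrack, Stage1Rank, rank_h

logger = logging.getLogger(__name__)

__all__ = [
    "RIHSegment",
    "Stage2Rank",
    "segment_rih",
    "mean_segment_length",
    "rank_hmax",
    "segments_to_bed",
]


@dataclasses.dataclass(frozen=True)
class RIHSegment:
    """One region of increased heterozygosity.

    ``start_idx``/``end_idx`` are inclusive *global* row indices into the
    source :class:`~hetscan.stage1.HTrack`; positions are the bp coordinates
    of the first and last member variant.  ``length_bp = end_pos -
    start_pos`` (an alternative variant-count length is ``n_variants``).
    """

    chrom: str
    start_idx: int
    end_idx: int
    start_pos: int
    end_pos: int
    hmax: float
    hmax_pos: int

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos

    @property
    def n_variants(self) -> int:
        return self.end_idx - self.start_idx + 1

    def length(self, mode: str = "bp") -> int:
        if mode == "bp":
            return self.length_bp
        if mode == "variants":
            return self.n_variants
        raise ValueError(f"unknown length mode {mode!r}")

    def contains(self, idx: int) -> bool:
        return self.start_idx <= idx <= self.end_idx


def _scan_chrom(H: np.ndarray) -> list[tuple[int, int]]:
    """Rise-then-fall scan of one chromosome's H values.

    Returns inclusive (start, end) local index pairs.  Zero differences are
    skipped throughout; a segment requires at least one strictly rising and
    one strictly falling difference.
    """
    n = len(H)
    if n < 2:
        return []
    d = np.sign(np.diff(H))
    segs: list[tuple[int, int]] = []
    prev_end = -1
    k = 0
    while k < n - 1:
        while k < n - 1 and d[k] <= 0:  # search for the next rise
            k += 1
        if k >= n - 1:
            break
        start = k  # left variant of the first rising difference
        while k < n - 1 and d[k] >= 0:  # consume the rise (plateaus absorbed)
            k += 1
        if k >= n - 1:
            break  # rising suffix never falls: no segment
        last_fall = -1
        while k < n - 1 and d[k] <= 0:  # consume the fall
            if d[k] < 0:
                last_fall = k
            k += 1
        end = last_fall + 1  # right variant of the last falling difference
        if start == prev_end:
            # boundary valley shared with the previous segment: keep ranges
            # disjoint by assigning the valley to the earlier segment
            start += 1
        segs.append((start, end))
        prev_end = end
    return segs


def segment_rih(track: HTrack) -> list[RIHSegment]:
    """Partition the H track into RIH segments, per chromosome.

    A chromosome whose H values never rise and fall (e.g. constant H) yields
    no segments; a warning is logged.
    """
    segments: list[RIHSegment] = []
    for chrom, sl in track.blocks():
        H = track.H[sl]
        local = _scan_chrom(H)
        if not local:
            logger.warning("chromosome %s: no RIH segments (monotone or constant H)", chrom)
            continue
        for s, e in local:
            seg_H = H[s : e + 1]
            peak = s + int(np.argmax(seg_H))  # leftmost attaining variant
            segments.append(
                RIHSegment(
                    chrom=chrom,
                    start_idx=sl.start + s,
                    end_idx=sl.start + e,
                    start_pos=int(track.pos[sl.start + s]),
                    end_pos=int(track.pos[sl.start + e]),
                    hmax=float(seg_H.max()),
                    hmax_pos=int(track.pos[sl.start + peak]),
                )
            )
    return segments


def mean_segment_length(segments: list[RIHSegment], mode: str = "bp") -> float:
    """Genome-wide arithmetic mean segment length ``w``."""
    if not segments:
        raise ValueError("no segments")
    return float(np.mean([s.length(mode) for s in segments]))


def segment_containing(segments: list[RIHSegment], row: int) -> RIHSegment | None:
    """Segment whose (disjoint, sorted) index range contains a track row."""
    per_chrom: dict[str, list[RIHSegment]] = {}
    for s in segments:
        per_chrom.setdefault(s.chrom, []).append(s)
    for segs in per_chrom.values():
        starts = [s.start_idx for s in segs]
        i = bisect.bisect_right(starts, row) - 1
        if i >= 0 and segs[i].contains(row):
            return segs[i]
    return None


@dataclasses.dataclass(frozen=True)
class Stage2Rank:
    """Genome-wide rank of the target's containing-segment H_max.

    ``status`` is "ok", "no_rih" (the target's H value sits in a monotone
    stretch outside every segment), or "no_value" (no Stage-1 H at the
    target).  ``rank2``/``rank3``/``rank4`` are None when the length cut
    discards the target's own segment — the risk the stricter cuts carry.
    """

    status: str
    n_segments: int
    segment: RIHSegment | None = None
    rank: int | None = None
    rank2: int | None = None
    rank3: int | None = None
    rank4: int | None = None
    w: float | None = None
    d: int | None = None

    def rank_or_n(self, which: str = "rank") -> str:
        """Report-friendly value: the rank, or "n" when unavailable."""
        v = getattr(self, which)
        return "n" if v is None else str(v)


def rank_hmax(
    track: HTrack,
    segments: list[RIHSegment],
    target: VariantSite,
    length_mode: str = "bp",
) -> Stage2Rank:
    """Rank the target's containing-segment H_max among all segments.

    ``rank2``/``rank3``/``rank4`` re-rank after keeping only segments whose
    length is at least ``w/4``, ``w/2`` and ``w`` (``w`` = genome-wide mean
    length).  The target's own segment is subject to the same cut.
    """
    if not segments:
        raise ValueError("no segments to rank against")
    s1 = rank_h(track, target)
    if s1.status != "ok":
        return Stage2Rank(status="no_value", n_segments=len(segments))
    row = track.index_of(target)
    assert row is not None
    seg = segment_containing(segments, row)
    if seg is None:
        logger.info(
            "target %s:%d has an H value but falls in no RIH segment",
            target.chrom,
            target.pos,
        )
        return Stage2Rank(status="no_rih", n_segments=len(segments))

    hmax_all = np.array([s.hmax for s in segments])
    lengths = np.array([s.length(length_mode) for s in segments], dtype=float)
    w = float(lengths.mean())
    filtered: dict[str, int | None] = {}
    for name, frac in (("rank2", 0.25), ("rank3", 0.5), ("rank4", 1.0)):
        thr = frac * w
        if seg.length(length_mode) < thr:
            filtered[name] = None  # the cut discarded the target's segment
        else:
            filtered[name] = competition_rank(hmax_all[lengths >= thr], seg.hmax)
    return Stage2Rank(
        status="ok",
        n_segments=len(segments),
        segment=seg,
        rank=competition_rank(hmax_all, seg.hmax),
        w=w,
        d=abs(seg.hmax_pos - target.pos),
        **filtered,
    )


def segments_to_bed(
    segments: list[RIHSegment],
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    """BED export: chrom, start-1, end, hmax, length_bp (0-based half-open)."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start_pos - 1}\t{s.end_pos}\t{s.hmax:.6f}\t{s.length_bp}\n"
            )
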