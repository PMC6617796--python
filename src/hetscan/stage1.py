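"""Stage 1: moving-average heterozygosity.

At every variant the scan counts, over a window of the variant and the ``m``
variants on either side of it (a ``2m+1``-point window, pooled over all
analyzed individuals), the number ``g`` of homozygous and ``h`` of
heterozygous genotypes, and emits the heterozygosity fraction

    H = h / (g + h).

Missing genotypes contribute to neither count.  The window never spans a
chromosome boundary, so the first and last ``m`` variants of each chromosome
carry no H value.  With several individuals the raw counts are pooled (summed)
across individuals rather than averaging per-individual H — the two differ
under missingness, and pooling is what makes ``g + h = (2m+1) n`` when no
genotype is missing.

A candidate variant is scored by the competition rank of its H among all
emitted H values (largest H = rank 1; ties share the smallest rank) and by
``top% = 100 * rank / N_var``.
"""
from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterator
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import competition_rank, round_half_up
from .io import HET, HOM, GenotypeMatrix, VariantSite

logger = logging.getLogger(__name__)

__all__ = ["WindowConfig", "HTrack", "Stage1Rank", "window_counts", "compute_htrack", "rank_h"]


@dataclasses.dataclass(frozen=True)
class WindowConfig:
    """Half-window size ``m`` in variants (window spans ``2m+1`` variants)."""

    m: int = 50

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError(f"m must be >= 0, got {self.m}")

    @property
    def span(self) -> int:
        return 2 * self.m + 1


@dataclasses.dataclass
class HTrack:
    """Per-variant windowed heterozygosity values, genome-wide.

    One entry per *eligible* variant: variants closer than ``m`` to a
    chromosome edge, and the rare variant whose whole window is missing,
    carry no value.  Entries keep chromosome grouping and position order of
    the source matrix.
    """

    m: int
    chrom: np.ndarray  # str per emitted value
    pos: np.ndarray  # int64
    g: np.ndarray  # int64 window homozygote count
    h: np.ndarray  # int64 window heterozygote count
    H: np.ndarray  # float64 in [0, 1]
    n_skipped: int = 0  # all-missing windows dropped

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, int], int] | None = None

    @property
    def n_var(self) -> int:
        """Number of emitted H values (the N_var of rank reports)."""
        return len(self.H)

    def blocks(self) -> Iterator[tuple[str, slice]]:
        if self.n_var == 0:
            return
        start = 0
        for i in range(1, self.n_var):
            if self.chrom[i] != self.chrom[start]:
                yield str(self.chrom[start]), slice(start, i)
                start = i
        yield str(self.chrom[start]), slice(start, self.n_var)

    def index_of(self, site: VariantSite) -> int | None:
        """Track row of a site, or None if the site carries no H value."""
        if self._index is None:
            self._index = {}
            for i, (c, p) in enumerate(zip(self.chrom, self.pos)):
                self._index.setdefault((str(c), int(p)), i)
        return self._index.get((site.chrom, site.pos))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "g": self.g, "h": self.h, "H": self.H}
        )

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        """Tab-separated track: chrom, pos, g, h, H (6 decimals)."""
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("chrom\tpos\tg\th\tH\n")
            for c, p, g, h, H in zip(self.chrom, self.pos, self.g, self.h, self.H):
                fh.write(f"{c}\t{p}\t{g}\t{h}\t{H:.6f}\n")

    def to_bedgraph(self, path: str | Path) -> None:
        """bedGraph export of H (0-based half-open single-bp intervals)."""
        with open(path, "w") as fh:
            fh.write('track type=bedGraph name="hetscan H"\n')
            for c, p, H in zip(self.chrom, self.pos, self.H):
                fh.write(f"{c}\t{p - 1}\t{p}\t{H:.6f}\n")


def window_counts(
    matrix: GenotypeMatrix, chrom: str, i: int, cfg: WindowConfig
) -> tuple[int, int] | None:
    """(g, h) counts for the window centred on within-chromosome index ``i``.

    Counts are pooled over all samples of the matrix; MISSING genotypes are
    excluded.  Returns None when the window would touch a chromosome edge
    (the caller skips such variants).
    """
    for c, sl in matrix.blocks():
        if c == chrom:
            n = sl.stop - sl.start
            if i < cfg.m or i > n - 1 - cfg.m:
                return None
            w = matrix.calls[sl][i - cfg.m : i + cfg.m + 1]
            return int(np.sum(w == HOM)), int(np.sum(w == HET))
    raise KeyError(f"chromosome {chrom!r} not in matrix")


def _window_sum(x: np.ndarray, m: int) -> np.ndarray:
    """Sliding (2m+1)-window sums of an integer vector (exact, via cumsum)."""
    c = np.concatenate([[0], np.cumsum(x, dtype=np.int64)])
    return c[2 * m + 1 :] - c[: len(x) - 2 * m]


def compute_htrack(matrix: GenotypeMatrix, cfg: WindowConfig | None = None) -> HTrack:
    """Compute the Stage-1 H track for every eligible variant, genome-wide.

    Chromosomes with fewer than ``2m+1`` variants yield no values.  A window
    in which every genotype is missing has no defined H; such variants are
    skipped (not assigned 0, which would bias downstream segmentation) and
    counted in ``n_skipped``.
    """
    cfg = cfg or WindowConfig()
    if matrix.n_sites == 0:
        raise ValueError("empty genotype matrix")
    m = cfg.m
    chroms: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    gs: list[np.ndarray] = []
    hs: list[np.ndarray] = []
    n_skipped = 0
    for c, sl in matrix.blocks():
        calls = matrix.calls[sl]
        n = calls.shape[0]
        if n < cfg.span:
            logger.warning("chromosome %s has %d < %d variants; no H values", c, n, cfg.span)
            continue
        site_g = np.sum(calls == HOM, axis=1).astype(np.int64)
        site_h = np.sum(calls == HET, axis=1).astype(np.int64)
        wg = _window_sum(site_g, m)
        wh = _window_sum(site_h, m)
        keep = (wg + wh) > 0
        if not keep.all():
            n_skipped += int(np.sum(~keep))
            logger.warning(
                "chromosome %s: %d all-missing window(s) skipped", c, int(np.sum(~keep))
            )
        pos = matrix.pos[sl][m : n - m]
        chroms.append(np.asarray(matrix.chrom[sl][m : n - m])[keep])
        poss.append(pos[keep])
        gs.append(wg[keep])
        hs.append(wh[keep])
    if not poss:
        raise ValueError(f"no chromosome has more than {2 * m} variants; reduce m")
    g = np.concatenate(gs)
    h = np.concatenate(hs)
    return HTrack(
        m=m,
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        g=g,
        h=h,
        H=h / (g + h),
        n_skipped=n_skipped,
    )


@dataclasses.dataclass(frozen=True)
class Stage1Rank:
    """Genome-wide rank of a target variant's Stage-1 H value.

    ``status`` is "ok" when the target carries an H value, "no_value" when it
    does not (edge variant, skipped window, or absent from the data) — the
    Stage-1 analogue of a target that cannot be scored.
    """

    status: str
    n_var: int
    rank: int | None = None
    H: float | None = None

    @property
    def top_pct(self) -> float | None:
        """100 * rank / N_var, full precision."""
        if self.rank is None:
            return None
        return 100.0 * self.rank / self.n_var

    @property
    def top_pct_display(self) -> float | None:
        """top% rounded half-up to one decimal, the report convention."""
        return None if self.top_pct is None else round_half_up(self.top_pct, 1)


def rank_h(track: HTrack, target: VariantSite) -> Stage1Rank:
    """Rank the target's H among all emitted H values (largest = rank 1)."""
    row = track.index_of(target)
    if row is None:
        return Stage1Rank(status="no_value", n_var=track.n_var)
    Hval = float(track.H[row])
    return Stage1Rank(
        status="ok",
        n_var=track.n_var,
        rank=competition_rank(track.H, Hval),
        H=Hval,
    )
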