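"""Empirical genome-wide significance by random placement of a null target.

Under the null hypothesis the disease variant could sit at any of the marker
positions carrying an H value.  Each replicate places a null disease variant
uniformly at random among those markers and records the H value there and
the H_max of the RIH segment containing it (if any).  Because the scan
itself does not depend on where the target is placed, replicates can reread
the precomputed track — an exact shortcut, not an approximation.

With ``N`` replicates and the observed value included in the count, the
number ``k`` of values at least as large as the observed one gives

    p = k / (N + 1),

so the smallest attainable p is ``1/(N+1)`` (0.001 at the default N = 999).
Null positions falling in no RIH segment contribute no H_max exceedance.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

from .io import VariantSite
from .stage1 import HTrack
from .stage2 import RIHSegment

__all__ = ["EmpiricalResult", "empirical_p", "hmax_by_row"]


@dataclasses.dataclass(frozen=True)
class EmpiricalResult:
    """Empirical significance of an observed H (and containing H_max)."""

    target: VariantSite
    H_obs: float
    Hmax_obs: float | None
    N: int
    k_H: int
    p_H: float
    k_Hmax: int | None
    p_Hmax: float | None
    seed: int | None

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        def fmt(v):
            return "n" if v is None else (f"{v:.6g}" if isinstance(v, float) else str(v))

        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("target\tH_obs\tp_H\tHmax_obs\tp_Hmax\tN\tseed\n")
            fh.write(
                f"{self.target.chrom}:{self.target.pos}\t{self.H_obs:.6f}\t"
                f"{self.p_H:.6g}\t{fmt(self.Hmax_obs)}\t{fmt(self.p_Hmax)}\t"
                f"{self.N}\t{fmt(self.seed)}\n"
            )


def hmax_by_row(track: HTrack, segments: list[RIHSegment]) -> np.ndarray:
    """H_max of the segment containing each track row (NaN where none)."""
    out = np.full(track.n_var, np.nan)
    for s in segments:
        out[s.start_idx : s.end_idx + 1] = s.hmax
    return out


def empirical_p(
    track: HTrack,
    segments: list[RIHSegment],
    target: VariantSite,
    N: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EmpiricalResult:
    """Empirical p-values for the target's H and containing-segment H_max.

    Replicates draw null positions uniformly, independently and with
    replacement among all markers carrying an H value.  Fixing ``seed``
    makes the result bit-reproducible; ``rng`` may be passed instead for
    callers managing their own generator stream.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    row = track.index_of(target)
    if row is None:
        raise ValueError(f"target {target.chrom}:{target.pos} has no H value")
    H_obs = float(track.H[row])
    hmax_at = hmax_by_row(track, segments)
    Hmax_obs = None if math.isnan(hmax_at[row]) else float(hmax_at[row])

    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, track.n_var, size=N)
    k_H = 1 + int(np.sum(track.H[idx] >= H_obs))  # the observed value counts
    p_H = k_H / (N + 1)
    if Hmax_obs is None:
        k_Hmax = p_Hmax = None
    else:
        null_hmax = hmax_at[idx]
        exceed = null_hmax[~np.isnan(null_hmax)] >= Hmax_obs
        k_Hmax = 1 + int(np.sum(exceed))
        p_Hmax = k_Hmax / (N + 1)
    return EmpiricalResult(
        target=target,
        H_obs=H_obs,
        Hmax_obs=Hmax_obs,
        N=N,
        k_H=k_H,
        p_H=p_H,
        k_Hmax=k_Hmax,
        p_Hmax=p_Hmax,
        seed=seed,
    )
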