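"""Closed-form two-locus model for heterozygosity near an inherited dominant variant.

Consider a disease locus with wild-type allele ``+`` and mutant allele ``u``
(population frequency ``e``), and a nearby marker with alleles ``A``/``B``
where ``f`` is the frequency of ``A`` and ``D`` the linkage-disequilibrium
parameter.  Haplotype frequencies are

    u-A: ef + D        u-B: e(1-f) - D
    +-A: (1-e)f - D    +-B: (1-e)(1-f) + D

Within the unrecombined founder region flanking an inherited dominant
variant, only the founder allele (call it ``A``) occurs on the disease
haplotype, so the u-B haplotype is absent (D' = 1, D = D_max = e(1-f)).  A
carrier is then heterozygous at the marker exactly when the homologous
(non-disease) chromosome carries ``B``:

    H = P(B | +) = (1 - f) / (1 - e)  >  1 - f,

whereas a marker far from the disease variant is heterozygous with the
Hardy-Weinberg probability ``2 f (1 - f)``.  The enrichment ratio

    r = H / [2 f (1 - f)] = 1 / [2 f (1 - e)]  >  1 / (2 f)

is large precisely for rare founder alleles — the phenomenon the windowed
scan exploits.  These closed forms serve as the analytic oracle for the
synthetic-cohort generator.
"""
from __future__ import annotations

import dataclasses

__all__ = [
    "PopGenParams",
    "haplotype_freqs",
    "het_near_disease",
    "het_random",
    "het_ratio",
]


def _check_unit_open(name: str, x: float) -> None:
    if not 0.0 < x < 1.0:
        raise ValueError(f"{name} must be in (0, 1), got {x}")


@dataclasses.dataclass(frozen=True)
class PopGenParams:
    """Disease-allele frequency ``e``, marker A-allele frequency ``f``, LD ``D``."""

    e: float
    f: float
    D: float = 0.0

    def __post_init__(self) -> None:
        _check_unit_open("e", self.e)
        _check_unit_open("f", self.f)
        lo, hi = self.d_range
        if not lo <= self.D <= hi:
            raise ValueError(
                f"D={self.D} outside admissible range [{lo:.6g}, {hi:.6g}] "
                f"for e={self.e}, f={self.f} (a haplotype frequency would be negative)"
            )

    @property
    def d_range(self) -> tuple[float, float]:
        """Admissible D interval keeping all four haplotype frequencies >= 0."""
        e, f = self.e, self.f
        return (max(-e * f, -(1 - e) * (1 - f)), min(e * (1 - f), (1 - e) * f))

    @property
    def d_max(self) -> float:
        """D at complete disequilibrium with the u-B haplotype absent."""
        return self.e * (1 - self.f)


def haplotype_freqs(params: PopGenParams) -> dict[str, float]:
    """The four haplotype frequencies {uA, uB, +A, +B}; they sum to 1."""
    e, f, D = params.e, params.f, params.D
    return {
        "uA": e * f + D,
        "uB": e * (1 - f) - D,
        "+A": (1 - e) * f - D,
        "+B": (1 - e) * (1 - f) + D,
    }


def het_near_disease(e: float, f: float) -> float:
    """Carrier marker heterozygosity inside the founder region, (1-f)/(1-e).

    Assumes complete disequilibrium (D = D_max) with the founder allele A at
    frequency ``f``.  Requires ``e <= f``: otherwise the conditional
    probability would exceed 1 and the D_max assumption is inconsistent.
    """
    _check_unit_open("e", e)
    _check_unit_open("f", f)
    H = (1 - f) / (1 - e)
    if H > 1.0:
        raise ValueError(
            f"(1-f)/(1-e) = {H:.6g} > 1 for e={e}, f={f}: the complete-"
            "disequilibrium model requires e <= f"
        )
    return H


def het_random(f: float) -> float:
    """Hardy-Weinberg heterozygosity 2 f (1 - f) at a random marker."""
    _check_unit_open("f", f)
    return 2 * f * (1 - f)


def het_ratio(e: float, f: float) -> float:
    """Enrichment ratio r = 1 / [2 f (1 - e)] of founder-region over random markers."""
    het_near_disease(e, f)  # validates parameters and model consistency
    return 1.0 / (2 * f * (1 - e))
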