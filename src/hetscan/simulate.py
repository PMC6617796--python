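"""Synthetic cohorts with a planted inherited dominant variant.

The generator emulates the minimal population structure the scan relies on:
carriers share a fixed founder haplotype across an unrecombined region R
around the disease position, while everything else — noncarrier genotypes,
and carrier genotypes outside R — is an independent Hardy-Weinberg draw at
each marker's population allele frequency.  No pedigree or recombination
process is simulated; R is imposed directly as the segment between the two
recombination events flanking the variant.

Allele conventions.  At each marker the ALT allele has population frequency
``f`` drawn from a rare-skewed law (so ALT is the minor allele).  Within R
the default ``founder_mode="allele_a"`` puts the ALT allele on the founder
haplotype — the complete-disequilibrium configuration of the closed-form
model, where ``f`` is by definition the frequency of the allele on the
disease haplotype.  A carrier's homologous chromosome carries ALT with
probability ``(f - e)/(1 - e)`` (its frequency among wild-type haplotypes),
so the per-site carrier heterozygosity in R is exactly ``(1-f)/(1-e)``
versus ``2f(1-f)`` elsewhere.  ``founder_mode="random"`` instead draws the
founder allele from the population frequency; that configuration has *no*
expected heterozygosity elevation (the marginal is again ``2f(1-f)``) and
serves as a structured null.

The disease variant itself is inserted as a marker (carriers heterozygous
``u/+``, noncarriers Hardy-Weinberg at frequency ``e``), so the natural scan
target exists in the output.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from .io import HET, HOM, MISSING, GenotypeMatrix, VariantSite

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "TruthRecord", "simulate_cohort", "pseudo_disease_target"]


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a scaled-down whole-genome regime: 4 chromosomes of
    50 Mb with 5,000 markers each (one per 10 kb), a rare-skewed Beta(0.8, 4)
    minor-allele-frequency law clipped to [0.01, 0.5], three carriers and
    three noncarriers, an unrecombined region extending 600 kb either side
    of the disease variant (~60 markers per side, comfortably spanning the
    default 101-point scan window), 2% missing genotypes, and a disease
    allele at frequency 0.01.
    """

    n_variants: int = 5000  # per chromosome
    n_chromosomes: int = 4
    chrom_length_bp: int = 50_000_000
    maf_distribution: tuple = ("beta", 0.8, 4.0)  # ("beta",a,b) | ("fixed",f) | ("uniform",lo,hi)
    maf_min: float = 0.01
    disease_chrom: str | None = None  # default: first chromosome
    disease_pos: int | None = None  # default: chromosome midpoint
    r_halfwidth_bp: int = 600_000
    n_carriers: int = 3
    n_noncarriers: int = 3
    disease_freq: float = 0.01  # e
    founder_mode: str = "allele_a"  # or "random"
    missing_rate: float = 0.02
    include_disease_site: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one variant and one chromosome")
        if self.n_carriers < 0 or self.n_noncarriers < 0:
            raise ValueError("sample counts must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not 0.0 <= self.disease_freq < 0.5:
            raise ValueError(f"disease_freq must be in [0, 0.5), got {self.disease_freq}")
        if self.founder_mode not in ("allele_a", "random"):
            raise ValueError(f"unknown founder_mode {self.founder_mode!r}")
        if self.n_variants > self.chrom_length_bp:
            raise ValueError("more variants than base pairs per chromosome")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def resolved_disease_site(self) -> tuple[str, int]:
        chrom = self.disease_chrom or self.chrom_names[0]
        if chrom not in self.chrom_names:
            raise ValueError(f"disease_chrom {chrom!r} not among {self.chrom_names}")
        pos = self.disease_pos if self.disease_pos is not None else self.chrom_length_bp // 2
        if not 1 <= pos <= self.chrom_length_bp:
            raise ValueError(f"disease_pos {pos} outside chromosome [1, {self.chrom_length_bp}]")
        return chrom, pos


@dataclasses.dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, consistent with the emitted VCF."""

    disease_site: VariantSite
    r_start: int
    r_end: int
    carrier_status: dict[str, bool]  # sample id -> is carrier
    founder_alleles: dict[int, int]  # R-variant pos -> founder allele (0=REF, 1=ALT)
    maf: dict[str, list[float]]  # chrom -> per-variant ALT frequency
    config: SimConfig
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "disease_site": {
                "chrom": self.disease_site.chrom,
                "pos": self.disease_site.pos,
                "id": self.disease_site.id,
            },
            "r_start": self.r_start,
            "r_end": self.r_end,
            "carrier_status": self.carrier_status,
            "founder_alleles": {str(k): v for k, v in self.founder_alleles.items()},
            "maf": self.maf,
            "config": dataclasses.asdict(self.config),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct sorted positions in [1, length]."""
    got: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 16))
    while len(got) < n:
        more = rng.integers(1, length + 1, size=n)
        got = np.unique(np.concatenate([got, more]))
    # deterministic thinning to exactly n while keeping order
    keep = np.sort(rng.choice(len(got), size=n, replace=False))
    return got[keep]


def _draw_maf(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    law = cfg.maf_distribution
    kind = law[0]
    if kind == "beta":
        f = rng.beta(law[1], law[2], size=n)
    elif kind == "fixed":
        f = np.full(n, float(law[1]))
    elif kind == "uniform":
        f = rng.uniform(law[1], law[2], size=n)
    else:
        raise ValueError(f"unknown maf law {kind!r}")
    lo = max(cfg.maf_min, cfg.disease_freq, 1e-6)
    return np.clip(f, lo, 0.5)


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Generate a truth-labelled cohort; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    e = cfg.disease_freq
    d_chrom, d_pos = cfg.resolved_disease_site()
    r_start = d_pos - cfg.r_halfwidth_bp
    r_end = d_pos + cfg.r_halfwidth_bp
    if r_start < 1 or r_end > cfg.chrom_length_bp:
        logger.warning(
            "region R [%d, %d] extends past chromosome [1, %d]; truncated",
            r_start,
            r_end,
            cfg.chrom_length_bp,
        )
        r_start = max(1, r_start)
        r_end = min(cfg.chrom_length_bp, r_end)

    samples = [f"car{i + 1:02d}" for i in range(cfg.n_carriers)] + [
        f"non{i + 1:02d}" for i in range(cfg.n_noncarriers)
    ]
    if not samples:
        raise ValueError("cohort needs at least one sample")
    k = len(samples)
    is_carrier = np.array([s.startswith("car") for s in samples])

    chroms: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    calls: list[np.ndarray] = []
    maf_truth: dict[str, list[float]] = {}
    founder_alleles: dict[int, int] = {}

    for chrom in cfg.chrom_names:
        pos = _draw_positions(rng, cfg.n_variants, cfg.chrom_length_bp)
        site_ids = np.full(len(pos), ".", dtype=object)
        if chrom == d_chrom and cfg.include_disease_site:
            if d_pos not in pos:
                pos = np.sort(np.append(pos, d_pos))
            site_ids = np.full(len(pos), ".", dtype=object)
            site_ids[np.searchsorted(pos, d_pos)] = "disease_u"
        n = len(pos)
        f = _draw_maf(rng, cfg, n)

        in_r = (chrom == d_chrom) & (pos >= r_start) & (pos <= r_end)
        is_disease_site = np.zeros(n, dtype=bool)
        if chrom == d_chrom and cfg.include_disease_site:
            is_disease_site[np.searchsorted(pos, d_pos)] = True
            f[is_disease_site] = e if e > 0 else cfg.maf_min

        # two independent haplotypes per sample at frequency f (HWE)
        hap1 = rng.random((n, k)) < f[:, None]
        hap2 = rng.random((n, k)) < f[:, None]

        if np.any(in_r) and cfg.n_carriers:
            idx = np.where(in_r & ~is_disease_site)[0]
            if cfg.founder_mode == "allele_a":
                founder = np.ones(len(idx), dtype=bool)  # ALT on the disease haplotype
                p_other = (f[idx] - e) / (1 - e)  # ALT frequency among + haplotypes
            else:
                founder = rng.random(len(idx)) < f[idx]
                p_other = f[idx]
            hap1[np.ix_(idx, np.where(is_carrier)[0])] = founder[:, None]
            hap2[np.ix_(idx, np.where(is_carrier)[0])] = (
                rng.random((len(idx), int(is_carrier.sum()))) < p_other[:, None]
            )
            for j, pidx in enumerate(idx):
                founder_alleles[int(pos[pidx])] = int(founder[j])

        classes = np.where(hap1 != hap2, int(HET), int(HOM)).astype(np.int8)
        if cfg.include_disease_site and chrom == d_chrom:
            # carriers are u/+ at the disease variant itself
            drow = int(np.where(is_disease_site)[0][0])
            classes[drow, is_carrier] = int(HET)
        if cfg.missing_rate > 0:
            miss = rng.random((n, k)) < cfg.missing_rate
            classes[miss] = int(MISSING)

        chroms.append(np.full(n, chrom, dtype=object))
        poss.append(pos.astype(np.int64))
        ids.append(site_ids)
        calls.append(classes)
        maf_truth[chrom] = [float(x) for x in f]

    matrix = GenotypeMatrix(
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        ids=np.concatenate(ids),
        samples=samples,
        calls=np.vstack(calls),
    )
    truth = TruthRecord(
        disease_site=VariantSite(d_chrom, d_pos, "disease_u" if cfg.include_disease_site else None),
        r_start=r_start,
        r_end=r_end,
        carrier_status={s: bool(c) for s, c in zip(samples, is_carrier)},
        founder_alleles=founder_alleles,
        maf=maf_truth,
        config=cfg,
        seed=cfg.seed,
    )
    return matrix, truth


def pseudo_disease_target(matrix: GenotypeMatrix, chrom: str, position: int) -> VariantSite:
    """The marker nearest a queried position (ties broken toward lower pos).

    Used to place pseudo-disease variants in control individuals whose data
    lack the true variant.
    """
    for c, sl in matrix.blocks():
        if c != chrom:
            continue
        pos = matrix.pos[sl]
        i = int(np.searchsorted(pos, position))
        cand = []
        if i > 0:
            cand.append(int(pos[i - 1]))
        if i < len(pos):
            cand.append(int(pos[i]))
        best = min(cand, key=lambda p: (abs(p - position), p))
        row = sl.start + int(np.searchsorted(pos, best))
        vid = matrix.ids[row]
        return VariantSite(chrom, best, None if vid == "." else str(vid))
    raise KeyError(f"chromosome {chrom!r} not in matrix")
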