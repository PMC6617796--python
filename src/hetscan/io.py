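"""Genotype input/output.

Reads a multi-sample VCF into an ordered matrix of genotype *classes*.  The
heterozygosity scan only distinguishes heterozygous from homozygous calls, so
allele identity is collapsed at read time: any genotype whose two allele
indices differ (including two distinct ALT alleles, e.g. ``1/2``) is
heterozygous, identical indices are homozygous, and any missing allele
(``./.``, ``./1``) makes the whole call missing.

Only CHROM, POS, ID and the GT field are consulted.  The writer emits a
minimal valid VCF 4.2 with a GT-only FORMAT; since only genotype classes are
retained, homozygous calls are written as ``0/0`` and heterozygous calls as
``0/1`` — a write/read round trip preserves classes, not alleles.
"""
from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Iterator, Sequence
from enum import IntEnum
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeClass",
    "HOM",
    "HET",
    "MISSING",
    "VariantSite",
    "GenotypeMatrix",
    "VCFError",
    "UnsortedVCFError",
    "UnknownSampleError",
    "classify_genotype",
    "read_vcf",
    "write_vcf",
]

#: Chromosome names flagged (not excluded) in scan output; the method treats
#: them like autosomes but hemizygous genotypes make H hard to interpret.
SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY", "23", "24"})


class GenotypeClass(IntEnum):
    """Genotype call collapsed to the het/hom dichotomy."""

    HOM = 0
    HET = 1
    MISSING = 2


HOM = GenotypeClass.HOM
HET = GenotypeClass.HET
MISSING = GenotypeClass.MISSING


class VCFError(ValueError):
    """Malformed or unusable VCF input."""


class UnsortedVCFError(VCFError):
    """Records are not position-sorted within a chromosome."""


class UnknownSampleError(VCFError):
    """A requested sample is absent from the VCF header."""


@dataclasses.dataclass(frozen=True)
class VariantSite:
    """A genomic marker position (1-based, as in VCF)."""

    chrom: str
    pos: int
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


def classify_genotype(allele_indices: Sequence[int | None]) -> GenotypeClass:
    """Classify a parsed GT field (pair of allele indices) as HOM/HET/MISSING.

    ``None`` or a negative index marks a missing allele.  Half-missing calls
    such as ``./1`` are conservatively treated as MISSING.  Phasing is
    irrelevant and the classification is symmetric in allele order.
    """
    try:
        a, b = allele_indices
    except (TypeError, ValueError) as exc:
        raise VCFError(
            f"malformed genotype {allele_indices!r}: expected two allele indices"
        ) from exc
    if a is None or b is None or a < 0 or b < 0:
        return MISSING
    return HET if a != b else HOM


@dataclasses.dataclass
class GenotypeMatrix:
    """Ordered per-site, per-sample genotype classes.

    Sites are grouped by chromosome in file order and sorted by position
    within each chromosome (duplicate positions permitted, kept in file
    order).  ``calls`` is an int8 array of :class:`GenotypeClass` values of
    shape ``(n_sites, n_samples)``.
    """

    chrom: np.ndarray  # str per site
    pos: np.ndarray  # int64 per site
    ids: np.ndarray  # str or '.' per site
    samples: list[str]
    calls: np.ndarray  # int8, (n_sites, n_samples)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        self._check_order()

    def _check_order(self) -> None:
        seen: set[str] = set()
        prev_chrom = None
        for c in self.chrom:
            if c != prev_chrom:
                if c in seen:
                    raise UnsortedVCFError(f"chromosome {c} occurs in two blocks")
                seen.add(c)
                prev_chrom = c
        for c, sl in self.blocks():
            p = self.pos[sl]
            if np.any(np.diff(p) < 0):
                raise UnsortedVCFError(
                    f"positions on {c} are not sorted; sort the input "
                    "(e.g. `bcftools sort`) and retry"
                )

    # -- structure ---------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chromosomes(self) -> list[str]:
        return [c for c, _ in self.blocks()]

    def blocks(self) -> Iterator[tuple[str, slice]]:
        """Yield ``(chrom, slice)`` for each chromosome block in order."""
        if self.n_sites == 0:
            return
        start = 0
        for i in range(1, self.n_sites):
            if self.chrom[i] != self.chrom[start]:
                yield str(self.chrom[start]), slice(start, i)
                start = i
        yield str(self.chrom[start]), slice(start, self.n_sites)

    def sites(self) -> Iterator[VariantSite]:
        for c, p, i in zip(self.chrom, self.pos, self.ids):
            yield VariantSite(str(c), int(p), None if i in (".", None) else str(i))

    def subset_samples(self, names: Iterable[str]) -> "GenotypeMatrix":
        names = list(names)
        missing = [s for s in names if s not in self.samples]
        if missing:
            raise UnknownSampleError(
                f"unknown sample(s) {missing}; available: {self.samples}"
            )
        cols = [self.samples.index(s) for s in names]
        return GenotypeMatrix(
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ids=self.ids.copy(),
            samples=names,
            calls=self.calls[:, cols].copy(),
        )


def _cyvcf2_classes(variant, n_samples: int) -> np.ndarray:
    """Classify all samples of one cyvcf2 record."""
    out = np.empty(n_samples, dtype=np.int8)
    for j, entry in enumerate(variant.genotypes):
        alleles = entry[:-1]  # last element is the phased flag
        if len(alleles) < 2:
            # haploid or absent call: not interpretable as het/hom
            out[j] = MISSING
        else:
            a, b = alleles[0], alleles[1]
            out[j] = MISSING if (a < 0 or b < 0) else (HET if a != b else HOM)
    return out


def read_vcf(
    path: str | Path,
    sample_subset: Sequence[str] | None = None,
    pass_only: bool = False,
) -> GenotypeMatrix:
    """Read a (possibly bgzipped) VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF 4.x file, plain or bgzip-compressed.
    sample_subset
        Optional sample names to keep, in the given order.  Unknown names
        raise :class:`UnknownSampleError` listing available samples.
    pass_only
        If true, keep only records whose FILTER is PASS/'.'.  Off by
        default: no variant QC is applied, since robustness to allele
        frequency is intrinsic to the windowed statistic.

    Multi-allelic records are kept as single sites.  One matrix row is
    produced per retained VCF record; input must be position-sorted per
    chromosome (duplicated positions are allowed and retained in file
    order).
    """
    vcf = VCF(str(path))
    if sample_subset is not None:
        requested = list(sample_subset)
        available = list(vcf.samples)
        unknown = [s for s in requested if s not in available]
        if unknown:
            raise UnknownSampleError(
                f"unknown sample(s) {unknown}; available: {available}"
            )
        vcf.set_samples(requested)
    samples = list(vcf.samples)
    if not samples:
        raise VCFError(f"no samples in {path}")

    chroms: list[str] = []
    positions: list[int] = []
    ids: list[str] = []
    rows: list[np.ndarray] = []
    prev: tuple[str, int] | None = None
    finished: set[str] = set()
    for variant in vcf:
        if pass_only and variant.FILTER is not None:
            continue
        c, p = variant.CHROM, variant.POS
        if prev is not None:
            if c != prev[0]:
                finished.add(prev[0])
                if c in finished:
                    raise UnsortedVCFError(
                        f"chromosome {c} is split into several blocks in {path}; "
                        "sort the input (e.g. `bcftools sort`) and retry"
                    )
            elif p < prev[1]:
                raise UnsortedVCFError(
                    f"unsorted record {c}:{p} after {prev[0]}:{prev[1]} in {path}; "
                    "sort the input (e.g. `bcftools sort`) and retry"
                )
        prev = (c, p)
        chroms.append(c)
        positions.append(p)
        ids.append(variant.ID or ".")
        rows.append(_cyvcf2_classes(variant, len(samples)))
    vcf.close()

    calls = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    flagged = sorted(set(chroms) & SEX_CHROMOSOMES)
    if flagged:
        logger.warning(
            "sex chromosome(s) %s scanned like autosomes; interpret H with care",
            ",".join(flagged),
        )
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ids=np.array(ids, dtype=object),
        samples=samples,
        calls=calls,
    )


_GT_STRING = {int(HOM): "0/0", int(HET): "0/1", int(MISSING): "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    extra_header_lines: Sequence[str] = (),
) -> None:
    """Write genotype classes as a minimal VCF 4.2 (GT-only FORMAT).

    Allele identity is not retained by :class:`GenotypeMatrix`, so HOM is
    emitted as ``0/0`` and HET as ``0/1`` with placeholder REF/ALT alleles.
    """
    path = Path(path)
    lengths: dict[str, int] = {}
    for c, sl in matrix.blocks():
        lengths[c] = int(matrix.pos[sl].max()) if sl.stop > sl.start else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hetscan\n")
        for line in extra_header_lines:
            fh.write(line.rstrip("\n") + "\n")
        for c, ln in lengths.items():
            fh.write(f"##contig=<ID={c},length={ln + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_sites):
            gts = "\t".join(_GT_STRING[int(g)] for g in matrix.calls[i])
            fh.write(
                f"{matrix.chrom[i]}\t{matrix.pos[i]}\t{matrix.ids[i]}\t"
                f"A\tC\t.\tPASS\t.\tGT\t{gts}\n"
            )
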