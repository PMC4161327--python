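"""Pairwise linkage disequilibrium from phased haplotypes and proxy selection.

The entry point of the fine-mapping funnel: given a phased reference panel
(emulating, e.g., the 1000 Genomes EUR panel) and a GWAS index SNP, compute
r² against every other biallelic SNP and keep those above a threshold as
LD proxies — the candidate set carried into annotation overlap.

r² is computed from haplotype frequencies: with alt-allele frequencies
``p_a`` and ``p_b`` and alt-alt haplotype frequency ``p_ab``,

    D  = p_ab − p_a·p_b
    r² = D² / (p_a(1−p_a) · p_b(1−p_b))

which for 0/1 allele codes equals the squared Pearson correlation of the
two columns. Monomorphic sites have no defined r² and raise instead of
returning a sentinel, so callers can never silently rank them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")


class MonomorphicSiteError(ValueError):
    """r² is undefined when either site carries a single allele."""


class MissingGenotypeError(ValueError):
    """A record had no usable phased genotype for some sample."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP (VCF conventions: 1-based position, single-base alleles)."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref and alt alleles are identical ({self.ref})")
        for allele in (self.ref, self.alt):
            if allele not in _VALID_ALLELES:
                raise ValueError(f"{self.id}: allele {allele!r} not a single base in ACGT")


@dataclass
class HaplotypePanel:
    """Phased biallelic variants × chromosomes.

    ``haplotypes`` holds 0/1 alt-allele indicators with one row per parental
    chromosome (two per diploid sample) and one column per variant, ordered
    by genomic position.
    """

    variants: list[VariantRecord]
    haplotypes: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError(
                f"haplotype matrix has {self.haplotypes.shape[1]} columns "
                f"for {len(self.variants)} variants"
            )
        bad = ~np.isin(self.haplotypes, (0, 1))
        if bad.any():
            raise ValueError("haplotype matrix entries must be 0 or 1")
        self._index = {v.id: i for i, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValueError("duplicate variant ids in panel")

    @property
    def n_chromosomes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant(self, variant_id: str) -> VariantRecord:
        return self.variants[self.column_index(variant_id)]

    def column_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None

    def column(self, variant_id: str) -> np.ndarray:
        return self.haplotypes[:, self.column_index(variant_id)]


@dataclass(frozen=True)
class LDResult:
    """Pairwise LD summary between two variants on the same haplotypes."""

    variant_a: str
    variant_b: str
    p_a: float
    p_b: float
    p_ab: float
    d: float
    r2: float


def r2_from_haplotype_freqs(p_ab: float, p_a: float, p_b: float) -> tuple[float, float]:
    """Return (D, r²) from the alt-alt haplotype frequency and the two marginals."""
    # grouped per site so the product commutes: r2(a,b) == r2(b,a) exactly
    denom = (p_a * (1.0 - p_a)) * (p_b * (1.0 - p_b))
    if denom <= 0.0:
        raise MonomorphicSiteError(
            f"r2 undefined: monomorphic site (p_a={p_a}, p_b={p_b})"
        )
    d = p_ab - p_a * p_b
    return d, (d * d) / denom


def allele_frequency(panel: HaplotypePanel, variant_id: str) -> float:
    """Alt-allele frequency: proportion of chromosomes carrying the alt allele."""
    col = panel.column(variant_id)
    return float(col.sum()) / col.shape[0]


def compute_r2(panel: HaplotypePanel, a: str, b: str) -> LDResult:
    """Pairwise LD between two panel variants; symmetric in (a, b).

    Raises :class:`MonomorphicSiteError` if either site is fixed, so that
    callers must explicitly skip such pairs rather than rank them.
    """
    col_a = panel.column(a).astype(np.float64)
    col_b = panel.column(b).astype(np.float64)
    n = col_a.shape[0]
    p_a = float(col_a.sum()) / n
    p_b = float(col_b.sum()) / n
    p_ab = float((col_a * col_b).sum()) / n
    d, r2 = r2_from_haplotype_freqs(p_ab, p_a, p_b)
    # clip fp noise; r2 is mathematically in [0, 1]
    r2 = min(max(r2, 0.0), 1.0)
    return LDResult(variant_a=a, variant_b=b, p_a=p_a, p_b=p_b, p_ab=p_ab, d=d, r2=r2)


def select_proxies(
    panel: HaplotypePanel, index: str, threshold: float
) -> list[tuple[str, float]]:
    """All panel variants with r² ≥ ``threshold`` against the index SNP.

    The index itself appears with r² = 1 whenever the threshold admits it.
    Output is sorted by descending r², ties broken by ascending genomic
    position. Monomorphic variants are skipped with a logged id.
    """
    panel.column_index(index)  # raise early on unknown id
    if allele_frequency(panel, index) in (0.0, 1.0):
        raise MonomorphicSiteError(f"index SNP {index} is monomorphic in the panel")
    hits: list[tuple[str, float, int]] = []
    skipped: list[str] = []
    for v in panel.variants:
        try:
            res = compute_r2(panel, v.id, index)
        except MonomorphicSiteError:
            skipped.append(v.id)
            continue
        if res.r2 >= threshold:
            hits.append((v.id, res.r2, v.pos))
    if skipped:
        logger.info("select_proxies: skipped %d monomorphic variants: %s",
                    len(skipped), ",".join(skipped))
    hits.sort(key=lambda h: (-h[1], h[2]))
    return [(vid, r2) for vid, r2, _ in hits]


def read_vcf_haplotypes(path: str | Path, region: str | None = None) -> HaplotypePanel:
    """Build a :class:`HaplotypePanel` from a phased diploid VCF.

    Only biallelic SNPs are retained; multiallelic, indel and unphased
    records are skipped with a logged count. A record lacking a GT field,
    or any sample with a missing genotype, is an error — LD estimates would
    be silently biased by dropping rows.

    ``region`` is an optional ``chrom`` or ``chrom:start-end`` filter
    (1-based, inclusive).
    """
    from cyvcf2 import VCF

    want_chrom, want_start, want_end = _parse_region(region)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if want_chrom is not None:
            if rec.CHROM != want_chrom:
                continue
            if want_start is not None and not (want_start <= rec.POS <= want_end):
                continue
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        if alts[0] not in _VALID_ALLELES or rec.REF not in _VALID_ALLELES:
            n_skipped += 1
            continue
        if "GT" not in (rec.FORMAT or []):
            raise MissingGenotypeError(
                f"record {rec.CHROM}:{rec.POS} ({rec.ID or '.'}) has no GT field"
            )
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        if any(g[0] < 0 or g[1] < 0 for g in gts):
            raise MissingGenotypeError(
                f"missing genotype at {rec.CHROM}:{rec.POS} ({rec.ID or '.'}); "
                "no imputation is performed"
            )
        if not all(g[2] for g in gts):
            n_skipped += 1  # unphased record
            continue
        col = np.fromiter(
            (allele for g in gts for allele in (g[0], g[1])),
            dtype=np.int8,
            count=2 * len(gts),
        )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alts[0]}"
        variants.append(VariantRecord(id=vid, chrom=rec.CHROM, pos=rec.POS,
                                      ref=rec.REF, alt=alts[0]))
        columns.append(col)
    if n_skipped:
        logger.info("read_vcf_haplotypes: skipped %d multiallelic/indel/unphased records",
                    n_skipped)
    if not variants:
        matrix = np.zeros((2 * len(sample_ids), 0), dtype=np.int8)
        panel = HaplotypePanel(variants=[], haplotypes=matrix, sample_ids=sample_ids)
    else:
        order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
        matrix = np.stack([columns[i] for i in order], axis=1)
        panel = HaplotypePanel(
            variants=[variants[i] for i in order],
            haplotypes=matrix,
            sample_ids=sample_ids,
        )
    panel.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return panel


def write_proxy_report(
    panel: HaplotypePanel,
    index: str,
    proxies: Sequence[tuple[str, float]],
    path: str | Path,
) -> None:
    """TSV proxy report: variant_id, chrom, pos, r2, d, freq."""
    lines = ["variant_id\tchrom\tpos\tr2\td\tfreq"]
    for vid, _ in proxies:
        v = panel.variant(vid)
        res = compute_r2(panel, vid, index)
        lines.append(
            f"{vid}\t{v.chrom}\t{v.pos}\t{res.r2:.6g}\t{res.d:.6g}\t{res.p_a:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_region(region: str | None) -> tuple[str | None, int | None, int | None]:
    if region is None:
        return None, None, None
    if ":" not in region:
        return region, None, None
    chrom, _, span = region.partition(":")
    start_s, _, end_s = span.partition("-")
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ValueError(f"malformed region {region!r}; expected chrom:start-end") from None
    if start > end:
        raise ValueError(f"region start > end in {region!r}")
    return chrom, start, end
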