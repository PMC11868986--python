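"""Genotype panel input and linkage-disequilibrium expansion of index SNPs.

r-squared between two sites is D^2 / (pA (1-pA) pB (1-pB)) computed from
haplotype frequencies: direct counts for phased panels, EM estimation of the
four haplotype frequencies for unphased genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1
#: minimum pairwise-complete haplotypes for an r2 estimate
MIN_COMPLETE_HAPS = 20


@dataclass(frozen=True)
class VariantKey:
    chrom: str
    pos0: int  # 0-based
    id: str
    ref: str
    alt: str

    @property
    def pos1(self) -> int:
        return self.pos0 + 1


@dataclass
class GenotypePanel:
    """Haplotype x variant allele matrix (codes 0/1, -1 missing)."""

    variants: list[VariantKey]
    matrix: np.ndarray
    phased: bool
    samples: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape[1] != len(self.variants):
            raise ValueError("matrix width does not match variant count")
        self._index = {v.id: i for i, v in enumerate(self.variants)}

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    def column(self, variant_id: str) -> np.ndarray:
        return self.matrix[:, self.index_of(variant_id)]

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None


@dataclass
class LDExpansionResult:
    index_id: str
    members: list[tuple[str, float]]
    window: int
    found: bool = True

    @property
    def member_ids(self) -> list[str]:
        return [m[0] for m in self.members]


def read_panel(vcf_path: str | Path, region: str | None = None,
               split_multiallelic: bool = False,
               include_indels: bool = False) -> GenotypePanel:
    """Read a VCF into a GenotypePanel.

    ``region`` is "chrom" or "chrom:start-end" (1-based inclusive), filtered
    while streaming so plain uncompressed VCFs work without an index.
    Multiallelic records are split into per-alt biallelic rows when
    ``split_multiallelic`` is set, otherwise skipped and logged.
    """
    from cyvcf2 import VCF

    chrom = lo = hi = None
    if region:
        if ":" in region:
            chrom, span = region.split(":", 1)
            lo_s, hi_s = span.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            chrom = region

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    variants: list[VariantKey] = []
    columns: list[np.ndarray] = []
    phased = True
    for rec in vcf:
        if chrom is not None and rec.CHROM != chrom:
            continue
        if lo is not None and not (lo <= rec.POS <= hi):
            continue
        alts = rec.ALT
        if len(alts) > 1 and not split_multiallelic:
            logger.info("skipping multiallelic record %s at %s:%d",
                        rec.ID, rec.CHROM, rec.POS)
            continue
        gts = rec.genotypes  # [[a, b, phased], ...]
        for ai, alt in enumerate(alts, start=1):
            if not include_indels and (len(rec.REF) != 1 or len(alt) != 1):
                logger.info("skipping indel %s at %s:%d", rec.ID, rec.CHROM, rec.POS)
                continue
            col = np.empty(2 * len(samples), dtype=np.int8)
            for si, gt in enumerate(gts):
                a, b = gt[0], gt[1]
                if not gt[2]:
                    phased = False
                col[2 * si] = MISSING if a < 0 else (1 if a == ai else 0)
                col[2 * si + 1] = MISSING if b < 0 else (1 if b == ai else 0)
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            if len(alts) > 1:
                vid = f"{vid}:{alt}"
            variants.append(VariantKey(rec.CHROM, rec.POS - 1, vid, rec.REF, alt))
            columns.append(col)
    if not columns:
        raise ValueError(f"no usable variants read from {vcf_path}"
                         + (f" (region {region})" if region else ""))
    matrix = np.stack(columns, axis=1)
    return GenotypePanel(variants, matrix, phased, samples)


@dataclass(frozen=True)
class VariantSite:
    """A variant to be scored (possibly multiallelic)."""

    chrom: str
    pos0: int
    id: str
    ref: str
    alts: tuple[str, ...]

    @property
    def alt(self) -> str:
        return self.alts[0]


def read_variant_sites(vcf_path: str | Path) -> list[VariantSite]:
    """Read variants (sites only; genotypes ignored) from a VCF."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(vcf_path)):
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}"
        out.append(VariantSite(rec.CHROM, rec.POS - 1, vid, rec.REF,
                               tuple(rec.ALT)))
    return out


def _r2_from_hap_freqs(f00: float, f01: float, f10: float, f11: float) -> float:
    pa = f10 + f11
    pb = f01 + f11
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        raise ValueError("monomorphic site: r2 undefined")
    d = f11 - pa * pb
    return min(1.0, d * d / denom)


def _r2_phased(col1: np.ndarray, col2: np.ndarray) -> float:
    ok = (col1 != MISSING) & (col2 != MISSING)
    a, b = col1[ok].astype(float), col2[ok].astype(float)
    n = a.size
    if n == 0:
        raise ValueError("no pairwise-complete haplotypes")
    f11 = float(((a == 1) & (b == 1)).sum()) / n
    f10 = float(((a == 1) & (b == 0)).sum()) / n
    f01 = float(((a == 0) & (b == 1)).sum()) / n
    f00 = 1.0 - f11 - f10 - f01
    return _r2_from_hap_freqs(f00, f01, f10, f11)


def em_haplotype_freqs(g1: np.ndarray, g2: np.ndarray, tol: float = 1e-8,
                       max_iter: int = 100) -> tuple[float, float, float, float]:
    """EM estimate of (f00, f01, f10, f11) from unphased genotype dosages.

    Only double heterozygotes are phase-ambiguous; all other genotype
    combinations contribute fixed haplotype counts.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    known = np.zeros(4)  # f00, f01, f10, f11
    n_dh = 0
    for a, b in zip(g1, g2):
        if a == 1 and b == 1:
            n_dh += 1
            continue
        # alleles at each site for the two haplotypes, determined by phase
        s1 = (1, 0) if a == 1 else (int(a == 2), int(a == 2))
        s2 = (1, 0) if b == 1 else (int(b == 2), int(b == 2))
        for x, y in zip(s1, s2):
            known[2 * x + y] += 1
    n_hap = 2 * len(g1)
    f = (known + n_dh * 0.5) / n_hap if n_dh else known / n_hap
    if n_dh == 0:
        return tuple(f)
    f = np.maximum(f, 1e-12)
    f /= f.sum()
    for _ in range(max_iter):
        denom = f[3] * f[0] + f[2] * f[1]
        c = 0.5 if denom == 0 else f[3] * f[0] / denom
        new = known.copy()
        new[0] += c * n_dh
        new[3] += c * n_dh
        new[1] += (1 - c) * n_dh
        new[2] += (1 - c) * n_dh
        new /= n_hap
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    return float(f[0]), float(f[1]), float(f[2]), float(f[3])


def _r2_unphased(col1: np.ndarray, col2: np.ndarray) -> float:
    # fold haplotype columns back to per-sample dosages
    d1 = col1.reshape(-1, 2)
    d2 = col2.reshape(-1, 2)
    ok = (d1 != MISSING).all(axis=1) & (d2 != MISSING).all(axis=1)
    g1 = d1[ok].sum(axis=1)
    g2 = d2[ok].sum(axis=1)
    if g1.size == 0:
        raise ValueError("no pairwise-complete samples")
    if len(set(g1.tolist())) == 1 and g1[0] in (0, 2):
        raise ValueError("monomorphic site: r2 undefined")
    f00, f01, f10, f11 = em_haplotype_freqs(g1, g2)
    return _r2_from_hap_freqs(f00, f01, f10, f11)


def compute_r2(panel: GenotypePanel, v1: str, v2: str) -> float:
    """r-squared between two panel variants (by id).

    Raises ValueError for monomorphic sites or all-missing pairs.
    """
    col1 = panel.column(v1)
    col2 = panel.column(v2)
    for name, col in ((v1, col1), (v2, col2)):
        vals = col[col != MISSING]
        if vals.size == 0 or (vals == vals[0]).all():
            raise ValueError(f"variant {name!r} is monomorphic: r2 undefined")
    if panel.phased:
        return _r2_phased(col1, col2)
    return _r2_unphased(col1, col2)


def expand_ld(panel: GenotypePanel, index_snps: list[str],
              r2_min: float = 0.3, window: int = 500_000,
              min_complete: int = MIN_COMPLETE_HAPS) -> list[LDExpansionResult]:
    """For each index SNP, all panel variants within ``window`` with r2 >= r2_min.

    The threshold is inclusive. Index SNPs absent from the panel yield an
    empty flagged result rather than an error. The index SNP itself is always
    a member with r2 = 1.
    """
    # fast path: phased, no missing data -> r2 is the squared Pearson
    # correlation of the 0/1 haplotype columns, computed vectorized
    complete = panel.phased and not (panel.matrix == MISSING).any()
    if complete:
        m = panel.matrix.astype(float)
        means = m.mean(axis=0)
        sds = m.std(axis=0)

    results = []
    for index_id in index_snps:
        try:
            idx = panel.index_of(index_id)
        except KeyError:
            logger.warning("index SNP %s absent from panel", index_id)
            results.append(LDExpansionResult(index_id, [], window, found=False))
            continue
        anchor = panel.variants[idx]
        members = [(index_id, 1.0)]
        if complete:
            centered = m[:, idx] - means[idx]
            cov = centered @ m / m.shape[0]
            for j, cand in enumerate(panel.variants):
                if (j == idx or cand.chrom != anchor.chrom
                        or abs(cand.pos0 - anchor.pos0) > window
                        or sds[j] == 0 or sds[idx] == 0):
                    continue
                r = cov[j] / (sds[idx] * sds[j])
                r2 = min(1.0, r * r)
                if r2 >= r2_min:
                    members.append((cand.id, float(r2)))
            results.append(LDExpansionResult(index_id, members, window))
            continue
        for j, cand in enumerate(panel.variants):
            if j == idx or cand.chrom != anchor.chrom:
                continue
            if abs(cand.pos0 - anchor.pos0) > window:
                continue
            c1, c2 = panel.matrix[:, idx], panel.matrix[:, j]
            n_complete = int(((c1 != MISSING) & (c2 != MISSING)).sum())
            if n_complete < min_complete:
                logger.info("skipping pair %s/%s: only %d complete haplotypes",
                            index_id, cand.id, n_complete)
                continue
            try:
                r2 = compute_r2(panel, index_id, cand.id)
            except ValueError:
                continue
            if r2 >= r2_min:
                members.append((cand.id, r2))
        results.append(LDExpansionResult(index_id, members, window))
    return results


def unique_members(results: list[LDExpansionResult]) -> set[str]:
    """Union of member ids across loci (the headline SNP-count quantity)."""
    out: set[str] = set()
    for res in results:
        out.update(res.member_ids)
    return out
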