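"""Candidate-variant selection, evidence scoring, ranking and summaries.

A variant is ranked when it passes two gates: significant eQTL support
(FDR-corrected within at least one dataset) and a category-1 regulatory
annotation. Ranked variants are ordered by a 0-4 additive evidence score
(promoter marks, enhancer marks, DNase protein binding, motif change), with
ties broken by smaller allelic-difference p-value and then variant id.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_CATEGORY_RE = re.compile(r"^[1-9]\d*[a-f]?$")

EVIDENCE_FLAGS = ("promoter_mark", "enhancer_mark", "dnase_protein", "motif_change")


@dataclass
class AnnotationRecord:
    variant_id: str
    regulomedb_category: str
    promoter_mark: bool = False
    enhancer_mark: bool = False
    dnase_protein: bool = False
    motif_change: bool = False

    def __post_init__(self) -> None:
        if not _CATEGORY_RE.match(self.regulomedb_category):
            raise ValueError(
                f"malformed RegulomeDB category {self.regulomedb_category!r}")

    def flags(self) -> tuple[bool, ...]:
        return tuple(getattr(self, f) for f in EVIDENCE_FLAGS)


@dataclass
class PrioritizedVariant:
    variant_id: str
    passes_eqtl: bool
    passes_regulome: bool
    evidence_score: int
    rank: int | None = None
    context: str = "other"
    tf_hits: list[tuple[str, str]] = field(default_factory=list)
    p_rank_min: float = 1.0
    replicated: bool = False


def regulome_pass(category: str) -> bool:
    """True iff the category is in the 1a-1f family."""
    if not _CATEGORY_RE.match(category):
        raise ValueError(f"malformed RegulomeDB category {category!r}")
    return category.startswith("1")


def evidence_score(record: AnnotationRecord) -> int:
    """Number of true flags among the four annotation features."""
    return sum(record.flags())


def read_annotations(path: str | Path) -> dict[str, AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"regulomedb_category": str})
    out = {}
    for row in df.itertuples(index=False):
        out[row.variant] = AnnotationRecord(
            row.variant, str(row.regulomedb_category),
            bool(row.promoter_mark), bool(row.enhancer_mark),
            bool(row.dnase_protein), bool(row.motif_change))
    return out


# ---------------------------------------------------------------------------
# Gene model / genomic context


@dataclass
class Gene:
    chrom: str
    start: int  # 0-based half-open
    end: int
    name: str
    exons: list[tuple[int, int]] = field(default_factory=list)


def read_gene_model(path: str | Path) -> list[Gene]:
    """Read a gene model from BED12 or GFF3 (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    return _read_bed12(path)


def _read_bed12(path: Path) -> list[Gene]:
    genes = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        exons = []
        if len(f) >= 12:
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        else:
            exons = [(start, end)]
        genes.append(Gene(chrom, start, end, name, exons))
    return genes


def _read_gff3(path: Path) -> list[Gene]:
    genes: dict[str, Gene] = {}
    exon_rows = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            continue
        chrom, _, ftype, start1, end1 = f[0], f[1], f[2], int(f[3]), int(f[4])
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        if ftype == "gene":
            gid = attrs.get("ID", attrs.get("Name", f"{chrom}:{start1}"))
            genes[gid] = Gene(chrom, start1 - 1, end1, gid)
        elif ftype == "exon":
            exon_rows.append((attrs.get("Parent", ""), chrom, start1 - 1, end1))
    for parent, chrom, s, e in exon_rows:
        target = genes.get(parent)
        if target is None:  # exon of an mRNA: attach to enclosing gene
            for g in genes.values():
                if g.chrom == chrom and g.start <= s and e <= g.end:
                    target = g
                    break
        if target is not None:
            target.exons.append((s, e))
    return list(genes.values())


def classify_context(variant, gene_model: Sequence[Gene]) -> str:
    """exonic > intronic > intergenic for a variant with chrom/pos0."""
    chrom, pos = variant.chrom, variant.pos0
    in_gene = False
    for g in gene_model:
        if g.chrom != chrom or not (g.start <= pos < g.end):
            continue
        for s, e in g.exons:
            if s <= pos < e:
                return "exonic"
        in_gene = True
    return "intronic" if in_gene else "intergenic"


# ---------------------------------------------------------------------------
# Ranking


def rank_variants(disruption_hits: Sequence, evidence_summaries: Sequence,
                  annotations: Mapping[str, AnnotationRecord],
                  contexts: Mapping[str, str] | None = None
                  ) -> list[PrioritizedVariant]:
    """Apply the eQTL and RegulomeDB gates, score evidence and rank.

    ``disruption_hits`` are kept DisruptionResults; ``evidence_summaries``
    come from :func:`regsnap.eqtl_integration.integrate`. Variants failing a
    gate are retained in the output with ``rank=None``.
    """
    per_variant: dict[str, PrioritizedVariant] = {}
    for hit in disruption_hits:
        pv = per_variant.get(hit.variant_id)
        if pv is None:
            pv = PrioritizedVariant(hit.variant_id, False, False, 0)
            per_variant[pv.variant_id] = pv
        pv.tf_hits.append((hit.motif_name, hit.direction))
        if hit.p_rank is not None:
            pv.p_rank_min = min(pv.p_rank_min, hit.p_rank)

    for summary in evidence_summaries:
        pv = per_variant.get(summary.variant_id)
        if pv is None:
            continue
        if summary.n_significant_datasets >= 1:
            pv.passes_eqtl = True
        if summary.replicated:
            pv.replicated = True

    for pv in per_variant.values():
        record = annotations.get(pv.variant_id)
        if record is None:
            logger.info("no annotation for %s: treating all flags false",
                        pv.variant_id)
            pv.passes_regulome = False
            pv.evidence_score = 0
        else:
            pv.passes_regulome = regulome_pass(record.regulomedb_category)
            pv.evidence_score = evidence_score(record)
        if contexts is not None:
            pv.context = contexts.get(pv.variant_id, "other")

    candidates = [pv for pv in per_variant.values()
                  if pv.passes_eqtl and pv.passes_regulome]
    candidates.sort(key=lambda pv: (-pv.evidence_score, pv.p_rank_min,
                                    pv.variant_id))
    for i, pv in enumerate(candidates, start=1):
        pv.rank = i
    ordered = candidates + sorted(
        (pv for pv in per_variant.values() if pv.rank is None),
        key=lambda pv: pv.variant_id)
    return ordered


def summarize(hits: Sequence, contexts: Mapping[str, str] | None = None) -> dict:
    """Per-TF counts, pairwise co-disruption matrix and context histogram.

    ``hits`` are DisruptionResults (one row per variant x motif). The
    co-disruption matrix is symmetric with a zero diagonal; percentages are
    count / number of distinct variants.
    """
    variants_by_tf: dict[str, set[str]] = {}
    all_variants: set[str] = set()
    for h in hits:
        variants_by_tf.setdefault(h.motif_name, set()).add(h.variant_id)
        all_variants.add(h.variant_id)
    total = len(all_variants)
    per_tf = {
        tf: {"count": len(vs),
             "percent": 100.0 * len(vs) / total if total else 0.0}
        for tf, vs in sorted(variants_by_tf.items())
    }
    tfs = sorted(variants_by_tf)
    matrix = pd.DataFrame(0, index=tfs, columns=tfs, dtype=int)
    for i, a in enumerate(tfs):
        for b in tfs[i + 1:]:
            shared = len(variants_by_tf[a] & variants_by_tf[b])
            matrix.loc[a, b] = shared
            matrix.loc[b, a] = shared
    context_hist: dict[str, int] = {}
    if contexts is not None:
        for v in all_variants:
            ctx = contexts.get(v, "other")
            context_hist[ctx] = context_hist.get(ctx, 0) + 1
    return {
        "n_variants": total,
        "per_tf": per_tf,
        "co_disruption": matrix,
        "context_distribution": context_hist,
    }


def prioritized_to_frame(variants: Sequence[PrioritizedVariant]) -> pd.DataFrame:
    rows = []
    for pv in variants:
        rows.append({
            "variant": pv.variant_id,
            "rank": pv.rank if pv.rank is not None else ".",
            "passes_eqtl": pv.passes_eqtl,
            "passes_regulome": pv.passes_regulome,
            "evidence_score": pv.evidence_score,
            "replicated": pv.replicated,
            "context": pv.context,
            "p_rank_min": pv.p_rank_min,
            "tf_hits": ";".join(f"{tf}:{d}" for tf, d in pv.tf_hits),
        })
    return pd.DataFrame(rows)
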