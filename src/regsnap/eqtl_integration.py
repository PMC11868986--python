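"""Join disrupting SNPs to per-dataset eQTL summaries with an FDR gate.

q-values are Benjamini-Hochberg within each dataset; a variant-gene pair is
"replicated" when it is significant (q < q_max) in at least two datasets.
Effect directions are taken as the sign of beta, which is assumed already
oriented to the risk allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EQTL_COLUMNS = ["variant", "gene", "beta", "p", "dataset"]


@dataclass
class EvidenceSummary:
    variant_id: str
    gene: str | None
    q_by_dataset: dict[str, float] = field(default_factory=dict)
    n_significant_datasets: int = 0
    replicated: bool = False
    effect_directions: dict[str, int] = field(default_factory=dict)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.empty(0)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EQTL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing eQTL columns {missing}")
    return df[EQTL_COLUMNS]


def integrate(disrupting_variants: Iterable[str],
              eqtl_tables: Sequence[pd.DataFrame] | pd.DataFrame,
              q_max: float = 0.001) -> list[EvidenceSummary]:
    """Per variant-gene evidence summaries for the given variants.

    ``eqtl_tables`` may be one concatenated frame or a sequence of frames;
    each row is (variant, gene, beta, p, dataset). FDR is applied within
    each dataset. Variants absent from every table are reported with empty
    evidence. Duplicated (variant, gene, dataset) rows raise.
    """
    if isinstance(eqtl_tables, pd.DataFrame):
        table = eqtl_tables.copy()
    else:
        table = pd.concat(list(eqtl_tables), ignore_index=True)
    dup = table.duplicated(["variant", "gene", "dataset"], keep=False)
    if dup.any():
        offenders = table.loc[dup, ["variant", "gene", "dataset"]]
        raise ValueError(
            "duplicated (variant, gene, dataset) rows:\n"
            + offenders.drop_duplicates().to_string(index=False))
    table = table.sort_values(["dataset", "variant", "gene"], kind="mergesort")
    table["q"] = np.concatenate([
        bh_fdr(group["p"].to_numpy())
        for _, group in table.groupby("dataset", sort=True)
    ]) if len(table) else np.empty(0)

    wanted = list(dict.fromkeys(disrupting_variants))
    sub = table[table["variant"].isin(wanted)]
    summaries: list[EvidenceSummary] = []
    seen: set[str] = set()
    for (variant, gene), group in sub.groupby(["variant", "gene"], sort=True):
        seen.add(variant)
        q_by = dict(zip(group["dataset"], group["q"].astype(float)))
        sig = group[group["q"] < q_max]
        n_sig = int(len(sig))
        direction = int(np.sign(sig["beta"].mean())) if n_sig else 0
        summaries.append(EvidenceSummary(
            variant_id=variant, gene=gene, q_by_dataset=q_by,
            n_significant_datasets=n_sig, replicated=n_sig >= 2,
            effect_directions={gene: direction}))
    for variant in wanted:
        if variant not in seen:
            summaries.append(EvidenceSummary(variant_id=variant, gene=None))
    return summaries


def summaries_to_frame(summaries: Sequence[EvidenceSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "variant": s.variant_id,
            "gene": s.gene if s.gene is not None else ".",
            "n_significant_datasets": s.n_significant_datasets,
            "replicated": s.replicated,
            "direction": s.effect_directions.get(s.gene, 0) if s.gene else 0,
            "q_min": min(s.q_by_dataset.values()) if s.q_by_dataset else float("nan"),
        })
    return pd.DataFrame(rows)
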