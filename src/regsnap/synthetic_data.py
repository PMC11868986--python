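"""Synthetic pipeline inputs with planted, machine-checkable ground truth.

Every generator is seeded and deterministic: the same seed yields
byte-identical output files. The emitted manifest records exactly what was
planted (LD proxies and their target r2, motif instances, disrupting
variants and their true score difference, eQTL effects, annotation truth)
so each downstream stage can be validated by round-trip recovery.

Coordinates are 0-based half-open internally; VCF output is 1-based.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .binding_disruption import extract_scan_window
from .genotypes_ld import VariantKey
from .motif_core import (
    BASES,
    BackgroundModel,
    PWM,
    best_match_score,
    encode,
    log_odds,
    revcomp,
    write_meme,
)
from .motif_discovery import Peak, write_peaks

REGULOME_CATEGORY_1 = ["1a", "1b", "1c", "1d", "1e", "1f"]
REGULOME_CATEGORY_REST = ["2a", "2b", "2c", "3a", "4", "5", "6", "7"]


@dataclass
class SimulationManifest:
    """Ground truth of everything planted by the generators."""

    seed: int
    planted_proxies: list[tuple[str, str, float]] = field(default_factory=list)
    planted_motif_sites: list[tuple[str, int, str]] = field(default_factory=list)
    causal_variants: list[tuple[str, float, str]] = field(default_factory=list)
    eqtl_effects: list[tuple[str, str, str, float, float]] = field(default_factory=list)
    annotation_truth: list[tuple[str, str, list[bool]]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationManifest":
        data = json.loads(Path(path).read_text())
        return cls(
            seed=data["seed"],
            planted_proxies=[tuple(x) for x in data["planted_proxies"]],
            planted_motif_sites=[tuple(x) for x in data["planted_motif_sites"]],
            causal_variants=[tuple(x) for x in data["causal_variants"]],
            eqtl_effects=[tuple(x) for x in data["eqtl_effects"]],
            annotation_truth=[(v, c, list(f)) for v, c, f in data["annotation_truth"]],
        )

    def causal_ids(self) -> list[str]:
        return [v for v, _, _ in self.causal_variants]


# ---------------------------------------------------------------------------
# Reference


def simulate_reference(length: int, gc: float, seed: int
                       ) -> tuple[str, BackgroundModel]:
    """An iid random sequence with the requested G+C fraction.

    Returns the sequence and a zero-order background model estimated from it.
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=probs)
    sequence = "".join(BASES[c] for c in codes)
    return sequence, BackgroundModel.from_sequence(sequence)


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Haplotype panel


@dataclass
class HaplotypeBlock:
    """One LD block: an anchor (index) SNP plus correlated proxies.

    ``target_r2_profile`` gives the target r2 of each proxy against the
    anchor; when None, haplotypes are resampled from ``founder_haps``
    founder patterns instead (founder_haps=1 means one pattern plus its
    complement, i.e. perfect LD throughout the block).
    """

    n_snps: int
    founder_haps: int = 2
    target_r2_profile: Sequence[float] | None = None
    positions: Sequence[int] | None = None  # pos0 per SNP
    ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise ValueError("each block needs at least 2 SNPs")
        if self.target_r2_profile is not None:
            if len(self.target_r2_profile) != self.n_snps - 1:
                raise ValueError("target_r2_profile must have n_snps - 1 entries")
            for r2 in self.target_r2_profile:
                if not 0.0 <= r2 <= 1.0:
                    raise ValueError("target r2 must lie in [0, 1]")


def _polymorphic_bernoulli(rng: np.random.Generator, n: int, p: float = 0.5,
                           max_tries: int = 1000) -> np.ndarray:
    for _ in range(max_tries):
        col = (rng.random(n) < p).astype(np.int8)
        if 0 < col.sum() < n:
            return col
    raise ValueError("could not draw a polymorphic SNP column (monomorphic request)")


def simulate_haplotype_panel(n_hap: int, blocks: Sequence[HaplotypeBlock],
                             seed: int, chrom: str = "chr1",
                             block_spacing: int = 2000, snp_spacing: int = 50,
                             start: int = 0):
    """Haplotypes for block-structured LD with controllable within-block r2.

    Returns ``(variants, matrix, manifest_entries)`` where ``matrix`` is
    (n_hap, n_snps) with codes {0,1}, variants are VariantKeys (ref="A",
    alt="G" placeholders unless a reference is supplied downstream), and
    manifest_entries are (index_id, proxy_id, target_r2) tuples.
    """
    if n_hap < 50:
        raise ValueError("n_hap must be >= 50")
    if n_hap % 2:
        raise ValueError("n_hap must be even (two haplotypes per sample)")
    rng = np.random.default_rng(seed)
    blocks = [b if isinstance(b, HaplotypeBlock) else HaplotypeBlock(*b)
              for b in blocks]
    variants: list[VariantKey] = []
    columns: list[np.ndarray] = []
    proxies: list[tuple[str, str, float]] = []
    pos = start
    for bi, block in enumerate(blocks):
        ids = list(block.ids) if block.ids is not None else (
            [f"idx{bi}"] + [f"blk{bi}_snp{j}" for j in range(1, block.n_snps)])
        if block.positions is not None:
            positions = list(block.positions)
        else:
            positions = [pos + j * snp_spacing for j in range(block.n_snps)]
            pos = positions[-1] + block_spacing
        if block.target_r2_profile is not None:
            anchor = _polymorphic_bernoulli(rng, n_hap)
            cols = [anchor]
            for r2 in block.target_r2_profile:
                q = (1.0 + np.sqrt(r2)) / 2.0
                keep = rng.random(n_hap) < q
                col = np.where(keep, anchor, 1 - anchor).astype(np.int8)
                if col.sum() in (0, n_hap):
                    raise ValueError(
                        f"block {bi}: proxy came out monomorphic at r2={r2}")
                cols.append(col)
        else:
            if block.founder_haps == 1:
                pattern = _polymorphic_bernoulli(
                    rng, block.n_snps) if block.n_snps > 1 else np.array([1], np.int8)
                founders = np.stack([pattern, 1 - pattern])
            else:
                founders = np.empty((block.founder_haps, block.n_snps), np.int8)
                for j in range(block.n_snps):
                    founders[:, j] = _polymorphic_bernoulli(rng, block.founder_haps)
            choice = rng.integers(founders.shape[0], size=n_hap)
            cols = [founders[choice, j] for j in range(block.n_snps)]
        for j, (vid, p0, col) in enumerate(zip(ids, positions, cols)):
            variants.append(VariantKey(chrom, p0, vid, "A", "G"))
            columns.append(col.astype(np.int8))
            if j > 0 and block.target_r2_profile is not None:
                proxies.append((ids[0], vid, float(block.target_r2_profile[j - 1])))
            elif j > 0:
                proxies.append((ids[0], vid, float("nan")))
    matrix = np.stack(columns, axis=1)
    return variants, matrix, proxies


def write_vcf(variants: Sequence, path: str | Path,
              matrix: np.ndarray | None = None,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a VCF 4.2; with ``matrix`` (n_hap x n_var) phased GTs are emitted."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=regsnap-synthetic\n")
        if matrix is not None:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
        contigs = contig_lengths or {}
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        n_samples = 0
        if matrix is not None:
            n_samples = matrix.shape[0] // 2
            header += ["FORMAT"] + [f"S{i + 1}" for i in range(n_samples)]
        fh.write("\t".join(header) + "\n")
        order = sorted(range(len(variants)),
                       key=lambda i: (variants[i].chrom, variants[i].pos0))
        for i in order:
            v = variants[i]
            alt = getattr(v, "alt", None) or ",".join(v.alts)
            row = [v.chrom, str(v.pos0 + 1), v.id, v.ref, alt, ".", "PASS", "."]
            if matrix is not None:
                row.append("GT")
                col = matrix[:, i]
                row += [f"{col[2 * s]}|{col[2 * s + 1]}" for s in range(n_samples)]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# ChIP-seq peaks with planted motif instances


def sample_motif_instance(pwm: PWM, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.choice(4, p=row)] for row in pwm.probs)


def simulate_chipseq_peaks(reference: str, pwm: PWM, n_peaks: int,
                           plant_frac: float, seed: int,
                           peak_width: int = 200, gap: int = 100,
                           chrom: str = "chr1", start: int = 0,
                           height_sigma: float = 0.5
                           ) -> tuple[str, list[Peak], list[tuple[str, int, str]]]:
    """Non-overlapping peaks; a chosen fraction get a motif instance planted
    at the summit (written into the returned reference copy).

    Planted peaks draw their log-normal height with a +1 sigma shift so the
    top of the height ranking is enriched for planted peaks. Returns
    ``(new_reference, peaks, planted_sites)`` with sites as
    (peak_id, offset_from_peak_start, strand).
    """
    if len(pwm) > peak_width:
        raise ValueError("PWM wider than the peak width")
    if not 0.0 <= plant_frac <= 1.0:
        raise ValueError("plant_frac must lie in [0, 1]")
    needed = start + n_peaks * (peak_width + gap)
    if needed > len(reference):
        raise ValueError(f"reference too short: need {needed} bases")
    rng = np.random.default_rng(seed)
    n_plant = int(round(plant_frac * n_peaks))
    planted_idx = set(rng.choice(n_peaks, size=n_plant, replace=False).tolist())
    seq = list(reference)
    peaks: list[Peak] = []
    sites: list[tuple[str, int, str]] = []
    for i in range(n_peaks):
        p_start = start + i * (peak_width + gap)
        p_end = p_start + peak_width
        name = f"peak{i}"
        summit = peak_width // 2
        mu = height_sigma if i in planted_idx else 0.0
        height = float(np.exp(rng.normal(mu, height_sigma)))
        if i in planted_idx:
            instance = sample_motif_instance(pwm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            written = instance if strand == "+" else revcomp(instance)
            offset = summit - len(pwm) // 2
            abs_pos = p_start + offset
            seq[abs_pos:abs_pos + len(pwm)] = list(written)
            sites.append((name, offset, strand))
        peaks.append(Peak(chrom, p_start, p_end, name, height, ".", summit))
    return "".join(seq), peaks, sites


# ---------------------------------------------------------------------------
# Disrupting variants


@dataclass(frozen=True)
class SiteVariant:
    chrom: str
    pos0: int
    id: str
    ref: str
    alt: str

    @property
    def alts(self) -> list[str]:
        return [self.alt]


def plant_disrupting_variants(pwm: PWM, reference: str,
                              peaks: Sequence[Peak],
                              planted_sites: Sequence[tuple[str, int, str]],
                              n_causal: int, n_null: int, seed: int,
                              half_window: int = 20, chrom: str = "chr1",
                              min_null_distance: int = 100
                              ) -> tuple[list[SiteVariant], dict[str, float]]:
    """Causal variants inside planted motif sites; null variants far away.

    Causal variants sit at the motif column of maximal information content
    with the alt allele chosen to minimize that column's probability; the
    recorded true_delta_score is best_match_score(ref) - best_match_score(alt)
    recomputed on the actual reference, so downstream scoring must
    reproduce it exactly.
    """
    if n_causal + n_null < 1:
        raise ValueError("request at least one variant")
    if n_causal > len(planted_sites):
        raise ValueError(
            f"only {len(planted_sites)} planted sites for {n_causal} causal variants")
    rng = np.random.default_rng(seed)
    peak_by_name = {p.name: p for p in peaks}
    bg = BackgroundModel.uniform()
    lo_mat = log_odds(pwm, bg)
    site_order = rng.permutation(len(planted_sites))[:n_causal]
    variants: list[SiteVariant] = []
    truth: dict[str, float] = {}
    planted_positions = []
    for peak_id, offset, strand in planted_sites:
        p = peak_by_name[peak_id]
        planted_positions.append((p.start + offset, p.start + offset + len(pwm)))
    for vi, si in enumerate(site_order):
        peak_id, offset, strand = planted_sites[si]
        p = peak_by_name[peak_id]
        site_start = p.start + offset
        instance = reference[site_start:site_start + len(pwm)].upper()
        if strand == "-":
            instance = revcomp(instance)
        # choose the column maximizing the achievable per-column score drop
        # for the instance actually planted (highest-information positions
        # with the consensus base present win)
        inst_codes = encode(instance)
        best_col, best_drop, alt_code = 0, -np.inf, 0
        for c in range(len(pwm)):
            others = [b for b in range(4) if b != inst_codes[c]]
            drop = lo_mat[c, inst_codes[c]] - min(lo_mat[c, b] for b in others)
            if drop > best_drop:
                best_col, best_drop = c, drop
                alt_code = min(others, key=lambda b: lo_mat[c, b])
        col = best_col
        if strand == "+":
            pos0 = site_start + col
            alt_base = BASES[alt_code]
        else:
            pos0 = site_start + (len(pwm) - 1 - col)
            alt_base = revcomp(BASES[alt_code])
        ref_base = reference[pos0].upper()
        var = SiteVariant(chrom, pos0, f"causal{vi}", ref_base, alt_base)
        variants.append(var)
        window, focal = extract_scan_window({chrom: reference}, chrom, pos0,
                                            half_window)
        s_ref, _, _ = best_match_score(pwm, window, focal, ref_base, bg)
        s_alt, _, _ = best_match_score(pwm, window, focal, alt_base, bg)
        truth[var.id] = float(s_ref - s_alt)
    # null variants: anywhere >= min_null_distance from every planted site
    candidates = []
    for pos in range(half_window, len(reference) - half_window):
        if all(pos < s - min_null_distance or pos >= e + min_null_distance
               for s, e in planted_positions):
            candidates.append(pos)
    if n_null > len(candidates):
        raise ValueError("reference too small for the requested null variants")
    null_pos = rng.choice(len(candidates), size=n_null, replace=False)
    for vi, ci in enumerate(sorted(null_pos.tolist())):
        pos0 = candidates[ci]
        ref_base = reference[pos0].upper()
        alt_base = BASES[(BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
        variants.append(SiteVariant(chrom, pos0, f"null{vi}", ref_base, alt_base))
    return variants, truth


# ---------------------------------------------------------------------------
# eQTL tables


def simulate_eqtl_tables(variant_ids: Sequence[str], n_datasets: int,
                         n_true: int, seed: int,
                         beta_range: tuple[float, float] = (0.2, 0.8),
                         true_ids: Sequence[str] | None = None,
                         dataset_names: Sequence[str] | None = None):
    """Per-dataset eQTL summary rows with planted variant-gene effects.

    Planted pairs get log-uniform p in [1e-12, 1e-9] in every dataset (small
    enough to survive BH at q < 0.001); everything else is uniform.
    Returns ``(tables, effects)`` where tables is {dataset: list of row
    dicts} and effects the manifest tuples (variant, gene, dataset, beta, p).
    """
    if n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    ids = list(variant_ids)
    if true_ids is None:
        if n_true > len(ids):
            raise ValueError("n_true exceeds available variants")
        true_ids = ids[:n_true]
    else:
        unknown = set(true_ids) - set(ids)
        if unknown:
            raise ValueError(f"unknown planted variant ids: {sorted(unknown)}")
        if len(true_ids) != n_true:
            raise ValueError("n_true does not match true_ids length")
    rng = np.random.default_rng(seed)
    datasets = list(dataset_names) if dataset_names else [
        f"brain_ds{i + 1}" for i in range(n_datasets)]
    true_set = set(true_ids)
    gene_of = {v: f"GENE_{v}" for v in ids}
    sign_of = {v: (1 if rng.random() < 0.5 else -1) for v in ids}
    magnitude = {v: float(rng.uniform(*beta_range)) for v in ids}
    tables: dict[str, list[dict]] = {ds: [] for ds in datasets}
    effects: list[tuple[str, str, str, float, float]] = []
    for ds in datasets:
        for v in ids:
            if v in true_set:
                p = float(10 ** rng.uniform(-12, -9))
                beta = sign_of[v] * magnitude[v]
                effects.append((v, gene_of[v], ds, beta, p))
            else:
                p = float(rng.uniform(np.nextafter(0, 1), 1.0))
                beta = float(rng.normal(0.0, 0.1))
            tables[ds].append({"variant": v, "gene": gene_of[v],
                               "beta": beta, "p": p, "dataset": ds})
    return tables, effects


def write_eqtl_tables(tables: dict[str, list[dict]], outdir: str | Path
                      ) -> dict[str, Path]:
    import pandas as pd

    outdir = Path(outdir)
    paths = {}
    for ds, rows in tables.items():
        path = outdir / f"eqtl_{ds}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        paths[ds] = path
    return paths


# ---------------------------------------------------------------------------
# Annotations


def simulate_annotations(variant_ids: Sequence[str], causal_ids: Sequence[str],
                         flip_prob: float = 0.05, seed: int = 0,
                         decoy_flag_prob: float = 0.1):
    """Annotation rows: causal variants get category 1 and all four flags
    (each independently flipped with ``flip_prob``); others get categories
    >= 2 and sparse flags.

    Returns ``(rows, truth)``: TSV row dicts and manifest truth tuples.
    """
    if not 0.0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5)")
    unknown = set(causal_ids) - set(variant_ids)
    if unknown:
        raise ValueError(f"unknown variant ids in causal_ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    causal = set(causal_ids)
    rows = []
    truth = []
    for v in variant_ids:
        if v in causal:
            category = REGULOME_CATEGORY_1[int(rng.integers(len(REGULOME_CATEGORY_1)))]
            flags = [not (rng.random() < flip_prob) for _ in range(4)]
        else:
            category = REGULOME_CATEGORY_REST[
                int(rng.integers(len(REGULOME_CATEGORY_REST)))]
            flags = [bool(rng.random() < decoy_flag_prob) for _ in range(4)]
        rows.append({
            "variant": v, "regulomedb_category": category,
            "promoter_mark": flags[0], "enhancer_mark": flags[1],
            "dnase_protein": flags[2], "motif_change": flags[3],
        })
        truth.append((v, category, flags))
    return rows, truth


# ---------------------------------------------------------------------------
# Gene model


def simulate_gene_model(reference_length: int, n_genes: int, seed: int,
                        chrom: str = "chr1") -> list[dict]:
    """A few evenly spaced genes with two exons each (BED12 rows)."""
    rng = np.random.default_rng(seed)
    span = reference_length // max(n_genes, 1)
    rows = []
    for i in range(n_genes):
        start = i * span + int(rng.integers(0, span // 4 + 1))
        length = int(rng.integers(span // 4, span // 2))
        end = min(start + length, reference_length)
        exon1 = (0, max(length // 6, 1))
        exon2 = (length - max(length // 6, 1), length)
        rows.append({
            "chrom": chrom, "start": start, "end": end, "name": f"gene{i}",
            "block_sizes": [exon1[1] - exon1[0], exon2[1] - exon2[0]],
            "block_starts": [exon1[0], exon2[0]],
        })
    return rows


def write_gene_model_bed12(rows: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            sizes = ",".join(str(s) for s in r["block_sizes"]) + ","
            starts = ",".join(str(s) for s in r["block_starts"]) + ","
            fh.write("\t".join([
                r["chrom"], str(r["start"]), str(r["end"]), r["name"], "0", "+",
                str(r["start"]), str(r["end"]), "0",
                str(len(r["block_sizes"])), sizes, starts]) + "\n")


# ---------------------------------------------------------------------------
# Full default scenario


#: sharp core (seedable by discovery), then a two-base degenerate column with
#: near-zero probability for the other two bases (the disruption target:
#: its log-odds contrast is ~11.7, far beyond any other column), then soft
#: tail columns that keep window-score variance down.
DEFAULT_SHARP = "TGACGTCATGCA"
DEFAULT_SOFT = "GATCGAT"


def default_generating_pwm(sharp_dominance: float = 0.93,
                           soft_dominance: float = 0.4) -> PWM:
    """Generating motif used by the default scenario (length 20).

    The degenerate column accepts A/T (a self-complementary pair, so neither
    alt allele is rescued by the reverse strand); planted variants flip it
    to C/G for a ~11.7 log2-unit score drop.
    """
    rows = []
    for ch in DEFAULT_SHARP:
        row = np.full(4, (1.0 - sharp_dominance) / 3.0)
        row["ACGT".index(ch)] = sharp_dominance
        rows.append(row)
    ultra = np.array([0.5, 5e-5, 5e-5, 0.5])
    rows.append(ultra / ultra.sum())
    for ch in DEFAULT_SOFT:
        row = np.full(4, (1.0 - soft_dominance) / 3.0)
        row["ACGT".index(ch)] = soft_dominance
        rows.append(row)
    return PWM("TF1", np.array(rows), source="synthetic")


def decoy_pwms(n: int, length: int, seed: int) -> list[PWM]:
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        probs = rng.dirichlet(np.full(4, 0.5), size=length)
        out.append(PWM(f"DECOY{i + 1}", probs, source="synthetic"))
    return out


def simulate_scenario(outdir: str | Path, seed: int,
                      n_peaks: int = 100, plant_frac: float = 0.8,
                      n_causal: int = 5, n_null: int = 200,
                      n_datasets: int = 3, n_hap: int = 200,
                      proxy_r2: float = 0.9, flip_prob: float = 0.05,
                      reference_length: int | None = None,
                      gc: float = 0.45) -> tuple[SimulationManifest, dict[str, Path]]:
    """Generate every pipeline input for the default end-to-end scenario.

    Layout: peaks (with planted TF1 motif instances) occupy the start of
    chr1; causal variants sit inside planted motifs, null variants at least
    100 bp away. The haplotype panel places each causal/null variant in an
    LD block behind an index SNP (target r2 ``proxy_r2``), so LD expansion
    recovers them. eQTL tables plant effects for the causal variants only,
    and annotations give causal variants category-1 plus four-flag evidence.
    Returns the manifest and a dict of written file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in root.spawn(8)]

    pwm = default_generating_pwm()
    peak_width, gap = 200, 100
    if reference_length is None:
        reference_length = n_peaks * (peak_width + gap) + 20_000
    reference, background = simulate_reference(reference_length, gc, seeds[0])
    reference, peaks, sites = simulate_chipseq_peaks(
        reference, pwm, n_peaks, plant_frac, seeds[1],
        peak_width=peak_width, gap=gap)
    variants, truth = plant_disrupting_variants(
        pwm, reference, peaks, sites, n_causal, n_null, seeds[2])

    # LD panel: one block per scored variant (index anchor + the variant)
    blocks = []
    used_positions = {v.pos0 for v in variants}
    for vi, v in enumerate(variants):
        step = 21 if v.pos0 + 30 < reference_length else -21
        anchor_pos = v.pos0 + step  # outside the scan window of the variant
        while anchor_pos in used_positions:
            anchor_pos += 1 if step > 0 else -1
        used_positions.add(anchor_pos)
        blocks.append(HaplotypeBlock(
            n_snps=2, target_r2_profile=[proxy_r2],
            positions=[anchor_pos, v.pos0], ids=[f"index_{v.id}", v.id]))
    panel_variants, matrix, proxies = simulate_haplotype_panel(
        n_hap, blocks, seeds[3])
    # align panel ref/alt with the reference sequence and variant alleles
    alleles = {v.id: (v.ref, v.alt) for v in variants}
    fixed = []
    for pv in panel_variants:
        if pv.id in alleles:
            ref, alt = alleles[pv.id]
        else:
            ref = reference[pv.pos0].upper()
            alt = "G" if ref != "G" else "A"
        fixed.append(VariantKey(pv.chrom, pv.pos0, pv.id, ref, alt))
    panel_variants = fixed

    eqtl_tables, effects = simulate_eqtl_tables(
        [v.id for v in variants], n_datasets, n_causal, seeds[4],
        true_ids=[v.id for v in variants[:n_causal]])
    annot_rows, annot_truth = simulate_annotations(
        [v.id for v in variants], [v.id for v in variants[:n_causal]],
        flip_prob, seeds[5])
    gene_rows = simulate_gene_model(reference_length, 8, seeds[6])

    manifest = SimulationManifest(
        seed=seed,
        planted_proxies=proxies,
        planted_motif_sites=sites,
        causal_variants=[(v.id, truth[v.id], f"GENE_{v.id}")
                         for v in variants[:n_causal]],
        eqtl_effects=effects,
        annotation_truth=annot_truth,
    )

    import pandas as pd

    paths: dict[str, Path] = {}
    paths["reference"] = outdir / "reference.fa"
    write_fasta({"chr1": reference}, paths["reference"])
    paths["peaks"] = outdir / "peaks.bed"
    write_peaks(peaks, paths["peaks"])
    paths["panel"] = outdir / "panel.vcf"
    write_vcf(panel_variants, paths["panel"], matrix,
              {"chr1": reference_length})
    paths["variants"] = outdir / "variants.vcf"
    write_vcf(variants, paths["variants"], None, {"chr1": reference_length})
    paths["index_snps"] = outdir / "index_snps.tsv"
    pd.DataFrame({"id": [f"index_{v.id}" for v in variants]}).to_csv(
        paths["index_snps"], sep="\t", index=False)
    paths["motif_db"] = outdir / "motif_db.meme"
    # decoy set is fixed: the motif database is an external resource,
    # identical across scenario seeds
    write_meme([pwm] + decoy_pwms(10, len(pwm), 987654321), paths["motif_db"],
               background)
    for ds, path in write_eqtl_tables(eqtl_tables, outdir).items():
        paths[f"eqtl_{ds}"] = path
    paths["annotations"] = outdir / "annotations.tsv"
    pd.DataFrame(annot_rows).to_csv(paths["annotations"], sep="\t", index=False)
    paths["gene_model"] = outdir / "genes.bed"
    write_gene_model_bed12(gene_rows, paths["gene_model"])
    paths["manifest"] = outdir / "manifest.json"
    manifest.to_json(paths["manifest"])
    return manifest, paths
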