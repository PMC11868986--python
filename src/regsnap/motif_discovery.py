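"""De novo motif discovery from top ChIP-seq peaks.

A deliberately small seed-and-refine scheme: exact k-mer seeds are tested
for presence enrichment in positives versus per-sequence dinucleotide
shuffles, the best seed per round is extended to the target width, refined
with one EM pass over best-site alignments, and scored for enrichment on a
held-out half of the positives. Up to ``nmotifs`` motifs are accepted
greedily, masking the sites of each accepted motif. Benjamini-Hochberg
across the accepted motifs provides the discovery FDR filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .motif_core import BASES, PWM, BackgroundModel, encode, log_odds, revcomp

logger = logging.getLogger(__name__)

#: widths above this are reached only by extension (runtime cap)
MAX_SEED_WIDTH = 12
MAX_KMER = 8


@dataclass
class Peak:
    chrom: str
    start: int  # 0-based half-open
    end: int
    name: str = "."
    height: float = 0.0
    strand: str = "."
    summit: int | None = None  # offset from start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"peak {self.name}: end must exceed start")
        if not math.isfinite(self.height):
            raise ValueError(f"peak {self.name}: non-finite height")

    @property
    def center(self) -> int:
        if self.summit is not None:
            return self.start + self.summit
        return (self.start + self.end) // 2


@dataclass
class DiscoveredMotif:
    pwm: PWM
    enrichment_p: float
    seed_kmer: str
    q_value: float = float("nan")
    width: int = 0

    def __post_init__(self) -> None:
        if not self.width:
            self.width = len(self.pwm)


def read_peaks(path: str | Path) -> list[Peak]:
    """Read BED6(+summit) peaks; column 5 is the peak height."""
    peaks = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        summit = int(f[6]) if len(f) > 6 and f[6] != "." else None
        peaks.append(Peak(f[0], int(f[1]), int(f[2]),
                          f[3] if len(f) > 3 else ".",
                          float(f[4]) if len(f) > 4 else 0.0,
                          f[5] if len(f) > 5 else ".",
                          summit))
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            summit = "." if p.summit is None else str(p.summit)
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t"
                     f"{p.height:.4f}\t{p.strand}\t{summit}\n")


def select_top_peaks(peaks: Sequence[Peak], n: int = 500, flank: int = 20,
                     reference: Mapping[str, str] | None = None) -> list[str]:
    """Sequences (summit +/- flank, uppercased) of the top-n peaks by height.

    Ties are broken by coordinate. Sequences with more than 10% non-ACGT
    characters are dropped and logged.
    """
    if not peaks:
        raise ValueError("empty peak set")
    if reference is None:
        raise ValueError("a reference is required to extract sequences")
    ranked = sorted(peaks, key=lambda p: (-p.height, p.chrom, p.start))[:n]
    seqs = []
    for p in ranked:
        contig = str(reference[p.chrom])
        lo = max(0, p.center - flank)
        hi = min(len(contig), p.center + flank + 1)
        seq = contig[lo:hi].upper()
        bad = sum(c not in "ACGT" for c in seq)
        if bad > 0.1 * len(seq):
            logger.info("dropping peak %s: %d/%d non-ACGT", p.name, bad, len(seq))
            continue
        seqs.append(seq)
    return seqs


# ---------------------------------------------------------------------------
# Dinucleotide shuffle (random-arborescence Eulerian walk)


def dinucleotide_shuffle(sequence: str, seed: int | np.random.Generator = 0) -> str:
    """Shuffle preserving exact dinucleotide (and hence mononucleotide) counts."""
    if len(sequence) < 3:
        raise ValueError("sequence too short to shuffle (need length >= 3)")
    encode(sequence)  # validates ACGT alphabet
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = sequence.upper()
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = [v for v in edges if v != seq[-1]]
    last = seq[-1]
    # pick one terminal edge per non-terminal vertex so that following
    # terminal edges always reaches the last vertex (arborescence condition)
    for _ in range(10_000):
        terminal = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            cur, hops = v, 0
            while cur != last and hops <= len(terminal):
                if cur not in terminal:
                    break
                cur = terminal[cur]
                hops += 1
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - arborescence sampling converges quickly
        raise RuntimeError("failed to sample a valid shuffle")
    shuffled_edges = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in terminal:
            rest.remove(terminal[v])
        rng.shuffle(rest)
        if v in terminal:
            rest.append(terminal[v])
        shuffled_edges[v] = rest
    out = [seq[0]]
    cursors = {v: 0 for v in shuffled_edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][cursors[cur]]
        cursors[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_counts(sequence: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(sequence, sequence[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Seed-and-refine discovery


def _kmer_presence(seqs: Sequence[str], masks: Sequence[np.ndarray] | None,
                   k: int) -> dict[str, int]:
    """Number of sequences containing each k-mer (either strand)."""
    counts: dict[str, int] = {}
    for si, seq in enumerate(seqs):
        seen: set[str] = set()
        mask = masks[si] if masks is not None else None
        for i in range(len(seq) - k + 1):
            if mask is not None and mask[i:i + k].any():
                continue
            kmer = seq[i:i + k]
            seen.add(min(kmer, revcomp(kmer)))
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _presence_pvalue(k_pos: int, n_pos: int, k_bg: int, n_bg: int) -> float:
    """One-sided enrichment p (hypergeometric tail, = one-sided Fisher)."""
    return float(hypergeom.sf(k_pos - 1, n_pos + n_bg, k_pos + k_bg, n_pos))


def _best_site(codes: np.ndarray, lo_mat: np.ndarray,
               mask: np.ndarray | None = None) -> tuple[float, int, str] | None:
    """Best-scoring window anywhere in the sequence, both strands."""
    L = lo_mat.shape[0]
    m = codes.size
    if m < L:
        return None
    pos = np.arange(L)
    best = None
    for strand, mat in (("+", lo_mat), ("-", lo_mat[::-1, ::-1])):
        for s in range(m - L + 1):
            if mask is not None and mask[s:s + L].any():
                continue
            score = float(mat[pos, codes[s:s + L]].sum())
            if best is None or score > best[0]:
                best = (score, s, strand)
    return best


def _sites_to_pwm(sites: list[str], name: str) -> PWM:
    counts = np.full((len(sites[0]), 4), 0.5)  # pseudocount
    for site in sites:
        codes = encode(site)
        counts[np.arange(codes.size), codes] += 1.0
    return PWM(name, counts / counts.sum(axis=1, keepdims=True),
               source="discovery", nsites=len(sites))


def _extend_seed(seed_kmer: str, width: int, seqs: Sequence[str],
                 masks: Sequence[np.ndarray], name: str) -> PWM | None:
    """Align exact seed occurrences, pad to ``width``, and build a PWM."""
    k = len(seed_kmer)
    left = (width - k) // 2
    sites = []
    for si, seq in enumerate(seqs):
        site = None
        for variant in (seed_kmer, revcomp(seed_kmer)):
            i = seq.find(variant)
            while i >= 0 and site is None:
                lo, hi = i - left, i - left + width
                if lo >= 0 and hi <= len(seq) and not masks[si][lo:hi].any():
                    site = seq[lo:hi] if variant == seed_kmer else revcomp(seq[lo:hi])
                else:
                    i = seq.find(variant, i + 1)
            if site is not None:
                break
        if site is not None:
            sites.append(site)  # at most one site per sequence
    if len(sites) < 2:
        return None
    return _sites_to_pwm(sites, name)


def _refine(pwm: PWM, seqs: Sequence[str], masks: Sequence[np.ndarray],
            background: BackgroundModel) -> PWM:
    """One EM-style pass: realign to best sites with positive score, rebuild."""
    lo_mat = log_odds(pwm, background)
    sites = []
    for si, seq in enumerate(seqs):
        hit = _best_site(encode(seq), lo_mat, masks[si])
        if hit is None or hit[0] <= 0:
            continue
        score, s, strand = hit
        site = seq[s:s + len(pwm)]
        sites.append(site if strand == "+" else revcomp(site))
    if len(sites) < 2:
        return pwm
    return _sites_to_pwm(sites, pwm.name)


def _presence_threshold(pwm: PWM, background: BackgroundModel,
                        frac: float = 0.7) -> float:
    lo_mat = log_odds(pwm, background)
    return frac * float(lo_mat.max(axis=1).sum())


def _holdout_pvalue(pwm: PWM, holdout: Sequence[str],
                    holdout_bg: Sequence[str],
                    background: BackgroundModel) -> float:
    theta = _presence_threshold(pwm, background)
    lo_mat = log_odds(pwm, background)

    def n_hits(seqs: Sequence[str]) -> int:
        n = 0
        for seq in seqs:
            hit = _best_site(encode(seq), lo_mat)
            if hit is not None and hit[0] >= theta:
                n += 1
        return n

    k_pos = n_hits(holdout)
    k_bg = n_hits(holdout_bg)
    return _presence_pvalue(k_pos, len(holdout), k_bg, len(holdout_bg))


def discover_motifs(pos_seqs: Sequence[str], seed: int = 0, nmotifs: int = 5,
                    minw: int = 6, maxw: int = 20,
                    min_seqs: int = 20) -> list[DiscoveredMotif]:
    """Discover up to ``nmotifs`` enriched PWMs from positive sequences.

    Enrichment p-values are computed on a held-out half of the positives
    against their dinucleotide shuffles and are therefore valid for the
    selected motifs; pass them to :func:`motif_fdr_filter` for FDR control.
    """
    if len(pos_seqs) < min_seqs:
        raise ValueError(f"need at least {min_seqs} positive sequences, "
                         f"got {len(pos_seqs)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos_seqs))
    half = len(pos_seqs) // 2
    train = [pos_seqs[i].upper() for i in order[:half]]
    holdout = [pos_seqs[i].upper() for i in order[half:]]
    train_bg = [dinucleotide_shuffle(s, rng) for s in train]
    holdout_bg = [dinucleotide_shuffle(s, rng) for s in holdout]
    background = BackgroundModel.from_sequence("".join(train))
    masks = [np.zeros(len(s), dtype=bool) for s in train]
    no_mask = [np.zeros(len(s), dtype=bool) for s in train_bg]

    widths = range(minw, min(maxw, MAX_SEED_WIDTH) + 1)
    motifs: list[DiscoveredMotif] = []
    for round_i in range(nmotifs):
        best = None  # (p, kmer, width)
        for w in widths:
            k = min(w, MAX_KMER)
            pos_counts = _kmer_presence(train, masks, k)
            bg_counts = _kmer_presence(train_bg, no_mask, k)
            min_count = max(3, int(round(0.1 * len(train))))
            for kmer, k_pos in pos_counts.items():
                if k_pos < min_count:
                    continue
                p = _presence_pvalue(k_pos, len(train),
                                     bg_counts.get(kmer, 0), len(train_bg))
                cand = (p, kmer, w)
                if best is None or cand < best:
                    best = cand
        if best is None or best[0] > 0.05:
            break
        p_train, kmer, w = best
        name = f"motif_{round_i + 1}_{kmer}"
        pwm = _extend_seed(kmer, w, train, masks, name)
        if pwm is None:
            break
        pwm = _refine(pwm, train, masks, background)
        p_holdout = _holdout_pvalue(pwm, holdout, holdout_bg, background)
        motifs.append(DiscoveredMotif(pwm, p_holdout, kmer))
        # mask accepted motif's sites in the training set
        theta = _presence_threshold(pwm, background)
        lo_mat = log_odds(pwm, background)
        for si, seq in enumerate(train):
            hit = _best_site(encode(seq), lo_mat, masks[si])
            if hit is not None and hit[0] >= theta:
                masks[si][hit[1]:hit[1] + len(pwm)] = True
    return motifs


def motif_fdr_filter(motifs: Sequence[DiscoveredMotif],
                     alpha: float = 0.05) -> list[DiscoveredMotif]:
    """Benjamini-Hochberg across the motif list; keep q <= alpha."""
    if not motifs:
        return []
    from .eqtl_integration import bh_fdr

    qs = bh_fdr([m.enrichment_p for m in motifs])
    kept = []
    for m, q in zip(motifs, qs):
        m.q_value = float(q)
        if q <= alpha:
            kept.append(m)
    return kept
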