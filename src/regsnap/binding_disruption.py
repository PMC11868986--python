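"""Allele-specific TF binding statistics and the disrupting-SNP caller.

For each variant x motif pair we report the best log-odds window score of
each allele (windows covering the variant within +/- half_window), an
affinity p-value per allele (probability that a random background sequence
of the same scan length scores at least as well) and a rank p-value for the
allelic score difference (probability under the background null of an
absolute difference at least as large). Exact p-values enumerate all
background sequences when the scan is short enough; otherwise seeded Monte
Carlo is used, with the null distribution cached per (motif, scan geometry)
so that many variants share one sample.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .motif_core import (
    BASE_INDEX,
    BackgroundModel,
    PWM,
    best_match_score,
    encode,
    focal_window_starts,
    log_odds,
)

#: exact enumeration is permitted up to this scan length (4^10 sequences)
EXACT_MAX_SCAN = 10

#: float slop when comparing null scores against the observed score
SCORE_TOL = 1e-9


@dataclass
class DisruptionResult:
    """One variant x motif test."""

    variant_id: str
    motif_name: str
    score_ref: float
    score_alt: float
    p_ref: float | None = None
    p_alt: float | None = None
    p_rank: float | None = None
    direction: str = "none"  # loss | gain | none
    best_window_ref: tuple[int, str] | None = None
    best_window_alt: tuple[int, str] | None = None
    mc_se: dict | None = None
    kept: bool = False

    @property
    def delta_score(self) -> float:
        return self.score_ref - self.score_alt


class REF_MISMATCH(ValueError):
    """Reference allele does not match the FASTA base at the variant position."""


def _window_scores(codes: np.ndarray, lo_mat: np.ndarray,
                   starts: np.ndarray) -> np.ndarray:
    """Plus-strand window scores for a batch: (n_seq, n_windows)."""
    L = lo_mat.shape[0]
    pos = np.arange(L)
    out = np.empty((codes.shape[0], starts.size))
    for k, s in enumerate(starts):
        out[:, k] = lo_mat[pos, codes[:, s:s + L]].sum(axis=1)
    return out


def best_scores_batch(codes: np.ndarray, lo_mat: np.ndarray,
                      focal: int) -> np.ndarray:
    """Best focal-covering window score over both strands for each row."""
    starts = focal_window_starts(codes.shape[1], lo_mat.shape[0], focal)
    if starts.size == 0:
        raise ValueError("no valid scoring window covers the focal position")
    fwd = _window_scores(codes, lo_mat, starts)
    rev = _window_scores(codes, lo_mat[::-1, ::-1], starts)
    return np.maximum(fwd.max(axis=1), rev.max(axis=1))


def _enumerate_codes(length: int) -> np.ndarray:
    """All 4**length sequences as an (4**length, length) int8 array."""
    n = 4 ** length
    idx = np.arange(n)
    out = np.empty((n, length), dtype=np.int8)
    for j in range(length - 1, -1, -1):
        out[:, j] = idx % 4
        idx //= 4
    return out


def _sequence_weights(codes: np.ndarray, background: BackgroundModel) -> np.ndarray:
    return np.exp(np.log(background.base_freqs)[codes].sum(axis=1))


def _key_digest(*parts) -> int:
    h = hashlib.blake2b(digest_size=8)
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
        else:
            h.update(repr(p).encode())
    return int.from_bytes(h.digest(), "little")


class NullCache:
    """Caches null score samples / exact distributions keyed by scan geometry.

    Monte-Carlo seeds are derived deterministically from ``root_seed`` and
    the cache key, so results are reproducible and independent of the order
    in which variants are scored.
    """

    def __init__(self, root_seed: int = 0, n_mc: int = 100_000):
        self.root_seed = int(root_seed)
        self.n_mc = int(n_mc)
        self._store: dict = {}

    def _rng(self, digest: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=[self.root_seed, digest]))

    def affinity_null(self, lo_mat: np.ndarray, background: BackgroundModel,
                      scan_len: int, focal: int, mode: str) -> tuple:
        """Return ("exact", scores, weights) or ("mc", sorted_scores)."""
        digest = _key_digest("affinity", lo_mat, background.base_freqs,
                             scan_len, focal, mode)
        if digest in self._store:
            return self._store[digest]
        if mode == "exact":
            codes = _enumerate_codes(scan_len)
            scores = best_scores_batch(codes, lo_mat, focal)
            weights = _sequence_weights(codes, background)
            entry = ("exact", scores, weights)
        else:
            rng = self._rng(digest)
            codes = background.sample(rng, self.n_mc, scan_len)
            entry = ("mc", np.sort(best_scores_batch(codes, lo_mat, focal)))
        self._store[digest] = entry
        return entry

    def rank_null(self, lo_mat: np.ndarray, background: BackgroundModel,
                  scan_len: int, focal: int, ref_code: int, alt_code: int,
                  mode: str) -> tuple:
        a, b = sorted((ref_code, alt_code))
        digest = _key_digest("rank", lo_mat, background.base_freqs,
                             scan_len, focal, a, b, mode)
        if digest in self._store:
            return self._store[digest]
        if mode == "exact":
            codes = _enumerate_codes(scan_len)
            weights = _sequence_weights(codes, background)
        else:
            rng = self._rng(digest)
            codes = background.sample(rng, self.n_mc, scan_len)
            weights = None
        codes[:, focal] = a
        s_a = best_scores_batch(codes, lo_mat, focal)
        codes[:, focal] = b
        s_b = best_scores_batch(codes, lo_mat, focal)
        stat = np.abs(s_a - s_b)
        if mode == "exact":
            entry = ("exact", stat, weights)
        else:
            entry = ("mc", np.sort(stat))
        self._store[digest] = entry
        return entry


def _tail_probability(entry: tuple, observed: float) -> tuple[float, float | None]:
    """P(null >= observed - tol); returns (p, se) with se=None for exact."""
    if entry[0] == "exact":
        _, values, weights = entry
        p = float(weights[values >= observed - SCORE_TOL].sum() / weights.sum())
        return min(max(p, 0.0), 1.0), None
    _, sorted_vals = entry
    n = sorted_vals.size
    idx = np.searchsorted(sorted_vals, observed - SCORE_TOL, side="left")
    p = float(n - idx) / n
    se = float(np.sqrt(p * (1.0 - p) / n))
    return p, se


def _resolve_mode(mode: str, scan_len: int) -> str:
    if mode == "auto":
        return "exact" if scan_len <= EXACT_MAX_SCAN else "mc"
    if mode not in ("exact", "mc"):
        raise ValueError(f"invalid mode {mode!r}")
    if mode == "exact" and scan_len > EXACT_MAX_SCAN:
        raise ValueError(
            f"exact mode limited to scan length {EXACT_MAX_SCAN}, got {scan_len}")
    return mode


def affinity_pvalue(score: float, pwm: PWM, background: BackgroundModel,
                    scan_len: int, focal: int, mode: str = "auto",
                    n_mc: int = 100_000, seed: int = 0,
                    pseudocount: float = 1e-4,
                    cache: NullCache | None = None) -> tuple[float, float | None]:
    """P(best focal score of a random background sequence >= ``score``).

    Returns ``(p, se)``; ``se`` is the binomial standard error in Monte-Carlo
    mode and None for exact enumeration.
    """
    mode = _resolve_mode(mode, scan_len)
    cache = cache or NullCache(seed, n_mc)
    lo_mat = log_odds(pwm, background, pseudocount)
    entry = cache.affinity_null(lo_mat, background, scan_len, focal, mode)
    return _tail_probability(entry, score)


def rank_pvalue(pwm: PWM, reference_window: str, focal_offset: int,
                ref_allele: str, alt_allele: str,
                background: BackgroundModel, mode: str = "auto",
                n_mc: int = 100_000, seed: int = 0,
                pseudocount: float = 1e-4,
                cache: NullCache | None = None) -> tuple[float, float | None]:
    """P-value for the allelic score difference |S_ref - S_alt|.

    The null substitutes the two alleles at ``focal_offset`` of random
    background sequences of the same length as ``reference_window``.
    """
    if ref_allele.upper() == alt_allele.upper():
        return 1.0, None
    scan_len = len(reference_window)
    mode = _resolve_mode(mode, scan_len)
    cache = cache or NullCache(seed, n_mc)
    lo_mat = log_odds(pwm, background, pseudocount)
    s_ref, _, _ = best_match_score(pwm, reference_window, focal_offset,
                                   ref_allele, background, pseudocount)
    s_alt, _, _ = best_match_score(pwm, reference_window, focal_offset,
                                   alt_allele, background, pseudocount)
    observed = abs(s_ref - s_alt)
    if observed <= SCORE_TOL:
        return 1.0, None
    entry = cache.rank_null(lo_mat, background, scan_len, focal_offset,
                            BASE_INDEX[ref_allele.upper()],
                            BASE_INDEX[alt_allele.upper()], mode)
    return _tail_probability(entry, observed)


def extract_scan_window(reference: Mapping[str, str], chrom: str, pos0: int,
                        half_window: int = 20) -> tuple[str, int]:
    """Sequence of pos0 +/- half_window (truncated at contig ends) and the
    focal offset within it."""
    seq = reference[chrom]
    if not (0 <= pos0 < len(seq)):
        raise ValueError(f"position {pos0} outside contig {chrom}")
    lo = max(0, pos0 - half_window)
    hi = min(len(seq), pos0 + half_window + 1)
    return str(seq[lo:hi]).upper(), pos0 - lo


def score_variant(pwm: PWM, reference: Mapping[str, str], variant,
                  half_window: int = 20,
                  background: BackgroundModel | None = None,
                  pseudocount: float = 1e-4) -> list[DisruptionResult]:
    """Score ref and alt alleles of a variant against one PWM.

    ``variant`` needs attributes chrom, pos0, id, ref, alts (or alt).
    Multiallelic variants yield one result per alt allele. Raises
    REF_MISMATCH when the FASTA base differs from the declared ref allele.
    """
    bg = background or BackgroundModel.uniform()
    window, focal = extract_scan_window(reference, variant.chrom, variant.pos0,
                                        half_window)
    fasta_base = window[focal].upper()
    if fasta_base != variant.ref.upper():
        raise REF_MISMATCH(
            f"{variant.id}: FASTA has {fasta_base} at {variant.chrom}:{variant.pos0}, "
            f"variant ref is {variant.ref}")
    alts = getattr(variant, "alts", None) or [variant.alt]
    s_ref, w_ref, st_ref = best_match_score(pwm, window, focal, variant.ref,
                                            bg, pseudocount)
    results = []
    for alt in alts:
        s_alt, w_alt, st_alt = best_match_score(pwm, window, focal, alt,
                                                bg, pseudocount)
        if s_alt < s_ref - SCORE_TOL:
            direction = "loss"
        elif s_alt > s_ref + SCORE_TOL:
            direction = "gain"
        else:
            direction = "none"
        results.append(DisruptionResult(
            variant_id=variant.id, motif_name=pwm.name,
            score_ref=s_ref, score_alt=s_alt, direction=direction,
            best_window_ref=(w_ref, st_ref), best_window_alt=(w_alt, st_alt),
            p_rank=1.0 if direction == "none" else None,
        ))
    return results


def evaluate_variants(pwms: Sequence[PWM], reference: Mapping[str, str],
                      variants: Sequence, half_window: int = 20,
                      background: BackgroundModel | None = None,
                      mode: str = "auto", n_mc: int = 100_000, seed: int = 0,
                      pseudocount: float = 1e-4,
                      cache: NullCache | None = None) -> list[DisruptionResult]:
    """Score every variant against every PWM and attach all three p-values."""
    bg = background or BackgroundModel.uniform()
    cache = cache or NullCache(seed, n_mc)
    out: list[DisruptionResult] = []
    for variant in variants:
        window, focal = extract_scan_window(reference, variant.chrom,
                                            variant.pos0, half_window)
        alts = getattr(variant, "alts", None) or [variant.alt]
        eff_mode = _resolve_mode(mode, len(window))
        for pwm in pwms:
            if len(pwm) > len(window):
                continue
            for alt_allele, res in zip(alts, score_variant(
                    pwm, reference, variant, half_window, bg, pseudocount)):
                res.p_ref, se_ref = affinity_pvalue(
                    res.score_ref, pwm, bg, len(window), focal, eff_mode,
                    n_mc, seed, pseudocount, cache)
                res.p_alt, se_alt = affinity_pvalue(
                    res.score_alt, pwm, bg, len(window), focal, eff_mode,
                    n_mc, seed, pseudocount, cache)
                if res.p_rank is None:
                    res.p_rank, se_rank = rank_pvalue(
                        pwm, window, focal, variant.ref, alt_allele, bg,
                        eff_mode, n_mc, seed, pseudocount, cache)
                else:
                    se_rank = None
                if eff_mode == "mc":
                    res.mc_se = {"p_ref": se_ref, "p_alt": se_alt,
                                 "p_rank": se_rank}
                out.append(res)
    return out


def affinity_pass_count(results: Sequence[DisruptionResult],
                        alpha_affinity: float = 0.001) -> int:
    """Number of results passing the per-allele occupancy (affinity) gate.

    Used as the Bonferroni denominator when correcting only the rank tests
    that are actually conducted (pairs with evidence of TF occupancy).
    """
    return sum(1 for r in results if min(r.p_ref, r.p_alt) < alpha_affinity)


def call_disrupting(results: Sequence[DisruptionResult],
                    alpha_affinity: float = 0.001,
                    alpha_rank: float = 0.05,
                    n_tests: int | None = None) -> tuple[list[DisruptionResult], dict]:
    """Apply the two significance gates and summarize.

    Keeps results with min(p_ref, p_alt) < alpha_affinity and
    p_rank < alpha_rank / n_tests (Bonferroni over the scored pairs by
    default). Returns (kept results, summary dict).
    """
    if n_tests is None:
        n_tests = len(results)
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = alpha_rank / n_tests
    kept = []
    for r in results:
        ok = (min(r.p_ref, r.p_alt) < alpha_affinity
              and r.p_rank < threshold)
        r.kept = bool(ok)
        if ok:
            kept.append(r)
    per_motif: dict[str, dict[str, int]] = {}
    for r in kept:
        d = per_motif.setdefault(r.motif_name, {"loss": 0, "gain": 0, "none": 0})
        d[r.direction] += 1
    summary = {
        "n_tests": n_tests,
        "rank_threshold": threshold,
        "n_kept": len(kept),
        "n_variants_kept": len({r.variant_id for r in kept}),
        "per_motif": per_motif,
    }
    return kept, summary
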