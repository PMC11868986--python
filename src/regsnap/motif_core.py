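"""Position weight matrices: representation, MEME I/O, scanning and comparison.

Conventions used throughout the package:

- base order is A, C, G, T (columns 0..3 of every matrix);
- sequences are encoded as int8 arrays with A=0, C=1, G=2, T=3;
- log-odds scores are in log2 units;
- coordinates are 0-based half-open unless a file format dictates otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_ROW_SUM_TOL = 1e-3


def encode(sequence: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array (A=0,C=1,G=2,T=3)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    if (codes < 0).any():
        bad = sequence[int(np.argmax(codes < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(sequence: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return sequence.translate(comp)[::-1]


@dataclass
class PWM:
    """A position weight matrix of per-position base probabilities.

    ``probs`` has shape (L, 4) in A,C,G,T order; every row sums to 1.
    """

    name: str
    probs: np.ndarray
    source: str = ""
    nsites: int | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probs must be an (L, 4) matrix")
        if self.probs.shape[0] < 1:
            raise ValueError("PWM must have at least one column")
        if (self.probs < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > _ROW_SUM_TOL)[0]
        if bad.size:
            raise ValueError(
                f"PWM {self.name!r}: row {bad[0]} sums to {sums[bad[0]]:.4f}, not 1"
            )
        # normalize away floating fuzz below the tolerance
        self.probs = self.probs / sums[:, None]

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.probs[::-1, ::-1].copy(),
                   source=self.source, nsites=self.nsites)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def information_content(self) -> float:
        """Total information content in bits (uniform background)."""
        p = np.clip(self.probs, 1e-12, None)
        return float((2.0 + (p * np.log2(p)).sum(axis=1)).sum())


@dataclass
class BackgroundModel:
    """Zero- or first-order background over A,C,G,T."""

    base_freqs: np.ndarray
    order: int = 0
    transition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.base_freqs.shape != (4,):
            raise ValueError("base_freqs must have 4 entries")
        if (self.base_freqs <= 0).any():
            raise ValueError("background frequencies must be positive")
        if abs(self.base_freqs.sum() - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1")
        self.base_freqs = self.base_freqs / self.base_freqs.sum()
        if self.order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        if self.order == 1:
            t = np.asarray(self.transition, dtype=float)
            if t.shape != (4, 4) or np.abs(t.sum(axis=1) - 1.0).max() > 1e-6:
                raise ValueError("transition must be a 4x4 row-stochastic matrix")
            self.transition = t

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequence(cls, sequence: str | np.ndarray, order: int = 0) -> "BackgroundModel":
        codes = encode(sequence) if isinstance(sequence, str) else sequence
        counts = np.bincount(codes, minlength=4).astype(float) + 1.0
        freqs = counts / counts.sum()
        if order == 0:
            return cls(freqs)
        trans = np.ones((4, 4))
        np.add.at(trans, (codes[:-1], codes[1:]), 1.0)
        trans /= trans.sum(axis=1, keepdims=True)
        return cls(freqs, order=1, transition=trans)

    def sample(self, rng: np.random.Generator, n: int, length: int) -> np.ndarray:
        """Draw ``n`` background sequences of ``length`` as an (n, length) code array."""
        if self.order == 0:
            return rng.choice(4, size=(n, length), p=self.base_freqs).astype(np.int8)
        out = np.empty((n, length), dtype=np.int8)
        out[:, 0] = rng.choice(4, size=n, p=self.base_freqs)
        cum = np.cumsum(self.transition, axis=1)
        for j in range(1, length):
            u = rng.random(n)
            out[:, j] = (u[:, None] > cum[out[:, j - 1]]).sum(axis=1)
        return out


@dataclass
class MotifMatch:
    """Best ungapped alignment of a query PWM against a database PWM."""

    query_name: str
    db_name: str
    offset: int
    strand: str
    similarity: float


def from_consensus(iupac_string: str, name: str | None = None) -> PWM:
    """Build a PWM from an IUPAC consensus: uniform over allowed bases per column."""
    if not iupac_string:
        raise ValueError("empty consensus string")
    rows = []
    for ch in iupac_string.upper():
        allowed = IUPAC_CODES.get(ch)
        if allowed is None:
            raise ValueError(f"non-IUPAC character {ch!r} in consensus")
        row = np.zeros(4)
        for b in allowed:
            row[BASE_INDEX[b]] = 1.0 / len(allowed)
        rows.append(row)
    return PWM(name or iupac_string, np.array(rows), source="consensus")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme(path: str | Path) -> list[PWM]:
    """Read PWMs from a MEME minimal motif format file."""
    pwms: list[PWM] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif_{len(pwms) + 1}"
            i += 1
            nsites = None
            while i < n and not lines[i].strip().startswith("letter-probability"):
                i += 1
            if i >= n:
                raise ValueError(f"motif {name!r}: missing letter-probability matrix")
            header = lines[i].strip()
            width = None
            for tok, nxt in zip(header.split(), header.split()[1:] + [""]):
                if tok == "w=":
                    width = int(nxt)
                if tok == "nsites=":
                    nsites = int(float(nxt))
            i += 1
            rows = []
            while i < n:
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                vals = stripped.split()
                if len(vals) != 4:
                    break
                rows.append([float(v) for v in vals])
                i += 1
            if width is not None and len(rows) != width:
                raise ValueError(
                    f"motif {name!r}: header says w={width} but {len(rows)} rows found"
                )
            mat = np.array(rows)
            sums = mat.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > _ROW_SUM_TOL)[0]
            if bad.size:
                raise ValueError(
                    f"motif {name!r}: row {bad[0]} sums to {sums[bad[0]]:.4f}, not 1"
                )
            pwms.append(PWM(name, mat, source=str(path), nsites=nsites))
        else:
            i += 1
    return pwms


def write_meme(pwms: Iterable[PWM], path: str | Path,
               background: BackgroundModel | None = None) -> None:
    """Write PWMs in MEME minimal motif format."""
    bg = background or BackgroundModel.uniform()
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg.base_freqs)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            nsites = f" nsites= {pwm.nsites}" if pwm.nsites is not None else ""
            fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)}{nsites}\n")
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Scanning


def log_odds(pwm: PWM, background: BackgroundModel | None = None,
             pseudocount: float = 1e-4) -> np.ndarray:
    """Log2-odds matrix: log2((p + c) / (1 + 4c) / bg)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = background or BackgroundModel.uniform()
    if (bg.base_freqs <= 0).any():
        raise ValueError("zero background frequency")
    num = (pwm.probs + pseudocount) / (1.0 + 4.0 * pseudocount)
    return np.log2(num / bg.base_freqs)


def focal_window_starts(seq_len: int, motif_len: int, focal_pos: int) -> np.ndarray:
    """Start positions of all length-L windows inside the sequence that cover focal_pos."""
    lo = max(0, focal_pos - motif_len + 1)
    hi = min(seq_len - motif_len, focal_pos)
    if hi < lo:
        return np.empty(0, dtype=int)
    return np.arange(lo, hi + 1)


def best_match_score(pwm: PWM, sequence: str, focal_pos: int, allele: str,
                     background: BackgroundModel | None = None,
                     pseudocount: float = 1e-4) -> tuple[float, int, str]:
    """Best log-odds window score over both strands, windows covering ``focal_pos``.

    The given ``allele`` replaces the base at ``focal_pos`` before scanning.
    Ties are broken by smaller window start, then plus strand. Returns
    ``(score, window_start, strand)``.
    """
    codes = encode(sequence)
    if not (0 <= focal_pos < codes.size):
        raise ValueError("focal_pos outside sequence")
    if len(allele) != 1:
        raise ValueError("allele must be a single base")
    codes = codes.copy()
    codes[focal_pos] = BASE_INDEX[allele.upper()]
    lo_mat = log_odds(pwm, background, pseudocount)
    starts = focal_window_starts(codes.size, len(pwm), focal_pos)
    if starts.size == 0:
        raise ValueError("no valid scoring window covers the focal position")
    best: tuple[float, int, str] | None = None
    for strand, mat in (("+", lo_mat), ("-", lo_mat[::-1, ::-1])):
        for s in starts:
            score = float(mat[np.arange(len(pwm)), codes[s:s + len(pwm)]].sum())
            key = (score, -s, strand == "+")
            if best is None or key > (best[0], -best[1], best[2] == "+"):
                best = (score, int(s), strand)
    return best


# ---------------------------------------------------------------------------
# Motif comparison


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    x = a.ravel()
    y = b.ravel()
    vx = x - x.mean()
    vy = y - y.mean()
    denom = math.sqrt(float(vx @ vx) * float(vy @ vy))
    if denom == 0.0:
        return 0.0
    return float(vx @ vy) / denom


def pwm_similarity(query: PWM, target: PWM, min_overlap: int = 4) -> MotifMatch:
    """Best Pearson correlation of aligned probability columns.

    All ungapped offsets of the target relative to the query are tried on
    both target strands; ``offset`` is the position of the target's first
    column relative to the query's first column on the reported strand.
    """
    lq, lt = len(query), len(target)
    if min(lq, lt) < min_overlap:
        raise ValueError(
            f"min_overlap={min_overlap} exceeds a motif length ({lq}, {lt})"
        )
    best: MotifMatch | None = None
    for strand, tgt in (("+", target.probs), ("-", target.probs[::-1, ::-1])):
        for offset in range(-(lt - min_overlap), lq - min_overlap + 1):
            q_lo = max(0, offset)
            q_hi = min(lq, offset + lt)
            if q_hi - q_lo < min_overlap:
                continue
            t_lo = q_lo - offset
            sim = _column_correlation(query.probs[q_lo:q_hi], tgt[t_lo:t_lo + (q_hi - q_lo)])
            if best is None or sim > best.similarity:
                best = MotifMatch(query.name, target.name, offset, strand, sim)
    if best is None:
        raise ValueError("no alignment satisfies min_overlap")
    return best


def match_to_database(discovered: Sequence[PWM], db: Sequence[PWM],
                      sim_min: float = 0.75, min_overlap: int = 4,
                      logger=None) -> list[MotifMatch]:
    """All database motifs matching each discovered motif at similarity >= sim_min.

    Matches are grouped per query, sorted by descending similarity within a
    query. Queries with no match are dropped (and logged when a logger is
    given); duplicate database entries are reported as-is.
    """
    if not db:
        raise ValueError("empty motif database")
    out: list[MotifMatch] = []
    for query in discovered:
        matches = []
        for target in db:
            try:
                m = pwm_similarity(query, target, min_overlap=min_overlap)
            except ValueError:
                continue
            if m.similarity >= sim_min:
                matches.append(m)
        matches.sort(key=lambda m: (-m.similarity, m.db_name))
        if not matches and logger is not None:
            logger.info("motif %s matched nothing in the database; dropped", query.name)
        out.extend(matches)
    return out
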