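"""Position-weight-matrix, k-mer and signal-track utilities.

These primitives back two stages of the MPBA analysis: choosing the
variable position inside each motif when designing a combinatorial
mutation library (highest-information-content column of the TF's in-vitro
PWM), and scoring genome-wide binding signal around k-mer occurrences in
promoters to express motif enrichment of a TF's cleavage signal.

Conventions: bases are ordered A, C, G, T; coordinates are 0-based,
half-open; PWM columns are probability distributions over bases.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: IUPAC degeneracy codes -> the set of plain bases each stands for.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position probability matrix: 4 rows (A,C,G,T) x L columns.

    Each column is a probability distribution over bases (sums to 1).
    """

    tf_name: str
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("PWM must be a 4 x L matrix (rows A,C,G,T)")
        if self.probs.shape[1] < 1:
            raise ValueError("PWM must have at least one column")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("PWM entries must lie in [0, 1]")
        colsums = self.probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            bad = np.where(np.abs(colsums - 1.0) > 1e-9)[0]
            raise ValueError(f"PWM columns {bad.tolist()} do not sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[1]

    def reverse_complement(self) -> "PWM":
        """PWM of the reverse-complement motif (rows swapped A<->T, C<->G
        and columns reversed)."""
        return PWM(self.tf_name, self.probs[::-1, ::-1])


@dataclass
class MotifPattern:
    """A consensus motif written with IUPAC degeneracy codes.

    Bracketed alternatives such as ``GAATG[CT]`` are accepted and folded
    into the equivalent IUPAC code.
    """

    tf_name: str
    pattern: str

    def __post_init__(self):
        sets = parse_iupac_pattern(self.pattern)
        if len(sets) < 4:
            raise ValueError("motif pattern must be at least 4 bases long")
        self._sets = sets

    @property
    def base_sets(self) -> list[frozenset]:
        return self._sets

    def __len__(self) -> int:
        return len(self._sets)


def parse_iupac_pattern(pattern: str) -> list[frozenset]:
    """Parse an IUPAC/bracket pattern into one base-set per position."""
    sets: list[frozenset] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i].upper()
        if ch == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed '[' in pattern {pattern!r}")
            group = pattern[i + 1:j].upper()
            if not group or any(b not in _BASE_INDEX for b in group):
                raise ValueError(f"invalid bracket group in {pattern!r}")
            sets.append(frozenset(group))
            i = j + 1
        elif ch in IUPAC_CODES:
            sets.append(frozenset(IUPAC_CODES[ch]))
            i += 1
        else:
            raise ValueError(f"invalid symbol {ch!r} in pattern {pattern!r}")
    return sets


def pattern_in_kmer(kmer: str, pattern: MotifPattern | str) -> bool:
    """True if the k-mer, on either strand, contains a match to the pattern.

    Both the k-mer and its reverse complement are searched because k-mer
    indices are strand-collapsed.
    """
    if isinstance(pattern, str):
        sets = parse_iupac_pattern(pattern)
    else:
        sets = pattern.base_sets
    m = len(sets)
    for seq in (kmer, reverse_complement(kmer)):
        for off in range(len(seq) - m + 1):
            if all(seq[off + j] in sets[j] for j in range(m)):
                return True
    return False


# ---------------------------------------------------------------------------
# PWM statistics


def column_information_content(pwm: PWM) -> np.ndarray:
    """Per-column information content in bits: IC_j = 2 + sum_b p.log2(p).

    0 for a uniform column, 2 for a deterministic one; 0*log2(0) = 0.
    """
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return 2.0 + plogp.sum(axis=0)


def central_variable_position(pwm: PWM, span: tuple[int, int]) -> int:
    """Absolute coordinate of the motif column with maximal information.

    Ties are broken by the column closest to the motif midpoint, then the
    leftmost; this selects the "central position with the highest
    information content" that becomes the library's variable position.
    """
    start, end = span
    L = len(pwm)
    if end - start != L:
        raise ValueError(
            f"motif span length {end - start} does not match PWM length {L}"
        )
    ic = column_information_content(pwm)
    mid = (L - 1) / 2.0
    best = min(range(L), key=lambda j: (-ic[j], abs(j - mid), j))
    return start + best


def hamming_to_canonical(motif: str, canonical: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(motif) != len(canonical):
        raise ValueError("sequences must have equal length")
    return sum(a != b for a, b in zip(motif.upper(), canonical.upper()))


def pwm_euclidean_distance(a: PWM, b: PWM) -> float:
    """Euclidean distance between two PWMs over all 4xL entries.

    Unequal-length PWMs are compared by sliding the shorter over the longer
    and taking the minimum distance over all full-overlap offsets.
    """
    pa, pb = a.probs, b.probs
    if pa.shape[1] == pb.shape[1]:
        return float(np.sqrt(((pa - pb) ** 2).sum()))
    if pa.shape[1] > pb.shape[1]:
        long_, short = pa, pb
    else:
        long_, short = pb, pa
    ls, ll = short.shape[1], long_.shape[1]
    best = np.inf
    for off in range(ll - ls + 1):
        d = np.sqrt(((long_[:, off:off + ls] - short) ** 2).sum())
        best = min(best, float(d))
    return best


# ---------------------------------------------------------------------------
# Canonical (strand-collapsed) k-mer indexing


def _encode(kmer: str) -> int:
    code = 0
    for ch in kmer:
        try:
            code = code * 4 + _BASE_INDEX[ch]
        except KeyError:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer {kmer!r}")
    return code


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def canonical_kmer_index(kmer: str, k: int = 7) -> int:
    """Stable index shared by a k-mer and its reverse complement.

    The index is the smaller of the two base-4 encodings, so for odd k
    (no palindromes) the 4^k k-mers collapse into 4^k / 2 classes.
    """
    kmer = kmer.upper()
    if len(kmer) != k:
        raise ValueError(f"expected a {k}-mer, got {kmer!r}")
    return min(_encode(kmer), _encode(reverse_complement(kmer)))


def kmer_from_index(index: int, k: int = 7) -> str:
    """Representative k-mer (the lexicographically smaller strand) of a
    canonical index."""
    return _decode(index, k)


# ---------------------------------------------------------------------------
# Signal tracks and promoter intervals


@dataclass
class SignalTrack:
    """Per-base non-negative signal over one contiguous genomic interval.

    ``sequence``, when present, is the DNA of the same interval and is
    required by the k-mer scoring operations.
    """

    chrom: str
    start: int
    values: np.ndarray
    sequence: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")
        if self.start < 0:
            raise ValueError("track origin must be non-negative")
        if np.any(self.values < 0):
            raise ValueError("track values must be non-negative")
        if self.sequence is not None:
            self.sequence = str(self.sequence).upper()
            if len(self.sequence) != len(self.values):
                raise ValueError("sequence length must equal track length")

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def region_sum(self, start: int, end: int) -> float:
        if start < self.start or end > self.end or start >= end:
            raise ValueError(f"[{start}, {end}) outside track bounds")
        return float(self.values[start - self.start:end - self.start].sum())


@dataclass
class PromoterSet:
    """A set of (chrom, start, end[, name]) intervals, 0-based half-open."""

    intervals: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        cleaned = []
        for iv in self.intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            name = iv[3] if len(iv) > 3 else None
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval {iv!r}")
            cleaned.append((chrom, start, end, name))
        self.intervals = cleaned

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def kmer_relative_binding_scores(
    track: SignalTrack,
    promoters: PromoterSet,
    k: int = 7,
    window: int = 20,
) -> dict[int, float]:
    """Mean signal around every promoter k-mer occurrence, per canonical index.

    Every position of a k-mer fully inside a promoter is an occurrence; the
    signal is averaged over a ``window``-bp window centered on the k-mer
    midpoint (for the default 20 bp: 10 bases left of the central base
    through 9 bases right of it, the central base included). The score of a
    canonical index is the mean over all of its occurrences in all
    promoters; indices never observed are absent from the map. Occurrences
    whose window extends past the track bounds are skipped and counted in
    the QC log.
    """
    if track.sequence is None:
        raise ValueError("k-mer scoring requires a track with a sequence")
    half = window // 2
    positions: set[int] = set()
    for chrom, pstart, pend, _ in promoters:
        if chrom != track.chrom:
            continue
        lo = max(pstart, track.start)
        hi = min(pend, track.end) - k + 1
        positions.update(range(lo, hi))
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    n_skipped = n_ambiguous = 0
    for pos in sorted(positions):
        kmer = track.sequence[pos - track.start:pos - track.start + k]
        if any(ch not in _BASE_INDEX for ch in kmer):
            n_ambiguous += 1
            continue
        mid = pos + k // 2
        w0, w1 = mid - half, mid - half + window
        if w0 < track.start or w1 > track.end:
            n_skipped += 1
            continue
        score = float(track.values[w0 - track.start:w1 - track.start].mean())
        idx = canonical_kmer_index(kmer, k)
        sums[idx] = sums.get(idx, 0.0) + score
        counts[idx] = counts.get(idx, 0) + 1
    if n_skipped or n_ambiguous:
        logger.info(
            "k-mer scoring: skipped %d occurrences at track edges, "
            "%d with ambiguous bases", n_skipped, n_ambiguous,
        )
    return {idx: sums[idx] / counts[idx] for idx in sums}


def motif_enrichment(
    scores: dict[int, float],
    pattern: MotifPattern | str,
    k: int = 7,
) -> float:
    """Relative binding score of a motif: mean score of pattern-matching
    k-mer classes divided by the mean score of all observed classes."""
    if not scores:
        raise ValueError("empty k-mer score map")
    matching = [
        s for idx, s in scores.items()
        if pattern_in_kmer(kmer_from_index(idx, k), pattern)
    ]
    if not matching:
        pat = pattern.pattern if isinstance(pattern, MotifPattern) else pattern
        raise ValueError(f"no scored {k}-mer matches pattern {pat!r}")
    return float(np.mean(matching) / np.mean(list(scores.values())))


def matching_index_count(
    scores: dict[int, float], pattern: MotifPattern | str, k: int = 7
) -> int:
    """Number of scored canonical k-mer classes matching the pattern."""
    return sum(
        1 for idx in scores
        if pattern_in_kmer(kmer_from_index(idx, k), pattern)
    )


# ---------------------------------------------------------------------------
# Promoter-level TF counting


def promoter_zscore_tf_count(
    per_promoter_signal: pd.DataFrame,
    promoter,
    z_threshold: float = 3.0,
) -> int:
    """Count TFs whose z-scored promoter signal exceeds the threshold.

    Each TF column is z-scored across promoters (population standard
    deviation); zero-variance columns are excluded with a warning. The
    comparison is strict (z > threshold).
    """
    df = per_promoter_signal.astype(float)
    std = df.std(axis=0, ddof=0)
    dead = std[std == 0].index
    if len(dead):
        warnings.warn(
            f"z-score undefined for zero-variance TF columns: {list(dead)}",
            stacklevel=2,
        )
        df = df.drop(columns=dead)
        std = std.drop(index=dead)
    if df.shape[1] == 0:
        return 0
    z = (df - df.mean(axis=0)) / std
    return int((z.loc[promoter] > z_threshold).sum())


def all_kmer_class_count(k: int = 7) -> int:
    """Number of distinct canonical classes over all 4^k k-mers (brute force)."""
    return len({
        canonical_kmer_index("".join(p), k)
        for p in itertools.product(BASES, repeat=k)
    })
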