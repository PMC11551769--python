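"""Motif-interaction statistics.

Whether nearby motifs cooperate is scored against an independence null:
if motif A alone yields occupancy OccA and motif B alone OccB (each
measured against the both-mutated reference, within a fixed state of all
other motifs — a *context*), independent binding predicts a joint
occupancy of ``1 - (1 - OccA)(1 - OccB)``. The cooperativity score of a
pair is the mean over all 2^(n-2) contexts of observed minus expected
joint occupancy: positive scores indicate cooperation, negative ones
inhibition.

The same depletion contrast underlies the recruitment statistic (effect
of a non-canonical motif with all of the tested TF's own motifs mutated)
and the self-motif-dependent region occupancy (all self motifs intact vs
all mutated, averaged over the states of the remaining motifs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .library import MotifSite
from .occupancy import NormalizedTable, occupancy_from_depletion


def expected_pair_occupancy(occ_a, occ_b):
    """Joint occupancy of two motifs under independent binding:
    ``1 - (1 - OccA) * (1 - OccB)``."""
    a = np.asarray(occ_a, dtype=float)
    b = np.asarray(occ_b, dtype=float)
    out = 1.0 - (1.0 - a) * (1.0 - b)
    if out.ndim == 0:
        return float(out)
    return out


def motif_pair_distance(site_a: MotifSite, site_b: MotifSite) -> int:
    """Gap between two motif spans in bp; 0 means the second motif starts
    one base pair after the end of the first."""
    first, second = sorted([site_a, site_b], key=lambda s: s.start)
    return max(second.start - first.end, 0)


def context_occupancy(
    norm: NormalizedTable,
    library_id: str,
    condition: tuple,
    target_keys: set[str],
    reference_keys: set[str],
) -> float:
    """Occupancy from the depletion contrast of two key sets.

    Delta values are averaged in log space within each set (the sets are
    typically all remaining-motif states compatible with a constraint),
    then converted: ``1 - 2^(mean Delta_target - mean Delta_reference)``.
    """
    if not target_keys or not reference_keys:
        raise ValueError("key sets must be non-empty")
    if set(target_keys) & set(reference_keys):
        raise ValueError("target and reference key sets must be disjoint")
    delta = norm.condition_delta(library_id, condition)
    missing = (set(target_keys) | set(reference_keys)) - set(delta.index)
    if missing:
        raise KeyError(f"keys missing from table: {sorted(missing)}")
    mt = float(delta.loc[sorted(target_keys)].mean())
    mr = float(delta.loc[sorted(reference_keys)].mean())
    return occupancy_from_depletion(mt, mr)


def _keys_with(n: int, fixed: dict[int, str], free: list[int]) -> list[str]:
    """All keys with given bit values at ``fixed`` positions, enumerating
    the ``free`` positions."""
    keys = []
    for bits in itertools.product("01", repeat=len(free)):
        key = ["?"] * n
        for pos, bit in fixed.items():
            key[pos] = bit
        for pos, bit in zip(free, bits):
            key[pos] = bit
        keys.append("".join(key))
    return keys


@dataclass
class PairInteraction:
    """Cooperativity of one motif pair under one condition."""

    library_id: str
    pair: tuple[int, int]
    condition: tuple
    contexts: pd.DataFrame  # context, occ_a, occ_b, observed, expected
    score: float
    sem: float
    distance: int | None = None

    @property
    def n_contexts(self) -> int:
        return len(self.contexts)


def cooperativity_score(
    norm: NormalizedTable,
    library_id: str,
    condition: tuple,
    pair: tuple[int, int],
    sites: list[MotifSite] | None = None,
) -> PairInteraction:
    """Score one motif pair against the independence null.

    For every context (state of the other n-2 motifs) the four keys
    varying only the pair are contrasted against the both-mutated key:
    single-motif occupancies give the expectation
    ``1 - (1-OccA)(1-OccB)``; the score is the unweighted mean of
    observed - expected over contexts, with its SEM. Negative
    (noise-driven) marginals are propagated unclipped and flagged, since
    there the expectation is no longer an upper bound for either margin.
    """
    delta = norm.condition_delta(library_id, condition)
    n = len(delta.index[0])
    if n < 2:
        raise ValueError("cooperativity needs a library with >= 2 sites")
    a, b = pair
    if a == b or not (0 <= a < n and 0 <= b < n):
        raise ValueError(f"invalid site pair {pair} for n={n}")
    others = [i for i in range(n) if i not in (a, b)]
    rows = []
    for bits in itertools.product("01", repeat=len(others)):
        ctx = dict(zip(others, bits))

        def key(bit_a: str, bit_b: str) -> str:
            k = ["?"] * n
            k[a], k[b] = bit_a, bit_b
            for pos, bit in ctx.items():
                k[pos] = bit
            return "".join(k)

        d00 = delta.loc[key("0", "0")]
        occ_a = occupancy_from_depletion(delta.loc[key("1", "0")], d00)
        occ_b = occupancy_from_depletion(delta.loc[key("0", "1")], d00)
        observed = occupancy_from_depletion(delta.loc[key("1", "1")], d00)
        expected = expected_pair_occupancy(occ_a, occ_b)
        rows.append({
            "context": "".join(bits),
            "occ_a": occ_a,
            "occ_b": occ_b,
            "observed": observed,
            "expected": expected,
            "negative_marginal": bool(occ_a < 0 or occ_b < 0),
        })
    contexts = pd.DataFrame(rows)
    diff = contexts["observed"] - contexts["expected"]
    score = float(diff.mean())
    sem = float(stats.sem(diff, ddof=1)) if len(diff) > 1 else float("nan")
    distance = (
        motif_pair_distance(sites[a], sites[b]) if sites is not None else None
    )
    return PairInteraction(
        library_id=library_id, pair=(min(a, b), max(a, b)),
        condition=condition, contexts=contexts, score=score, sem=sem,
        distance=distance,
    )


def all_pair_scores(
    norm: NormalizedTable,
    library_id: str,
    condition: tuple,
    sites: list[MotifSite] | None = None,
    call_threshold: float = 0.1,
) -> pd.DataFrame:
    """Cooperativity scores for every motif pair of a library.

    ``called`` marks pairs whose |score| exceeds the reporting cutoff
    (default 10%, the scale above which pairs are called cooperative or
    inhibitory).
    """
    delta = norm.condition_delta(library_id, condition)
    n = len(delta.index[0])
    rows = []
    for a, b in itertools.combinations(range(n), 2):
        pi = cooperativity_score(norm, library_id, condition, (a, b), sites)
        rows.append({
            "library_id": library_id,
            "site_a": a,
            "site_b": b,
            "distance": pi.distance,
            "n_contexts": pi.n_contexts,
            "score": pi.score,
            "sem": pi.sem,
            "observed_mean": float(pi.contexts["observed"].mean()),
            "expected_mean": float(pi.contexts["expected"].mean()),
            "called": abs(pi.score) > call_threshold,
        })
    return pd.DataFrame(rows)


def _canonical_indices(sites: list[MotifSite], tf_name: str) -> list[int]:
    idx = [i for i, s in enumerate(sites) if s.is_canonical_for(tf_name)]
    if not idx:
        raise ValueError(f"no canonical sites annotated for {tf_name}")
    return idx


@dataclass
class RecruitmentRecord:
    """Occupancy contribution of a non-canonical motif, measured with all
    of the tested TF's own motifs mutated."""

    library_id: str
    site_index: int
    tested_tf: str
    occupancy: float


def recruitment_score(
    norm: NormalizedTable,
    library_id: str,
    condition: tuple,
    tested_tf: str,
    non_canonical_site: int,
    sites: list[MotifSite],
) -> RecruitmentRecord:
    """Non-cooperative recruitment by one non-canonical motif.

    Contrast: sequences with the non-canonical motif intact and every
    self motif mutated, against sequences with both the non-canonical
    motif and the self motifs mutated; the remaining sites are averaged
    over all their states in log space.
    """
    self_idx = _canonical_indices(sites, tested_tf)
    if non_canonical_site in self_idx:
        raise ValueError(
            f"site {non_canonical_site} is canonical for {tested_tf}"
        )
    n = len(sites)
    free = [
        i for i in range(n) if i != non_canonical_site and i not in self_idx
    ]
    fixed_mut = {i: "0" for i in self_idx}
    target = _keys_with(n, {**fixed_mut, non_canonical_site: "1"}, free)
    reference = _keys_with(n, {**fixed_mut, non_canonical_site: "0"}, free)
    occ = context_occupancy(
        norm, library_id, condition, set(target), set(reference)
    )
    return RecruitmentRecord(
        library_id=library_id, site_index=non_canonical_site,
        tested_tf=tested_tf, occupancy=occ,
    )


@dataclass
class SelfMotifOccupancy:
    """Occupancy attributable to all of a TF's own motifs jointly."""

    library_id: str
    tested_tf: str
    occupancy: float


def self_motif_region_occupancy(
    norm: NormalizedTable,
    library_id: str,
    condition: tuple,
    tested_tf: str,
    sites: list[MotifSite],
) -> SelfMotifOccupancy:
    """Contrast all-self-motifs-intact vs all-self-motifs-mutated,
    averaged over the states of the remaining motifs."""
    self_idx = _canonical_indices(sites, tested_tf)
    n = len(sites)
    free = [i for i in range(n) if i not in self_idx]
    target = _keys_with(n, {i: "1" for i in self_idx}, free)
    reference = _keys_with(n, {i: "0" for i in self_idx}, free)
    occ = context_occupancy(
        norm, library_id, condition, set(target), set(reference)
    )
    return SelfMotifOccupancy(
        library_id=library_id, tested_tf=tested_tf, occupancy=occ
    )


def tf_pair_motif_correlation(
    occ_tf1: pd.Series,
    occ_tf2: pd.Series,
    r_threshold: float = 0.4,
) -> tuple[float, bool]:
    """Pearson correlation of two TFs' per-variant occupancies on the
    same library; pairs with r above the threshold are flagged as having
    similar motif effects.
    """
    shared = occ_tf1.index.intersection(occ_tf2.index)
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 shared variants, have {len(shared)}"
        )
    r, _ = stats.pearsonr(
        occ_tf1.loc[shared].astype(float), occ_tf2.loc[shared].astype(float)
    )
    return float(r), bool(r > r_threshold)
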