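"""From raw variant counts to TF occupancy.

The normalization chain follows the assay's readout logic: counts are
depth-normalized to reads-per-million, technical replicates are averaged
on the per-million scale, values are log2-transformed, each
MNase-activated sample is normalized to its paired pre-activation (time
0) sample within the same biological replicate, and biological
replicates are averaged in log space. The resulting per-variant log2
depletion Delta is converted to an occupancy fraction against the fully
mutated variant:

    occupancy = 1 - 0.5^-(Delta_variant - Delta_fully_mutated)
              = 1 - 2^(Delta_variant - Delta_fully_mutated)

which is 0 when a variant is depleted exactly as much as the motif-free
reference and approaches 1 under complete cleavage. Occupancy estimates
are a lower bound on the fraction of cells in which the sequence is
bound, since cleavage of a bound plasmid may be incomplete.

Nucleosome (histone-MNase) occupancies are additionally rescaled by a
genomic anchor: the 99th percentile of library-sized (164 bp) MNase-seq
window sums over promoters defines 100% nucleosome occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import PromoterSet, SignalTrack
from .reads import SampleMeta, VariantCountTable

PER_MILLION = 1e6


@dataclass
class NormalizedTable:
    """Per-variant log2 depletion values.

    ``delta_reps`` rows are (library_id, key); columns are a MultiIndex
    (tf_name, timepoint, bio_rep) of per-biological-replicate Delta
    values (activated minus paired time-0, in log2 per-million units).
    """

    delta_reps: pd.DataFrame

    def __post_init__(self):
        self.delta_reps = self.delta_reps.sort_index()
        self.delta_reps = self.delta_reps.sort_index(axis=1)

    @property
    def conditions(self) -> list[tuple]:
        """(tf_name, timepoint) pairs present in the table."""
        return sorted({(tf, tp) for tf, tp, _ in self.delta_reps.columns})

    @property
    def delta(self) -> pd.DataFrame:
        """Bio-replicate-averaged Delta, columns (tf_name, timepoint)."""
        return self.delta_reps.T.groupby(level=[0, 1]).mean().T

    @property
    def sem(self) -> pd.DataFrame:
        """Standard error of Delta across biological replicates."""
        return self.delta_reps.T.groupby(level=[0, 1]).sem(ddof=1).T

    @property
    def n_bio(self) -> pd.Series:
        return self.delta_reps.T.groupby(level=[0, 1]).size()

    def condition_delta(self, library_id: str, condition: tuple) -> pd.Series:
        """Mean Delta for one library under one (tf, timepoint), by key."""
        tf, tp = condition
        cols = [c for c in self.delta_reps.columns if c[0] == tf and c[1] == tp]
        if not cols:
            raise KeyError(f"condition {condition} not in table")
        sub = self.delta_reps.loc[library_id, cols]
        return sub.mean(axis=1)


def normalize_counts(
    table: VariantCountTable,
    samples: list[SampleMeta],
    pseudocount: float = 1.0,
) -> NormalizedTable:
    """Run the full count-normalization chain.

    Order of operations: reads-per-million within each sample (over
    assigned variant reads), technical-replicate mean on the per-million
    scale, ``log2(x + pseudocount)``, activated minus the paired time-0
    sample of the same biological replicate. Missing time-0 pairs are an
    error; zero-depth samples must be removed upstream (QC).
    """
    meta = {s.sample_id: s for s in samples}
    missing = [c for c in table.sample_ids if c not in meta]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    totals = table.assigned_totals()
    if (totals == 0).any():
        dead = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero assigned reads: {dead}")
    pm = table.counts * PER_MILLION / totals

    # technical-replicate mean per (tf, timepoint, bio_rep), columns in
    # sorted sample order so results are invariant to input ordering
    groups: dict[tuple, list[str]] = {}
    for sid in sorted(table.sample_ids):
        s = meta[sid]
        groups.setdefault((s.tf_name, s.timepoint, s.bio_rep), []).append(sid)
    tech_mean = pd.DataFrame(
        {g: pm[cols].mean(axis=1) for g, cols in sorted(groups.items())}
    )
    tech_mean.columns = pd.MultiIndex.from_tuples(
        tech_mean.columns, names=["tf_name", "timepoint", "bio_rep"]
    )
    logged = np.log2(tech_mean + pseudocount)

    fm_zero = (
        tech_mean.loc[[i for i in tech_mean.index if set(i[1]) == {"0"}]] == 0
    )
    if fm_zero.to_numpy().any():
        warnings.warn(
            "fully mutated reference variant has zero counts in at least "
            "one sample group; occupancies will lean on the pseudocount",
            stacklevel=2,
        )

    delta_cols: dict[tuple, pd.Series] = {}
    for (tf, tp, bio) in logged.columns:
        if tp == 0:
            continue
        ref = (tf, 0, bio)
        if ref not in logged.columns:
            raise ValueError(
                f"no paired time-0 sample for (tf={tf}, timepoint={tp}, "
                f"bio_rep={bio})"
            )
        delta_cols[(tf, tp, bio)] = logged[(tf, tp, bio)] - logged[ref]
    if not delta_cols:
        raise ValueError("no activated samples to normalize")
    delta_reps = pd.DataFrame(dict(sorted(delta_cols.items())))
    delta_reps.columns = pd.MultiIndex.from_tuples(
        delta_reps.columns, names=["tf_name", "timepoint", "bio_rep"]
    )
    return NormalizedTable(delta_reps=delta_reps)


def occupancy_from_depletion(delta_variant, delta_fully_mutated):
    """Occupancy fraction from log2 depletion contrast:
    ``1 - 2^(Delta_variant - Delta_fm)``.

    Strictly decreasing in the contrast; 0 exactly when the variant is
    depleted as much as the fully mutated reference; negative when it is
    *less* depleted (reported as-is by default, see ``clip`` options in
    :func:`occupancy_table`).
    """
    diff = np.asarray(delta_variant, dtype=float) - np.asarray(
        delta_fully_mutated, dtype=float
    )
    out = 1.0 - np.exp2(diff)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class OccupancyTable:
    """Per-variant occupancy fractions with SEM across biological reps."""

    occupancy: pd.DataFrame   # rows (library_id, key), cols (tf, timepoint)
    sem: pd.DataFrame
    n_bio: pd.Series


def occupancy_table(norm: NormalizedTable, clip: bool = False) -> OccupancyTable:
    """Convert a NormalizedTable to occupancies against each library's
    fully mutated variant.

    The point estimate uses the bio-replicate-averaged Delta; the SEM is
    taken across per-replicate occupancies. ``clip`` truncates negative
    values to 0 (and values to at most 1, which the formula guarantees
    anyway).
    """
    occ_reps = {}
    for col in norm.delta_reps.columns:
        series = norm.delta_reps[col]
        parts = []
        for lib in series.index.get_level_values(0).unique():
            sub = series.loc[lib]
            fm = "0" * len(sub.index[0])
            vals = occupancy_from_depletion(sub.to_numpy(), sub.loc[fm])
            parts.append(pd.Series(
                vals,
                index=pd.MultiIndex.from_product(
                    [[lib], sub.index], names=["library_id", "key"]
                ),
            ))
        occ_reps[col] = pd.concat(parts)
    occ_reps = pd.DataFrame(occ_reps)
    occ_reps.columns = pd.MultiIndex.from_tuples(
        occ_reps.columns, names=["tf_name", "timepoint", "bio_rep"]
    )

    delta = norm.delta
    occ = {}
    for col in delta.columns:
        series = delta[col]
        parts = []
        for lib in series.index.get_level_values(0).unique():
            sub = series.loc[lib]
            fm = "0" * len(sub.index[0])
            vals = occupancy_from_depletion(sub.to_numpy(), sub.loc[fm])
            parts.append(pd.Series(
                vals,
                index=pd.MultiIndex.from_product(
                    [[lib], sub.index], names=["library_id", "key"]
                ),
            ))
        occ[col] = pd.concat(parts)
    occ = pd.DataFrame(occ)
    occ.columns = pd.MultiIndex.from_tuples(
        occ.columns, names=["tf_name", "timepoint"]
    )
    if clip:
        occ = occ.clip(lower=0.0, upper=1.0)
    sem = occ_reps.T.groupby(level=[0, 1]).sem(ddof=1).T
    n_bio = occ_reps.T.groupby(level=[0, 1]).size()
    return OccupancyTable(occupancy=occ, sem=sem, n_bio=n_bio)


# ---------------------------------------------------------------------------
# Nucleosome-occupancy rescaling against a genomic MNase-seq anchor


@dataclass
class NucleosomeAnchor:
    """The 100%-nucleosome-occupancy reference.

    ``anchor_value`` is the 99th percentile of library-sized window sums
    of MNase-seq signal over promoters.
    """

    anchor_value: float
    window: int = 164

    def __post_init__(self):
        if self.anchor_value <= 0:
            raise ValueError("anchor value must be positive")

    def region_occupancy(
        self, track: SignalTrack, start: int, end: int
    ) -> float:
        """Genomic nucleosome occupancy of a region: its summed signal
        over the anchor, capped at 1."""
        return min(track.region_sum(start, end) / self.anchor_value, 1.0)


def nucleosome_anchor(
    track: SignalTrack,
    promoters: PromoterSet,
    window: int = 164,
    step: int = 10,
) -> NucleosomeAnchor:
    """Anchor from the distribution of ``window``-bp sums at ``step``-bp
    offsets across all promoters (99th percentile, linear interpolation).

    Promoters shorter than the window are skipped with a warning.
    """
    cum = np.concatenate([[0.0], np.cumsum(track.values)])
    sums: list[float] = []
    for chrom, pstart, pend, name in promoters:
        if chrom != track.chrom:
            continue
        lo = max(pstart, track.start)
        hi = min(pend, track.end)
        if hi - lo < window:
            warnings.warn(
                f"promoter {name or f'{chrom}:{pstart}-{pend}'} shorter than "
                f"the {window} bp window; skipped", stacklevel=2,
            )
            continue
        for s in range(lo, hi - window + 1, step):
            i = s - track.start
            sums.append(float(cum[i + window] - cum[i]))
    if not sums:
        raise ValueError("no promoter windows available for the anchor")
    return NucleosomeAnchor(
        anchor_value=float(np.percentile(sums, 99)), window=window
    )


def histone_occupancy(
    delta_vs_wt, library_genomic_occupancy: float, literal: bool = False
) -> float:
    """Nucleosome occupancy of a variant, rescaled to the genome.

    Default reading: fold-change relative to the wild-type variant times
    the library's genomic anchor occupancy, ``2^Delta * occ`` — a variant
    behaving like wild type gets exactly the genomic occupancy. The
    literal exponent form ``0.5^(Delta * occ)`` is available for
    comparison via ``literal=True``.
    """
    d = np.asarray(delta_vs_wt, dtype=float)
    if literal:
        out = np.float_power(0.5, d * library_genomic_occupancy)
    else:
        out = np.exp2(d) * library_genomic_occupancy
    if out.ndim == 0:
        return float(out)
    return out
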