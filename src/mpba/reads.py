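"""Assignment of amplicon reads to library variants.

Each read (forward orientation, primers already removed) is matched
against every library design: the bases at the design's variable
positions must equal either the wild-type or the mutant base (yielding
the variant key), the constant scaffold may carry at most a small
mismatch budget, and the last few bases must align exactly at the
expected 3' offset. A read whose 3' anchor is found at a shifted offset
is length-shifted, i.e. carries an indel, and is filtered; a read whose
scaffold matches but whose variable-position base is neither the
wild-type nor the mutant base belongs to no library variant and is
discarded as unassigned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .library import LibraryDesign
from .motifs import reverse_complement

ASSIGNED = "assigned"
CONTROL = "control"
UNASSIGNED = "unassigned"
FILTERED_INDEL = "filtered_indel"
CATEGORIES = (ASSIGNED, CONTROL, UNASSIGNED, FILTERED_INDEL)


@dataclass
class SampleMeta:
    """One sequencing sample of the assay.

    ``timepoint`` is the MNase activation time in seconds; 0 denotes the
    pre-activation reference. ``bio_rep`` identifies the biological
    replicate (independent culture) and ``tech_rep`` the technical
    replicate within it.
    """

    sample_id: str
    tf_name: str
    timepoint: float
    bio_rep: int = 1
    tech_rep: int = 1
    library_ids: list[str] | None = None

    def __post_init__(self):
        if self.timepoint < 0:
            raise ValueError("timepoint must be >= 0")

    @property
    def is_reference(self) -> bool:
        return self.timepoint == 0


@dataclass
class VariantCountTable:
    """Read counts per (library, variant key) per sample.

    ``counts`` rows are a (library_id, key) MultiIndex covering every
    library's full 2^n key set (zero-filled); columns are sample ids.
    ``control_counts`` holds the per-sample count of the poorly bound
    spike-in control sequence, and ``stats`` the per-sample assignment
    category tallies.
    """

    counts: pd.DataFrame
    control_counts: pd.Series = None
    stats: pd.DataFrame = None

    def __post_init__(self):
        if not isinstance(self.counts.index, pd.MultiIndex):
            raise ValueError("counts index must be (library_id, key)")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.sort_index()
        self.counts = self.counts[sorted(self.counts.columns)]
        if self.control_counts is None:
            self.control_counts = pd.Series(
                0, index=self.counts.columns, dtype=int
            )
        else:
            self.control_counts = (
                self.control_counts.reindex(self.counts.columns)
                .fillna(0).astype(int)
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def assigned_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


class Assignment(NamedTuple):
    category: str
    library_id: str | None = None
    key: str | None = None


def _match_design(
    read: str,
    design: LibraryDesign,
    max_scaffold_mismatch: int,
    anchor_len: int,
    max_anchor_shift: int,
) -> tuple[Assignment | None, bool]:
    """Match one read against one design.

    Returns (assignment-or-None, indel_candidate). The assignment carries
    category ASSIGNED or UNASSIGNED when the scaffold matched; None means
    the read does not belong to this design at all.
    """
    seq = design.sequence
    L = len(seq)
    var_positions = {s.variable_position for s in design.sites}
    anchor_start = L - anchor_len
    anchor_const = [
        p for p in range(anchor_start, L) if p not in var_positions
    ]

    def anchor_at(shift: int) -> bool:
        return all(
            0 <= p + shift < len(read) and read[p + shift] == seq[p]
            for p in anchor_const
        )

    in_frame = len(read) >= L and anchor_at(0)
    if in_frame:
        mism = 0
        for p in range(anchor_start):
            if p in var_positions:
                continue
            if read[p] != seq[p]:
                mism += 1
                if mism > max_scaffold_mismatch:
                    break
        if mism <= max_scaffold_mismatch:
            bits = []
            for site in design.sites:
                base = read[site.variable_position]
                if base == site.wt_base:
                    bits.append("1")
                elif base == site.mut_base:
                    bits.append("0")
                else:
                    return Assignment(UNASSIGNED), False
            return Assignment(ASSIGNED, design.region_id, "".join(bits)), False
    # 3' anchor at a shifted offset: a length-shifted (indel) read.
    for shift in range(1, max_anchor_shift + 1):
        for signed in (-shift, shift):
            if anchor_at(signed):
                return None, True
    return None, False


def assign_read(
    read: str,
    designs: list[LibraryDesign],
    control: str | None = None,
    max_scaffold_mismatch: int = 2,
    anchor_len: int = 6,
    max_anchor_shift: int = 3,
    search_revcomp: bool = False,
) -> Assignment:
    """Assign one read to a (library, variant key), the control, or a
    discard category (``unassigned`` / ``filtered_indel``)."""
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    orientations = [read]
    if search_revcomp:
        orientations.append(reverse_complement(read))
    indel_candidate = False
    unassigned_hit = False
    for oriented in orientations:
        for design in designs:
            result, indel = _match_design(
                oriented, design, max_scaffold_mismatch, anchor_len,
                max_anchor_shift,
            )
            indel_candidate = indel_candidate or indel
            if result is not None:
                if result.category == ASSIGNED:
                    return result
                unassigned_hit = True
        if control is not None and len(oriented) >= len(control):
            mism = sum(
                a != b for a, b in zip(oriented[:len(control)], control)
            )
            if mism <= max_scaffold_mismatch:
                return Assignment(CONTROL)
    if unassigned_hit:
        return Assignment(UNASSIGNED)
    if indel_candidate:
        return Assignment(FILTERED_INDEL)
    return Assignment(UNASSIGNED)


def _check_scaffold_collisions(designs: list[LibraryDesign]) -> None:
    seen: dict[str, str] = {}
    for d in designs:
        for key, seq in d.variants.items():
            if seq in seen and seen[seq] != d.region_id:
                warnings.warn(
                    f"designs {seen[seq]} and {d.region_id} share variant "
                    "sequences; such reads are ambiguous", stacklevel=3,
                )
                return
            seen[seq] = d.region_id


def count_reads(
    reads: Iterable[str],
    designs: list[LibraryDesign],
    control: str | None = None,
    sample_id: str = "sample",
    **assign_kwargs,
) -> VariantCountTable:
    """Count a single sample's read stream over all designs.

    The returned table covers every key of every design (zero-filled) and
    records the control count and the per-category assignment tallies
    (which sum to the total number of reads).
    """
    _check_scaffold_collisions(designs)
    index = pd.MultiIndex.from_tuples(
        [(d.region_id, k) for d in designs for k in d.keys],
        names=["library_id", "key"],
    )
    counts = pd.Series(0, index=index, dtype=int)
    tallies = {c: 0 for c in CATEGORIES}
    for read in reads:
        read = str(getattr(read, "seq", read))
        a = assign_read(read, designs, control=control, **assign_kwargs)
        tallies[a.category] += 1
        if a.category == ASSIGNED:
            counts.loc[(a.library_id, a.key)] += 1
    table = VariantCountTable(
        counts=counts.to_frame(sample_id),
        control_counts=pd.Series(
            {sample_id: tallies[CONTROL]}, dtype=int
        ),
        stats=pd.DataFrame({sample_id: tallies}).T,
    )
    return table


def combine_counts(tables: list[VariantCountTable]) -> VariantCountTable:
    """Merge single-sample tables into one multi-sample table."""
    if not tables:
        raise ValueError("no tables to combine")
    counts = pd.concat([t.counts for t in tables], axis=1).fillna(0).astype(int)
    control = pd.concat([t.control_counts for t in tables])
    stats = pd.concat(
        [t.stats for t in tables if t.stats is not None]
    ) if any(t.stats is not None for t in tables) else None
    return VariantCountTable(counts=counts, control_counts=control, stats=stats)


def qc_filter_samples(
    table: VariantCountTable,
    samples: list[SampleMeta],
    min_reads: int = 50_000,
    min_tech_corr: float = 0.7,
) -> tuple[VariantCountTable, dict[str, str]]:
    """Drop shallow or discordant samples.

    A sample is dropped when its assigned total is below ``min_reads``, or
    when the Pearson correlation of log2(count+1) with *every* sibling
    technical replicate (same TF, timepoint and biological replicate) is
    below ``min_tech_corr``. Returns the filtered table and a report of
    dropped samples with reasons.
    """
    meta = {s.sample_id: s for s in samples}
    missing = [c for c in table.sample_ids if c not in meta]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    totals = table.assigned_totals()
    report: dict[str, str] = {}
    for sid in table.sample_ids:
        if totals[sid] < min_reads:
            report[sid] = f"low depth ({totals[sid]} < {min_reads})"
    log_counts = np.log2(table.counts + 1)
    for sid in table.sample_ids:
        if sid in report:
            continue
        s = meta[sid]
        siblings = [
            c for c in table.sample_ids
            if c != sid and c not in report
            and meta[c].tf_name == s.tf_name
            and meta[c].timepoint == s.timepoint
            and meta[c].bio_rep == s.bio_rep
        ]
        if not siblings:
            continue
        best = max(
            float(np.corrcoef(log_counts[sid], log_counts[c])[0, 1])
            for c in siblings
        )
        if math.isnan(best) or best < min_tech_corr:
            report[sid] = (
                f"low technical-replicate correlation "
                f"(best r = {best:.3f} < {min_tech_corr})"
            )
    keep = [c for c in table.sample_ids if c not in report]
    if not keep:
        raise ValueError(f"all samples failed QC: {report}")
    filtered = VariantCountTable(
        counts=table.counts[keep],
        control_counts=table.control_counts[keep],
        stats=table.stats.loc[keep] if table.stats is not None else None,
    )
    return filtered, report
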