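"""Readers and writers for the standard file formats around the pipeline.

Tabular data goes through pandas; FASTA through Biopython; PWMs are read
either as plain 4-column (A, C, G, T) probability tables or minimal MEME
records via Bio.motifs. Count tables round-trip as TSV with the control
sequence stored as a reserved ``_control_`` row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .motifs import PWM, PromoterSet, SignalTrack
from .occupancy import NormalizedTable, OccupancyTable
from .reads import SampleMeta, VariantCountTable
from .simulate import CONTROL_ID


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {record id: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def read_pwm(path: str | Path, tf_name: str | None = None) -> PWM:
    """Read a PWM from plain 4-column text (A C G T per row = position)
    or minimal MEME format (first motif)."""
    path = Path(path)
    head = path.read_text()
    if "MEME version" in head:
        with open(path) as fh:
            records = bio_motifs.parse(fh, "minimal")
        motif = records[0]
        probs = np.array([list(motif.pwm[b]) for b in "ACGT"])
        return PWM(tf_name or motif.name or path.stem, probs)
    table = np.loadtxt(path)
    if table.ndim == 1:
        table = table.reshape(1, -1)
    if table.shape[1] != 4:
        raise ValueError(
            f"{path}: expected 4 columns (A, C, G, T), got {table.shape[1]}"
        )
    return PWM(tf_name or path.stem, table.T)


def read_bedgraph(path: str | Path, sequence: str | None = None) -> SignalTrack:
    """bedGraph -> per-base SignalTrack (single chromosome; gaps filled
    with 0 between the first and last covered base)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    df = df[df["chrom"] != "track"]
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(
            f"{path}: expected a single chromosome, found {list(chroms)}"
        )
    start = int(df["start"].min())
    end = int(df["end"].max())
    values = np.zeros(end - start)
    for _, row in df.iterrows():
        values[int(row["start"]) - start:int(row["end"]) - start] = row["value"]
    return SignalTrack(
        chrom=str(chroms[0]), start=start, values=values, sequence=sequence
    )


def read_bed(path: str | Path) -> PromoterSet:
    """BED3/BED4 -> PromoterSet."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            intervals.append(
                (f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else None)
            )
    return PromoterSet(intervals)


# ---------------------------------------------------------------------------
# Sample sheets

_SHEET_COLUMNS = [
    "sample_id", "tf_name", "timepoint", "bio_rep", "tech_rep", "library_ids"
]


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SHEET_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    samples = []
    for _, row in df.iterrows():
        libs = None
        if "library_ids" in df.columns and pd.notna(row.get("library_ids")):
            libs = str(row["library_ids"]).split(",")
        samples.append(SampleMeta(
            sample_id=str(row["sample_id"]), tf_name=str(row["tf_name"]),
            timepoint=float(row["timepoint"]), bio_rep=int(row["bio_rep"]),
            tech_rep=int(row["tech_rep"]), library_ids=libs,
        ))
    return samples


def write_sample_sheet(samples: list[SampleMeta], path: str | Path) -> None:
    rows = [{
        "sample_id": s.sample_id, "tf_name": s.tf_name,
        "timepoint": s.timepoint, "bio_rep": s.bio_rep,
        "tech_rep": s.tech_rep,
        "library_ids": ",".join(s.library_ids) if s.library_ids else "",
    } for s in samples]
    pd.DataFrame(rows, columns=_SHEET_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Count / normalized / occupancy tables


def write_counts(table: VariantCountTable, path: str | Path) -> None:
    """Counts TSV with (library_id, key) rows; the control counts are a
    reserved ``_control_`` row."""
    out = table.counts.copy()
    out.loc[(CONTROL_ID, "-"), :] = table.control_counts
    out.astype(int).to_csv(path, sep="\t")


def read_counts(path: str | Path) -> VariantCountTable:
    df = pd.read_csv(
        path, sep="\t", index_col=[0, 1], dtype={"key": str}
    )
    df.index = pd.MultiIndex.from_tuples(
        [(lib, str(key)) for lib, key in df.index],
        names=["library_id", "key"],
    )
    if CONTROL_ID in df.index.get_level_values(0):
        control = df.loc[CONTROL_ID].iloc[0].astype(int)
        df = df.drop(index=CONTROL_ID, level=0)
    else:
        control = None
    return VariantCountTable(counts=df.astype(int), control_counts=control)


def write_normalized(norm: NormalizedTable, path: str | Path) -> None:
    flat = norm.delta_reps.copy()
    flat.columns = [
        f"{tf}|{tp:g}|{bio}" for tf, tp, bio in flat.columns
    ]
    flat.to_csv(path, sep="\t")


def read_normalized(path: str | Path) -> NormalizedTable:
    df = pd.read_csv(path, sep="\t", index_col=[0, 1], dtype={"key": str})
    df.index = pd.MultiIndex.from_tuples(
        [(lib, str(key)) for lib, key in df.index],
        names=["library_id", "key"],
    )
    cols = []
    for c in df.columns:
        tf, tp, bio = c.rsplit("|", 2)
        cols.append((tf, float(tp), int(bio)))
    df.columns = pd.MultiIndex.from_tuples(
        cols, names=["tf_name", "timepoint", "bio_rep"]
    )
    return NormalizedTable(delta_reps=df)


def write_occupancy(occ: OccupancyTable, path: str | Path) -> None:
    """Long-format occupancy TSV: one row per variant per condition."""
    rows = []
    for (tf, tp) in occ.occupancy.columns:
        for (lib, key), value in occ.occupancy[(tf, tp)].items():
            rows.append({
                "library_id": lib, "key": key, "tf_name": tf,
                "timepoint": tp, "occupancy": value,
                "sem": occ.sem[(tf, tp)].loc[(lib, key)],
                "n_bio_reps": int(occ.n_bio[(tf, tp)]),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
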