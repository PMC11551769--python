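"""Combinatorial motif-mutation library design.

A regulatory region carrying n TF-bound motifs is expanded into all 2^n
variants that leave each motif intact or carry a single point mutation at
its variable position (the motif's highest-information-content base, whose
mutation is expected to abolish binding). Variant identity is a bit string
in 5'->3' order of the variable positions: bit i = 1 means site i intact,
0 means mutated; the all-ones key is the wild type and the all-zeros key
is the fully mutated reference lacking all motifs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .motifs import BASES, PWM, central_variable_position

#: Region length used throughout the assay design; other lengths only warn.
NOMINAL_REGION_LENGTH = 164

_PURINES = frozenset("AG")


def _is_transversion(a: str, b: str) -> bool:
    return (a in _PURINES) != (b in _PURINES)


@dataclass
class MotifSite:
    """One annotated motif with its single variable (mutable) position."""

    tf_name: str
    start: int
    end: int
    variable_position: int
    wt_base: str
    mut_base: str
    strand: str = "+"
    canonical_for: str | None = None

    def __post_init__(self):
        self.wt_base = self.wt_base.upper()
        self.mut_base = self.mut_base.upper()
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid motif span [{self.start}, {self.end})")
        if not (self.start <= self.variable_position < self.end):
            raise ValueError(
                f"variable position {self.variable_position} outside span "
                f"[{self.start}, {self.end})"
            )
        if self.wt_base not in BASES or self.mut_base not in BASES:
            raise ValueError("wt/mut bases must be one of A, C, G, T")
        if self.wt_base == self.mut_base:
            raise ValueError("mutant base must differ from the wild-type base")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    def is_canonical_for(self, tf_name: str) -> bool:
        """A site is 'self' for a TF when explicitly marked canonical for
        it, or (absent a mark) when it carries that TF's name."""
        if self.canonical_for is not None:
            return self.canonical_for == tf_name
        return self.tf_name == tf_name


@dataclass
class LibraryDesign:
    """A region, its motif sites and the full 2^n variant set."""

    region_id: str
    sequence: str
    sites: list[MotifSite]
    variants: dict[str, str] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def wild_type_key(self) -> str:
        return "1" * self.n_sites

    @property
    def fully_mutated_key(self) -> str:
        return "0" * self.n_sites

    @property
    def keys(self) -> list[str]:
        return sorted(self.variants)


def iter_keys(n: int):
    """All length-n 0/1 keys, all-intact first (lexicographic over bits)."""
    for bits in itertools.product("10", repeat=n):
        yield "".join(bits)


def default_mutant_base(pwm_column, wt_base: str) -> str:
    """Mutant base: lowest PWM probability at the column, excluding the
    wild-type base; ties prefer a transversion, then alphabetical order."""
    candidates = [b for b in BASES if b != wt_base]
    probs = {b: float(pwm_column[i]) for i, b in enumerate(BASES)}
    lo = min(probs[b] for b in candidates)
    tied = [b for b in candidates if probs[b] <= lo + 1e-12]
    tied.sort(key=lambda b: (not _is_transversion(wt_base, b), b))
    return tied[0]


def annotate_sites(region: str, motif_hits: list[dict]) -> list[MotifSite]:
    """Resolve motif hits into fully specified sites, 5'->3'.

    Each hit is a mapping with ``tf_name``, ``start``, ``end`` and either
    an explicit ``variable_position``/``mut_base`` pair (always honored) or
    a ``pwm`` from which the variable position (highest-information
    column) and mutant base (lowest-probability base) are derived.
    Optional keys: ``strand`` (default '+'), ``canonical_for``.
    """
    region = region.upper()
    sites: list[MotifSite] = []
    for hit in motif_hits:
        tf = hit["tf_name"]
        start, end = int(hit["start"]), int(hit["end"])
        if not (0 <= start < end <= len(region)):
            raise ValueError(
                f"{tf}: motif span [{start}, {end}) outside region"
            )
        strand = hit.get("strand", "+")
        pwm: PWM | None = hit.get("pwm")
        var = hit.get("variable_position")
        if var is None:
            if pwm is None:
                raise ValueError(
                    f"{tf}: need a variable_position or a PWM to derive one"
                )
            oriented = pwm if strand == "+" else pwm.reverse_complement()
            var = central_variable_position(oriented, (start, end))
        var = int(var)
        wt = region[var]
        mut = hit.get("mut_base")
        if mut is None:
            if pwm is None:
                raise ValueError(f"{tf}: need a mut_base or a PWM to derive one")
            oriented = pwm if strand == "+" else pwm.reverse_complement()
            mut = default_mutant_base(oriented.probs[:, var - start], wt)
        sites.append(MotifSite(
            tf_name=tf, start=start, end=end, variable_position=var,
            wt_base=wt, mut_base=str(mut).upper(), strand=strand,
            canonical_for=hit.get("canonical_for"),
        ))
    positions = [s.variable_position for s in sites]
    if len(set(positions)) != len(positions):
        dup = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"motifs share variable positions {dup}")
    sites.sort(key=lambda s: s.variable_position)
    return sites


def enumerate_variants(
    region: str, sites: list[MotifSite], region_id: str = "region"
) -> LibraryDesign:
    """Expand a region and its sites into the full 2^n variant library."""
    region = region.upper()
    if len(region) != NOMINAL_REGION_LENGTH:
        warnings.warn(
            f"region length {len(region)} differs from the nominal "
            f"{NOMINAL_REGION_LENGTH} bp assay design",
            stacklevel=2,
        )
    positions = [s.variable_position for s in sites]
    if len(set(positions)) != len(positions):
        raise ValueError("sites share variable positions")
    for s in sites:
        if region[s.variable_position] != s.wt_base:
            raise ValueError(
                f"{s.tf_name}: wt base {s.wt_base} does not match region "
                f"base {region[s.variable_position]} at {s.variable_position}"
            )
    sites = sorted(sites, key=lambda s: s.variable_position)
    variants: dict[str, str] = {}
    for key in iter_keys(len(sites)):
        seq = list(region)
        for bit, site in zip(key, sites):
            if bit == "0":
                seq[site.variable_position] = site.mut_base
        variants[key] = "".join(seq)
    if len(set(variants.values())) != len(variants):
        raise ValueError("duplicate variant sequences generated")
    return LibraryDesign(
        region_id=region_id, sequence=region, sites=sites, variants=variants
    )


# ---------------------------------------------------------------------------
# Serialization (FASTA of variants + TSV site manifest)

_MANIFEST_COLUMNS = [
    "tf_name", "start", "end", "strand", "variable_position",
    "wt_base", "mut_base", "canonical_for",
]


def write_library(design: LibraryDesign, path: str | Path) -> None:
    """Write a design as ``<region_id>.fa`` (variants, headers
    ``region_id|key``) plus ``<region_id>.sites.tsv`` (site manifest, rows
    in key bit order)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / f"{design.region_id}.fa", "w") as fh:
        for key in design.keys:
            fh.write(f">{design.region_id}|{key}\n{design.variants[key]}\n")
    with open(path / f"{design.region_id}.sites.tsv", "w") as fh:
        fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for s in design.sites:
            fh.write("\t".join([
                s.tf_name, str(s.start), str(s.end), s.strand,
                str(s.variable_position), s.wt_base, s.mut_base,
                s.canonical_for or ".",
            ]) + "\n")


def read_library(path: str | Path, region_id: str) -> LibraryDesign:
    """Read back a design written by :func:`write_library`."""
    path = Path(path)
    sites: list[MotifSite] = []
    with open(path / f"{region_id}.sites.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MANIFEST_COLUMNS:
            raise ValueError(f"unexpected manifest columns in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(MotifSite(
                tf_name=f[0], start=int(f[1]), end=int(f[2]), strand=f[3],
                variable_position=int(f[4]), wt_base=f[5], mut_base=f[6],
                canonical_for=None if f[7] == "." else f[7],
            ))
    variants: dict[str, str] = {}
    with open(path / f"{region_id}.fa") as fh:
        key = None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                rid, key = line[1:].rsplit("|", 1)
                if rid != region_id:
                    raise ValueError(f"record {rid} does not match {region_id}")
                variants[key] = ""
            elif key is not None:
                variants[key] += line.upper()
    n = len(sites)
    wt_key = "1" * n
    if set(variants) != set(iter_keys(n)):
        raise ValueError("variant keys do not form the full 2^n set")
    design = enumerate_variants(variants[wt_key], sites, region_id=region_id)
    if design.variants != variants:
        raise ValueError("stored variants inconsistent with site manifest")
    return design


def list_libraries(path: str | Path) -> list[str]:
    """Region ids of all designs stored in a directory."""
    path = Path(path)
    return sorted(p.name[:-len(".sites.tsv")]
                  for p in path.glob("*.sites.tsv"))
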