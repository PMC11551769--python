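"""Generative model of the binding assay with known ground truth.

The simulator mirrors the experiment's causal chain: each library
variant starts at a pre-activation abundance (Dirichlet-distributed per
biological replicate, emulating synthesis and cloning skew); when the
TF-fused MNase is activated for time t, a variant is cleaved in the
fraction of cells where it is bound, so its surviving abundance scales
by ``1 - bound_fraction * e_t`` where ``e_t`` is the cleavage efficiency
by time t; sequencing draws overdispersed (gamma-multinomial) counts at
a fixed depth, independently per technical replicate. A poorly bound
control sequence is spiked at a fixed fraction and never cleaved.

The per-variant bound fraction generalizes the pairwise independence
algebra to n sites — ``1 - prod_i(1 - p_i)`` over intact sites — plus
additive pairwise deviations ``c_ij`` for intact pairs, clamped to
[0, 1]. With all ``c_ij = 0`` the downstream cooperativity score is 0 in
expectation; an injected ``c_ij`` equals the score by construction when
no third site rescales the contrast (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import LibraryDesign
from .motifs import BASES
from .reads import SampleMeta, VariantCountTable

CONTROL_ID = "_control_"


@dataclass
class BindingModel:
    """Ground-truth binding parameters of one library.

    ``p[i]``: probability that site i is bound when intact (fraction of
    cells). ``c[(i, j)]``: additive deviation of the joint region-bound
    fraction from independence when both i and j are intact.
    ``e[t]``: probability that a bound plasmid has been cleaved by
    activation time t (seconds).
    """

    p: np.ndarray
    c: dict[tuple[int, int], float] = field(default_factory=dict)
    e: dict[float, float] = field(default_factory=lambda: {180.0: 1.0})

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("site binding probabilities must be in [0, 1]")
        self.c = {
            (min(i, j), max(i, j)): float(v) for (i, j), v in self.c.items()
        }
        for (i, j) in self.c:
            if not (0 <= i < j < len(self.p)):
                raise ValueError(f"invalid interaction pair ({i}, {j})")
        for t, eff in self.e.items():
            if t <= 0 or not (0 <= eff <= 1):
                raise ValueError(
                    "activation times must be positive with efficiency in [0, 1]"
                )


def variant_bound_fraction(model: BindingModel, key: str) -> float:
    """Fraction of cells in which a variant is bound: independence
    baseline over intact sites plus additive pair terms, clamped to
    [0, 1]."""
    if len(key) != len(model.p):
        raise ValueError(
            f"key length {len(key)} does not match model with "
            f"{len(model.p)} sites"
        )
    intact = [i for i, bit in enumerate(key) if bit == "1"]
    base = 1.0 - float(np.prod([1.0 - model.p[i] for i in intact]))
    coop = sum(
        v for (i, j), v in model.c.items() if i in intact and j in intact
    )
    return min(max(base + coop, 0.0), 1.0)


@dataclass
class ExperimentConfig:
    """One simulated experiment (a TF measured on one library).

    Defaults reflect the assay's study conditions: sequencing depth of
    1e6 reads per sample, 3 biological x 2 technical replicates, mild
    PCR overdispersion (gamma shape 50), a 1% control spike, and a
    Dirichlet concentration of 5 per variant for pre-activation skew.
    """

    design: LibraryDesign
    model: BindingModel
    tf_name: str = "TF"
    alpha: float = 5.0
    depth: int = 1_000_000
    n_bio: int = 3
    n_tech: int = 2
    overdispersion: float = 50.0
    control_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if len(self.model.p) != self.design.n_sites:
            raise ValueError("model size does not match design")
        if not (0 <= self.control_fraction < 1):
            raise ValueError("control fraction must be in [0, 1)")
        if self.overdispersion <= 0 or self.alpha <= 0:
            raise ValueError("overdispersion and alpha must be positive")


def simulate_counts(
    cfg: ExperimentConfig,
) -> tuple[VariantCountTable, list[SampleMeta], dict]:
    """Draw a full count table plus sample sheet and ground-truth record.

    Pre-activation abundances are drawn once per biological replicate;
    technical replicates are independent gamma-multinomial count draws
    from the same biological abundances. All outputs are bit-reproducible
    for a given seed.
    """
    rng = np.random.default_rng(cfg.seed)
    keys = cfg.design.keys
    bf = np.array([variant_bound_fraction(cfg.model, k) for k in keys])
    raw = np.array([
        1.0 - np.prod([
            1.0 - cfg.model.p[i] for i, bit in enumerate(k) if bit == "1"
        ]) + sum(
            v for (i, j), v in cfg.model.c.items()
            if k[i] == "1" and k[j] == "1"
        )
        for k in keys
    ])
    n_clamped = int(np.sum((raw < 0) | (raw > 1)))

    timepoints = [0.0] + sorted(cfg.model.e)
    cf = cfg.control_fraction
    columns: dict[str, np.ndarray] = {}
    control: dict[str, int] = {}
    samples: list[SampleMeta] = []
    for bio in range(1, cfg.n_bio + 1):
        pre = rng.dirichlet(np.full(len(keys), cfg.alpha))
        for t in timepoints:
            eff = 0.0 if t == 0 else cfg.model.e[t]
            mass = np.concatenate([pre * (1 - cf) * (1 - bf * eff), [cf]])
            probs = mass / mass.sum()
            for tech in range(1, cfg.n_tech + 1):
                w = probs * rng.gamma(
                    cfg.overdispersion, 1.0 / cfg.overdispersion,
                    size=len(probs),
                )
                draw = rng.multinomial(cfg.depth, w / w.sum())
                sid = f"{cfg.tf_name}_t{t:g}_b{bio}_r{tech}"
                columns[sid] = draw[:-1]
                control[sid] = int(draw[-1])
                samples.append(SampleMeta(
                    sample_id=sid, tf_name=cfg.tf_name, timepoint=t,
                    bio_rep=bio, tech_rep=tech,
                    library_ids=[cfg.design.region_id],
                ))
    counts = pd.DataFrame(
        columns,
        index=pd.MultiIndex.from_product(
            [[cfg.design.region_id], keys], names=["library_id", "key"]
        ),
    )
    table = VariantCountTable(
        counts=counts,
        control_counts=pd.Series(control, dtype=int),
        stats=None,
    )
    truth = {
        "p": cfg.model.p.tolist(),
        "c": {f"{i},{j}": v for (i, j), v in cfg.model.c.items()},
        "e": {float(t): float(v) for t, v in cfg.model.e.items()},
        "bound_fraction": dict(zip(keys, bf.tolist())),
        "n_clamped": n_clamped,
        "seed": cfg.seed,
        "depth": cfg.depth,
    }
    return table, samples, truth


def _mutate_read(read: str, sub_rate: float, indel_rate: float, rng) -> str:
    if indel_rate > 0 and rng.random() < indel_rate:
        pos = int(rng.integers(len(read)))
        if rng.random() < 0.5:
            read = read[:pos] + read[pos + 1:]
        else:
            base = BASES[int(rng.integers(4))]
            read = read[:pos] + base + read[pos:]
    if sub_rate > 0:
        n_sub = rng.binomial(len(read), sub_rate)
        if n_sub:
            positions = rng.choice(len(read), size=n_sub, replace=False)
            chars = list(read)
            for pos in positions:
                others = [b for b in BASES if b != chars[pos]]
                chars[pos] = others[int(rng.integers(3))]
            read = "".join(chars)
    return read


def simulate_reads(
    design: LibraryDesign,
    counts: pd.Series,
    control: str | None = None,
    control_count: int = 0,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
):
    """Yield one sample's reads from its variant counts.

    Emits each variant's sequence ``counts[key]`` times (keys in sorted
    order) and the control sequence ``control_count`` times, applying a
    per-read indel-injection rate (one 1-bp insertion or deletion) and a
    per-base substitution error rate. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    for key in sorted(counts.index):
        seq = design.variants[key]
        for _ in range(int(counts[key])):
            yield _mutate_read(seq, sub_rate, indel_rate, rng)
    if control is not None:
        for _ in range(int(control_count)):
            yield _mutate_read(control, sub_rate, indel_rate, rng)


def shuffled_control_sequence(design: LibraryDesign, seed: int = 0) -> str:
    """A synthetic poorly-bound control: the design's scaffold with its
    bases shuffled, so no annotated motif survives."""
    rng = np.random.default_rng(seed)
    chars = np.array(list(design.sequence))
    rng.shuffle(chars)
    return "".join(chars)
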