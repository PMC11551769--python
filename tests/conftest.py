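import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mpba

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_region(length: int = 164, seed: int = 7) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def region164() -> str:
    return random_region(164)


def spaced_sites(region: str, n: int, tf_names=None, canonical_for=None):
    """n motif sites with variable positions spread across the region."""
    L = len(region)
    positions = np.linspace(10, L - 12, n).astype(int)
    mut = {"A": "C", "C": "A", "G": "T", "T": "G"}  # transversions
    sites = []
    for i, pos in enumerate(positions):
        wt = region[pos]
        sites.append(mpba.MotifSite(
            tf_name=(tf_names[i] if tf_names else f"TF{i}"),
            start=int(pos) - 3, end=int(pos) + 3,
            variable_position=int(pos), wt_base=wt, mut_base=mut[wt],
            canonical_for=(canonical_for[i] if canonical_for else None),
        ))
    return sites


def make_design(n: int, region_len: int = 164, seed: int = 7,
                region_id: str = "lib", tf_names=None, canonical_for=None):
    """A ready LibraryDesign with n spaced sites on a random region."""
    import warnings

    region = random_region(region_len, seed=seed)
    sites = spaced_sites(region, n, tf_names, canonical_for)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mpba.enumerate_variants(region, sites, region_id=region_id)


def run_pipeline(design, model, seed=0, depth=1_000_000, **cfg_kwargs):
    """Simulate and normalize: the standard route to a NormalizedTable."""
    cfg = mpba.ExperimentConfig(
        design=design, model=model, depth=depth, seed=seed, **cfg_kwargs
    )
    table, samples, truth = mpba.simulate_counts(cfg)
    return mpba.normalize_counts(table, samples), truth


def manual_norm(deltas: dict, library_id="lib", tf="TF", timepoint=180.0):
    """Build a NormalizedTable directly from {key: delta} (one bio rep)."""
    index = pd.MultiIndex.from_product(
        [[library_id], sorted(deltas)], names=["library_id", "key"]
    )
    df = pd.DataFrame(
        {(tf, timepoint, 1): [deltas[k] for k in sorted(deltas)]}, index=index
    )
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["tf_name", "timepoint", "bio_rep"]
    )
    return mpba.NormalizedTable(delta_reps=df)
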