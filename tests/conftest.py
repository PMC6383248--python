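import pandas as pd
import pytest

from mcpr_sae import SamplerConfig, default_covariate_spec, fit, generate_dataset
from mcpr_sae.model import build_design
from mcpr_sae.simulate import small_config


def make_records(rows):
    """Build a record table from (region, ea, round, y) tuples with defaults."""
    df = pd.DataFrame(rows, columns=["region_id", "ea_id", "round", "y"])
    df.insert(0, "country_id", "XX")
    df["woman_id"] = [f"W{i}" for i in range(len(df))]
    df["weight"] = 1.0
    return df


@pytest.fixture(scope="session")
def covariate_spec():
    return default_covariate_spec()


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced synthetic survey: 4 regions, 20 EAs, 4 rounds, 800 women/round."""
    cfg = small_config(seed=42)
    records, truth = generate_dataset(cfg)
    return records, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset, covariate_spec):
    """A short but convergent 2-chain fit of the small synthetic survey."""
    records, truth = small_dataset
    post = fit(
        records,
        covariate_spec,
        SamplerConfig(chains=2, warmup=300, draws=400, seed=7),
    )
    design = build_design(
        records,
        covariate_spec,
        effect_level="ea",
        transforms=post.transforms,
        area_ids=post.area_ids,
        rounds=post.rounds,
    )
    return post, design
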