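import pytest

from homeobias import deg, pairclass, simdata


@pytest.fixture(scope="session")
def noise_free_dataset():
    """cv=0 dataset over a uniform mix of every default template."""
    templates = simdata.default_templates()
    mix = {t.name: 1.0 / len(templates) for t in templates}
    config = simdata.SimConfig(n_pairs=1100, template_mix=mix, cv=0.0, seed=11)
    return simdata.simulate_dataset(config)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-mix dataset at the default noise level."""
    return simdata.simulate_dataset(simdata.SimConfig(n_pairs=1500, seed=3))


@pytest.fixture(scope="session")
def classified(noisy_dataset):
    """Expressed-pair dataset plus bias/ELD/explain tables."""
    d = noisy_dataset
    kept = deg.expressed_pairs(d.pair_map, d.parent_a, d.parent_c, d.polyploid)
    ds = pairclass.PairDataset.from_tables(kept, d.parent_a, d.parent_c, d.polyploid)
    bias = pairclass.classify_bias_table(ds)
    eld = pairclass.classify_eld_table(ds)
    explain = pairclass.explain_eld_table(ds, eld)
    return {"dataset": ds, "kept": kept, "bias": bias, "eld": eld, "explain": explain}
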