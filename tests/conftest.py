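import numpy as np
import pytest

from actinoprint.synthetic import (
    CommunityConfig,
    GenusSpec,
    generate_community,
    make_templates,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(
    n_genera: int = 3,
    n_isolates: int = 9,
    template_length: int = 300,
    seed: int = 1,
    divergence: float = 0.004,
    prevalence: tuple[float, float] = (0.6, 0.4),
) -> CommunityConfig:
    """A compact community config used across tests."""
    templates = make_templates(n_genera, template_length, seed)
    names = [f"G{i + 1}" for i in range(n_genera)]
    spec = [
        GenusSpec(name=name, proportion=1.0 / n_genera, template_id=tid)
        for name, tid in zip(names, templates)
    ]
    # equalize any float drift in proportions
    spec[-1].proportion = 1.0 - sum(g.proportion for g in spec[:-1])
    return CommunityConfig(
        n_isolates=n_isolates,
        genus_spec=spec,
        templates=templates,
        divergence_within_genus=divergence,
        gene_prevalence={name: prevalence for name in names},
        seed=seed,
    )


@pytest.fixture
def small_community():
    return generate_community(small_config())
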