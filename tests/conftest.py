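import numpy as np
import pandas as pd
import pytest

from resistscope import synthetic


@pytest.fixture
def two_group_swap_scheme():
    """Minimal dye-swap design: groups A and B, one sample each,
    hybridized in both orientations."""
    return synthetic.HybridizationScheme(
        arrays=[("arr1", "b1", "a1"), ("arr2", "a1", "b1")],
        samples=[("a1", "A"), ("b1", "B")],
    )


@pytest.fixture
def loop3_scheme():
    """Noise-free-recoverable loop over three groups, two samples each."""
    samples = [(f"{g}{i}", g) for g in "ABC" for i in (1, 2)]
    ids = [s for s, _ in samples]
    arrays = []
    for k, step in enumerate((1, 2), start=1):
        for i in range(len(ids)):
            arrays.append((f"L{k}_{i}", ids[i], ids[(i + step) % len(ids)]))
    return synthetic.HybridizationScheme(arrays, samples)


def mvalue_table(scheme, truth, noise_sd=0.0, dye_bias_sd=0.0, seed=0):
    cfg = synthetic.SimConfig(
        n_probes=len(truth.probe_to_gene),
        n_genes=len(set(truth.probe_to_gene.values())),
        probes_per_gene=1,
        array_noise_sd=noise_sd,
        dye_bias_sd=dye_bias_sd,
        seed=seed,
    )
    m, _ = synthetic.generate_expression_experiment(scheme, truth, cfg)
    return m


@pytest.fixture
def ct_builder():
    """Noise-free Ct table factory for qPCR closed-form checks."""

    def build(samples, efficiencies, replicates=2):
        table, _ = synthetic.generate_ct_table(
            samples, efficiencies, replicates=replicates, ct_noise_sd=0.0
        )
        return table

    return build
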