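"""Shared fixtures: one default synthetic dataset and its derived artifacts.

Everything heavy is session-scoped so the whole suite pays for the default
simulation, scan and DE stages exactly once.
"""

from __future__ import annotations

import pytest

from florinet.expression_de import test_differential_expression
from florinet.motif_scan import build_scoring_model, scan_promoters
from florinet.promoters import extract_promoters
from florinet.synthetic_data import SyntheticConfig, generate_dataset
from florinet.trn_build import assemble_trn, compute_coexpression, deg_union


@pytest.fixture(scope="session")
def dataset():
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def promoters(dataset):
    return extract_promoters(dataset.genome, dataset.genes)


@pytest.fixture(scope="session")
def scoring_models(dataset):
    return [build_scoring_model(m) for m in dataset.motifs]


@pytest.fixture(scope="session")
def hits(promoters, scoring_models):
    return scan_promoters(promoters, scoring_models, p_threshold=1e-5)


@pytest.fixture(scope="session")
def de_tables(dataset):
    return {
        f"{b}-vs-{a}": test_differential_expression(dataset.counts, a, b)
        for a, b in (("C", "I"), ("C", "F"))
    }


@pytest.fixture(scope="session")
def trns(dataset, hits, de_tables):
    degs = deg_union(de_tables)
    floral = dataset.gene_sets["floral"]
    out = {}
    for a, b in (("C", "I"), ("C", "F")):
        rho = compute_coexpression(
            dataset.counts, list(dataset.tf_map), dataset.counts.samples_of(a, b)
        )
        out[f"{a}-{b}"] = assemble_trn(
            hits, rho, degs, dataset.tf_map, floral, comparison=f"{a}-{b}"
        )
    return out
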