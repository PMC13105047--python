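"""Shared fixtures: synthetic bundles at two scales plus derived objects.

The small bundle exercises plumbing; the large bundle carries enough
planted signal (CG motif, purine-diluted pyrimidine tract, length and
methylation shifts, AGGU recursive sites) for the statistical recovery
tests.  Read counts are floored at the detection threshold so junction
detection is exhaustive and labels match the generator truth exactly.
"""

from __future__ import annotations

import pytest

from rsplice import pipeline as pl
from rsplice.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def bundle_small(tmp_path_factory):
    cfg = SyntheticConfig(seed=11, n_genes=60, read_floor=3)
    return generate(cfg, tmp_path_factory.mktemp("bundle_small"))


@pytest.fixture(scope="session")
def small_inputs(bundle_small):
    return pl.load_bundle_dir(bundle_small.outdir)


@pytest.fixture(scope="session")
def small_classified(small_inputs):
    params = pl.PipelineParams(seed=11)
    return pl.stage_classify(small_inputs, params)


@pytest.fixture(scope="session")
def bundle_large(tmp_path_factory):
    cfg = SyntheticConfig(seed=7, n_genes=2500, rs_gene_fraction=0.45,
                          read_floor=3)
    return generate(cfg, tmp_path_factory.mktemp("bundle_large"))


@pytest.fixture(scope="session")
def large_inputs(bundle_large):
    return pl.load_bundle_dir(bundle_large.outdir)


@pytest.fixture(scope="session")
def large_classified(large_inputs):
    params = pl.PipelineParams(seed=7)
    return pl.stage_classify(large_inputs, params)


@pytest.fixture(scope="session")
def grouped_model(large_inputs, large_classified):
    """Grouped k-mer matrix + fitted 6-topic mixture at the first-intron
    canonical 5'SS."""
    from rsplice import topics as tp
    _, classified, _ = large_classified
    first = [ci for ci in classified
             if ci.intron.position_class == "first"]
    seqs = tp.extract_site_sequences(first, large_inputs.genome,
                                     "canonical5", window=(-30, 50))
    matrix = tp.grouped_kmer_matrix(seqs, group_size=15, seed=3)
    model = tp.fit_mixture(matrix, n_topics=6, seed=3, max_iter=100)
    return matrix, model


@pytest.fixture(scope="session")
def trained_first(large_inputs, large_classified):
    """Trained first-intron classifier (report, scores, features)."""
    params = pl.PipelineParams(seed=5)
    introns, classified, _ = large_classified
    meth, _ = pl.stage_methyl(large_inputs, classified, params)
    return pl.stage_train(large_inputs, introns, classified, meth, params,
                          scope="first")
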