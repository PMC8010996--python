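import numpy as np
import pytest

import recqtl


@pytest.fixture(scope="session")
def small_panel():
    """Small deterministic two-chromosome panel."""
    cfg = recqtl.SimConfig(n_individuals=120, chrom_sizes=[300, 200], seed=7)
    return recqtl.simulate_panel(cfg)


@pytest.fixture(scope="session")
def qtl_sim():
    """Medium cohort with an embedded recessive QTL, phenotypes and variants.

    Shared across fine-mapping and conditional-scan tests; built once.
    """
    cfg = recqtl.SimConfig(n_individuals=900, chrom_sizes=[1200, 800], seed=42)
    panel = recqtl.simulate_panel(cfg)
    window = recqtl.Window("chr1", 301, 350)
    causal = recqtl.embed_recessive_qtl(
        panel, "chr1", window, target_freq=0.18, tolerance=0.02, seed=43
    )
    phenotypes = recqtl.simulate_fertility(panel, causal, beta_hom=-0.8, h2=0.1, seed=44)
    variants, causal = recqtl.simulate_sequence_variants(
        panel, causal, n_variants=120, seed=45, n_unlinked=5
    )
    grm = recqtl.compute_grm(panel)
    pcs = recqtl.top_pcs(grm, 10)
    return {
        "panel": panel,
        "causal": causal,
        "phenotypes": phenotypes,
        "variants": variants,
        "grm": grm,
        "pcs": pcs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
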