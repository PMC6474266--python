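import numpy as np
import pandas as pd
import pytest

from gbmdecon import signatures, syndata
from gbmdecon.exprio import ExpressionMatrix, to_linear


@pytest.fixture(scope="session")
def small_panel():
    """Planted 3-group reference panel (the standard recovery setting)."""
    return syndata.simulate_reference_panel(
        n_genes=1200, n_per_group=40, k_groups=3, effect_size=3.0, noise_sd=0.5, seed=1
    )


@pytest.fixture(scope="session")
def small_basis(small_panel):
    """Six-population signature: 3 tumour groups + stromal + 2 lymphoid."""
    panel, truth = small_panel
    pops = ["stromal", "B_cells", "Treg"]
    immune = syndata.simulate_immune_references(
        1200, pops, marker_frac=0.04, seed=2
    )
    labels = truth.true_cluster_of_reference.map(lambda g: f"tumour_{g}")
    de = signatures.moderated_t_one_vs_rest(panel, labels)
    sel = signatures.select_signature_genes(de, 0.05, 50)
    immune_markers = syndata.immune_marker_blocks(1200, pops, 0.04)
    union = sorted(
        {g for v in sel.values() for g in v}
        | {g for v in immune_markers.values() for g in v}
    )
    panel_lin = to_linear(panel)
    cols = {
        grp: panel_lin.values.loc[union, labels.index[labels == grp]].mean(axis=1)
        for grp in sorted(labels.unique())
    }
    values = pd.DataFrame(cols).join(to_linear(immune).values.loc[union])
    roles = {g: "tumour-group" for g in cols}
    roles.update({"stromal": "stromal", "B_cells": "lymphoid", "Treg": "lymphoid"})
    return signatures.SignatureMatrix(values, roles)


@pytest.fixture
def tiny_matrix():
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(values, "log2")
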