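"""Differential expression between cell-line groups and signature assembly.

A moderated one-vs-rest t-test finds genes over-expressed in each
cell-line group (FDR < 0.05, top 50 per group); immune/stromal markers
are the genes most specific to each pure reference profile.  Group-mean
linear-scale profiles over the union of these genes form the
deconvolution basis.

Reads results/study/ and results/analysis/cell_line_clusters.csv; writes
results/analysis/differential_expression.csv and signature_matrix.tsv.
"""

from pathlib import Path

import pandas as pd

from gbmdecon.exprio import read_expression, to_linear
from gbmdecon.pipeline import select_immune_marker_genes
from gbmdecon.signatures import (
    SignatureMatrix,
    moderated_t_one_vs_rest,
    select_signature_genes,
    write_signature,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
FDR, TOP_G = 0.05, 50


def main() -> None:
    panel = read_expression(ROOT / "study" / "reference_panel.tsv")
    immune = read_expression(ROOT / "study" / "immune_references.tsv")
    roles = pd.read_csv(ROOT / "study" / "population_roles.csv", index_col=0)["role"]
    groups = pd.read_csv(
        ROOT / "analysis" / "cell_line_clusters.csv", index_col=0
    )["group"].map(lambda g: f"tumour_{g}")

    de = moderated_t_one_vs_rest(panel, groups)
    tumour_markers = select_signature_genes(de, FDR, TOP_G)
    immune_markers = select_immune_marker_genes(immune, TOP_G)
    union = sorted(
        {g for v in tumour_markers.values() for g in v}
        | {g for v in immune_markers.values() for g in v}
    )

    panel_lin, immune_lin = to_linear(panel), to_linear(immune)
    cols = {
        grp: panel_lin.values.loc[union, groups.index[groups == grp]].mean(axis=1)
        for grp in sorted(groups.unique())
    }
    values = pd.DataFrame(cols).join(immune_lin.values.loc[union])
    sig_roles = {g: "tumour-group" for g in cols}
    sig_roles.update(roles.to_dict())
    basis = SignatureMatrix(values, sig_roles)

    out = ROOT / "analysis"
    de.to_csv(out / "differential_expression.csv", index=False)
    write_signature(basis, out / "signature_matrix.tsv")

    n_sig = (de["fdr"] < FDR).groupby(de["group"]).sum()
    print("differentially expressed genes (FDR<0.05) per group:",
          n_sig.to_dict())
    print(f"signature matrix: {len(union)} genes x {len(basis.populations)} "
          f"populations, condition number {basis.condition_number():.1f}")


if __name__ == "__main__":
    main()
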