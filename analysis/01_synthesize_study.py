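"""Generate the synthetic two-cohort study all downstream analyses consume.

Emulates the structure of the real study design: a panel of 129 pure
tumour cell-line transcriptomes in three latent groups, ten pure
immune/stromal reference profiles, a discovery cohort of 200 bulk tumours
and a validation cohort of 100, each a convex mixture of the references
with survival outcomes whose hazard rises with the third tumour-group
fraction, the Treg fraction and age.  Ground truth ships alongside.

Writes results/study/ (expression TSVs, survival and annotation CSVs,
truth tables, config.yaml).
"""

from pathlib import Path

from gbmdecon import pipeline, syndata

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    study = syndata.synthesize_study(seed=SEED)
    config = pipeline.write_study(study, OUT)
    panel = study["panel"]
    disc, val = study["discovery"], study["validation"]
    print(f"reference panel: {panel.shape[0]} genes x {panel.shape[1]} cell lines "
          f"({study['panel_truth'].true_cluster_of_reference.nunique()} latent groups)")
    print(f"immune/stromal references: {study['immune'].shape[1]} populations")
    print(f"discovery cohort: {disc['bulk'].shape[1]} tumours, "
          f"{int(disc['survival']['event'].sum())} deaths observed")
    print(f"validation cohort: {val['bulk'].shape[1]} tumours, "
          f"{int(val['survival']['event'].sum())} deaths observed")
    print(f"config written to {config}")


if __name__ == "__main__":
    main()
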