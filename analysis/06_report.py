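"""Joined benchmark report and correlation analyses.

Reads the tables written by analyses 01-04 and computes the study-style
correlations: median enrichment vs binding-site identity, median
enrichment vs binding-site side-chain accuracy, and accuracy vs identity,
each as an OLS fit with Pearson's R.

Writes results/regressions.csv and results/report.csv.
"""

from pathlib import Path

import pandas as pd

from screeneval.stats import build_report, regress, summarize_template

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    enr = pd.read_csv(RESULTS / "enrichment_summary.csv")
    per_model = pd.read_csv(RESULTS / "enrichment_per_model.csv")
    acc = pd.read_csv(RESULTS / "structure_accuracy.csv")
    ident = pd.read_csv(RESULTS / "sequence_identity.csv")

    joined = (
        enr.merge(acc.drop(columns=["bs_identity"]), on="template_id")
        .merge(ident, on="template_id")
    )
    regressions = [
        regress(joined["measured_identity"], joined["median_alogauc"],
                name="median_alogauc~bs_identity"),
        regress(joined["mean_rmsd_bssc"], joined["median_alogauc"],
                name="median_alogauc~rmsd_bssc"),
        regress(joined["measured_identity"], joined["mean_rmsd_bssc"],
                name="rmsd_bssc~bs_identity"),
    ]

    summaries = [
        summarize_template(
            tid,
            grp["alogauc"].tolist(),
            ensemble_alogauc=float(
                enr.set_index("template_id").loc[tid, "ensemble_alogauc"]
            ),
        )
        for tid, grp in per_model.groupby("template_id", sort=True)
    ]
    rmsd_rows = acc[["template_id", "mean_rmsd_tmbb", "mean_rmsd_bsbb",
                     "mean_rmsd_bssc", "mean_pairwise_bssc"]]
    tables = build_report(summaries, regressions, rmsd_rows)
    tables["regressions"].to_csv(RESULTS / "regressions.csv", index=False)
    tables["combined"].to_csv(RESULTS / "report.csv", index=False)

    for r in regressions:
        print(f"{r.name}: slope {r.slope:+.3f}, R {r.pearson_r:+.2f} (n={r.n})")
    print(f"report.csv: {len(tables['combined'])} templates, "
          f"{len(tables['combined'].columns)} columns")


if __name__ == "__main__":
    main()
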