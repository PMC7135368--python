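"""Chemotype bias of single-template screens and its relief by ensembles.

Three templates each favour one chemotype (a 40-ligand subset gets an extra
affinity boost in that template's screen, emulating similarity to the
template's co-crystallized ligand).  Subset enrichment shows the bias;
two-template ensembles recover strong enrichment for both chemotypes.

Writes results/chemotype_enrichment.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from screeneval.enrichment import screen_alogauc
from screeneval.ensemble import ChemotypeSet, merge_best_score, subset_enrichment
from screeneval.synthetic import ScoreSimConfig, gen_screen

from common import BASE_SEED, MU_DECOY, N_DECOYS, N_LIGANDS, SIGMA

RESULTS = Path(__file__).resolve().parents[1] / "results"

CHEMOTYPES = {
    "chemoA": range(0, 40),
    "chemoB": range(40, 80),
    "chemoC": range(80, 120),
}
FAVOURED = {"tmpl1": "chemoA", "tmpl2": "chemoB", "tmpl3": "chemoC"}
BOOST = -1.5  # extra score (kcal/mol-like) for the favoured chemotype


def build_screen(template: str, seed: int):
    shifts = np.zeros(N_LIGANDS)
    favoured = FAVOURED[template]
    shifts[list(CHEMOTYPES[favoured])] = BOOST
    cfg = ScoreSimConfig(
        n_ligands=N_LIGANDS,
        n_decoys=N_DECOYS,
        mu_ligand=MU_DECOY - 1.0 * SIGMA,
        mu_decoy=MU_DECOY,
        sigma=SIGMA,
        seed=seed,
    )
    return gen_screen(cfg, model_id=template, ligand_shifts=shifts)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    screens = {
        t: build_screen(t, BASE_SEED + 50 + i) for i, t in enumerate(FAVOURED)
    }
    sets = {
        name: ChemotypeSet(name, frozenset(f"lig{i:05d}" for i in idx))
        for name, idx in CHEMOTYPES.items()
    }
    evaluations: dict[str, object] = dict(screens)
    evaluations["tmpl1+tmpl2"] = merge_best_score(
        [screens["tmpl1"], screens["tmpl2"]], ensemble_id="tmpl1+tmpl2"
    )
    evaluations["tmpl1+tmpl3"] = merge_best_score(
        [screens["tmpl1"], screens["tmpl3"]], ensemble_id="tmpl1+tmpl3"
    )

    rows = []
    for eval_id, screen in evaluations.items():
        rows.append(
            {
                "screen": eval_id,
                "chemotype": "all",
                "alogauc": screen_alogauc(screen).alogauc,
            }
        )
        for name, cset in sets.items():
            rows.append(
                {
                    "screen": eval_id,
                    "chemotype": name,
                    "alogauc": subset_enrichment(screen, cset).alogauc,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "chemotype_enrichment.csv", index=False)

    for template, favoured in FAVOURED.items():
        sub = df[(df["screen"] == template) & (df["chemotype"] != "all")]
        top = sub.loc[sub["alogauc"].idxmax(), "chemotype"]
        print(
            f"{template}: best-enriched chemotype {top} "
            f"(favoured by construction: {favoured}) "
            f"{'<- bias reproduced' if top == favoured else ''}"
        )
    ens = df[df["screen"] == "tmpl1+tmpl2"].set_index("chemotype")["alogauc"]
    print(
        f"tmpl1+tmpl2 ensemble: chemoA {ens['chemoA']:.1f}, "
        f"chemoB {ens['chemoB']:.1f} aLogAUC (both strongly enriched)"
    )


if __name__ == "__main__":
    main()
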