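"""Cell-shape analysis: control cutoffs and class mix of two populations.

Derives roundness cutoffs from simulated epithelial and mesenchymal
control populations (750 cells each, i.e. 250 cells per field across 3
fields), then classifies a mesenchymal-dominant "control-like" population
and a mixed "knockdown-like" population, mirroring the shift toward mixed
morphology seen after Zeb1 knockdown.
"""

from pathlib import Path

import pandas as pd

from pemt import classify_cells, derive_cutoffs, generate_cell_population
from pemt.morphology import score_outlines
from pemt.synthetic import CONTROL_AXIS_RATIO_PARAMS

STUDY_SEED = 2021
ROOT = Path(__file__).resolve().parents[1]

POPULATIONS = {
    # (epithelial, mixed, mesenchymal) generating proportions
    "control_like": (0.10, 0.25, 0.65),
    "knockdown_like": (0.25, 0.45, 0.30),
}


def main() -> None:
    epi, _ = generate_cell_population(750, (1, 0, 0), CONTROL_AXIS_RATIO_PARAMS,
                                      seed=STUDY_SEED + 1)
    mes, _ = generate_cell_population(750, (0, 0, 1), CONTROL_AXIS_RATIO_PARAMS,
                                      seed=STUDY_SEED + 2)
    cuts = derive_cutoffs(score_outlines(epi).values, score_outlines(mes).values)
    print(
        f"control-derived cutoffs: epithelial >= {cuts.epithelial_cut:.3f}, "
        f"mesenchymal <= {cuts.mesenchymal_cut:.3f}"
    )

    rows = []
    for offset, (name, mix) in enumerate(POPULATIONS.items(), start=10):
        outlines, _ = generate_cell_population(750, mix, seed=STUDY_SEED + offset)
        report = classify_cells(score_outlines(outlines).values, cuts)
        row = {"population": name}
        for cls in ("epithelial", "mixed", "mesenchymal"):
            row[f"{cls}_pct"] = round(report.percentages[cls], 1)
            row[f"{cls}_planted_pct"] = 100 * mix[
                ("epithelial", "mixed", "mesenchymal").index(cls)
            ]
        rows.append(row)
        print(f"{name}: {row}")

    table = pd.DataFrame(rows)
    out = ROOT / "results" / "05_morphology.tsv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, sep="\t", index=False)
    print(f"class percentages -> {out}")


if __name__ == "__main__":
    main()
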