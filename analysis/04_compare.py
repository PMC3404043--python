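"""Cross-model overlap, KEGG color export, and qPCR concordance.

Classifies every gene into the eight overlap classes, writes the per-gene
class table and the six-color KEGG upload table, then simulates a qPCR
validation panel (strong, well-measured hits per model) and reports the
sequencing-vs-qPCR Pearson correlation.
"""

import pathlib

from stratde import (
    assign_color_classes,
    compare_models,
    qpcr_concordance,
    simulate_qpcr,
)
from stratde.compare_report import write_color_table
from stratde.io_formats import read_de_calls, read_truth_table, write_comparison, write_qpcr

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = 0
PANEL_SIZE = 10
NOISE_SD = 0.25  # log2 units
MIN_EXPR = 5.0  # CPM floor for well-measured panel genes


def main() -> None:
    calls = {m: read_de_calls(RESULTS / f"de_{m}.tsv") for m in ("A", "B")}
    truth = read_truth_table(RESULTS / "truth.tsv")

    comparison = compare_models(calls["A"], calls["B"])
    write_comparison(comparison, RESULTS / "comparison.tsv")
    colors = assign_color_classes(comparison)
    write_color_table(colors, RESULTS / "kegg_colors.tsv")
    s = comparison.summary
    print(f"shared: {s['up-both']} up, {s['down-both']} down; "
          f"A-only: {s['up-A-only']}/{s['down-A-only']} up/down; "
          f"B-only: {s['up-B-only']}/{s['down-B-only']}; "
          f"discordant: {s['discordant']}")
    print(f"{len(colors)} genes written to kegg_colors.tsv across 6 color classes")

    for offset, model in enumerate(("A", "B")):
        de_calls = calls[model]
        well = de_calls[["ctrl_norm", "diab_norm"]].min(axis=1) >= MIN_EXPR
        de = de_calls[(de_calls["call"] != "unchanged")
                      & (de_calls["stratum"] == "high") & well]
        panel = de.reindex(de["log2fc"].abs().sort_values(ascending=False).index)
        panel = panel.head(PANEL_SIZE)
        qpcr = simulate_qpcr(truth, list(panel["gene_id"]), NOISE_SD,
                             seed=SEED + 2 + offset, model=model)
        conc = qpcr_concordance(de_calls, qpcr)
        write_qpcr(conc.pairs, RESULTS / f"concordance_{model}.tsv",
                   {"pearson_r": f"{conc.r:.6g}"})
        print(f"model {model}: qPCR concordance r = {conc.r:.3f} "
              f"over {len(conc.pairs)} panel genes")


if __name__ == "__main__":
    main()
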