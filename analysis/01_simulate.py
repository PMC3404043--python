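"""Generate the synthetic two-model oocyte count study.

Emits the count table (four libraries: control/diabetic for models A and
B), the planting truth table, a synthetic GO-style annotation with one
enriched term, and qPCR-style re-measurements for a validation panel drawn
later by 04_compare. Everything downstream starts from these files.
"""

import pathlib

from stratde import SyntheticSpec, simulate_annotation, simulate_counts
from stratde.io_formats import write_annotation, write_count_table, write_truth_table

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = SyntheticSpec(seed=SEED)
    table, truth = simulate_counts(spec)
    write_count_table(table, RESULTS / "counts.tsv", {"seed": SEED})
    write_truth_table(truth, RESULTS / "truth.tsv", {"seed": SEED})

    annotation = simulate_annotation(
        truth, n_terms=50, enriched_terms=1, enrichment_odds=20.0, seed=SEED + 1
    )
    write_annotation(annotation, RESULTS / "annotation.gmt")

    n_pass = {
        m: int((table.counts[table.libraries_for(m)].sum(axis=1) > 10).sum())
        for m in ("A", "B")
    }
    print(f"simulated {len(table.gene_ids)} genes; "
          f"{n_pass['A']} (A) / {n_pass['B']} (B) exceed 10 summed reads")
    print(f"wrote counts.tsv, truth.tsv, annotation.gmt under {RESULTS}")


if __name__ == "__main__":
    main()
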