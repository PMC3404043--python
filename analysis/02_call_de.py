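"""Stratified fold-change DE calling for both disease models.

Reads results/counts.tsv, applies the detection filter (summed reads
strictly > 10 per model), CPM normalisation, the 1/10-of-mean expression
stratification, and the stratum-specific cutoffs (|log2fc| > 0.8 high,
> 2 low); writes one DE-call table per model.
"""

import pathlib

from stratde import FilterParams, run_model
from stratde.io_formats import file_checksum, read_count_table, write_de_calls

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"
LIB_SPEC = {
    "ctrl_A": ("A", "control"), "diab_A": ("A", "diabetic"),
    "ctrl_B": ("B", "control"), "diab_B": ("B", "diabetic"),
}


def main() -> None:
    counts_path = RESULTS / "counts.tsv"
    table = read_count_table(counts_path, LIB_SPEC)
    params = FilterParams()
    for model in ("A", "B"):
        calls = run_model(table, params, model)
        hdr = {
            "model": model, "min_reads": params.min_reads,
            "stratum_fraction": params.stratum_fraction,
            "high_cutoff": params.high_cutoff, "low_cutoff": params.low_cutoff,
            "normalization": params.normalization, "pseudocount": params.pseudocount,
            "counts_sha1": file_checksum(counts_path),
        }
        write_de_calls(calls, RESULTS / f"de_{model}.tsv", hdr)
        n_up = int((calls["call"] == "up").sum())
        n_down = int((calls["call"] == "down").sum())
        print(f"model {model}: {len(calls)} genes pass the filter; "
              f"{n_up} up-regulated, {n_down} down-regulated in the diabetic library")


if __name__ == "__main__":
    main()
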