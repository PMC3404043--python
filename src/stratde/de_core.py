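"""Stratified fold-change DE calling on read-count tables.

The procedure, per disease model:

1. **Detection filter** — keep genes whose raw counts, summed over the
   model's control and diabetic libraries, are strictly greater than
   ``min_reads`` (default 10).
2. **Normalisation** — counts-per-million per library (default), or raw
   counts for the literal single-lane procedure.
3. **Stratification** — with ``m`` the mean over filtered genes of the
   per-gene mean normalised count across the model's two libraries, a gene
   is *highly expressed* iff its per-gene mean is strictly greater than
   ``m * stratum_fraction`` (default 1/10), else *lowly expressed*.
4. **Calling** — ``log2fc = log2((diabetic + eps) / (control + eps))``
   (diabetic over control, so up means up in the diabetic oocyte); a
   high-stratum gene is up iff ``log2fc > 0.8`` and down iff
   ``log2fc < -0.8``; a low-stratum gene uses the stricter cutoff 2. All
   inequalities are strict; everything else is *unchanged*.

The stricter low-stratum cutoff exists to hold down the false-positive
rate among weakly measured genes, where count noise inflates fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from stratde.io_formats import DE_COLUMNS, CountTable

logger = logging.getLogger(__name__)

NORM_METHODS = ("cpm", "none")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the DE procedure (defaults are the study's values)."""

    min_reads: int = 10
    stratum_fraction: float = 0.1
    pseudocount: float = 0.5
    normalization: str = "cpm"
    high_cutoff: float = 0.8
    low_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValueError(f"min_reads must be >= 0, got {self.min_reads}")
        if self.stratum_fraction <= 0:
            raise ValueError(f"stratum_fraction must be > 0, got {self.stratum_fraction}")
        if self.pseudocount < 0:
            raise ValueError(f"pseudocount must be >= 0, got {self.pseudocount}")
        if self.normalization not in NORM_METHODS:
            raise ValueError(f"normalization must be one of {NORM_METHODS}, got {self.normalization!r}")
        if self.high_cutoff <= 0 or self.low_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


def filter_detected(table: CountTable, params: FilterParams, model: str) -> CountTable:
    """Keep genes with summed raw counts strictly above ``min_reads``.

    The sum runs over all of the given model's libraries (control plus
    diabetic). An empty result is allowed (warning only): downstream stages
    accept empty input.
    """
    libs = table.libraries_for(model)
    total = table.counts[libs].sum(axis=1)
    keep = total > params.min_reads
    retained = table.subset(table.counts.index[keep])
    logger.info(
        "detection filter model %s: retained %d, discarded %d (min_reads=%d, strict >)",
        model, int(keep.sum()), int((~keep).sum()), params.min_reads,
    )
    if keep.sum() == 0:
        logger.warning("detection filter model %s: no genes retained", model)
    return retained


def normalize(table: CountTable, method: str = "cpm") -> pd.DataFrame:
    """Per-library scaling of counts; returns a float gene x library frame.

    ``cpm`` scales each library to 1e6 total reads; ``none`` returns the
    raw counts as floats.
    """
    if method not in NORM_METHODS:
        raise ValueError(f"normalization must be one of {NORM_METHODS}, got {method!r}")
    mat = table.counts.astype(float)
    if method == "none":
        return mat
    totals = mat.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"cannot CPM-normalize zero-total libraries: {list(zero.index)}")
    return mat * (1e6 / totals)


def _model_means(norm: pd.DataFrame, table: CountTable, model: str) -> pd.Series:
    return norm[table.libraries_for(model)].mean(axis=1)


def stratify(
    norm: pd.DataFrame, table: CountTable, params: FilterParams, model: str
) -> pd.Series:
    """Partition genes into 'high'/'low' strata for one model.

    The threshold is ``stratum_fraction`` times the grand mean over genes of
    the per-gene mean normalised count across the model's libraries; high
    means strictly above the threshold.
    """
    per_gene = _model_means(norm, table, model)
    if per_gene.empty:
        logger.warning("stratify model %s: empty input", model)
        return pd.Series(dtype=object, name="stratum")
    threshold = per_gene.mean() * params.stratum_fraction
    strata = pd.Series(
        np.where(per_gene > threshold, "high", "low"), index=per_gene.index, name="stratum"
    )
    logger.info(
        "stratify model %s: threshold %.4g -> %d high / %d low",
        model, threshold, int((strata == "high").sum()), int((strata == "low").sum()),
    )
    return strata


def log2_fold_change(ctrl, diab, pseudocount: float = 0.5):
    """log2((diab + eps) / (ctrl + eps)); antisymmetric in its arguments."""
    ctrl = np.asarray(ctrl, dtype=float)
    diab = np.asarray(diab, dtype=float)
    if (ctrl < 0).any() or (diab < 0).any():
        raise ValueError("counts must be non-negative")
    if pseudocount == 0 and ((ctrl == 0) & (diab == 0)).any():
        raise ValueError("log2 fold change undefined: both counts 0 with pseudocount 0")
    with np.errstate(divide="ignore"):
        out = np.log2(diab + pseudocount) - np.log2(ctrl + pseudocount)
    return out if out.ndim else float(out)


def classify(log2fc, stratum, params: FilterParams) -> np.ndarray:
    """Apply the stratum-specific strict cutoffs to log2 fold changes.

    High-stratum genes are up iff ``log2fc > high_cutoff`` (down below the
    negated cutoff); low-stratum genes use ``low_cutoff``. Values exactly at
    a cutoff are unchanged.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    stratum = np.asarray(stratum, dtype=object)
    cutoff = np.where(stratum == "high", params.high_cutoff, params.low_cutoff)
    out = np.full(log2fc.shape, "unchanged", dtype=object)
    out[log2fc > cutoff] = "up"
    out[log2fc < -cutoff] = "down"
    return out


def call_de(table: CountTable, params: FilterParams, model: str) -> pd.DataFrame:
    """Classify each gene of a filtered table as up / down / unchanged.

    Expects the detection filter to have been applied already. Returns one
    record per gene with the normalised condition means, stratum, log2 fold
    change and call. With replicate libraries, condition values are means
    over the condition's libraries.
    """
    norm = normalize(table, params.normalization)
    strata = stratify(norm, table, params, model)
    ctrl = norm[table.libraries_for(model, "control")].mean(axis=1)
    diab = norm[table.libraries_for(model, "diabetic")].mean(axis=1)
    lfc = pd.Series(
        log2_fold_change(ctrl.to_numpy(), diab.to_numpy(), params.pseudocount),
        index=ctrl.index,
    )
    call = pd.Series(
        classify(lfc.to_numpy(), strata.to_numpy(), params), index=lfc.index, dtype=object
    )
    out = pd.DataFrame(
        {
            "gene_id": lfc.index,
            "model": model,
            "ctrl_norm": ctrl.to_numpy(),
            "diab_norm": diab.to_numpy(),
            "stratum": strata.to_numpy(),
            "log2fc": lfc.to_numpy(),
            "call": call.to_numpy(),
        },
        columns=DE_COLUMNS,
    ).reset_index(drop=True)
    for stratum in ("high", "low"):
        sub = out[out["stratum"] == stratum]
        logger.info(
            "call_de model %s %s stratum: %d up / %d down / %d unchanged",
            model, stratum,
            int((sub["call"] == "up").sum()),
            int((sub["call"] == "down").sum()),
            int((sub["call"] == "unchanged").sum()),
        )
    return out


def run_model(table: CountTable, params: FilterParams, model: str) -> pd.DataFrame:
    """Filter then call one model; the standard per-model entry point."""
    return call_de(filter_detected(table, params, model), params, model)
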