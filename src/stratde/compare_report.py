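"""Cross-model overlap classes, KEGG color-map export, qPCR concordance.

Each gene in the union of both models' filtered sets gets exactly one of
eight classes: up/down in both models, up/down in one model only,
direction-discordant (up in one, down in the other — reported separately,
never counted as shared), or unchanged. The six DE classes map onto the
standard KEGG color-map palette; concordance is the Pearson correlation of
sequencing and qPCR log2 fold changes over a validation panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COMPARISON_CLASSES = (
    "up-both",
    "down-both",
    "up-A-only",
    "down-A-only",
    "up-B-only",
    "down-B-only",
    "discordant",
    "unchanged",
)

# model A = STZ-like, model B = NOD-like
COLOR_MAP = {
    "up-both": "red",
    "down-both": "blue",
    "up-B-only": "yellow",
    "down-B-only": "green",
    "up-A-only": "orange",
    "down-A-only": "purple",
}


@dataclass
class ModelComparison:
    """Per-gene overlap class plus summary counts per class."""

    classes: pd.DataFrame  # columns: gene_id, class
    summary: dict[str, int]

    def genes_in_class(self, cls: str) -> set:
        return set(self.classes.loc[self.classes["class"] == cls, "gene_id"])


@dataclass
class ConcordanceResult:
    """Paired sequencing/qPCR log2 fold changes and their Pearson r."""

    pairs: pd.DataFrame  # columns: gene_id, seq_log2fc, qpcr_log2fc
    r: float


def _directions(calls: pd.DataFrame) -> dict[str, str]:
    return dict(zip(calls["gene_id"], calls["call"]))


def compare_models(calls_A: pd.DataFrame, calls_B: pd.DataFrame) -> ModelComparison:
    """Classify every gene in the union of both models' filtered sets.

    Genes filtered out of one model count as unchanged there, so a gene up
    in A but undetected in B is ``up-A-only``. A gene called up in one model
    and down in the other is ``discordant``.
    """
    if len(calls_A) == 0 and len(calls_B) == 0:
        logger.warning("compare_models: both call lists empty")
        return ModelComparison(
            pd.DataFrame(columns=["gene_id", "class"]), {c: 0 for c in COMPARISON_CLASSES}
        )
    dir_a = _directions(calls_A)
    dir_b = _directions(calls_B)
    genes = sorted(set(dir_a) | set(dir_b))
    rows = []
    for g in genes:
        a = dir_a.get(g, "unchanged")
        b = dir_b.get(g, "unchanged")
        if a == b == "unchanged":
            cls = "unchanged"
        elif a == b:
            cls = f"{a}-both"
        elif "unchanged" in (a, b):
            direction, model = (a, "A") if b == "unchanged" else (b, "B")
            cls = f"{direction}-{model}-only"
        else:
            cls = "discordant"
        rows.append({"gene_id": g, "class": cls})
    classes = pd.DataFrame(rows, columns=["gene_id", "class"])
    summary = {c: int((classes["class"] == c).sum()) for c in COMPARISON_CLASSES}
    logger.info("compare_models: %s", summary)
    return ModelComparison(classes, summary)


def assign_color_classes(comparison: ModelComparison) -> dict[str, str]:
    """Map DE genes to the six-color KEGG palette.

    red/blue: up-/down-regulated in both models; orange/purple: uniquely in
    model A (STZ-like); yellow/green: uniquely in model B (NOD-like).
    Unchanged and discordant genes are omitted, so the result can be
    uploaded as a KEGG color-map table (gene id TAB color).
    """
    return {
        gene: COLOR_MAP[cls]
        for gene, cls in zip(comparison.classes["gene_id"], comparison.classes["class"])
        if cls in COLOR_MAP
    }


def write_color_table(colors: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(colors):
            fh.write(f"{gene}\t{colors[gene]}\n")


def qpcr_concordance(seq_lfc: pd.DataFrame, qpcr_lfc: pd.DataFrame) -> ConcordanceResult:
    """Pearson correlation of sequencing vs qPCR log2 fold changes.

    ``seq_lfc`` needs columns gene_id and log2fc (a DE-call table works);
    ``qpcr_lfc`` needs gene_id and qpcr_log2fc. Requires at least three
    shared genes and non-degenerate variance in both vectors.
    """
    seq_col = "log2fc" if "log2fc" in seq_lfc.columns else "seq_log2fc"
    seq = seq_lfc.set_index("gene_id")[seq_col]
    qpcr = qpcr_lfc.set_index("gene_id")["qpcr_log2fc"]
    shared = sorted(set(seq.index) & set(qpcr.index))
    if len(shared) < 3:
        raise ValueError(f"concordance needs >= 3 shared genes, got {len(shared)}")
    x = seq.loc[shared].to_numpy(dtype=float)
    y = qpcr.loc[shared].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance in one of the vectors")
    r = float(stats.pearsonr(x, y)[0])
    pairs = pd.DataFrame({"gene_id": shared, "seq_log2fc": x, "qpcr_log2fc": y})
    return ConcordanceResult(pairs, r)
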