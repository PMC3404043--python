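"""Synthetic count tables, annotations and qPCR panels with known truth.

The generator emulates the structure of a pooled-oocyte whole-transcriptome
study: two type-1 diabetes models (A, STZ-like; B, NOD-like), one control
and one diabetic library per model, a long-tailed log-normal baseline over
~16k genes of which roughly half clear the >10-summed-reads detection
filter, and differential expression planted multiplicatively on the
diabetic library's mean. Counts are negative-binomial with variance
mu + dispersion * mu**2; dispersion 0 degenerates to Poisson.

Everything is driven by a single :class:`SyntheticSpec`; identical specs
(including the seed) give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stratde.io_formats import CountTable, LibraryInfo, SlimMapping, Term, TermAnnotation

TRUTH_COLUMNS = ["gene_id", "class_A", "class_B", "true_lfc_A", "true_lfc_B", "stratum"]


class ParameterError(ValueError):
    """A SyntheticSpec field violates its constraint; the message names it."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic two-model count study.

    Defaults reproduce the study's scale: 16,457 genes with a log-normal
    baseline calibrated so that roughly 8,800 genes have more than 10
    summed reads per model, per-model DE fractions on the order of the
    reported up/down lists, and about 45% of each model's DE genes shared
    between models.
    """

    n_genes: int = 16457
    library_size: float = 2_000_000.0
    dispersion: float = 0.05
    frac_de_up: float = 0.073
    frac_de_down: float = 0.040
    lfc_high: float = 2.0
    lfc_low: float = 3.0
    frac_shared: float = 0.45
    baseline_shape: tuple[float, float] = (0.0, 2.42)  # (mu, sigma) of log-mean expression
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ParameterError(f"n_genes must be positive, got {self.n_genes}")
        if self.library_size <= 0:
            raise ParameterError(f"library_size must be positive, got {self.library_size}")
        if self.dispersion < 0:
            raise ParameterError(f"dispersion must be >= 0, got {self.dispersion}")
        for name in ("frac_de_up", "frac_de_down", "frac_shared"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {val}")
        if self.frac_de_up + self.frac_de_down > 1.0:
            raise ParameterError(
                f"frac_de_up + frac_de_down must be <= 1, got {self.frac_de_up + self.frac_de_down}"
            )
        if self.baseline_shape[1] < 0:
            raise ParameterError(f"baseline_shape sigma must be >= 0, got {self.baseline_shape[1]}")
        if self.n_replicates < 1:
            raise ParameterError(f"n_replicates must be >= 1, got {self.n_replicates}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB counts with variance mean + dispersion * mean**2 (Poisson at 0)."""
    if dispersion == 0.0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    return rng.negative_binomial(size_param, size_param / (size_param + mean))


def _plant_de(rng: np.random.Generator, spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Assign per-gene, per-model DE classes honouring the sharing fraction.

    Returns two int8 arrays (model A, model B) with values +1 (up), -1
    (down), 0 (null). Shared genes get the same direction in both models.
    """
    n = spec.n_genes
    n_up = round(spec.frac_de_up * n)
    n_down = round(spec.frac_de_down * n)
    shared_up = round(spec.frac_shared * n_up)
    shared_down = round(spec.frac_shared * n_down)
    # each model has n_up up / n_down down genes; the first shared_* are common
    need = shared_up + shared_down + 2 * (n_up - shared_up) + 2 * (n_down - shared_down)
    if need > n:
        raise ParameterError("frac_de_up/frac_de_down/frac_shared demand more genes than n_genes")
    pool = rng.permutation(n)[:need]
    cls_a = np.zeros(n, dtype=np.int8)
    cls_b = np.zeros(n, dtype=np.int8)
    pos = 0

    def take(count: int) -> np.ndarray:
        nonlocal pos
        out = pool[pos : pos + count]
        pos += count
        return out

    both_up = take(shared_up)
    both_down = take(shared_down)
    a_up = take(n_up - shared_up)
    b_up = take(n_up - shared_up)
    a_down = take(n_down - shared_down)
    b_down = take(n_down - shared_down)
    cls_a[both_up] = 1
    cls_b[both_up] = 1
    cls_a[both_down] = -1
    cls_b[both_down] = -1
    cls_a[a_up] = 1
    cls_b[b_up] = 1
    cls_a[a_down] = -1
    cls_b[b_down] = -1
    return cls_a, cls_b


def simulate_counts(spec: SyntheticSpec) -> tuple[CountTable, pd.DataFrame]:
    """Generate a four-library count table plus its truth table.

    The baseline per-gene mean is log-normal(``baseline_shape``) normalised
    to ``library_size`` expected reads per library; planted DE multiplies
    the diabetic mean by ``2**(+-lfc)``, where the magnitude is ``lfc_high``
    or ``lfc_low`` according to the gene's generation-time stratum (above or
    below 1/10 of the mean baseline). The truth table records, per gene, the
    class and signed log2 fold change for each model and the stratum.
    """
    rng = np.random.default_rng(spec.seed)
    mu_log, sigma_log = spec.baseline_shape
    rel = rng.lognormal(mu_log, sigma_log, spec.n_genes)
    lam = spec.library_size * rel / rel.sum()

    grand_mean = lam.mean()
    high = lam > grand_mean / 10.0
    lfc_mag = np.where(high, spec.lfc_high, spec.lfc_low)

    cls_a, cls_b = _plant_de(rng, spec)
    lfc_a = cls_a * lfc_mag
    lfc_b = cls_b * lfc_mag

    digits = max(5, len(str(spec.n_genes)))
    gene_ids = [f"g{i:0{digits}d}" for i in range(1, spec.n_genes + 1)]

    cols: dict[str, np.ndarray] = {}
    libraries: dict[str, LibraryInfo] = {}
    for model, lfc in (("A", lfc_a), ("B", lfc_b)):
        for condition, mean in (("control", lam), ("diabetic", lam * np.exp2(lfc))):
            for rep in range(1, spec.n_replicates + 1):
                label = f"{'ctrl' if condition == 'control' else 'diab'}_{model}"
                if spec.n_replicates > 1:
                    label = f"{label}_{rep}"
                cols[label] = _nb_draw(rng, mean, spec.dispersion).astype(np.int64)
                libraries[label] = LibraryInfo(label, model, condition)

    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    table = CountTable(counts, libraries)

    cls_name = {1: "up", -1: "down", 0: "null"}
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class_A": [cls_name[c] for c in cls_a],
            "class_B": [cls_name[c] for c in cls_b],
            "true_lfc_A": lfc_a,
            "true_lfc_B": lfc_b,
            "stratum": np.where(high, "high", "low"),
        },
        columns=TRUTH_COLUMNS,
    )
    return table, truth


def true_de_genes(truth: pd.DataFrame, model: str | None = None) -> set:
    """Genes planted as DE in the given model (or in either model)."""
    if model is None:
        mask = (truth["class_A"] != "null") | (truth["class_B"] != "null")
    else:
        mask = truth[f"class_{model}"] != "null"
    return set(truth.loc[mask, "gene_id"])


def simulate_annotation(
    truth: pd.DataFrame,
    n_terms: int,
    enriched_terms: int,
    enrichment_odds: float,
    seed: int,
    term_size: tuple[int, int] = (10, 120),
    namespace: str = "biological_process",
    model: str | None = None,
) -> TermAnnotation:
    """Random term annotation with a controllable DE-enrichment signal.

    Ordinary terms sample member genes uniformly; the first
    ``enriched_terms`` terms sample true-DE genes (per ``model``, or either
    model when None) with the stated odds relative to null genes.
    ``enrichment_odds=inf`` makes enriched terms entirely true-DE. Term
    sizes are uniform over ``term_size``; accs run GO:SIM0001 upward with
    enriched terms first.
    """
    if n_terms < 0 or enriched_terms < 0 or n_terms < enriched_terms:
        raise ParameterError(f"need n_terms >= enriched_terms >= 0, got {n_terms}, {enriched_terms}")
    if enrichment_odds < 1:
        raise ParameterError(f"enrichment_odds must be >= 1, got {enrichment_odds}")
    rng = np.random.default_rng(seed)
    genes = np.asarray(truth["gene_id"], dtype=object)
    de = np.isin(genes, sorted(true_de_genes(truth, model)))
    terms: dict[str, Term] = {}
    for i in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        size = min(size, len(genes))
        if i < enriched_terms:
            if math.isinf(enrichment_odds):
                candidates = genes[de]
                size = min(size, len(candidates))
                members = rng.choice(candidates, size=size, replace=False)
            else:
                weights = np.where(de, enrichment_odds, 1.0)
                members = rng.choice(genes, size=size, replace=False, p=weights / weights.sum())
        else:
            members = rng.choice(genes, size=size, replace=False)
        acc = f"GO:SIM{i + 1:04d}"
        label = "enriched" if i < enriched_terms else "background"
        terms[acc] = Term(acc, f"synthetic {label} term {i + 1}", namespace, frozenset(members))
    return TermAnnotation(terms)


def simulate_slim(annotation: TermAnnotation, n_slim: int, seed: int) -> SlimMapping:
    """Random many-to-one slim mapping over an annotation's terms."""
    if n_slim < 1:
        raise ParameterError(f"n_slim must be >= 1, got {n_slim}")
    rng = np.random.default_rng(seed)
    accs = annotation.accs()
    slim_accs = [f"GO:SLIM{i + 1:03d}" for i in range(n_slim)]
    assignment = rng.integers(0, n_slim, len(accs))
    mapping = {acc: slim_accs[j] for acc, j in zip(accs, assignment)}
    namespaces = {term.namespace for term in annotation.terms.values()} or {"biological_process"}
    ns = sorted(namespaces)[0]
    used = sorted(set(mapping.values()))
    mapping.update({s: s for s in used})
    names = {s: f"synthetic slim term {s[-3:]}" for s in used}
    return SlimMapping(mapping, names, {s: ns for s in used})


def simulate_qpcr(
    truth: pd.DataFrame,
    genes,
    noise_sd: float,
    seed: int,
    model: str = "A",
) -> pd.DataFrame:
    """qPCR-style log2 fold changes: truth plus Gaussian noise.

    Models a panel re-measured by relative quantification (delta-delta-Ct
    already applied): per gene, the reported log2 fold change is the true
    planted value for ``model`` plus N(0, noise_sd) in log2 units.
    """
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    genes = list(genes)
    lut = truth.set_index("gene_id")[f"true_lfc_{model}"]
    missing = [g for g in genes if g not in lut.index]
    if missing:
        raise KeyError(f"genes absent from truth table: {missing}")
    rng = np.random.default_rng(seed)
    vals = lut.loc[genes].to_numpy(dtype=float) + rng.normal(0.0, noise_sd, len(genes))
    return pd.DataFrame({"gene_id": genes, "qpcr_log2fc": vals})
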