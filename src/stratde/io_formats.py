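"""On-disk artifacts: count tables, GMT annotations, result TSVs.

All writers emit a commented ``#`` header recording the package version and
the parameters that produced the file; all readers validate strictly and
report malformed content with line numbers rather than dropping rows.

Floats are written with 6 significant digits and p-values in scientific
notation; round-tripping a written file reproduces the records at that
precision (integers and strings exactly).
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _version_token() -> str:
    from stratde import __version__  # deferred to avoid a circular import

    return __version__


MODELS = ("A", "B")
CONDITIONS = ("control", "diabetic")
GO_NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


class FormatError(ValueError):
    """Malformed input file (bad cell, duplicate id, wrong namespace...)."""


class ConfigError(ValueError):
    """Inconsistent configuration (library spec mismatch, missing slim map...)."""


@dataclass(frozen=True)
class LibraryInfo:
    """One sequencing library: a column of the count table."""

    label: str
    model: str  # 'A' (STZ-like) or 'B' (NOD-like)
    condition: str  # 'control' or 'diabetic'

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ConfigError(f"library {self.label!r}: model must be one of {MODELS}, got {self.model!r}")
        if self.condition not in CONDITIONS:
            raise ConfigError(
                f"library {self.label!r}: condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


@dataclass
class CountTable:
    """Gene x library matrix of non-negative integer read counts.

    ``counts`` is indexed by unique gene ids with one column per library
    label; ``libraries`` maps each label to its (model, condition) pair.
    """

    counts: pd.DataFrame
    libraries: dict[str, LibraryInfo]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.counts.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise FormatError(f"duplicate gene ids: {dups[:10]}")
        if set(self.counts.columns) != set(self.libraries):
            raise ConfigError(
                f"library spec does not match count columns: columns={list(self.counts.columns)}, "
                f"spec={sorted(self.libraries)}"
            )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (vals < 0).any():
            raise FormatError("counts must be non-negative")
        for model in {info.model for info in self.libraries.values()}:
            conds = {info.condition for info in self.libraries.values() if info.model == model}
            if not {"control", "diabetic"} <= conds:
                raise ConfigError(f"model {model!r} lacks a control or diabetic library")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def models(self) -> list[str]:
        return sorted({info.model for info in self.libraries.values()})

    def libraries_for(self, model: str, condition: str | None = None) -> list[str]:
        """Column labels for one model, optionally one condition, in table order."""
        return [
            lab
            for lab in self.counts.columns
            if self.libraries[lab].model == model
            and (condition is None or self.libraries[lab].condition == condition)
        ]

    def subset(self, gene_ids) -> "CountTable":
        return CountTable(self.counts.loc[list(gene_ids)], dict(self.libraries))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.libraries == other.libraries


@dataclass(frozen=True)
class Term:
    acc: str
    name: str
    namespace: str
    genes: frozenset

    def __post_init__(self) -> None:
        if self.namespace not in GO_NAMESPACES:
            raise FormatError(f"term {self.acc}: namespace {self.namespace!r} not one of {GO_NAMESPACES}")
        if not self.genes:
            raise FormatError(f"term {self.acc}: empty gene set")


@dataclass
class SlimMapping:
    """Explicit detailed-term -> slim-term table (no ontology graph walk).

    ``mapping`` sends a term acc to its slim parent's acc; ``names`` and
    ``namespaces`` describe the slim terms themselves. Slim accs present as
    mapping keys must map to themselves (idempotence).
    """

    mapping: dict[str, str]
    names: dict[str, str]
    namespaces: dict[str, str]

    def __post_init__(self) -> None:
        for slim_acc in set(self.mapping.values()):
            if slim_acc in self.mapping and self.mapping[slim_acc] != slim_acc:
                raise ConfigError(f"slim mapping not idempotent at {slim_acc}")
            if slim_acc not in self.names:
                raise ConfigError(f"slim term {slim_acc} has no name")
            if self.namespaces.get(slim_acc) not in GO_NAMESPACES:
                raise ConfigError(f"slim term {slim_acc} has invalid namespace")


@dataclass
class TermAnnotation:
    """Ontology terms with their member gene sets, plus an optional slim map.

    Genes absent from any particular count table are retained here; the
    universe intersection happens at enrichment time.
    """

    terms: dict[str, Term] = field(default_factory=dict)
    slim: SlimMapping | None = None

    def __post_init__(self) -> None:
        for acc, term in self.terms.items():
            if acc != term.acc:
                raise FormatError(f"annotation key {acc!r} != term acc {term.acc!r}")
        if self.slim is not None:
            missing = sorted(set(self.terms) - set(self.slim.mapping))
            if missing:
                raise ConfigError(f"slim mapping is not total: missing {missing[:10]}")

    def __len__(self) -> int:
        return len(self.terms)

    def accs(self) -> list[str]:
        return list(self.terms)


# ---------------------------------------------------------------------------
# headers


def _header_lines(params: dict | None) -> list[str]:
    lines = [f"# stratde_version={_version_token()}"]
    for key, val in (params or {}).items():
        lines.append(f"# {key}={val}")
    return lines


def file_checksum(path) -> str:
    """SHA-1 of a file's bytes, for provenance headers."""
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def _write_tsv(df: pd.DataFrame, path, params: dict | None, float_format: str = "%.6g") -> None:
    buf = io.StringIO()
    for line in _header_lines(params):
        buf.write(line + "\n")
    df.to_csv(buf, sep="\t", index=False, float_format=float_format)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path, library_spec: dict[str, tuple[str, str]]) -> CountTable:
    """Read a gene x library TSV of integer counts.

    ``library_spec`` assigns each non-gene column a (model, condition) pair,
    e.g. ``{"ctrl_A": ("A", "control"), ...}``. Malformed cells raise
    :class:`FormatError` citing the row and column; duplicated gene ids raise
    with the offending id and all line numbers it occupies.
    """
    raw = _read_tsv(path, dtype=str)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: need a gene id column plus at least one count column")
    gene_col = raw.columns[0]
    count_cols = list(raw.columns[1:])
    if set(count_cols) != set(library_spec):
        raise ConfigError(
            f"{path}: columns {count_cols} do not match library spec {sorted(library_spec)}"
        )
    genes = raw[gene_col]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        # +2: header line plus 1-based numbering (comment lines not counted)
        lines = [int(i) + 2 for i in genes.index[genes == dup]]
        raise FormatError(f"{path}: duplicate gene id {dup!r} on data lines {lines}")
    mat = {}
    for col in count_cols:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round()) | (converted < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-integer or negative count {raw[col].iloc[row]!r} "
                f"at data line {row + 2}, column {col!r}"
            )
        mat[col] = converted.astype(np.int64).to_numpy()
    counts = pd.DataFrame(mat, index=pd.Index(genes, name=gene_col))[count_cols]
    libraries = {lab: LibraryInfo(lab, *library_spec[lab]) for lab in count_cols}
    return CountTable(counts, libraries)


def write_count_table(table: CountTable, path, params: dict | None = None) -> None:
    df = table.counts.reset_index()
    spec = {lab: f"{info.model}:{info.condition}" for lab, info in table.libraries.items()}
    hdr = dict(params or {})
    hdr["libraries"] = ",".join(f"{k}={v}" for k, v in spec.items())
    _write_tsv(df, path, hdr)


# ---------------------------------------------------------------------------
# annotations (GMT dialect): acc <TAB> name|namespace <TAB> gene...


def read_annotation(path) -> TermAnnotation:
    terms: dict[str, Term] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected acc, name|namespace, genes...")
            acc, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {acc} has an empty gene list")
            if acc in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term acc {acc}")
            if "|" in desc:
                name, namespace = desc.rsplit("|", 1)
            else:
                name, namespace = desc, "biological_process"
            if namespace not in GO_NAMESPACES:
                raise FormatError(f"{path}:{lineno}: unknown namespace {namespace!r} for {acc}")
            terms[acc] = Term(acc, name, namespace, frozenset(genes))
    return TermAnnotation(terms)


def write_annotation(annotation: TermAnnotation, path) -> None:
    with open(path, "w") as fh:
        for acc, term in annotation.terms.items():
            genes = "\t".join(sorted(term.genes))
            fh.write(f"{acc}\t{term.name}|{term.namespace}\t{genes}\n")


def read_slim_table(path) -> SlimMapping:
    """Read a term->slim TSV: term_acc, slim_acc, slim_name, slim_namespace."""
    df = _read_tsv(path, dtype=str)
    needed = ["term_acc", "slim_acc", "slim_name", "slim_namespace"]
    if list(df.columns) != needed:
        raise FormatError(f"{path}: expected columns {needed}, got {list(df.columns)}")
    mapping = dict(zip(df["term_acc"], df["slim_acc"]))
    names = dict(zip(df["slim_acc"], df["slim_name"]))
    namespaces = dict(zip(df["slim_acc"], df["slim_namespace"]))
    return SlimMapping(mapping, names, namespaces)


def write_slim_table(slim: SlimMapping, path) -> None:
    rows = [
        {
            "term_acc": acc,
            "slim_acc": slim_acc,
            "slim_name": slim.names[slim_acc],
            "slim_namespace": slim.namespaces[slim_acc],
        }
        for acc, slim_acc in slim.mapping.items()
    ]
    _write_tsv(pd.DataFrame(rows, columns=["term_acc", "slim_acc", "slim_name", "slim_namespace"]), path, None)


# ---------------------------------------------------------------------------
# result tables

DE_COLUMNS = ["gene_id", "model", "ctrl_norm", "diab_norm", "stratum", "log2fc", "call"]
ENRICH_COLUMNS = ["acc", "name", "namespace", "k", "n", "K", "N", "p", "q"]
COMPARISON_COLUMNS = ["gene_id", "class"]


def write_de_calls(calls: pd.DataFrame, path, params: dict | None = None) -> None:
    if calls is None:
        raise ValueError("de_calls is None")
    _write_tsv(calls[DE_COLUMNS], path, params)


def read_de_calls(path) -> pd.DataFrame:
    df = _read_tsv(
        path,
        dtype={"gene_id": str, "model": str, "stratum": str, "call": str},
    )
    if df.empty:
        return pd.DataFrame(columns=DE_COLUMNS)
    if list(df.columns) != DE_COLUMNS:
        raise FormatError(f"{path}: expected columns {DE_COLUMNS}, got {list(df.columns)}")
    return df


def write_enrichment(results: pd.DataFrame, path, params: dict | None = None) -> None:
    if results is None:
        raise ValueError("enrichment result is None")
    df = results.copy()
    if "q" not in df.columns:
        df["q"] = df["p"]
    df = df[ENRICH_COLUMNS]
    buf = io.StringIO()
    for line in _header_lines(params):
        buf.write(line + "\n")
    buf.write("\t".join(ENRICH_COLUMNS) + "\n")
    for _, row in df.iterrows():
        buf.write(
            f"{row['acc']}\t{row['name']}\t{row['namespace']}\t{int(row['k'])}\t{int(row['n'])}\t"
            f"{int(row['K'])}\t{int(row['N'])}\t{row['p']:.6e}\t{row['q']:.6e}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_enrichment(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"acc": str, "name": str, "namespace": str})
    if df.empty:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    if list(df.columns) != ENRICH_COLUMNS:
        raise FormatError(f"{path}: expected columns {ENRICH_COLUMNS}, got {list(df.columns)}")
    return df


def write_comparison(comparison, path, params: dict | None = None) -> None:
    if comparison is None:
        raise ValueError("comparison is None")
    _write_tsv(comparison.classes[COMPARISON_COLUMNS], path, params)


def read_comparison(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype=str)
    if df.empty:
        return pd.DataFrame(columns=COMPARISON_COLUMNS)
    if list(df.columns) != COMPARISON_COLUMNS:
        raise FormatError(f"{path}: expected columns {COMPARISON_COLUMNS}, got {list(df.columns)}")
    return df


def write_truth_table(truth: pd.DataFrame, path, params: dict | None = None) -> None:
    _write_tsv(truth, path, params)


def read_truth_table(path) -> pd.DataFrame:
    return _read_tsv(
        path, dtype={"gene_id": str, "class_A": str, "class_B": str, "stratum": str}
    )


def write_qpcr(qpcr: pd.DataFrame, path, params: dict | None = None) -> None:
    _write_tsv(qpcr, path, params)


def read_qpcr(path) -> pd.DataFrame:
    return _read_tsv(path, dtype={"gene_id": str})
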