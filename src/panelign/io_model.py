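"""Domain types and file I/O shared by every pipeline stage.

The canonical tabular dialect is TSV; comma-separated files are accepted on
read by sniffing the delimiter. Gene identifiers are case-sensitive opaque
strings, and human and mouse namespaces are never mixed inside one
collection.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError, ValidationError

CONSENSUS_CLUSTERS = ("A", "B", "C", "D", "E", "none")

EXPRESSION_UNITS = ("raw_count", "tpm", "normalized", "log_normalized")

#: Sample annotation keys required for every sample of an ExpressionMatrix.
ANNOTATION_KEYS = ("group", "model", "age_months", "sex", "lane")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoexpressionModule:
    """A human co-expression module: a fixed gene set with provenance.

    Modules are inputs to this toolkit (they come from an upstream
    meta-analysis of post-mortem brain cohorts); ``consensus_cluster``
    groups modules from different cohorts/regions that share gene content.
    """

    module_id: str
    cohort: str
    brain_region: str
    consensus_cluster: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"module {self.module_id!r}: empty member set")
        if self.consensus_cluster not in CONSENSUS_CLUSTERS:
            raise ValidationError(
                f"module {self.module_id!r}: invalid consensus cluster "
                f"{self.consensus_cluster!r} (expected one of {CONSENSUS_CLUSTERS})"
            )

    @property
    def size(self) -> int:
        return len(self.members)


class ExpressionMatrix:
    """Gene × sample expression values with a unit tag and sample annotations.

    ``values`` is a pandas DataFrame (rows = genes, columns = samples);
    ``annotations`` is a DataFrame indexed by sample id carrying at least the
    keys in :data:`ANNOTATION_KEYS`.
    """

    def __init__(self, values: pd.DataFrame, unit: str,
                 annotations: pd.DataFrame) -> None:
        if unit not in EXPRESSION_UNITS:
            raise ContractError(f"unknown expression unit {unit!r}")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups}")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {values.index[g]!r}, "
                f"sample {values.columns[s]!r}")
        if unit != "log_normalized" and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at gene {values.index[g]!r}, "
                f"sample {values.columns[s]!r}")
        missing = [s for s in values.columns if s not in annotations.index]
        if missing:
            raise ValidationError(
                f"samples missing annotations: {missing}")
        for key in ANNOTATION_KEYS:
            if key not in annotations.columns:
                raise ValidationError(f"annotation table missing key {key!r}")
        self.values = values
        self.unit = unit
        self.annotations = annotations.loc[values.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose annotations match every ``key=value`` condition."""
        mask = pd.Series(True, index=self.annotations.index)
        for key, val in conditions.items():
            mask &= self.annotations[key].astype(str) == str(val)
        return list(self.annotations.index[mask])

    def with_values(self, values: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, unit, self.annotations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (self.unit == other.unit
                and self.values.equals(other.values)
                and self.annotations.equals(other.annotations))


class OrthologyTable:
    """One-to-one human–mouse ortholog pairs with dN/dS statistics.

    The one-to-one invariant is enforced on construction: each human gene and
    each mouse gene appears at most once.  dN/dS is undefined (NaN) exactly
    when dS = 0.
    """

    def __init__(self, pairs: pd.DataFrame) -> None:
        required = {"human_gene", "mouse_gene", "dn", "ds"}
        missing = required - set(pairs.columns)
        if missing:
            raise FormatError(f"orthology table missing columns: {sorted(missing)}")
        if pairs["human_gene"].duplicated().any():
            dup = pairs.loc[pairs["human_gene"].duplicated(), "human_gene"].iloc[0]
            raise ValidationError(f"human gene {dup!r} appears more than once")
        if pairs["mouse_gene"].duplicated().any():
            dup = pairs.loc[pairs["mouse_gene"].duplicated(), "mouse_gene"].iloc[0]
            raise ValidationError(f"mouse gene {dup!r} appears more than once")
        if (pairs["dn"] < 0).any() or (pairs["ds"] < 0).any():
            raise ValidationError("negative dN or dS value")
        pairs = pairs.copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            dnds = np.where(pairs["ds"].to_numpy() > 0,
                            pairs["dn"].to_numpy() / pairs["ds"].to_numpy(),
                            np.nan)
        pairs["dnds"] = dnds
        self.pairs = pairs.reset_index(drop=True)
        self._h2m = dict(zip(pairs["human_gene"], pairs["mouse_gene"]))
        self._m2h = dict(zip(pairs["mouse_gene"], pairs["human_gene"]))
        self._dnds = dict(zip(pairs["human_gene"], pairs["dnds"]))

    def mouse_for(self, human_gene: str) -> str | None:
        return self._h2m.get(human_gene)

    def human_for(self, mouse_gene: str) -> str | None:
        return self._m2h.get(mouse_gene)

    def dnds_for(self, human_gene: str) -> float:
        """dN/dS for a human gene; NaN when absent or undefined (dS = 0)."""
        return self._dnds.get(human_gene, math.nan)

    def __len__(self) -> int:
        return len(self.pairs)


class LogFCTable:
    """Per-gene log2 fold changes with raw and BH-adjusted p-values."""

    def __init__(self, contrast_label: str, table: pd.DataFrame) -> None:
        required = {"logfc", "p", "adj_p"}
        missing = required - set(table.columns)
        if missing:
            raise FormatError(f"logFC table missing columns: {sorted(missing)}")
        if table.index.has_duplicates:
            dup = table.index[table.index.duplicated()][0]
            raise ValidationError(f"duplicate gene {dup!r} in logFC table")
        for col in ("p", "adj_p"):
            bad = table.index[(table[col] < 0) | (table[col] > 1)]
            if len(bad):
                raise ValidationError(
                    f"{col} outside [0,1] for gene {bad[0]!r}")
        self.contrast_label = contrast_label
        self.table = table

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def logfc(self, gene: str) -> float:
        return float(self.table.at[gene, "logfc"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LogFCTable):
            return NotImplemented
        return (self.contrast_label == other.contrast_label
                and self.table.equals(other.table))


PANEL_CATEGORIES = ("key", "housekeeping", "drug_target")


@dataclass(frozen=True)
class PanelEntry:
    mouse_gene: str
    category: str
    annotated_modules: frozenset[str] = frozenset()
    probe_a: str | None = None
    probe_b: str | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in PANEL_CATEGORIES:
            raise ValidationError(
                f"entry {self.mouse_gene!r}: bad category {self.category!r}")
        if self.category == "housekeeping" and self.annotated_modules:
            raise ValidationError(
                f"housekeeping entry {self.mouse_gene!r} must not carry "
                f"module annotations")


@dataclass
class PanelDefinition:
    """A capacity-bounded probe panel: key genes + housekeeping + drug targets."""

    entries: list[PanelEntry]
    capacity: int

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise ContractError("panel capacity must be positive")
        if len(self.entries) > self.capacity:
            raise ValidationError(
                f"{len(self.entries)} entries exceed capacity {self.capacity}")
        genes = [e.mouse_gene for e in self.entries]
        if len(genes) != len(set(genes)):
            dup = next(g for g in genes if genes.count(g) > 1)
            raise ValidationError(f"duplicate panel gene {dup!r}")

    @property
    def genes(self) -> list[str]:
        return [e.mouse_gene for e in self.entries]

    def entry_for(self, mouse_gene: str) -> PanelEntry:
        for e in self.entries:
            if e.mouse_gene == mouse_gene:
                return e
        raise KeyError(mouse_gene)

    def __eq__(self, other: object) -> bool:
        # entry order is presentational; panels are compared as sets
        if not isinstance(other, PanelDefinition):
            return NotImplemented
        key = lambda e: (e.category, e.mouse_gene)
        return (self.capacity == other.capacity
                and sorted(self.entries, key=key)
                == sorted(other.entries, key=key))


class GeneSetCollection:
    """Named gene sets over a fixed universe (GMT-style)."""

    def __init__(self, universe: Iterable[str],
                 sets: Mapping[str, Iterable[str]]) -> None:
        self.universe = frozenset(universe)
        clean: dict[str, frozenset[str]] = {}
        for name, genes in sets.items():
            gs = frozenset(genes)
            if not gs:
                raise ValidationError(f"gene set {name!r} is empty")
            stray = gs - self.universe
            if stray:
                raise ValidationError(
                    f"gene set {name!r} contains genes outside the universe: "
                    f"{sorted(stray)[:5]}")
            if name in clean:
                raise ValidationError(f"duplicate gene set name {name!r}")
            clean[name] = gs
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    delim = _sniff_delimiter(text.splitlines()[0])
    return pd.read_csv(io.StringIO(text), sep=delim, dtype=str)


def read_module_table(path: str | Path) -> list[CoexpressionModule]:
    """Read a long-format module membership table.

    Columns: module_id, cohort, brain_region, consensus_cluster, gene.
    Duplicate (module_id, gene) rows collapse to one member.
    """
    df = _read_table(path)
    required = ["module_id", "cohort", "brain_region", "consensus_cluster", "gene"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    modules = []
    for mid, grp in df.groupby("module_id", sort=True):
        meta = grp.iloc[0]
        modules.append(CoexpressionModule(
            module_id=str(mid),
            cohort=str(meta["cohort"]),
            brain_region=str(meta["brain_region"]),
            consensus_cluster=str(meta["consensus_cluster"]),
            members=frozenset(grp["gene"].astype(str)),
        ))
    return modules


def write_module_table(modules: Sequence[CoexpressionModule],
                       path: str | Path) -> None:
    rows = []
    for m in sorted(modules, key=lambda m: m.module_id):
        for g in sorted(m.members):
            rows.append((m.module_id, m.cohort, m.brain_region,
                         m.consensus_cluster, g))
    df = pd.DataFrame(rows, columns=["module_id", "cohort", "brain_region",
                                     "consensus_cluster", "gene"])
    df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: str | Path, unit: str,
                           annotations_path: str | Path) -> ExpressionMatrix:
    """Read a gene × sample matrix plus its companion annotation table.

    The first matrix column holds gene ids; the annotation table is keyed by
    a ``sample`` column and must cover every matrix sample.
    """
    df = _read_table(path)
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    values = df.astype(float)
    ann = _read_table(annotations_path)
    if "sample" not in ann.columns:
        raise FormatError(f"{annotations_path}: missing required column 'sample'")
    ann = ann.set_index("sample")
    return ExpressionMatrix(values, unit, ann)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path,
                            annotations_path: str | Path | None = None) -> None:
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    if annotations_path is not None:
        ann = m.annotations.copy()
        ann.index.name = "sample"
        ann.to_csv(annotations_path, sep="\t")


def read_orthology_table(path: str | Path) -> OrthologyTable:
    df = _read_table(path)
    for col in ("human_gene", "mouse_gene", "dn", "ds"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df.astype({"dn": float, "ds": float})
    return OrthologyTable(df)


def write_orthology_table(orth: OrthologyTable, path: str | Path) -> None:
    out = orth.pairs[["human_gene", "mouse_gene", "dn", "ds"]].copy()
    out = out.sort_values("human_gene").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)


def read_logfc_table(path: str | Path, contrast_label: str | None = None) -> LogFCTable:
    df = _read_table(path)
    for col in ("gene", "logfc", "p", "adj_p"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    label = contrast_label if contrast_label is not None else Path(path).stem
    table = df.set_index("gene").astype({"logfc": float, "p": float,
                                         "adj_p": float})
    return LogFCTable(label, table[["logfc", "p", "adj_p"]])


def write_logfc_table(t: LogFCTable, path: str | Path) -> None:
    out = t.table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


RCC_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")


def read_rcc_lane(path: str | Path) -> tuple[dict[str, tuple[str, int]], dict[str, str]]:
    """Parse one nCounter RCC lane file.

    Returns ``(counts, attributes)`` where ``counts`` maps gene name to
    ``(probe_class, count)`` and ``attributes`` holds the Sample_Attributes
    key/value pairs.  Only the sectioned-text layout is supported:
    ``<Section>`` ... ``</Section>`` with a CSV ``Code_Summary`` body.
    """
    path = Path(path)
    text = path.read_text()
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("<") and line.endswith(">"):
            name = line.strip("<>")
            if name.startswith("/"):
                current = None
            else:
                current = name
                sections[current] = []
        elif current is not None and line:
            sections[current].append(line)
    if "Code_Summary" not in sections:
        raise FormatError(f"{path}: missing Code_Summary section")
    attributes: dict[str, str] = {}
    for line in sections.get("Sample_Attributes", []):
        parts = line.split(",", 1)
        if len(parts) == 2:
            attributes[parts[0]] = parts[1]
    counts: dict[str, tuple[str, int]] = {}
    rows = sections["Code_Summary"]
    header = rows[0].split(",")
    try:
        i_class = header.index("CodeClass")
        i_name = header.index("Name")
        i_count = header.index("Count")
    except ValueError as exc:
        raise FormatError(f"{path}: Code_Summary header missing {exc}") from exc
    for ln, row in enumerate(rows[1:], start=2):
        fields = row.split(",")
        raw = fields[i_count]
        try:
            count = int(raw)
        except ValueError:
            raise FormatError(
                f"{path}: non-integer count {raw!r} in Code_Summary line {ln}")
        counts[fields[i_name]] = (fields[i_class], count)
    return counts, attributes


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    """Serialize a panel deterministically (sorted by gene within category)."""
    lines = [f"#panelign-panel\tcapacity={panel.capacity}"]
    lines.append("mouse_gene\tcategory\tannotated_modules\tprobe_a\tprobe_b\tscore")
    order = {c: i for i, c in enumerate(PANEL_CATEGORIES)}
    for e in sorted(panel.entries,
                    key=lambda e: (order[e.category], e.mouse_gene)):
        mods = ",".join(sorted(e.annotated_modules))
        lines.append("\t".join([
            e.mouse_gene, e.category, mods,
            e.probe_a or "", e.probe_b or "", repr(e.score)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_panel(path: str | Path) -> PanelDefinition:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#panelign-panel"):
        raise FormatError(f"{path}: not a panel file")
    capacity = int(lines[0].split("capacity=")[1])
    entries = []
    for line in lines[2:]:
        if not line.strip():
            continue
        gene, category, mods, pa, pb, score = line.split("\t")
        entries.append(PanelEntry(
            mouse_gene=gene, category=category,
            annotated_modules=frozenset(m for m in mods.split(",") if m),
            probe_a=pa or None, probe_b=pb or None, score=float(score)))
    return PanelDefinition(entries=entries, capacity=capacity)


def read_gmt(path: str | Path,
             universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: ``name <tab> description <tab> gene...`` per line.

    When ``universe`` is None it is taken as the union of all set members.
    """
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {ln}: expected at least 3 fields")
        sets[fields[0]] = fields[2:]
    if universe is None:
        universe = set().union(*map(set, sets.values())) if sets else set()
    return GeneSetCollection(universe, sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in sorted(collection.sets):
        genes = sorted(collection.sets[name])
        lines.append("\t".join([name, "na"] + genes))
    Path(path).write_text("\n".join(lines) + "\n")
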