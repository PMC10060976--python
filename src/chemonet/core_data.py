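"""Data containers and I/O for expression cohorts, gene sets and metabolic models.

The canonical in-memory expression object is :class:`ExpressionCohort`: a
genes × samples matrix of log2-transformed expression together with a
per-sample clinical/annotation table.  Tabular formats are plain
tab-separated text; gene sets use the GMT convention; metabolic models are
read from a BiGG-dialect JSON subset (``reactions[].id``,
``reactions[].gene_reaction_rule``, ``reactions[].subsystem``,
``genes[].id``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCohort",
    "GeneSetCollection",
    "MetabolicModelSpec",
    "ReactionSpec",
    "InfiltrationTable",
    "log2_transform",
    "collapse_probes",
    "zscore_genes",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "read_metabolic_model",
    "read_sample_meta",
]

#: clinical columns recognised in sample metadata tables
META_COLUMNS = ("tissue", "donor_id", "os_time", "os_event", "stage", "grade", "response", "cluster")


class DataValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique_casefold(names: Sequence[str], what: str) -> None:
    folded = [str(n).strip().casefold() for n in names]
    if len(set(folded)) != len(folded):
        seen: dict[str, str] = {}
        for raw, f in zip(names, folded):
            if f in seen and seen[f] != raw:
                raise DataValidationError(
                    f"{what} {raw!r} collides with {seen[f]!r} after case-folding"
                )
            if f in seen:
                raise DataValidationError(f"duplicate {what} {raw!r}")
            seen[f] = raw


@dataclass
class ExpressionCohort:
    """One cohort's log2 expression matrix (genes × samples) plus sample metadata.

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns.  ``sample_meta`` is indexed by sample id; missing clinical
    fields are explicit NA, never imputed.
    """

    cohort_id: str
    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique_casefold(list(self.values.index), "gene symbol")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DataValidationError(f"duplicate sample id {dup!r}")
        if self.sample_meta is None or len(self.sample_meta) == 0:
            self.sample_meta = pd.DataFrame(index=self.values.columns)
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise DataValidationError(f"samples absent from sample_meta: {sorted(missing)[:5]}")
        if "os_event" in self.sample_meta:
            ev = self.sample_meta["os_event"].dropna()
            if not ev.isin([0, 1]).all():
                raise DataValidationError("os_event must be 0/1")
        if "os_time" in self.sample_meta:
            t = self.sample_meta["os_time"].dropna()
            if (t < 0).any():
                raise DataValidationError("os_time must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def find_genes(self, queries: Sequence[str]) -> tuple[dict[str, str], list[str]]:
        """Case-insensitive gene lookup: mapping query -> row name, plus misses."""
        index = {g.strip().casefold(): g for g in self.values.index}
        found: dict[str, str] = {}
        missing: list[str] = []
        for q in queries:
            hit = index.get(str(q).strip().casefold())
            if hit is None:
                missing.append(q)
            else:
                found[q] = hit
        return found, missing

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionCohort":
        ids = list(sample_ids)
        return ExpressionCohort(
            cohort_id=self.cohort_id,
            values=self.values.loc[:, ids].copy(),
            sample_meta=self.sample_meta.loc[ids].copy(),
        )

    def tumor_samples(self) -> list[str]:
        if "tissue" not in self.sample_meta:
            return self.samples
        return list(self.sample_meta.index[self.sample_meta["tissue"] == "tumor"])

    def normal_samples(self) -> list[str]:
        if "tissue" not in self.sample_meta:
            return []
        return list(self.sample_meta.index[self.sample_meta["tissue"] == "normal"])


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. Reactome-style signatures)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise DataValidationError(f"gene set {name!r} is empty")
            if any((not isinstance(g, str)) or not g for g in genes):
                raise DataValidationError(f"gene set {name!r} contains an empty gene symbol")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class ReactionSpec:
    reaction_id: str
    gpr: str
    subsystem: str = ""

    @property
    def has_gpr(self) -> bool:
        return bool(self.gpr.strip())


@dataclass
class MetabolicModelSpec:
    """Metabolic model skeleton: reactions with GPR rules, subsystems, gene list."""

    reactions: list[ReactionSpec]
    genes: list[str]

    def __post_init__(self) -> None:
        ids = [r.reaction_id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise DataValidationError("reaction ids not unique")
        # defer GPR grammar validation to the caller (gpr module) to avoid an import cycle
        known = set(self.genes)
        from .gpr import parse_gpr  # local import: gpr has no core_data dependency

        for r in self.reactions:
            if not r.has_gpr:
                continue
            try:
                tree = parse_gpr(r.gpr)
            except ValueError as exc:
                raise DataValidationError(f"reaction {r.reaction_id!r}: unparseable GPR ({exc})") from exc
            unknown = tree.gene_ids() - known
            if unknown:
                raise DataValidationError(
                    f"reaction {r.reaction_id!r} references unknown genes {sorted(unknown)}"
                )

    @property
    def subsystems(self) -> list[str]:
        return sorted({r.subsystem or "unassigned" for r in self.reactions})


@dataclass
class InfiltrationTable:
    """Immune-cell infiltration estimates (cell types × samples, unitless, >= 0)."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(float)).all():
            raise DataValidationError("infiltration scores must be finite")

    @property
    def cell_types(self) -> list[str]:
        return list(self.scores.index)

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)


# ---------------------------------------------------------------------------
# transforms


def log2_transform(raw: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """log2(x + 1) on a non-negative matrix; shape-preserving and monotone."""
    arr = np.asarray(raw, dtype=float)
    bad = ~np.isfinite(arr) | (arr < 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        if isinstance(raw, pd.DataFrame):
            raise DataValidationError(
                f"negative or non-finite value at gene {raw.index[i]!r}, sample {raw.columns[j]!r}"
            )
        raise DataValidationError(f"negative or non-finite value at position ({i}, {j})")
    out = np.log2(arr + 1.0)
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out


def collapse_probes(probe_matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe rows to genes by geometric mean on the linear scale.

    Probes mapping to the same gene are combined row-wise; a zero in any
    probe yields a zero geometric mean for that entry (documented
    behaviour, not an error).  Every probe must be mapped.
    """
    arr = probe_matrix.to_numpy(float)
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise DataValidationError("probe matrix must be non-negative and finite")
    unmapped = [p for p in probe_matrix.index if p not in probe_to_gene]
    if unmapped:
        raise DataValidationError(f"unmapped probes: {unmapped[:5]}")
    groups: dict[str, list[str]] = {}
    for probe in probe_matrix.index:
        groups.setdefault(probe_to_gene[probe], []).append(probe)
    rows = {}
    for gene, probes in groups.items():
        block = probe_matrix.loc[probes].to_numpy(float)
        # geometric mean via product**(1/n); exact zero propagates as zero
        rows[gene] = np.prod(block, axis=0) ** (1.0 / len(probes))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=probe_matrix.columns)
    _check_unique_casefold(list(out.index), "gene symbol")
    return out


def zscore_genes(
    cohort: ExpressionCohort, gene_panel: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score panel genes within the cohort.

    Returns the scaled panel matrix (genes × samples; each row mean 0, SD 1,
    sample SD with n−1) and a params frame (mean, sd per gene) for reuse
    when projecting cluster models onto other cohorts.
    """
    found, missing = cohort.find_genes(gene_panel)
    if missing:
        raise DataValidationError(f"panel genes absent from cohort: {missing}")
    sub = cohort.values.loc[[found[g] for g in gene_panel]]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        raise DataValidationError(f"constant panel genes (zero variance): {constant}")
    scaled = sub.sub(mean, axis=0).div(sd, axis=0)
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return scaled, params


def apply_zscore_params(matrix: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Scale a panel matrix with previously fitted per-gene mean/SD."""
    return matrix.sub(params["mean"], axis=0).div(params["sd"], axis=0)


# ---------------------------------------------------------------------------
# I/O


def read_expression_matrix(path: str | Path, transposed: bool = False) -> pd.DataFrame:
    """Read a tab-separated expression matrix (first column = gene ids).

    With ``transposed=True`` the file is samples × genes and is flipped to
    the canonical genes × samples orientation.  Ragged rows and duplicate
    header ids are rejected with the offending line number.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise DataValidationError(f"{path}: empty file")
    header = lines[0].split("\t")
    ncol = len(header)
    ids = header[1:]
    if len(set(ids)) != len(ids):
        dup = next(x for x in ids if ids.count(x) > 1)
        raise DataValidationError(f"{path}:1: duplicate header id {dup!r}")
    index, data = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != ncol:
            raise DataValidationError(
                f"{path}:{lineno}: expected {ncol} fields, found {len(fields)}"
            )
        index.append(fields[0])
        data.append([float(x) for x in fields[1:]])
    df = pd.DataFrame(data, index=index, columns=ids, dtype=float)
    if transposed:
        df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataValidationError(f"{path}: duplicate row id {dup!r}")
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write counterpart of :func:`read_expression_matrix` (round-trips via repr)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["gene", *map(str, df.columns)]) + "\n")
        for gene, row in zip(df.index, df.to_numpy()):
            fh.write(str(gene) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated clinical/annotation table keyed by sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise DataValidationError(f"{path}: duplicate sample id in metadata")
    return df


def write_sample_meta(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file: name TAB description TAB gene TAB gene ..."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise DataValidationError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise DataValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=source or str(path))


def read_metabolic_model(path: str | Path) -> MetabolicModelSpec:
    """Read a BiGG-dialect JSON metabolic model subset.

    Reactions with an empty ``gene_reaction_rule`` are retained and flagged
    (``has_gpr`` False); they are excluded from regulation inference.
    """
    with Path(path).open() as fh:
        doc = json.load(fh)
    if "reactions" not in doc or "genes" not in doc:
        raise DataValidationError(f"{path}: JSON must contain 'reactions' and 'genes' arrays")
    genes = [g["id"] for g in doc["genes"]]
    reactions = [
        ReactionSpec(
            reaction_id=r["id"],
            gpr=r.get("gene_reaction_rule", "") or "",
            subsystem=r.get("subsystem", "") or "",
        )
        for r in doc["reactions"]
    ]
    return MetabolicModelSpec(reactions=reactions, genes=genes)


def write_metabolic_model(model: MetabolicModelSpec, path: str | Path) -> None:
    doc = {
        "reactions": [
            {"id": r.reaction_id, "gene_reaction_rule": r.gpr, "subsystem": r.subsystem}
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in model.genes],
    }
    with Path(path).open("w") as fh:
        json.dump(doc, fh, indent=1)
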