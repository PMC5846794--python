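"""Readers, writers and validated in-memory containers for every external file
the pipeline touches.

All delimited files are tab-separated by default (``sep`` override available).
Gene symbols are uppercased at ingestion everywhere: downstream matching of
assay analytes to gene sets, networks and tissue tables is done by symbol, and
case mismatches are the dominant silent-failure mode of that kind of join.

Aptamer panels routinely contain analytes that recognise several paralogous
proteins (e.g. a single reagent for the fibrinogen chains FGA/FGB/FGG); such
analytes map one assay id to a *list* of symbols and count as present in a set
whenever any mapped symbol matches.  Analytes with no annotation are retained
for classification but excluded from all symbol-based analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("signet")

VALID_CLASSES = ("control", "affected")


class ValidationError(ValueError):
    """An input file violated a structural invariant."""


class ParseError(ValueError):
    """An input file could not be parsed; the message names the offending cell/line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Subjects x proteins abundance matrix with phenotype annotations.

    Parameters
    ----------
    subject_ids : sequence of unique subject identifiers (matrix row order).
    protein_ids : sequence of unique assay identifiers (matrix column order).
    values : (n_subjects, n_proteins) array of positive abundances
        (relative fluorescence-like units).
    gene_map : assay id -> list of uppercase gene symbols (possibly empty for
        unannotated analytes).
    class_labels : per-subject label in {"control", "affected"}.
    ages : per-subject age in years (nonnegative).
    treated : per-subject boolean treatment flag (meaningful for affected).
    """

    subject_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray
    gene_map: dict[str, list[str]]
    class_labels: np.ndarray
    ages: np.ndarray
    treated: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        self.ages = np.asarray(self.ages, dtype=float)
        self.treated = np.asarray(self.treated, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n_s, n_p = len(self.subject_ids), len(self.protein_ids)
        if len(set(self.subject_ids)) != n_s:
            raise ValidationError("duplicate subject identifiers")
        if len(set(self.protein_ids)) != n_p:
            raise ValidationError("duplicate protein identifiers")
        if self.values.shape != (n_s, n_p):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{n_s} subjects x {n_p} proteins"
            )
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValidationError(
                f"missing value at subject {self.subject_ids[i]!r}, "
                f"protein {self.protein_ids[j]!r}"
            )
        if (self.values <= 0).any():
            i, j = np.argwhere(self.values <= 0)[0]
            raise ValidationError(
                f"non-positive abundance at subject {self.subject_ids[i]!r}, "
                f"protein {self.protein_ids[j]!r}"
            )
        bad = set(self.class_labels) - set(VALID_CLASSES)
        if bad:
            raise ValidationError(f"class labels outside {VALID_CLASSES}: {sorted(bad)}")
        if (self.ages < 0).any() or np.isnan(self.ages).any():
            raise ValidationError("ages must be nonnegative and complete")
        if self.class_labels.shape != (n_s,) or self.ages.shape != (n_s,) or self.treated.shape != (n_s,):
            raise ValidationError("phenotype arrays must have one entry per subject")

    # -- convenience views ------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def class_mask(self, label: str) -> np.ndarray:
        return self.class_labels == label

    def genes_for(self, protein_ids: Iterable[str]) -> list[str]:
        """Unique uppercase gene symbols mapped by the given assay ids (order-preserving)."""
        seen: dict[str, None] = {}
        for pid in protein_ids:
            for g in self.gene_map.get(pid, []):
                seen.setdefault(g, None)
        return list(seen)

    def mapped_genes(self) -> list[str]:
        """All unique gene symbols covered by the assay (the symbol background)."""
        return self.genes_for(self.protein_ids)

    def subset_subjects(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return ExpressionDataset(
            subject_ids=[self.subject_ids[i] for i in idx],
            protein_ids=list(self.protein_ids),
            values=self.values[idx],
            gene_map=dict(self.gene_map),
            class_labels=self.class_labels[idx],
            ages=self.ages[idx],
            treated=self.treated[idx],
        )


@dataclass
class GeneSetCollection:
    """Named sets of uppercase gene symbols."""

    sets: dict[str, frozenset[str]]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            fs = frozenset(str(m).upper() for m in members)
            if not fs:
                raise ValidationError(f"gene set {name!r} is empty")
            if name in clean:
                raise ValidationError(f"duplicate gene set name {name!r}")
            clean[name] = fs
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class InteractionNetwork:
    """Gene-symbol interaction graph (directed signaling or undirected physical).

    ``is_tf`` and ``is_de`` flag transcription factors and differentially
    abundant nodes; every flagged node must exist in the node set.
    """

    nodes: set[str]
    edges: set[tuple[str, str]]
    directed: bool
    is_tf: set[str] = field(default_factory=set)
    is_de: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = {str(n).upper() for n in self.nodes}
        norm = set()
        for u, v in self.edges:
            u, v = str(u).upper(), str(v).upper()
            if u == v:
                continue  # self-loops are dropped at construction
            norm.add((u, v) if self.directed else tuple(sorted((u, v))))
        self.edges = norm
        for u, v in self.edges:
            self.nodes.add(u)
            self.nodes.add(v)
        self.is_tf = {str(t).upper() for t in self.is_tf}
        self.is_de = {str(d).upper() for d in self.is_de}
        missing = (self.is_tf | self.is_de) - self.nodes
        if missing:
            raise ValidationError(f"flagged nodes absent from network: {sorted(missing)[:5]}")

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class TissueExpressionTable:
    """Genes x tissues nonnegative expression values with a detection threshold.

    The threshold is in the same (transcript-abundance) units as the values;
    the conventional 1.0 cutoff is the default used by the tissue categorizer.
    """

    genes: list[str]
    tissues: list[str]
    values: np.ndarray
    detection_threshold: float = 1.0

    def __post_init__(self) -> None:
        self.genes = [str(g).upper() for g in self.genes]
        self.tissues = [str(t) for t in self.tissues]
        self.values = np.asarray(self.values, dtype=float)
        if len(self.tissues) < 2:
            raise ValidationError("tissue table needs at least 2 tissues")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene symbols in tissue table")
        if self.values.shape != (len(self.genes), len(self.tissues)):
            raise ValidationError("tissue matrix shape does not match gene/tissue lists")
        if np.isnan(self.values).any() or (self.values < 0).any():
            raise ValidationError("tissue expression values must be nonnegative and complete")


# ---------------------------------------------------------------------------
# Expression matrix + phenotype + annotation
# ---------------------------------------------------------------------------


def read_expression(
    matrix_path: str | Path,
    phenotype_path: str | Path,
    annotation_path: str | Path,
    sep: str = "\t",
) -> ExpressionDataset:
    """Read an abundance matrix, its phenotype table and its assay annotation.

    The matrix has a header row of protein ids and a first column of subject
    ids.  The phenotype table has columns ``subject``, ``class``, ``age``,
    ``treated``.  The annotation table has columns ``assay_id``, ``uniprot``,
    ``gene_symbols`` (semicolon-separated, may be empty).
    """
    try:
        mat = pd.read_csv(matrix_path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot parse expression matrix {matrix_path}: {exc}") from exc
    for col in mat.columns:
        bad = pd.to_numeric(mat[col], errors="coerce")
        if bad.isna().any():
            row = mat.index[bad.isna()][0]
            raise ParseError(
                f"non-numeric abundance at row {row!r}, column {col!r} in {matrix_path}"
            )
        mat[col] = bad

    pheno = pd.read_csv(
        phenotype_path, sep=sep, dtype={"subject": str}, float_precision="round_trip"
    )
    required = {"subject", "class", "age", "treated"}
    if not required.issubset(pheno.columns):
        raise ParseError(
            f"phenotype table missing columns {sorted(required - set(pheno.columns))}"
        )
    pheno = pheno.set_index("subject")
    missing = [s for s in mat.index.astype(str) if s not in pheno.index]
    if missing:
        raise ValidationError(f"subjects absent from phenotype table: {missing[:5]}")
    pheno = pheno.loc[mat.index.astype(str)]
    labels = pheno["class"].astype(str).str.lower().to_numpy()
    bad = set(labels) - set(VALID_CLASSES)
    if bad:
        raise ValidationError(f"class values outside {VALID_CLASSES}: {sorted(bad)}")
    treated = pheno["treated"].map(_parse_bool).to_numpy(dtype=bool)

    gene_map = read_annotation(annotation_path, sep=sep)
    unknown = [p for p in mat.columns.astype(str) if p not in gene_map]
    if unknown:
        raise ValidationError(f"proteins absent from annotation table: {unknown[:5]}")

    return ExpressionDataset(
        subject_ids=list(mat.index.astype(str)),
        protein_ids=list(mat.columns.astype(str)),
        values=mat.to_numpy(dtype=float),
        gene_map={p: gene_map[p] for p in mat.columns.astype(str)},
        class_labels=labels,
        ages=pheno["age"].to_numpy(dtype=float),
        treated=treated,
    )


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ParseError(f"cannot parse boolean value {x!r} in phenotype 'treated' column")


def read_annotation(path: str | Path, sep: str = "\t") -> dict[str, list[str]]:
    ann = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if not {"assay_id", "gene_symbols"}.issubset(ann.columns):
        raise ParseError("annotation table must have columns assay_id, gene_symbols")
    gene_map: dict[str, list[str]] = {}
    for _, row in ann.iterrows():
        pid = str(row["assay_id"])
        if pid in gene_map:
            raise ValidationError(f"duplicate assay id {pid!r} in annotation")
        syms = [s.strip().upper() for s in str(row["gene_symbols"]).split(";") if s.strip()]
        gene_map[pid] = syms
    return gene_map


def write_expression(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    phenotype_path: str | Path,
    annotation_path: str | Path,
    sep: str = "\t",
) -> None:
    pd.DataFrame(
        dataset.values, index=dataset.subject_ids, columns=dataset.protein_ids
    ).to_csv(matrix_path, sep=sep, index_label="subject", float_format="%.17g")
    pd.DataFrame(
        {
            "subject": dataset.subject_ids,
            "class": dataset.class_labels,
            "age": dataset.ages,
            "treated": dataset.treated,
        }
    ).to_csv(phenotype_path, sep=sep, index=False, float_format="%.17g")
    pd.DataFrame(
        {
            "assay_id": dataset.protein_ids,
            "uniprot": ["" for _ in dataset.protein_ids],
            "gene_symbols": [";".join(dataset.gene_map[p]) for p in dataset.protein_ids],
        }
    ).to_csv(annotation_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, source: str = "synthetic") -> GeneSetCollection:
    """Read a standard GMT file: name, description, tab-separated member symbols.

    Member symbols are uppercased and duplicates within a set collapsed.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"GMT line {lineno} has {len(fields)} fields (need >=3)")
            name = fields[0]
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r} at line {lineno}")
            members = frozenset(f.strip().upper() for f in fields[2:] if f.strip())
            if not members:
                raise ParseError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets, source=source)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            fh.write("\t".join([name, collection.source, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Interaction networks
# ---------------------------------------------------------------------------


def read_network(
    path: str | Path,
    directed: bool,
    tf_list_path: str | Path | None = None,
    sep: str = "\t",
) -> InteractionNetwork:
    """Read a 2-column edge list (a 3rd relation-tag column is ignored).

    Self-loops are dropped with a logged count.  TF symbols absent from the
    network trigger a warning and are ignored.
    """
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    n_self = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(sep)
            if len(fields) < 2:
                raise ParseError(f"edge list line {lineno} has fewer than 2 columns")
            u, v = fields[0].strip().upper(), fields[1].strip().upper()
            if not u or not v:
                raise ParseError(f"empty node name at edge list line {lineno}")
            n_lines += 1
            if u == v:
                n_self += 1
                continue
            nodes.update((u, v))
            edges.add((u, v) if directed else tuple(sorted((u, v))))
    if n_lines == 0:
        raise ValidationError(f"edge file {path} contains no edges")
    if n_self:
        logger.info("dropped %d self-loop edge(s) from %s", n_self, path)

    tfs: set[str] = set()
    if tf_list_path is not None:
        with open(tf_list_path) as fh:
            wanted = {line.strip().upper() for line in fh if line.strip()}
        absent = wanted - nodes
        if absent:
            logger.warning(
                "%d TF symbol(s) absent from network, flag ignored: %s",
                len(absent),
                sorted(absent)[:5],
            )
        tfs = wanted & nodes
    return InteractionNetwork(nodes=nodes, edges=edges, directed=directed, is_tf=tfs)


def write_network(
    network: InteractionNetwork,
    path: str | Path,
    tf_list_path: str | Path | None = None,
    sep: str = "\t",
) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(network.edges):
            fh.write(f"{u}{sep}{v}\n")
    if tf_list_path is not None:
        with open(tf_list_path, "w") as fh:
            for t in sorted(network.is_tf):
                fh.write(t + "\n")


# ---------------------------------------------------------------------------
# Tissue expression table
# ---------------------------------------------------------------------------


def read_tissue_table(
    path: str | Path, detection_threshold: float = 1.0, sep: str = "\t"
) -> TissueExpressionTable:
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ParseError(f"non-numeric tissue expression at gene {row!r}, tissue {col!r}")
        df[col] = vals
    return TissueExpressionTable(
        genes=list(df.index.astype(str)),
        tissues=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        detection_threshold=detection_threshold,
    )


def write_tissue_table(table: TissueExpressionTable, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(table.values, index=table.genes, columns=table.tissues).to_csv(
        path, sep=sep, index_label="gene", float_format="%.17g"
    )


def read_gene_list(path: str | Path) -> list[str]:
    """One uppercase symbol per line (TF lists, pathway gene lists, backgrounds)."""
    with open(path) as fh:
        out = [line.strip().upper() for line in fh if line.strip()]
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(str(g).upper() + "\n")
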