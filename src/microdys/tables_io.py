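"""Count-table / metadata / phylogeny I/O and sample-inclusion rules.

The central container is :class:`CountTable`: a non-negative integer
taxon-by-sample matrix with optional taxonomy lineages (kingdom → species).
The TSV dialect is the classic OTU-table layout — taxa as rows, first column
``#TaxonID``, samples as columns; an optional trailing ``taxonomy`` column
holds semicolon-separated lineages.  BIOM-JSON 1.0 is accepted read-only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from microdys._errors import EmptyResultError, FormatError

logger = logging.getLogger(__name__)

#: Taxonomic ranks in lineage order, most to least inclusive.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Culture threshold (CFU/mL) defining small intestinal bacterial overgrowth.
SIBO_CFU_THRESHOLD = 1e5

#: Label used for taxa whose lineage is unassigned at the collapse rank.
UNCLASSIFIED = "unclassified"


@dataclass
class CountTable:
    """Taxon x sample integer count matrix with optional taxonomy.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer matrix, rows indexed by taxon ID, columns by sample ID.
    taxonomy : pandas.DataFrame, optional
        One row per taxon (same index as ``counts``); columns are a prefix
        of :data:`RANKS`.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            raise FormatError("duplicate taxon IDs in count table")
        if counts.columns.has_duplicates:
            raise FormatError("duplicate sample IDs in count table")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("count table contains non-integer cells")
            counts = counts.round().astype(np.int64)
            object.__setattr__(self, "counts", counts)
        if (counts.to_numpy() < 0).any():
            raise FormatError("count table contains negative values")
        if self.taxonomy is not None:
            tax = self.taxonomy
            if not tax.index.equals(counts.index):
                tax = tax.reindex(counts.index)
                if tax.isna().all(axis=1).any():
                    raise FormatError("taxonomy does not cover every taxon")
                object.__setattr__(self, "taxonomy", tax)
            bad = [c for c in tax.columns if c not in RANKS]
            if bad:
                raise FormatError(f"unknown taxonomy ranks: {bad}")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample read depth (column sums)."""
        return self.counts.sum(axis=0)

    def proportions(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        depths = self.depths()
        if (depths == 0).any():
            raise FormatError("cannot compute proportions with all-zero samples")
        return self.counts / depths

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts[list(sample_ids)], self.taxonomy)


def read_count_table(path, orientation: str = "taxa_rows") -> CountTable:
    """Read a count table from classic TSV or BIOM-JSON 1.0.

    Parameters
    ----------
    path : path-like
        Input file.  Files ending in ``.biom`` or whose first byte is ``{``
        are parsed as BIOM-JSON; everything else as tab-separated text with
        a header row.
    orientation : {"taxa_rows", "samples_rows"}
        Layout of the TSV (ignored for BIOM, which is self-describing).
    """
    path = Path(path)
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    head = path.read_text().lstrip()[:1]
    if path.suffix == ".biom" or head == "{":
        return _read_biom_json(path)

    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    taxonomy = None
    if "taxonomy" in df.columns:
        lineages = df.pop("taxonomy")
        taxonomy = parse_lineages(lineages)
    if orientation == "samples_rows":
        df = df.T
    try:
        numeric = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in count table: {exc}") from exc
    if not np.allclose(numeric.to_numpy(), np.round(numeric.to_numpy())):
        raise FormatError("count table contains non-integer cells")
    counts = numeric.round().astype(np.int64)
    counts.index.name = None
    counts.columns.name = None
    if orientation == "samples_rows" and taxonomy is not None:
        taxonomy = None  # taxonomy column only meaningful for taxa-rows layout
    return CountTable(counts, taxonomy)


def _read_biom_json(path: Path) -> CountTable:
    """Parse a (dense or sparse) BIOM-JSON 1.0 table."""
    doc = json.loads(path.read_text())
    if doc.get("format", "").startswith("Biological Observation Matrix") is False and (
        "rows" not in doc or "columns" not in doc
    ):
        raise FormatError("not a BIOM-JSON 1.0 document")
    taxon_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_r, n_c = len(taxon_ids), len(sample_ids)
    mat = np.zeros((n_r, n_c))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    counts = pd.DataFrame(mat, index=taxon_ids, columns=sample_ids)
    taxonomy = None
    lineages = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        lin = md.get("taxonomy")
        if lin:
            lineages[r["id"]] = ";".join(lin) if isinstance(lin, list) else str(lin)
    if lineages:
        taxonomy = parse_lineages(pd.Series(lineages).reindex(taxon_ids))
    return CountTable(counts, taxonomy)


def parse_lineages(lineages: pd.Series) -> pd.DataFrame:
    """Split semicolon-separated lineage strings into rank columns."""
    split = lineages.fillna("").astype(str).str.split(";", expand=True)
    split = split.apply(lambda col: col.str.strip())
    n = split.shape[1]
    if n > len(RANKS):
        raise FormatError(f"lineages have more than {len(RANKS)} ranks")
    split.columns = list(RANKS[:n])
    return split.replace("", np.nan)


def write_count_table(table: CountTable, path) -> None:
    """Write the classic taxa-rows TSV (round-trips with read_count_table)."""
    df = table.counts.copy()
    df.index.name = "#TaxonID"
    if table.taxonomy is not None:
        df["taxonomy"] = table.taxonomy.apply(
            lambda row: ";".join("" if pd.isna(v) else str(v) for v in row), axis=1
        )
    df.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read tab-separated per-sample metadata (first column = sample ID).

    ``group`` must be present and non-missing for every sample; other
    covariates may contain missing values (downstream analyses do listwise
    deletion and log the n actually used).
    """
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise FormatError("duplicate sample IDs in metadata")
    if "group" not in meta.columns:
        raise FormatError("metadata must contain a 'group' column")
    if meta["group"].isna().any():
        raise FormatError("metadata 'group' column has missing values")
    if "sibo_cfu" in meta.columns:
        cfu = meta["sibo_cfu"].dropna()
        if (cfu < 0).any():
            raise FormatError("sibo_cfu must be non-negative")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "#SampleID"
    out.to_csv(path, sep="\t")


def filter_low_depth(table: CountTable, min_reads: int = 1000) -> CountTable:
    """Drop samples with read depth strictly below ``min_reads``.

    The exclusion rule is strict (< min_reads): a sample with exactly
    ``min_reads`` reads is retained.  Removed sample IDs are logged.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    depths = table.depths()
    keep = depths >= min_reads
    dropped = list(depths.index[~keep])
    if dropped:
        logger.info("filter_low_depth: removed %d samples: %s", len(dropped), dropped)
    if not keep.any():
        raise EmptyResultError("all samples below the read-depth threshold")
    return CountTable(table.counts.loc[:, keep], table.taxonomy)


def collapse_to_rank(table: CountTable, rank: str) -> CountTable:
    """Sum counts over taxa sharing the same lineage truncated at ``rank``.

    Taxa with an unassigned lineage at ``rank`` are pooled into a labelled
    ``unclassified`` bin so per-sample depth is conserved.
    """
    if table.taxonomy is None:
        raise FormatError("collapse_to_rank requires taxonomy")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if rank not in table.taxonomy.columns:
        raise FormatError(f"rank {rank!r} absent from taxonomy")
    # taxonomy may carry only a subset of ranks (e.g. kingdom/phylum/genus)
    upto = [r for r in RANKS[: RANKS.index(rank) + 1] if r in table.taxonomy.columns]
    tax = table.taxonomy[upto]

    def label(row) -> str:
        if pd.isna(row[rank]) or row[rank] == UNCLASSIFIED:
            return UNCLASSIFIED
        return ";".join("" if pd.isna(v) else str(v) for v in row)

    keys = tax.apply(label, axis=1)
    collapsed = table.counts.groupby(keys, sort=True).sum()
    new_tax = pd.DataFrame(
        [k.split(";") if k != UNCLASSIFIED else [np.nan] * len(upto) for k in collapsed.index],
        index=collapsed.index,
        columns=upto,
    )
    return CountTable(collapsed, new_tax)


def classify_sibo(cfu: float) -> str:
    """Classify a quantitative aspirate culture result.

    Positive iff total growth is at or above 1e5 CFU/mL (inclusive
    boundary).
    """
    if cfu < 0 or not np.isfinite(cfu):
        raise ValueError("CFU/mL must be a non-negative finite number")
    return "positive" if cfu >= SIBO_CFU_THRESHOLD else "negative"


def read_tree(path) -> TreeNode:
    """Read a rooted Newick phylogeny; reject negative branch lengths."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"could not parse Newick file: {exc}") from exc
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError(f"negative branch length on node {node.name!r}")
    return tree


def check_tree_taxa(tree: TreeNode, taxon_ids) -> set[str]:
    """Warn (and return) the symmetric difference of tree tips vs taxa."""
    tips = {t.name for t in tree.tips()}
    taxa = set(taxon_ids)
    diff = tips.symmetric_difference(taxa)
    if diff:
        logger.warning(
            "tree tips and table taxa differ; symmetric difference: %s",
            sorted(diff),
        )
    return diff
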