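"""Taxonomic read-count containers, report parsing, and abundance filters.

The in-memory model mirrors Kraken-style rank-coded taxonomy: every node
carries *clade* reads (assigned to the node or anything below it) and
*direct* reads (assigned to exactly that node), per sample.  Count tables
are taxa x samples at a fixed rank; all downstream modules consume these
types.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Standard ranks from the top of the taxonomy down.  "root" sits above
#: "domain"; Kraken sub-ranks (D1, G2, ...) are treated as "no rank".
RANK_ORDER = (
    "root",
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_CODE_TO_RANK = {
    "R": "root",
    "D": "domain",
    "P": "phylum",
    "C": "class",
    "O": "order",
    "F": "family",
    "G": "genus",
    "S": "species",
    "U": "unclassified",
    "-": "no rank",
}

NO_RANK = "no rank"


class FormatError(ValueError):
    """Malformed input file (structure, duplicates, unparseable cells)."""


class ValidationError(ValueError):
    """Well-formed input violating a semantic contract (negative counts, ...)."""


def rank_index(rank: str) -> int:
    """Position of ``rank`` in the standard order (root=0 ... species=7)."""
    return RANK_ORDER.index(rank)


def parse_rank_code(code: str) -> str:
    """Map a Kraken report rank code to a full rank name.

    Single letters follow the report convention; suffixed sub-rank codes
    (``D1``, ``G2``...) and kingdom (``K``) map to ``"no rank"``.  Codes
    outside the known set are retained as ``"no rank"`` with a warning.
    """
    if code in _CODE_TO_RANK:
        return _CODE_TO_RANK[code]
    if len(code) >= 2 and code[0] in _CODE_TO_RANK and code[1:].isdigit():
        return NO_RANK
    if code == "K":  # kingdom: between domain and phylum, not a standard rank here
        return NO_RANK
    warnings.warn(f"unknown rank code {code!r}; node retained with rank 'no rank'")
    return NO_RANK


# ---------------------------------------------------------------------------
# Tree types
# ---------------------------------------------------------------------------


@dataclass
class TaxonNode:
    """One taxon with per-sample clade and direct read counts.

    ``clade`` and ``direct`` are float arrays of shape (n_samples,);
    post-decontamination counts are real-valued, so floats throughout.
    """

    taxon_id: int
    name: str
    rank: str
    clade: np.ndarray
    direct: np.ndarray
    parent: "TaxonNode | None" = None
    children: list["TaxonNode"] = field(default_factory=list)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TaxonNode({self.taxon_id}, {self.name!r}, {self.rank}, clade={self.clade})"

    def descendants(self) -> Iterable["TaxonNode"]:
        stack = list(self.children)
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)


@dataclass
class TaxonomyTree:
    """Rooted rank-coded taxonomy holding per-sample read counts."""

    root: TaxonNode
    samples: list[str]
    unclassified: np.ndarray | None = None

    def nodes(self) -> Iterable[TaxonNode]:
        yield self.root
        yield from self.root.descendants()

    def nodes_at_rank(self, rank: str) -> list[TaxonNode]:
        return [n for n in self.nodes() if n.rank == rank]

    def find(self, name: str) -> TaxonNode | None:
        for n in self.nodes():
            if n.name == name:
                return n
        return None

    def validate(self, tol: float = 1e-9) -> None:
        """Check clade >= direct and clade = direct + sum(children clade)."""
        bad: list[int] = []
        for node in self.nodes():
            if np.any(node.clade < node.direct - tol):
                raise ValidationError(
                    f"taxid {node.taxon_id}: clade reads below direct reads"
                )
            child_sum = sum((c.clade for c in node.children), np.zeros(len(self.samples)))
            if np.any(np.abs(node.clade - node.direct - child_sum) > max(tol, 1e-6)):
                bad.append(node.taxon_id)
        if bad:
            raise ValidationError(f"inconsistent clade sums at taxids {bad}")

    def copy(self) -> "TaxonomyTree":
        def clone(node: TaxonNode, parent: TaxonNode | None) -> TaxonNode:
            new = TaxonNode(
                node.taxon_id,
                node.name,
                node.rank,
                node.clade.copy(),
                node.direct.copy(),
                parent,
            )
            new.children = [clone(c, new) for c in node.children]
            return new

        return TaxonomyTree(
            clone(self.root, None),
            list(self.samples),
            None if self.unclassified is None else self.unclassified.copy(),
        )


# ---------------------------------------------------------------------------
# Count table
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Taxa x samples count matrix at a fixed taxonomic rank.

    ``data`` is a pandas DataFrame with taxon names as the index and sample
    ids as columns.  Counts are non-negative reals (integers for raw data,
    fractions after decontamination adjustment).
    """

    data: pd.DataFrame
    rank: str = "genus"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxa: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate samples: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric counts in table")
        if np.any(~np.isfinite(values)):
            raise ValidationError("non-finite counts in table")
        if np.any(values < 0):
            raise ValidationError("negative counts in table")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def copy(self) -> "CountTable":
        return CountTable(self.data.copy(), self.rank)

    def to_tsv(self, path, round_counts: bool = False) -> None:
        out = self.data.round(0).astype(np.int64) if round_counts else self.data
        out.to_csv(path, sep="\t", index_label="taxon")


def read_count_table(path, rank: str = "genus") -> CountTable:
    """Read a taxa x samples TSV (first column: taxon names; gzip ok)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty file")
        columns = header.rstrip("\n").split("\t")[1:]
        if len(columns) != len(set(columns)):
            raise FormatError(f"{path}: duplicated sample column")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: non-numeric values in column {col!r}")
    return CountTable(df, rank)


def read_long_count_table(path, rank: str = "genus") -> CountTable:
    """Read a long-format TSV with columns (taxon, sample, count)."""
    df = pd.read_csv(path, sep="\t")
    required = {"taxon", "sample", "count"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: long format needs columns {sorted(required)}")
    if df.duplicated(["taxon", "sample"]).any():
        raise FormatError(f"{path}: duplicate (taxon, sample) entries")
    wide = df.pivot(index="taxon", columns="sample", values="count").fillna(0.0)
    wide.columns.name = None
    wide.index.name = None
    return CountTable(wide, rank)


def write_count_table(table: CountTable, path, round_counts: bool = False) -> None:
    table.to_tsv(path, round_counts=round_counts)


# ---------------------------------------------------------------------------
# Kraken-style report parsing
# ---------------------------------------------------------------------------


def read_kraken_report(path, sample_id: str | None = None) -> TaxonomyTree:
    """Parse a 6-column Kraken2 report into a single-sample taxonomy tree.

    Columns: percent, clade reads, direct reads, rank code, taxid, name
    (two-space indentation per depth level).  The clade-sum identity
    ``clade = direct + sum(children clade)`` is validated on the result.
    """
    sample = sample_id if sample_id is not None else str(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    root: TaxonNode | None = None
    unclassified = np.zeros(1)
    stack: list[tuple[int, TaxonNode]] = []  # (depth, node)
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                parts = line.split(None, 5)
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            _, clade_s, direct_s, code, taxid_s, raw_name = parts[:6]
            try:
                clade = float(clade_s)
                direct = float(direct_s)
                taxid = int(taxid_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if clade < direct:
                raise ValidationError(
                    f"{path}:{lineno}: taxid {taxid} clade reads < direct reads"
                )
            depth = (len(raw_name) - len(raw_name.lstrip(" "))) // 2
            name = raw_name.strip()
            rank = parse_rank_code(code)
            if rank == "unclassified" or taxid == 0:
                unclassified = np.array([clade])
                continue
            node = TaxonNode(taxid, name, rank, np.array([clade]), np.array([direct]))
            while stack and stack[-1][0] >= depth:
                stack.pop()
            if stack:
                parent = stack[-1][1]
                node.parent = parent
                parent.children.append(node)
            elif root is None:
                root = node
            else:
                raise FormatError(f"{path}:{lineno}: multiple top-level taxa")
            stack.append((depth, node))
    if root is None:
        root = TaxonNode(1, "root", "root", np.zeros(1), np.zeros(1))
    tree = TaxonomyTree(root, [sample], unclassified)
    tree.validate()
    return tree


def aggregate_to_rank(tree: TaxonomyTree, rank: str) -> CountTable:
    """One row per node at ``rank``; counts are clade reads per sample."""
    nodes = tree.nodes_at_rank(rank)
    if not nodes:
        warnings.warn(f"rank {rank!r} absent from tree; returning empty table")
        return CountTable(pd.DataFrame(columns=tree.samples, dtype=float), rank)
    names: list[str] = []
    seen: set[str] = set()
    for n in nodes:
        name = n.name if n.name not in seen else f"{n.name}|{n.taxon_id}"
        seen.add(name)
        names.append(name)
    data = pd.DataFrame(
        np.vstack([n.clade for n in nodes]), index=names, columns=tree.samples
    )
    return CountTable(data, rank)


def combine_tables(tables: Sequence[CountTable]) -> CountTable:
    """Outer-join single-sample tables (e.g. per-report) on taxa; fill 0."""
    if not tables:
        raise ValueError("no tables to combine")
    rank = tables[0].rank
    df = pd.concat([t.data for t in tables], axis=1).fillna(0.0)
    return CountTable(df, rank)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_min_depth(table: CountTable, min_reads: int) -> CountTable:
    """Drop samples whose total assigned reads fall below ``min_reads``.

    The convention is strict: a sample with exactly ``min_reads`` is kept
    ("less than N reads were excluded").
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = table.sample_totals()
    keep = totals[totals >= min_reads].index
    if len(keep) == 0:
        logger.warning("filter_min_depth: no samples reach %d reads", min_reads)
    return CountTable(table.data.loc[:, keep], table.rank)


def filter_prevalence(table: CountTable, min_prevalence: float) -> CountTable:
    """Drop taxa present (count > 0) in less than ``min_prevalence`` of samples."""
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in [0, 1]")
    if table.data.shape[1] == 0:
        return table.copy()
    prevalence = (table.data > 0).mean(axis=1)
    keep = prevalence[prevalence >= min_prevalence].index
    return CountTable(table.data.loc[keep], table.rank)


def filter_survival_abundance(
    table: CountTable, min_reads: int = 50, min_sample_fraction: float = 0.10
) -> CountTable:
    """Keep taxa with >= ``min_reads`` in >= ``min_sample_fraction`` of samples.

    Defaults follow the RNA-seq rule (50 reads in 10% of samples); DNA
    platforms relax ``min_reads`` to 10.
    """
    if min_reads <= 0 or min_sample_fraction <= 0:
        raise ValueError("thresholds must be positive")
    frac = (table.data >= min_reads).mean(axis=1)
    keep = frac[frac >= min_sample_fraction].index
    return CountTable(table.data.loc[keep], table.rank)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "tissue",
    "platform",
    "study_site",
    "batch",
    "sex",
    "age_years",
    "ancestry",
    "stage",
    "histology",
    "survival_time_years",
    "vital_status",
]

TISSUES = {"tumor", "normal", "blood"}
PLATFORMS = {"16S", "RNA", "WGS"}
STAGES = {"I", "II", "III", "IV", "unknown"}


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV and validate required columns/domains."""
    df = pd.read_csv(path, sep="\t", dtype={"stage": str, "batch": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad_tissue = set(df["tissue"].dropna()) - TISSUES
    if bad_tissue:
        raise ValidationError(f"unknown tissue values {sorted(bad_tissue)}")
    bad_platform = set(df["platform"].dropna()) - PLATFORMS
    if bad_platform:
        raise ValidationError(f"unknown platform values {sorted(bad_platform)}")
    t = pd.to_numeric(df["survival_time_years"], errors="coerce")
    if (t.dropna() < 0).any():
        raise ValidationError("negative survival_time_years")
    return df.set_index("sample_id", drop=False)


def check_samples_covered(table: CountTable, metadata: pd.DataFrame) -> None:
    """Every sample in the table must have exactly one metadata record."""
    missing = set(table.samples) - set(metadata.index)
    if missing:
        raise ValidationError(f"samples without metadata: {sorted(missing)}")
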