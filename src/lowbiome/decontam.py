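"""List-based decontamination with rescue rule and recursive upward propagation.

Low-biomass tissue sequencing is dominated by reagent and handling
contamination, so genera on a curated frequent-contaminant list (Salter-style)
are removed outright — unless the genus encompasses two or more known
human-associated species, in which case it is rescued to avoid discarding
plausible signal.  A small set of forced removals (by default *Cutibacterium*,
a ubiquitous skin commensal and reagent contaminant) overrides the rescue.

Because reads removed at the genus level are still counted inside family-,
order-, ... level clade totals, removal is propagated upward: each ancestor's
clade count is multiplied by the retained (non-contaminant) fraction of its
descendants at the immediately lower standard rank, recursively up to the
root.  The adjusted counts are real-valued.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .taxonomy import NO_RANK, RANK_ORDER, CountTable, TaxonomyTree, rank_index

logger = logging.getLogger(__name__)


@dataclass
class ContaminantPolicy:
    """Curated lists and thresholds governing genus removal.

    Parameters
    ----------
    contaminant_genera:
        Genera flagged as frequent NGS contaminants.
    human_associated_species_counts:
        Genus -> number of known human-associated species; genera reaching
        ``rescue_min_species`` are rescued (kept) despite being listed.
    rescue_min_species:
        Minimum human-associated species count for rescue (default 2).
    forced_removals:
        Genera removed regardless of the rescue rule (default Cutibacterium).
    min_genus_reads:
        Per-cell minimum genus read count (2 for Bracken-adjusted DNA
        platforms, 5 for RNA-seq); cells below it are zeroed.
    """

    contaminant_genera: set[str]
    human_associated_species_counts: Mapping[str, int] = field(default_factory=dict)
    rescue_min_species: int = 2
    forced_removals: set[str] = field(default_factory=lambda: {"Cutibacterium"})
    min_genus_reads: int = 2

    def __post_init__(self) -> None:
        if self.rescue_min_species < 1:
            raise ValueError("rescue_min_species must be >= 1")
        self.contaminant_genera = set(self.contaminant_genera)
        self.forced_removals = set(self.forced_removals)


@dataclass
class DecontamReport:
    removed_genera: set[str]
    rescued_genera: set[str]
    rank_totals: pd.DataFrame  # columns: rank, before, after
    node_retained: pd.DataFrame | None = None  # node, rank, before, after

    def __post_init__(self) -> None:
        assert not (self.removed_genera & self.rescued_genera)

    def to_tsv(self, path) -> None:
        self.rank_totals.to_csv(path, sep="\t", index=False)


def load_genus_list(path) -> set[str]:
    """One genus per line; blank lines and ``#`` comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            name = line.split("#")[0].strip()
            if name:
                out.add(name)
    return out


def load_species_counts(path) -> dict[str, int]:
    """Two-column TSV: genus, number of human-associated species."""
    df = pd.read_csv(path, sep="\t", header=None, names=["genus", "n_species"])
    return dict(zip(df["genus"].astype(str), df["n_species"].astype(int)))


def resolve_removal_set(
    policy: ContaminantPolicy, observed_genera: Iterable[str]
) -> tuple[set[str], set[str]]:
    """Split observed genera into (removal set, rescue set) under the policy."""
    observed = set(observed_genera)
    unknown = (policy.contaminant_genera | policy.forced_removals) - observed
    if unknown:
        logger.info("list genera not observed (ignored): %s", sorted(unknown))
    rescued = {
        g
        for g in policy.contaminant_genera & observed
        if policy.human_associated_species_counts.get(g, 0) >= policy.rescue_min_species
        and g not in policy.forced_removals
    }
    removal = ((policy.contaminant_genera & observed) - rescued) | (
        policy.forced_removals & observed
    )
    return removal, rescued


def zero_out_taxa(table: CountTable, removal: Iterable[str]) -> CountTable:
    """Set removed genera's counts to zero in every sample."""
    removal = set(removal)
    absent = removal - set(table.taxa)
    if absent:
        logger.info("removal genera absent from table: %s", sorted(absent))
    out = table.data.copy()
    present = [g for g in removal if g in out.index]
    out.loc[present] = 0.0
    return CountTable(out, table.rank)


def apply_min_genus_reads(table: CountTable, min_reads: int) -> CountTable:
    """Zero out per-sample genus cells with fewer than ``min_reads`` reads."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    out = table.data.where(table.data >= min_reads, 0.0)
    return CountTable(out, table.rank)


def _next_level_descendants(node):
    """First standard-ranked node on each downward path ("next lowest level").

    'no rank' intermediates are transparent.  In trees without rank skipping
    this is exactly the set of descendants at the immediately lower standard
    rank; a lineage that skips a rank (genus directly under an order) still
    contributes through its first standard-ranked node.
    """
    out = []
    stack = list(node.children)
    while stack:
        child = stack.pop()
        if child.rank == NO_RANK:
            stack.extend(child.children)
        else:
            out.append(child)
    return out


def propagate_upward(
    tree: TaxonomyTree,
    removal: Iterable[str],
    *,
    empty_descendants: str = "keep",
) -> TaxonomyTree:
    """Zero removed genera and recursively adjust every higher rank.

    For each ancestor node at rank *r* (family upward to the root, processed
    in order of increasing rank), the adjusted clade count is::

        adjusted = original * (sum adjusted clade of rank-(r-1) descendants
                               / sum original clade of those descendants)

    per sample.  A node whose rank-(r-1) descendant total is zero keeps its
    reads (fraction 1) under ``empty_descendants="keep"`` — taxa observed
    only above genus level are not destroyed — or loses them under
    ``"zero"`` (the strict multiplicative reading).  Direct counts are
    scaled by the node's own retained fraction, which preserves the
    clade-sum identity on trees without rank skipping.

    Returns a new tree; the input is untouched.
    """
    if empty_descendants not in {"keep", "zero"}:
        raise ValueError("empty_descendants must be 'keep' or 'zero'")
    removal = set(removal)
    genus_names = {n.name for n in tree.nodes_at_rank("genus")}
    stray = removal - genus_names
    if stray:
        raise ValueError(f"removal names not at genus rank in tree: {sorted(stray)}")

    out = tree.copy()
    original = {id(n): n.clade.copy() for n in out.nodes()}

    # Genus level: wipe removed genera and their whole subtrees.
    wiped: set[int] = set()
    for node in out.nodes_at_rank("genus"):
        if node.name in removal:
            for n in [node, *node.descendants()]:
                n.clade = np.zeros_like(n.clade)
                n.direct = np.zeros_like(n.direct)
                wiped.add(id(n))

    # Ancestors: family -> ... -> root (increasing rank = toward the root).
    for rank in reversed(RANK_ORDER[: rank_index("genus")]):
        for node in out.nodes_at_rank(rank):
            desc = _next_level_descendants(node)
            orig_sum = sum((original[id(d)] for d in desc), np.zeros_like(node.clade))
            adj_sum = sum((d.clade for d in desc), np.zeros_like(node.clade))
            fraction = np.ones_like(node.clade)
            nz = orig_sum > 0
            fraction[nz] = adj_sum[nz] / orig_sum[nz]
            if empty_descendants == "zero":
                fraction[~nz] = 0.0
            elif not desc:
                logger.debug("node %s (%s): no lower-rank descendants; reads kept",
                             node.name, rank)
            node.clade = original[id(node)] * fraction
            node.direct = node.direct * fraction

    # 'no rank' intermediates above genus level: transparent as levels, but
    # their counts still shrink by the retained fraction of their first
    # standard-ranked descendants (all final after the rank sweep).
    for node in out.nodes():
        if node.rank != NO_RANK or id(node) in wiped:
            continue
        anc = node.parent
        below_genus = False
        while anc is not None:
            if anc.rank == "genus":
                below_genus = True
                break
            anc = anc.parent
        if below_genus:
            continue  # kept genus subtrees stay untouched
        desc = _next_level_descendants(node)
        if not desc:
            if empty_descendants == "zero":
                node.clade = np.zeros_like(node.clade)
                node.direct = np.zeros_like(node.direct)
            continue
        orig_sum = sum((original[id(d)] for d in desc), np.zeros_like(node.clade))
        adj_sum = sum((d.clade for d in desc), np.zeros_like(node.clade))
        fraction = np.ones_like(node.clade)
        nz = orig_sum > 0
        fraction[nz] = adj_sum[nz] / orig_sum[nz]
        if empty_descendants == "zero":
            fraction[~nz] = 0.0
        node.clade = original[id(node)] * fraction
        node.direct = node.direct * fraction
    return out


def decontaminate_tree(
    tree: TaxonomyTree,
    policy: ContaminantPolicy,
    *,
    empty_descendants: str = "keep",
) -> tuple[TaxonomyTree, DecontamReport]:
    """Full policy application on a tree: resolve lists, propagate, report."""
    observed = {n.name for n in tree.nodes_at_rank("genus")}
    removal, rescued = resolve_removal_set(policy, observed)
    adjusted = propagate_upward(tree, removal, empty_descendants=empty_descendants)
    rows = []
    for rank in RANK_ORDER:
        before = sum(float(n.clade.sum()) for n in tree.nodes_at_rank(rank))
        after = sum(float(n.clade.sum()) for n in adjusted.nodes_at_rank(rank))
        rows.append({"rank": rank, "before": before, "after": after})
    report = DecontamReport(removal, rescued, pd.DataFrame(rows))
    return adjusted, report


def decontaminate_table(
    table: CountTable, policy: ContaminantPolicy
) -> tuple[CountTable, DecontamReport]:
    """Policy application on a genus-rank count table (no tree available)."""
    removal, rescued = resolve_removal_set(policy, table.taxa)
    cleaned = zero_out_taxa(table, removal)
    cleaned = apply_min_genus_reads(cleaned, policy.min_genus_reads)
    rows = [
        {
            "rank": table.rank,
            "before": float(table.values.sum()),
            "after": float(cleaned.values.sum()),
        }
    ]
    report = DecontamReport(removal, rescued, pd.DataFrame(rows))
    return cleaned, report
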