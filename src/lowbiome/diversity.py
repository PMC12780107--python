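"""Rarefaction-based alpha/beta diversity and marginal-variance PERMANOVA.

Unequal sequencing depth is the dominant nuisance in low-biomass data, so
all diversity measures operate at a common rarefaction depth: expected
genus richness has a closed hypergeometric form; Shannon diversity is the
median over 100 random subsamples; Bray-Curtis dissimilarity is the mean
distance matrix over 50 random subsamples.  Community-composition tests
use a permutational multivariate ANOVA reporting the *marginal* variance
explained by each model term over 999 permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from skbio.stats.distance import DistanceMatrix

from .taxonomy import CountTable

logger = logging.getLogger(__name__)


@dataclass
class RarefactionProtocol:
    """Rarefaction depth and draw counts for alpha/beta diversity.

    Defaults follow the convention of 100 subsampling iterations for alpha
    diversity and 50 for Bray-Curtis beta diversity.
    """

    depth: int
    n_alpha_draws: int = 100
    n_beta_draws: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_alpha_draws < 1 or self.n_beta_draws < 1:
            raise ValueError("draw counts must be >= 1")


def expected_richness(counts, depth: int) -> float:
    """Expected number of distinct taxa in a subsample of ``depth`` reads.

    Sampling without replacement from a sample with taxon counts ``N_j``
    (total ``N``) gives ``E[S] = sum_j [1 - C(N - N_j, d) / C(N, d)]``,
    evaluated with log-gamma for numerical stability.
    """
    n = np.asarray(counts, dtype=float)
    n = n[n > 0]
    total = n.sum()
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total:g}")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rest = total - n
    p_absent = np.zeros_like(n)
    feasible = rest >= depth
    p_absent[feasible] = np.exp(
        log_comb(rest[feasible], depth) - log_comb(total, depth)
    )
    return float(np.sum(1.0 - p_absent))


def shannon(counts, base: float | None = None) -> float:
    """Shannon index -sum p log p (natural log by default)."""
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def rarefy(counts, depth: int, rng: np.random.Generator) -> np.ndarray:
    """One multivariate-hypergeometric subsample (without replacement)."""
    n = np.asarray(np.round(counts), dtype=np.int64)
    if depth > n.sum():
        raise ValueError("depth exceeds sample total")
    return rng.multivariate_hypergeometric(n, depth)


def shannon_rarefied(
    counts, protocol: RarefactionProtocol, *, base: float | None = None
) -> float:
    """Median Shannon index over ``n_alpha_draws`` rarefied subsamples."""
    rng = np.random.default_rng(np.random.SeedSequence(protocol.seed))
    draws = [
        shannon(rarefy(counts, protocol.depth, rng), base=base)
        for _ in range(protocol.n_alpha_draws)
    ]
    return float(np.median(draws))


def alpha_diversity(table: CountTable, protocol: RarefactionProtocol) -> pd.DataFrame:
    """Per-sample expected richness and median rarefied Shannon diversity.

    Samples below the rarefaction depth are excluded with a warning.  Each
    sample's draws use a seed derived from the master seed and the sample's
    position, so results do not depend on which other samples are present
    in the table (column order does matter for the derivation, by design a
    stable property of the input file).
    """
    rows = []
    for i, sample in enumerate(table.samples):
        counts = table.values[:, i]
        total = counts.sum()
        if total < protocol.depth:
            logger.warning(
                "sample %s: total %g below depth %d; excluded",
                sample, total, protocol.depth,
            )
            continue
        per_sample = RarefactionProtocol(
            protocol.depth,
            protocol.n_alpha_draws,
            protocol.n_beta_draws,
            seed=np.random.SeedSequence([protocol.seed, i]).generate_state(1)[0],
        )
        rows.append(
            {
                "sample_id": sample,
                "richness": expected_richness(counts, protocol.depth),
                "shannon": shannon_rarefied(counts, per_sample),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id") if rows else pd.DataFrame(
        columns=["richness", "shannon"]
    )


def braycurtis_rarefied(
    table: CountTable, protocol: RarefactionProtocol
) -> DistanceMatrix:
    """Mean Bray-Curtis distance matrix over ``n_beta_draws`` rarefactions.

    Samples below the rarefaction depth are dropped with a warning.  All
    samples share a common depth per draw, so counts and relative
    abundances give identical distances.
    """
    totals = table.sample_totals()
    keep = [s for s in table.samples if totals[s] >= protocol.depth]
    dropped = set(table.samples) - set(keep)
    if dropped:
        logger.warning("samples below depth %d dropped: %s",
                       protocol.depth, sorted(dropped))
    if len(keep) < 2:
        raise ValueError("fewer than 2 samples at or above the rarefaction depth")
    counts = np.round(table.data[keep].to_numpy(dtype=float).T).astype(np.int64)
    rng = np.random.default_rng(np.random.SeedSequence(protocol.seed))
    acc = np.zeros((len(keep), len(keep)))
    for _ in range(protocol.n_beta_draws):
        rare = np.vstack(
            [rng.multivariate_hypergeometric(row, protocol.depth) for row in counts]
        )
        acc += squareform(pdist(rare, metric="braycurtis"))
    return DistanceMatrix(acc / protocol.n_beta_draws, ids=keep)


# ---------------------------------------------------------------------------
# Marginal PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """Marginal PERMANOVA summary: one row per term plus residual and total."""

    summary: pd.DataFrame  # index: term; columns: SS, df, F, R2, p
    residual_ss: float
    residual_df: int
    total_ss: float
    n_permutations: int

    def __repr__(self) -> str:  # pragma: no cover
        return f"PermanovaResult(\n{self.summary}\nresidual SS={self.residual_ss:.4g})"


def _design_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    col = metadata[term]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float).reshape(-1, 1)
    dummies = pd.get_dummies(col.astype(str), drop_first=True, dtype=float)
    if dummies.shape[1] == 0:
        raise ValueError(f"term {term!r} is constant across samples (no df)")
    return dummies.to_numpy()


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto col(X) and its rank (via thin QR with pivoting)."""
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    # Re-orthogonalize on an independent column subset for rank deficiency.
    if rank < X.shape[1]:
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        rank = int((s > s.max() * max(X.shape) * np.finfo(float).eps).sum())
        q = u[:, :rank]
    return q @ q.T, rank


def permanova_marginal(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Marginal (Type-III-style) PERMANOVA over a distance matrix.

    The squared distance matrix is Gower-centered to ``G``; for a model
    matrix ``X`` with hat matrix ``H``, the explained sum of squares is
    ``tr(H G)``.  A term's marginal SS is ``SS(full) - SS(full minus
    term)``; its pseudo-F uses the full-model residual.  P-values come from
    random permutation of sample identities (rows/columns of ``D``), with
    the observed statistic included: ``p = (1 + #{F* >= F}) / (1 + n_perm)``.
    """
    ids = list(dist.ids)
    missing = set(ids) - set(metadata.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    meta = metadata.loc[ids]
    n = len(ids)

    d2 = np.asarray(dist.data, dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ d2 @ J
    total_ss = float(np.trace(G))

    blocks = {t: _design_columns(meta, t) for t in terms}
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept] + [blocks[t] for t in terms])
    H_full, rank_full = _hat(X_full)
    expected_rank = 1 + sum(b.shape[1] for b in blocks.values())
    if rank_full < expected_rank:
        raise ValueError(
            f"aliased model terms among {terms}: design rank {rank_full} < "
            f"{expected_rank} columns"
        )
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    reduced = {}
    for t in terms:
        X_red = np.hstack([intercept] + [blocks[u] for u in terms if u != t])
        reduced[t] = _hat(X_red)

    def term_stats(Gmat):
        ss_full = float(np.sum(H_full * Gmat))
        ss_resid = float(np.trace(Gmat)) - ss_full
        out = {}
        for t in terms:
            H_red, rank_red = reduced[t]
            ss_t = ss_full - float(np.sum(H_red * Gmat))
            df_t = rank_full - rank_red
            out[t] = (ss_t, df_t, (ss_t / df_t) / (ss_resid / df_resid))
        return out, ss_resid

    obs, ss_resid = term_stats(G)

    rng = np.random.default_rng(seed)
    exceed = {t: 0 for t in terms}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        stats, _ = term_stats(Gp)
        for t in terms:
            if stats[t][2] >= obs[t][2]:
                exceed[t] += 1

    rows = []
    for t in terms:
        ss_t, df_t, f_t = obs[t]
        rows.append(
            {
                "term": t,
                "SS": ss_t,
                "df": df_t,
                "F": f_t,
                "R2": ss_t / total_ss,
                "p": (1 + exceed[t]) / (1 + n_perm),
            }
        )
    summary = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(summary, ss_resid, df_resid, total_ss, n_perm)
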