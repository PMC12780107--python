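"""Independent brute-force oracles used to validate the implementations.

These deliberately re-derive each quantity by the most direct route
possible (enumeration, naive recursion, grid search) and share no code
with the package internals they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

RANKS = ["root", "domain", "phylum", "class", "order", "family", "genus", "species"]


# ---------------------------------------------------------------------------
# Decontamination propagation (naive recursion over a nested-dict tree)
# ---------------------------------------------------------------------------


def adjusted_clade(node: dict, removed: set[str]) -> float:
    """Recursive evaluation of the upward-propagation rule for one node.

    ``node`` = {"name", "rank", "clade", "children": [...]} with scalar
    counts.  Genus nodes are zeroed if removed; every higher standard-rank
    node is scaled by (adjusted / original) of its first standard-ranked
    descendants ("no rank" transparent), fraction 1 when that original sum
    is zero.
    """
    if node["rank"] == "genus":
        return 0.0 if node["name"] in removed else node["clade"]
    desc = _first_standard(node)
    orig = sum(d["clade"] for d in desc)
    if orig == 0:
        return node["clade"]
    adj = sum(adjusted_clade(d, removed) for d in desc)
    return node["clade"] * adj / orig


def _first_standard(node: dict) -> list[dict]:
    out = []
    for child in node.get("children", []):
        if child["rank"] == "no rank":
            out.extend(_first_standard(child))
        else:
            out.append(child)
    return out


# ---------------------------------------------------------------------------
# Expected richness by Monte-Carlo subsampling
# ---------------------------------------------------------------------------


def mean_subsampled_richness(counts, depth: int, n_draws: int, seed: int) -> tuple[float, float]:
    """(mean, standard error) of observed richness over random subsamples."""
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(counts)), np.asarray(counts, dtype=int))
    richness = np.empty(n_draws)
    for k in range(n_draws):
        picked = rng.choice(pool, size=depth, replace=False)
        richness[k] = len(np.unique(picked))
    return float(richness.mean()), float(richness.std(ddof=1) / math.sqrt(n_draws))


def exact_expected_richness_by_enumeration(counts, depth: int) -> float:
    """Average richness over every distinct subsample (tiny instances only)."""
    reads = [i for i, c in enumerate(counts) for _ in range(int(c))]
    total, n_comb = 0.0, 0
    for combo in itertools.combinations(range(len(reads)), depth):
        total += len({reads[i] for i in combo})
        n_comb += 1
    return total / n_comb


# ---------------------------------------------------------------------------
# One-factor PERMANOVA by direct group-sum arithmetic
# ---------------------------------------------------------------------------


def permanova_one_factor(d: np.ndarray, labels) -> tuple[float, float, float]:
    """(SS_between, R2, F) from the classic within/total decomposition."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(np.unique(labels))
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return ss_between, ss_between / ss_total, f


# ---------------------------------------------------------------------------
# Cox partial likelihood by brute-force grid search (single covariate)
# ---------------------------------------------------------------------------


def cox_loglik_naive(beta: float, time, event, z) -> float:
    """Breslow partial log-likelihood evaluated the slow, obvious way."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    z = np.asarray(z, float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        deaths = np.flatnonzero((time == t) & (event == 1))
        risk = np.flatnonzero(time >= t)
        ll += beta * z[deaths].sum() - len(deaths) * math.log(
            np.exp(beta * z[risk]).sum()
        )
    return ll


def cox_grid_mle(time, event, z, lo=-5.0, hi=5.0) -> float:
    """Maximize the naive partial likelihood by grid + golden-section refine."""
    grid = np.linspace(lo, hi, 2001)
    vals = [cox_loglik_naive(b, time, event, z) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    a, b = b0 - 0.01, b0 + 0.01
    phi = (math.sqrt(5) - 1) / 2
    for _ in range(80):
        c1 = b - phi * (b - a)
        c2 = a + phi * (b - a)
        if cox_loglik_naive(c1, time, event, z) > cox_loglik_naive(c2, time, event, z):
            b = c2
        else:
            a = c1
    return 0.5 * (a + b)
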