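"""Compositional statistics: CLR transform, paired differential abundance,
multiple-testing adjustment, meta-analysis, concordance, and marker scores.

Read counts are compositional (only relative information survives library
size), so abundances are mapped to the centered log-ratio (CLR) scale with
a small pseudo-count before any linear statistics.  Tumor-normal contrasts
use a paired t-test on per-subject CLR differences; platform subsets are
pooled with inverse-variance fixed-effect meta-analysis and Fisher's
combined probability test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .taxonomy import CountTable

logger = logging.getLogger(__name__)

DEFAULT_PSEUDO_COUNT = 0.05


@dataclass
class ClrMatrix:
    """Taxa x samples matrix on the CLR scale; each column sums to zero."""

    data: pd.DataFrame
    pseudo_count: float = DEFAULT_PSEUDO_COUNT

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def clr_transform(table: CountTable, pseudo_count: float = DEFAULT_PSEUDO_COUNT) -> ClrMatrix:
    """CLR: ``y_ij = ln(x_ij + c) - mean_i ln(x_ij + c)`` per sample j."""
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be > 0")
    logs = np.log(table.values + pseudo_count)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return ClrMatrix(
        pd.DataFrame(clr, index=table.taxa, columns=table.samples), pseudo_count
    )


@dataclass
class PairedTestResult:
    """Per-taxon paired t-test summary on CLR differences (tumor - normal)."""

    table: pd.DataFrame  # taxon-indexed: mean_diff, sd_diff, t, df, p, p_adj, degenerate
    n_pairs: int
    adjust_method: str


def paired_da_test(
    clr: ClrMatrix,
    pairs: list[tuple[str, str]],
    adjust: str = "bh",
) -> PairedTestResult:
    """Paired t-test per taxon on delta_i = CLR(tumor_i) - CLR(normal_i).

    ``pairs`` lists subject-matched (tumor_sample, normal_sample) ids.
    Taxa with zero variance of delta are degenerate: reported with p = 1
    and flagged.  Two-sided p from the t distribution with n-1 df,
    adjusted across taxa ("bh" or "holm").
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 complete pairs")
    tumor_ids = [t for t, _ in pairs]
    normal_ids = [n for _, n in pairs]
    delta = (
        clr.data[tumor_ids].to_numpy() - clr.data[normal_ids].to_numpy()
    )  # taxa x pairs
    n = delta.shape[1]
    mean = delta.mean(axis=1)
    sd = delta.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.nan, mean / (sd / math.sqrt(n)))
    p = np.where(degenerate, 1.0, 2 * stats.t.sf(np.abs(t), df=n - 1))
    p_adj = adjust_pvalues(p, method=adjust)
    table = pd.DataFrame(
        {
            "mean_diff": mean,
            "sd_diff": sd,
            "t": t,
            "df": n - 1,
            "p": p,
            "p_adj": p_adj,
            "degenerate": degenerate,
        },
        index=pd.Index(clr.taxa, name="taxon"),
    )
    return PairedTestResult(table, n, adjust)


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg ("bh") or Holm ("holm") adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "holm": "holm"}.get(method.lower())
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


@dataclass
class MetaResult:
    """Inverse-variance fixed-effect pooled estimate with Fisher combined p."""

    estimate: float
    se: float
    inputs: list[tuple[float, float]] = field(default_factory=list)
    fisher_x2: float = float("nan")
    fisher_df: int = 0
    p_combined: float = float("nan")

    @property
    def z(self) -> float:
        return self.estimate / self.se

    @property
    def p_pooled(self) -> float:
        return 2 * stats.norm.sf(abs(self.z))


def fixed_effect_meta(estimates: list[tuple[float, float]]) -> MetaResult:
    """Pool (estimate, se) inputs with weights 1/se^2.

    A single input is returned unchanged.  The combined p is Fisher's
    method over the per-input two-sided normal p-values.
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    for _, se in estimates:
        if se <= 0:
            raise ValueError("standard errors must be > 0")
    b = np.array([e for e, _ in estimates])
    se = np.array([s for _, s in estimates])
    w = 1.0 / se**2
    pooled_b = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    p_each = 2 * stats.norm.sf(np.abs(b / se))
    x2, df, p_comb = fisher_combine(p_each)
    return MetaResult(pooled_b, pooled_se, list(estimates), x2, df, p_comb)


def fisher_combine(p) -> tuple[float, int, float]:
    """Fisher's combined probability test: X2 = -2 sum ln p, df = 2k."""
    p = np.asarray(p, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("p = 0 clipped to smallest positive float for Fisher combination")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    x2 = float(-2 * np.log(p).sum())
    df = 2 * len(p)
    return x2, df, float(stats.chi2.sf(x2, df))


def meta_beta_r2(r2_subsets, p_subsets) -> tuple[float, float]:
    """Average beta-diversity R2 across subsets; combine p by Fisher."""
    r2 = np.asarray(r2_subsets, dtype=float)
    p = np.asarray(p_subsets, dtype=float)
    if r2.shape != p.shape:
        raise ValueError("R2 and p lists must have equal length")
    if np.any((r2 < 0) | (r2 > 1)):
        raise ValueError("R2 values must lie in [0, 1]")
    _, _, p_comb = fisher_combine(p)
    return float(r2.mean()), p_comb


def platform_concordance(
    clr_a: ClrMatrix, clr_b: ClrMatrix
) -> tuple[pd.Series, pd.Series]:
    """Pearson r between two platforms on shared samples and shared taxa.

    Returns (per-taxon r across shared samples, per-sample r across shared
    taxa).  Vectors with zero variance yield NaN.
    """
    samples = [s for s in clr_a.samples if s in set(clr_b.samples)]
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    taxa = [t for t in clr_a.taxa if t in set(clr_b.taxa)]
    a = clr_a.data.loc[taxa, samples]
    b = clr_b.data.loc[taxa, samples]

    def _corr(x: pd.DataFrame, y: pd.DataFrame, axis: int) -> pd.Series:
        xv = x.to_numpy()
        yv = y.to_numpy()
        if axis == 0:  # across samples, per taxon row
            xv, yv = xv, yv
        else:  # across taxa, per sample column
            xv, yv = xv.T, yv.T
        xc = xv - xv.mean(axis=1, keepdims=True)
        yc = yv - yv.mean(axis=1, keepdims=True)
        num = (xc * yc).sum(axis=1)
        den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / den, np.nan)
        index = x.index if axis == 0 else x.columns
        return pd.Series(r, index=index)

    return _corr(a, b, axis=0), _corr(a, b, axis=1)


def celltype_scores(
    expression: pd.DataFrame, marker_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Median log2(CPM + 1) over each marker gene set, per sample.

    ``expression`` is a gene x sample count matrix.  Marker genes missing
    from the expression table are logged and skipped; a set with no
    matched genes yields NaN scores.
    """
    totals = expression.sum(axis=0)
    cpm = expression.div(totals, axis=1) * 1e6
    log_cpm = np.log2(cpm + 1)
    rows = {}
    for cell_type, genes in marker_sets.items():
        present = [g for g in genes if g in log_cpm.index]
        missing = set(genes) - set(present)
        if missing:
            logger.info("%s: markers missing from expression: %s",
                        cell_type, sorted(missing))
        if not present:
            rows[cell_type] = pd.Series(np.nan, index=expression.columns)
        else:
            rows[cell_type] = log_cpm.loc[present].median(axis=0)
    return pd.DataFrame(rows).T


def read_gmt(path) -> dict[str, list[str]]:
    """GMT marker sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def diversity_glm(
    diversity: pd.Series,
    metadata: pd.DataFrame,
    feature: str,
    adjust_for: tuple[str, ...] = ("study_site",),
) -> pd.DataFrame:
    """Linear model of a diversity measure on a clinical feature.

    Fits OLS of ``diversity ~ feature + adjust_for`` (categoricals dummy
    coded) and returns the feature's coefficient rows (estimate, se, p).
    """
    import statsmodels.api as sm

    df = metadata.loc[diversity.index].copy()
    df["_y"] = diversity
    X_parts = []
    feature_cols: list[str] = []
    for name, is_feature in [(feature, True)] + [(a, False) for a in adjust_for]:
        col = df[name]
        if pd.api.types.is_numeric_dtype(col):
            part = col.to_frame(name)
        else:
            part = pd.get_dummies(col.astype(str), prefix=name, drop_first=True,
                                  dtype=float)
        X_parts.append(part)
        if is_feature:
            feature_cols = list(part.columns)
    X = sm.add_constant(pd.concat(X_parts, axis=1))
    fit = sm.OLS(df["_y"], X).fit()
    out = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "p": fit.pvalues}
    ).loc[feature_cols]
    return out
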