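"""Synthetic low-biomass multi-platform cohorts with known ground truth.

The generator emulates the structure that makes tissue microbiome analysis
hard: very low per-sample bacterial depth (log-normal depths with
platform-specific medians on the order of 10^2-10^4 reads), paired
tumor-normal samples from the same subject, batch-specific reagent
contamination, sparse planted tumor effects on the CLR scale, and
right-censored survival driven by proportional-hazards taxon effects.
Every generated cohort carries a ``SyntheticTruth`` manifest sufficient to
recompute what each analysis stage should find.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .power import SurvivalPowerSpec, simulate_event_times
from .taxonomy import CountTable, TaxonNode, TaxonomyTree

logger = logging.getLogger(__name__)

#: Median bacterial reads by (platform, tissue): the depth regimes of
#: tissue 16S, tumor RNA-seq, and WGS-derived microbiome read counts.
DEFAULT_DEPTH_MEDIANS = {
    ("16S", "tumor"): 730,
    ("16S", "normal"): 773,
    ("RNA", "tumor"): 9080,
    ("RNA", "normal"): 11053,
    ("WGS", "tumor"): 344,
    ("WGS", "normal"): 162,
    ("WGS", "blood"): 1440,
}

#: Typical reagent-contaminant genera for spiking (water/kit organisms).
DEFAULT_CONTAMINANT_GENERA = ("Ralstonia", "Methylobacterium", "Bradyrhizobium")


@dataclass
class CohortConfig:
    """Study-design parameters for one synthetic cohort.

    Depth is log-normal parameterized by its median (``depth_sigma`` on the
    log scale); composition is subject-level Dirichlet around a log-normal
    base abundance profile; tumor effects are planted on the CLR scale;
    survival uses a log-normal baseline with planted per-taxon log hazard
    ratios applied to standardized true CLR abundances.
    """

    n_subjects: int = 200
    platform: str = "16S"
    depth_median_tumor: int | None = None
    depth_median_normal: int | None = None
    depth_sigma: float = 0.7
    n_genera: int = 60
    genera_per_family: int = 4
    families_per_phylum: int = 4
    concentration: float = 50.0
    base_log_sd: float = 1.5
    tumor_effect: dict[str, float] = field(default_factory=dict)
    contaminants: dict[str, float] = field(default_factory=dict)
    contaminated_batches: tuple[str, ...] = ()
    surv_mu: float = 2.0
    surv_sigma: float = 1.2
    censor_fraction: float = 0.3
    hazard_log_hr: dict[str, float] = field(default_factory=dict)
    n_sites: int = 3
    n_batches: int = 4
    seed: int = 0
    #: When set, the cohort *design* (base abundance profile) is drawn from
    #: this seed instead of ``seed``, so replicate cohorts can share one
    #: fixed design while resampling subjects, counts, and noise.
    base_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_genera < 1:
            raise ValueError("need at least one subject and one genus")
        if self.platform not in {"16S", "RNA", "WGS"}:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.depth_median_tumor is None:
            self.depth_median_tumor = DEFAULT_DEPTH_MEDIANS[(self.platform, "tumor")]
        if self.depth_median_normal is None:
            self.depth_median_normal = DEFAULT_DEPTH_MEDIANS[(self.platform, "normal")]


@dataclass
class SyntheticTruth:
    """Ground-truth manifest for a generated cohort."""

    genera: list[str]
    taxonomy: dict[str, tuple[str, str]]  # genus -> (family, phylum)
    base_composition: np.ndarray
    tumor_effect: dict[str, float]
    clr_shift: dict[str, float]  # realized per-genus CLR shift incl. closure
    contaminants: dict[str, float]
    contaminated_batches: tuple[str, ...]
    hazard_log_hr: dict[str, float]
    subject_site: dict[str, str]
    subject_batch: dict[str, str]
    composition_normal: np.ndarray | None = None  # subjects x genera
    composition_tumor: np.ndarray | None = None
    realized_events: int | None = None
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "genera": self.genera,
            "taxonomy": {g: list(v) for g, v in self.taxonomy.items()},
            "base_composition": self.base_composition.tolist(),
            "tumor_effect": self.tumor_effect,
            "clr_shift": self.clr_shift,
            "contaminants": self.contaminants,
            "contaminated_batches": list(self.contaminated_batches),
            "hazard_log_hr": self.hazard_log_hr,
            "subject_site": self.subject_site,
            "subject_batch": self.subject_batch,
            "realized_events": self.realized_events,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _planted_log_shifts(genera: list[str], effects: dict[str, float]) -> np.ndarray:
    """Log-scale multipliers planting exact CLR shifts on the listed taxa.

    A CLR shift vector must sum to zero across taxa (closure), so planting
    shift ``t_j`` on k taxa forces the remaining D-k taxa to share
    ``-sum(t)/(D-k)``.  The returned vector realizes exactly ``t_j`` on
    each planted taxon.
    """
    unknown = set(effects) - set(genera)
    if unknown:
        raise ValueError(f"effect taxa not in the genus set: {sorted(unknown)}")
    d = len(genera)
    v = np.zeros(d)
    if not effects:
        return v
    total = sum(effects.values())
    k = len(effects)
    if d == k:
        raise ValueError("cannot plant effects on every taxon (closure)")
    v[:] = -total / (d - k)
    for j, g in enumerate(genera):
        if g in effects:
            v[j] = effects[g]
    return v


def generate_cohort(
    config: CohortConfig,
) -> tuple[CountTable, pd.DataFrame, SyntheticTruth]:
    """Generate a paired tumor-normal cohort for one platform.

    Per subject, a latent composition is drawn from a Dirichlet around the
    cohort base profile; the tumor composition shifts planted taxa on the
    CLR scale; counts are multinomial at a log-normal depth.  Deterministic
    under ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n, d = config.n_subjects, config.n_genera

    genera = [f"g{j + 1:03d}" for j in range(d)]
    taxonomy = {
        g: (
            f"f{j // config.genera_per_family + 1:02d}",
            f"p{j // (config.genera_per_family * config.families_per_phylum) + 1}",
        )
        for j, g in enumerate(genera)
    }

    if config.base_seed is not None:
        base_rng = np.random.default_rng(np.random.SeedSequence([config.base_seed, 9]))
    else:
        base_rng = rng
    base_logits = base_rng.normal(0.0, config.base_log_sd, size=d)
    base = np.exp(base_logits - base_logits.max())
    base /= base.sum()

    shifts = _planted_log_shifts(genera, config.tumor_effect)
    clr_shift = dict(zip(genera, shifts))

    alpha = np.maximum(config.concentration * base, 1e-3)
    comp_normal = rng.dirichlet(alpha, size=n)
    # Dirichlet draws at tiny alpha can underflow to exact zero; keep
    # compositions strictly positive so log-scale truths are finite.
    comp_normal = np.clip(comp_normal, 1e-12, None)
    comp_normal /= comp_normal.sum(axis=1, keepdims=True)
    comp_tumor = comp_normal * np.exp(shifts)[None, :]
    comp_tumor /= comp_tumor.sum(axis=1, keepdims=True)

    subjects = [f"S{i + 1:04d}" for i in range(n)]
    sites = [f"site{rng.integers(1, config.n_sites + 1)}" for _ in subjects]
    batches = [f"b{rng.integers(1, config.n_batches + 1)}" for _ in subjects]

    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    stage_levels = np.array(["I", "II", "III", "IV"])
    stage_p = np.array([0.61, 0.17, 0.16, 0.06])
    histo_levels = np.array(
        ["adenocarcinoma", "squamous", "carcinoid", "other"]
    )
    histo_p = np.array([0.89, 0.05, 0.03, 0.03])
    for i, subject in enumerate(subjects):
        age = float(np.clip(rng.normal(64.7, 8.5), 30, 90))
        sex = "F" if rng.uniform() < 0.8 else "M"
        ancestry = str(rng.choice(["EAS", "EUR", "AMR", "AFR"],
                                  p=[0.55, 0.39, 0.05, 0.01]))
        stage = str(rng.choice(stage_levels, p=stage_p / stage_p.sum()))
        histology = str(rng.choice(histo_levels, p=histo_p / histo_p.sum()))
        for tissue, comp, median in (
            ("tumor", comp_tumor[i], config.depth_median_tumor),
            ("normal", comp_normal[i], config.depth_median_normal),
        ):
            depth = max(int(round(rng.lognormal(np.log(median), config.depth_sigma))), 10)
            sample_id = f"{subject}_{'T' if tissue == 'tumor' else 'N'}"
            counts[sample_id] = rng.multinomial(depth, comp).astype(float)
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "subject_id": subject,
                    "tissue": tissue,
                    "platform": config.platform,
                    "study_site": sites[i],
                    "batch": batches[i],
                    "sex": sex,
                    "age_years": age,
                    "ancestry": ancestry,
                    "stage": stage,
                    "histology": histology,
                    "survival_time_years": np.nan,
                    "vital_status": pd.NA,
                }
            )

    table = CountTable(
        pd.DataFrame(counts, index=genera), rank="genus"
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    truth = SyntheticTruth(
        genera=genera,
        taxonomy=taxonomy,
        base_composition=base,
        tumor_effect=dict(config.tumor_effect),
        clr_shift=clr_shift,
        contaminants={},
        contaminated_batches=(),
        hazard_log_hr=dict(config.hazard_log_hr),
        subject_site=dict(zip(subjects, sites)),
        subject_batch=dict(zip(subjects, batches)),
        composition_normal=comp_normal,
        composition_tumor=comp_tumor,
        seed=config.seed,
    )
    return table, metadata, truth


def spike_contamination(
    table: CountTable,
    metadata: pd.DataFrame,
    truth: SyntheticTruth,
    config: CohortConfig,
) -> tuple[CountTable, SyntheticTruth]:
    """Add batch-specific contaminant reads to the count table.

    Contaminant genera (``config.contaminants``: genus -> expected reads
    per affected sample) must be disjoint from planted-effect taxa; counts
    are Poisson draws added only to samples in ``config.contaminated_batches``
    (other batches stay clean).  New genus rows are appended when absent.
    """
    overlap = set(config.contaminants) & (
        set(config.tumor_effect) | set(config.hazard_log_hr)
    )
    if overlap:
        raise ValueError(f"contaminants overlap planted-effect taxa: {sorted(overlap)}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    data = table.data.copy()
    for genus in config.contaminants:
        if genus not in data.index:
            data.loc[genus] = 0.0
            truth.taxonomy[genus] = ("f_contam", "p_contam")
    affected = set(config.contaminated_batches)
    for sample in data.columns:
        if metadata.loc[sample, "batch"] not in affected:
            continue
        for genus, intensity in config.contaminants.items():
            data.loc[genus, sample] += rng.poisson(intensity)
    truth.contaminants = dict(config.contaminants)
    truth.contaminated_batches = tuple(config.contaminated_batches)
    return CountTable(data, table.rank), truth


def generate_survival(
    metadata: pd.DataFrame,
    truth: SyntheticTruth,
    config: CohortConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Fill survival time and vital status from a planted PH model.

    The per-subject linear predictor is the sum of planted log hazard
    ratios times the subject's *standardized true* CLR abundance (tumor
    latent composition), so a hazard ratio reads "per standard deviation of
    CLR abundance".  Event times come from the inverse-probability method
    over the log-normal baseline; a random ``censor_fraction`` of subjects
    receives a censoring time uniform on (0, T).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    subjects = list(truth.subject_site)
    n = len(subjects)
    comp = truth.composition_tumor
    if comp is None:
        raise ValueError("truth lacks latent compositions")
    log_comp = np.log(comp)
    clr = log_comp - log_comp.mean(axis=1, keepdims=True)
    eta = np.zeros(n)
    for genus, loghr in config.hazard_log_hr.items():
        j = truth.genera.index(genus)
        x = clr[:, j]
        sd = x.std()
        if sd == 0:
            raise ValueError(f"constant CLR abundance for hazard taxon {genus}")
        eta += loghr * (x - x.mean()) / sd

    spec = SurvivalPowerSpec(
        config.surv_mu, config.surv_sigma, max(n, 10), beta=1.0,
        censor_fraction=config.censor_fraction, seed=config.seed,
    )
    t = simulate_event_times(spec, eta, rng=rng)
    event = np.ones(n, dtype=int)
    n_censor = int(round(config.censor_fraction * n))
    if n_censor:
        who = rng.choice(n, size=n_censor, replace=False)
        t[who] = rng.uniform(0.0, t[who])
        event[who] = 0

    out = metadata.copy()
    time_map = dict(zip(subjects, t))
    event_map = dict(zip(subjects, event))
    out["survival_time_years"] = out["subject_id"].map(time_map)
    out["vital_status"] = out["subject_id"].map(
        {s: ("dead" if e == 1 else "alive") for s, e in event_map.items()}
    )
    truth.realized_events = int(event.sum())
    return out, truth


def build_tree(table: CountTable, taxonomy: dict[str, tuple[str, str]]) -> TaxonomyTree:
    """Assemble a genus-resolved taxonomy tree from a table and a
    genus -> (family, phylum) mapping; ancestor clade counts are sums,
    ancestor direct counts zero."""
    n_samples = len(table.samples)
    zeros = lambda: np.zeros(n_samples)  # noqa: E731
    root = TaxonNode(1, "root", "root", zeros(), zeros())
    domain = TaxonNode(2, "Bacteria", "domain", zeros(), zeros(), parent=root)
    root.children.append(domain)
    phyla: dict[str, TaxonNode] = {}
    families: dict[str, TaxonNode] = {}
    next_id = 3
    for genus in table.taxa:
        fam, phy = taxonomy[genus]
        if phy not in phyla:
            phyla[phy] = TaxonNode(next_id, phy, "phylum", zeros(), zeros(), parent=domain)
            domain.children.append(phyla[phy])
            next_id += 1
        if fam not in families:
            families[fam] = TaxonNode(next_id, fam, "family", zeros(), zeros(),
                                      parent=phyla[phy])
            phyla[phy].children.append(families[fam])
            next_id += 1
        counts = table.data.loc[genus].to_numpy(dtype=float)
        node = TaxonNode(next_id, genus, "genus", counts.copy(), counts.copy(),
                         parent=families[fam])
        families[fam].children.append(node)
        next_id += 1
        for anc in (families[fam], phyla[phy], domain, root):
            anc.clade = anc.clade + counts
    return TaxonomyTree(root, list(table.samples))
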