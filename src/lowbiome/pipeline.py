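"""Reproducible end-to-end runs: simulate -> decontaminate -> filter ->
diversity / differential abundance / survival -> power, with a manifest.

One run writes one immutable directory; the manifest records the config
hash, the master seed, and a SHA-256 per output file, so a rerun with the
same config is byte-identical and stale outputs are detectable.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .compositions import clr_transform, paired_da_test
from .decontam import ContaminantPolicy, decontaminate_table
from .diversity import RarefactionProtocol, alpha_diversity, braycurtis_rarefied, permanova_marginal
from .power import PairedPowerSpec, SurvivalPowerSpec, paired_power, min_detectable_effect, survival_power_sim
from .simulate import CohortConfig, generate_cohort, generate_survival, spike_contamination
from .survival import prepare_survival, taxon_survival_scan
from .taxonomy import CountTable, filter_min_depth, filter_prevalence, filter_survival_abundance, read_count_table, read_metadata

logger = logging.getLogger(__name__)

#: Stage defaults; per-platform thresholds follow the standard read cutoffs
#: (sample depth 500/250/100 for RNA/16S/WGS, genus cell minimum 5/2/2,
#: prevalence 5% for differential abundance, survival abundance rule
#: 50-reads-in-10% for RNA relaxed to 10 reads for 16S/WGS).
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "decontam": True,
        "diversity": True,
        "permanova": True,
        "da": True,
        "survival": True,
        "power": True,
    },
    "inputs": {"counts": None, "metadata": None},
    "simulate": {
        "n_subjects": 150,
        "platform": "16S",
        "tumor_effect": {},
        "contaminants": {},
        "contaminated_batches": [],
        "hazard_log_hr": {},
    },
    "thresholds": {
        "min_depth": {"RNA": 500, "16S": 250, "WGS": 100},
        "icc_common_depth": 250,
        "prevalence_da": 0.05,
        "prevalence_batch": 0.01,
        "min_genus_reads": {"RNA": 5, "16S": 2, "WGS": 2},
        "survival_min_reads": {"RNA": 50, "16S": 10, "WGS": 10},
        "survival_min_frac": 0.10,
        "clr_pseudo": 0.05,
    },
    "rarefaction": {
        "depth": {"RNA": 500, "16S": 250, "WGS": 100},
        "alpha_draws": 100,
        "beta_draws": 50,
    },
    "permanova": {"terms": ["tissue", "batch"], "n_perm": 999},
    "decontam": {"contaminant_list": None, "species_counts": None},
    "power": {
        "paired_alphas": [2.8e-4, 0.01],
        "survival": {"censor_fraction": 0.3, "alpha": 0.01, "n_sims": 200,
                     "beta": 0.4},
    },
}


def merge_config(overrides: dict | None) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict) -> None:
        for key, value in src.items():
            if isinstance(value, dict) and isinstance(dst.get(key), dict):
                merge(dst[key], value)
            else:
                dst[key] = value

    if overrides:
        merge(config, overrides)
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _default_policy(cfg: dict, platform: str) -> ContaminantPolicy:
    from importlib.resources import files

    from .decontam import load_genus_list, load_species_counts

    data = files("lowbiome.data")
    cont_path = cfg["decontam"]["contaminant_list"] or str(
        data / "contaminant_genera.txt"
    )
    sp_path = cfg["decontam"]["species_counts"] or str(
        data / "human_associated_species_counts.tsv"
    )
    return ContaminantPolicy(
        contaminant_genera=load_genus_list(cont_path),
        human_associated_species_counts=load_species_counts(sp_path),
        min_genus_reads=cfg["thresholds"]["min_genus_reads"][platform],
    )


def run_pipeline(config: dict | None, out_dir) -> Path:
    """Execute the enabled stages and write outputs plus ``manifest.json``."""
    cfg = merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    outputs: list[Path] = []
    notes: dict = {}

    def save_df(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kwargs)
        outputs.append(path)

    # --- inputs -----------------------------------------------------------
    if stages["simulate"]:
        sim = dict(cfg["simulate"])
        sim["contaminated_batches"] = tuple(sim.get("contaminated_batches", ()))
        cohort_cfg = CohortConfig(seed=seed, **sim)
        table, metadata, truth = generate_cohort(cohort_cfg)
        if cohort_cfg.contaminants:
            table, truth = spike_contamination(table, metadata, truth, cohort_cfg)
        if cohort_cfg.hazard_log_hr or cohort_cfg.censor_fraction is not None:
            metadata, truth = generate_survival(metadata, truth, cohort_cfg)
        platform = cohort_cfg.platform
        save_df(table.data, "counts_raw.tsv", index_label="taxon")
        save_df(metadata, "metadata.tsv", index=False)
        truth.to_json(out / "truth.json")
        outputs.append(out / "truth.json")
    else:
        counts_path = cfg["inputs"]["counts"]
        meta_path = cfg["inputs"]["metadata"]
        if not counts_path or not meta_path:
            raise ValueError("stage 'simulate' disabled and no input counts/metadata "
                             "configured")
        table = read_count_table(counts_path)
        metadata = read_metadata(meta_path)
        platform = str(metadata["platform"].iloc[0])

    # --- decontamination --------------------------------------------------
    if stages["decontam"]:
        policy = _default_policy(cfg, platform)
        table, report = decontaminate_table(table, policy)
        save_df(table.data, "counts_decontaminated.tsv", index_label="taxon")
        report.to_tsv(out / "decontam_report.tsv")
        outputs.append(out / "decontam_report.tsv")
        notes["removed_genera"] = sorted(report.removed_genera)
        notes["rescued_genera"] = sorted(report.rescued_genera)
    else:
        notes["decontam"] = "disabled; raw tables propagated downstream"

    thr = cfg["thresholds"]
    table = filter_min_depth(table, thr["min_depth"][platform])

    # --- diversity --------------------------------------------------------
    depth = cfg["rarefaction"]["depth"][platform]
    protocol = RarefactionProtocol(
        depth=depth,
        n_alpha_draws=cfg["rarefaction"]["alpha_draws"],
        n_beta_draws=cfg["rarefaction"]["beta_draws"],
        seed=seed,
    )
    if stages["diversity"]:
        alpha = alpha_diversity(table, protocol)
        save_df(alpha, "alpha_diversity.tsv")
    if stages["permanova"]:
        dist = braycurtis_rarefied(table, protocol)
        perm = permanova_marginal(
            dist,
            metadata,
            terms=list(cfg["permanova"]["terms"]),
            n_perm=cfg["permanova"]["n_perm"],
            seed=seed,
        )
        save_df(perm.summary, "permanova.tsv")

    # --- differential abundance ------------------------------------------
    if stages["da"]:
        da_table = filter_prevalence(table, thr["prevalence_da"])
        clr = clr_transform(da_table, thr["clr_pseudo"])
        meta_kept = metadata.loc[[s for s in metadata.index if s in set(clr.samples)]]
        tumor = meta_kept[meta_kept["tissue"] == "tumor"].set_index("subject_id")
        normal = meta_kept[meta_kept["tissue"] == "normal"].set_index("subject_id")
        shared = [s for s in tumor.index if s in set(normal.index)]
        pairs = [
            (tumor.loc[s, "sample_id"], normal.loc[s, "sample_id"]) for s in shared
        ]
        if len(pairs) >= 3:
            da = paired_da_test(clr, pairs)
            save_df(da.table, "differential_abundance.tsv")
            notes["n_pairs"] = len(pairs)
        else:
            notes["da"] = "skipped: fewer than 3 complete pairs after filtering"

    # --- survival scan ----------------------------------------------------
    if stages["survival"]:
        surv_table = filter_survival_abundance(
            table, thr["survival_min_reads"][platform], thr["survival_min_frac"]
        )
        records = prepare_survival(metadata[metadata["tissue"] == "tumor"])
        if len(surv_table.taxa) and records["event"].sum() >= 5:
            clr_s = clr_transform(surv_table, thr["clr_pseudo"])
            scan = taxon_survival_scan(clr_s, records)
            save_df(scan, "survival_scan.tsv")
        else:
            notes["survival"] = "skipped: no taxa pass filters or too few events"

    # --- power ------------------------------------------------------------
    if stages["power"]:
        n_pairs = notes.get("n_pairs", cfg["simulate"]["n_subjects"])
        rows = []
        for alpha_level in cfg["power"]["paired_alphas"]:
            rows.append(
                {
                    "analysis": "paired",
                    "alpha": alpha_level,
                    "n": n_pairs,
                    "min_detectable_effect": min_detectable_effect(n_pairs, alpha_level),
                    "power_at_beta_0.3": paired_power(
                        PairedPowerSpec(n_pairs, alpha_level, 0.3)
                    ),
                }
            )
        sp = cfg["power"]["survival"]
        surv_records = prepare_survival(metadata[metadata["tissue"] == "tumor"])
        if surv_records["event"].sum() >= 2:
            from .power import fit_lognormal_survival

            mu, sigma = fit_lognormal_survival(
                surv_records["time_years"].clip(lower=1e-6),
                surv_records["event"],
            )
            res = survival_power_sim(
                SurvivalPowerSpec(
                    mu, sigma, len(surv_records), beta=sp["beta"],
                    censor_fraction=sp["censor_fraction"], alpha=sp["alpha"],
                    n_sims=sp["n_sims"], seed=seed,
                )
            )
            rows.append(
                {
                    "analysis": "survival_sim",
                    "alpha": sp["alpha"],
                    "n": len(surv_records),
                    "beta": sp["beta"],
                    "power": res.power,
                    "mc_se": res.mc_se,
                    "baseline_mu": mu,
                    "baseline_sigma": sigma,
                }
            )
        save_df(pd.DataFrame(rows), "power.tsv", index=False)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": cfg,
        "notes": notes,
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
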