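"""End-to-end orchestration: simulate -> assoc (x3 groups) -> meta -> factors -> subgroups.

Every stage draws from a substream derived from the single config seed, so
disabling one stage never changes another stage's output. The run writes a
provenance manifest (config hash, seed, package version, per-stage record
counts, output checksums) that is byte-identical across reruns of the same
config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, meta, programs, subgroups, synthetic
from ._rng import stage_rng
from .composition import fit_group_table
from .config import PipelineConfig
from .datatypes import PlantedEffect


class DependencyError(RuntimeError):
    """A stage's upstream output is missing."""


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    # derived per-stage integer seed, kept below 2^31
    return int(stage_rng(seed, stage).integers(0, 2**31 - 1))


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run all enabled stages; returns the artifact directory."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_log: dict[str, int] = {}

    # -- simulate ---------------------------------------------------------
    cohort = synthetic.generate_cohort(
        config.n_per_group, config.region_coverage, seed=_stage_seed(config.seed, "cohort")
    )
    effects = [
        PlantedEffect(e["subcluster"], e["phenotype"], dict(e["beta_per_group"]))
        for e in config.planted_effects
    ]
    composition = synthetic.generate_composition(
        cohort,
        config.subclusters,
        effects,
        total_nuclei=config.total_nuclei,
        concentration=config.concentration,
        seed=_stage_seed(config.seed, "composition"),
    )
    io.write_cohort(cohort, out / "cohort.tsv")
    io.write_composition(composition, out / "composition")
    io.write_json(
        {
            "planted_effects": [
                {"subcluster": e.subcluster, "phenotype": e.phenotype,
                 "beta_per_group": e.beta_per_group} for e in effects
            ]
        },
        out / "truth.json",
    )
    counts_log["donors"] = len(cohort)
    counts_log["samples"] = len(composition.counts)

    # -- assoc ------------------------------------------------------------
    frame = cohort.frame()
    fits = fit_group_table(
        composition, frame, config.traits,
        weighted=config.weighted, hc=config.hc, contrasts=config.contrasts,
    )
    fits.to_csv(out / "group_fits.tsv", sep="\t", index=False)
    counts_log["fits_attempted"] = len(fits)
    counts_log["fits_converged"] = int(fits["converged"].sum()) if len(fits) else 0

    # -- meta -------------------------------------------------------------
    if fits.empty:
        raise DependencyError("meta stage requires per-group fits from the assoc stage")
    pooled = meta.meta_analyze_table(
        fits, alpha=config.alpha, i2_max=config.i2_max,
        truncate_hksj=config.truncate_hksj,
    )
    pooled.to_csv(out / "meta.tsv", sep="\t", index=False)
    pooled[pooled["conserved"]].to_csv(out / "conserved_only.tsv", sep="\t", index=False)
    counts_log["meta_results"] = len(pooled)
    counts_log["conserved"] = int(pooled["conserved"].sum())

    # -- factors ----------------------------------------------------------
    factor_medians = None
    if config.run_factors:
        fseed = _stage_seed(config.seed, "factors")
        fcounts, _, _ = synthetic.generate_factor_counts(
            config.factor_n_cells, config.factor_n_genes, config.factor_k_true, seed=fseed
        )
        selection = programs.select_num_factors(
            fcounts, config.factor_k_grid, corr_max=config.corr_max, seed=fseed
        )
        model = selection.models[selection.chosen_K]
        samples = cohort.samples()
        rng = stage_rng(config.seed, "factor_cells")
        cell_samples = [samples[i] for i in rng.integers(0, len(samples), fcounts.shape[0])]
        medians = programs.median_scores_per_sample(
            model, np.array([f"{d}|{r}" for d, r in cell_samples])
        )
        idx = pd.MultiIndex.from_tuples(
            [tuple(s.split("|")) for s in medians.index], names=["donor_id", "region"]
        )
        factor_medians = pd.DataFrame(medians.to_numpy(), index=idx, columns=medians.columns)
        factor_medians.to_csv(out / "factor_medians.tsv", sep="\t")
        io.write_json(
            {"chosen_K": selection.chosen_K,
             "max_corr_per_k": selection.max_corr_per_k,
             "satisfied": selection.satisfied},
            out / "factor_selection.json",
        )
        counts_log["factor_samples"] = len(factor_medians)

    # -- subgroups --------------------------------------------------------
    if config.run_subgroups:
        region = config.subgroup_region
        regmask = composition.counts.index.get_level_values("region") == region
        props = composition.counts.loc[regmask]
        props.index = props.index.get_level_values("donor_id")
        blocks = [props]
        fscores = None
        if factor_medians is not None:
            fmask = factor_medians.index.get_level_values("region") == region
            fscores = factor_medians.loc[fmask]
            fscores.index = fscores.index.get_level_values("donor_id")
            fscores = fscores.groupby(level=0).median()
        features = subgroups.assemble_features(blocks, fscores)
        if len(features) >= 3:
            clustering = subgroups.cluster_donors(
                features, range(config.subgroup_k_min, config.subgroup_k_max + 1)
            )
            clustering.labels.to_csv(out / "subgroup_labels.tsv", sep="\t")
            ann = frame.loc[features.index, ["clinical_dx", "cerad", "braak", "group"]]
            subgroups.summarize_groups(clustering.labels, ann).to_csv(
                out / "subgroup_summary.tsv", sep="\t", index=False
            )
            subgroups.enrichment_test(clustering.labels, ann).to_csv(
                out / "subgroup_enrichment.tsv", sep="\t", index=False
            )
            counts_log["subgroup_k"] = clustering.chosen_k

    # -- manifest ---------------------------------------------------------
    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "package": "popcellmeta",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "record_counts": counts_log,
        "outputs": {p.name: _file_hash(p) for p in outputs},
    }
    io.write_json(manifest, out / "manifest.json")
    return out
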