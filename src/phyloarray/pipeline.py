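"""End-to-end orchestration: simulate -> profiles -> diversity/ordination ->
MAMP -> sub-profile discovery -> expression, with TSV outputs, input
validation and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import derive_seed
from .simulate import (
    CommunityTemplate,
    SimulationConfig,
    abundances_to_probes,
    load_reference_community,
    simulate_abundances,
    simulate_ct_table,
)
from . import diversity, discovery, expression, mamp, profiles


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration (YAML-loadable)."""

    out_dir: str = "phyloarray_run"
    seed: int = 0
    threshold: float | None = None  # default: 2x simulated background
    min_replicate_r: float = 0.94
    k: int = 9
    n_perm_error: int = 10_000
    n_perm_rda: int = 50_000
    alpha: float = 0.05
    rf_trees: int = 1000
    effect_multiplier: float = 1.0
    genes: tuple[str, ...] = ("18S", "IL-10", "IFN-g", "TNF-a", "ZO-1")

    def __post_init__(self) -> None:
        if not 0 < self.min_replicate_r < 1:
            raise ValueError("min_replicate_r must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.k < 2 or self.n_perm_error < 1 or self.n_perm_rda < 99:
            raise ValueError("k, n_perm_error, n_perm_rda out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "genes" in raw:
            raw["genes"] = tuple(raw["genes"])
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


def validate_inputs(
    probe_matrix: pd.DataFrame,
    taxonomy: pd.DataFrame,
    metadata: pd.DataFrame,
) -> list[str]:
    """Schema/cross-reference checks; returns a list of problems (empty = ok)."""
    problems = []
    if not probe_matrix.index.is_unique:
        problems.append("duplicate probe ids in matrix")
    if probe_matrix.columns.duplicated().any():
        problems.append("duplicate sample columns in matrix")
    if (probe_matrix.to_numpy() < 0).any():
        problems.append("negative intensities in probe matrix")
    missing = probe_matrix.index.difference(taxonomy.index)
    if len(missing):
        problems.append(f"probes absent from taxonomy map: {list(missing)[:5]}")
    for col in ("l2_group", "l1_group", "n_target_phylotypes"):
        if col not in taxonomy.columns:
            problems.append(f"taxonomy map missing column {col}")
    if "group" not in metadata.columns:
        problems.append("metadata missing 'group' column")
    else:
        samples = {c.rpartition("_r")[0] or c for c in probe_matrix.columns}
        unknown = samples - set(metadata.index)
        if unknown:
            problems.append(f"samples absent from metadata: {sorted(unknown)[:5]}")
    if not metadata.index.is_unique:
        problems.append("duplicate sample ids in metadata")
    return problems


def run_pipeline(
    config: RunConfig,
    template: CommunityTemplate | None = None,
) -> dict:
    """Run every stage on a simulated cohort and write outputs under out_dir.

    Returns a manifest dict (also written as manifest.json). Any stage
    failure leaves a FAILED marker naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    template = template or load_reference_community()
    stage = "setup"
    try:
        # --- simulate ---------------------------------------------------
        stage = "simulate"
        sim = SimulationConfig(
            effect_multiplier=config.effect_multiplier,
            seed=derive_seed(config.seed, "simulate"),
        )
        abund, meta = simulate_abundances(template, sim)
        probe_matrix, taxonomy = abundances_to_probes(abund, sim)
        ct = simulate_ct_table(meta, config.genes, seed=derive_seed(config.seed, "ct"))
        _write(probe_matrix, out / "probe_matrix.tsv")
        _write(taxonomy, out / "taxonomy_map.tsv")
        _write(meta, out / "sample_metadata.tsv")
        ct.to_csv(out / "ct_table.tsv", sep="\t", index=False)

        problems = validate_inputs(probe_matrix, taxonomy, meta)
        if problems:
            raise ValueError("input validation failed: " + "; ".join(problems))

        # --- profiles ---------------------------------------------------
        stage = "profiles"
        averaged, qc = profiles.filter_and_average_replicates(
            probe_matrix, min_r=config.min_replicate_r
        )
        normalized = profiles.min_max_normalize(averaged)
        threshold = config.threshold if config.threshold is not None else sim.threshold_default
        thresholded = profiles.apply_threshold_log10(normalized, threshold)
        l2 = profiles.aggregate(thresholded, taxonomy, "L2")
        l1 = profiles.aggregate(thresholded, taxonomy, "L1")
        rel_l2 = profiles.relative_abundance(l2)
        rel_l1 = profiles.relative_abundance(l1)
        cohort_table = profiles.group_mean_sd(rel_l2, meta)
        _write(qc, out / "replicate_qc.tsv")
        _write(rel_l2, out / "l2_relative_abundance.tsv")
        _write(rel_l1, out / "l1_relative_abundance.tsv")
        _write(cohort_table, out / "l2_cohort_summary.tsv")

        # --- diversity / ordination ------------------------------------
        stage = "diversity"
        alpha_div = diversity.alpha_diversity(thresholded)
        logged = profiles.apply_threshold_log10(normalized, threshold, log10=True)
        pca_res = diversity.pca(logged)
        rda_res = diversity.rda_permutation(
            logged,
            meta["group"],
            n_perm=config.n_perm_rda,
            seed=derive_seed(config.seed, "rda"),
        )
        _write(alpha_div, out / "alpha_diversity.tsv")
        _write(pca_res.scores, out / "pca_scores.tsv")
        _write(rda_res.scores, out / "rda_scores.tsv")

        # --- MAMP -------------------------------------------------------
        stage = "mamp"
        per_sample, per_cohort = mamp.mamp_summary(rel_l2, template.annotations, meta)
        _write(per_sample, out / "mamp_per_sample.tsv")
        _write(per_cohort, out / "mamp_per_cohort.tsv")

        # --- discovery --------------------------------------------------
        stage = "discovery"
        rf_params = discovery.RFParams(n_estimators=config.rf_trees)
        errors, best, selected = discovery.nested_cv_select_method(
            rel_l2, meta, k=config.k,
            seed=derive_seed(config.seed, "discovery"), rf_params=rf_params,
        )
        result = discovery.permutation_test_error(
            rel_l2, meta, best, n_perm=config.n_perm_error, k=config.k,
            seed=derive_seed(config.seed, "discovery"), rf_params=rf_params,
        )
        discovery_out = {
            "per_method_cv_error": errors,
            "best_method": best.label,
            "selected_groups": list(selected),
            "cv_error": result.cv_error,
            "null_median": result.null_median,
            "null_ci": [result.null_ci_low, result.null_ci_high],
            "permutation_p": result.permutation_p,
            "n_perm": result.n_perm,
        }
        (out / "discovery.json").write_text(json.dumps(discovery_out, indent=2))

        # --- expression -------------------------------------------------
        stage = "expression"
        rq = expression.relative_quantity(ct)
        rq.to_csv(out / "relative_quantities.tsv", sep="\t", index=False)
        tests = []
        for gene, block in rq.groupby("gene"):
            block = block.set_index("sample_id")
            res = expression.gated_group_test(
                block["rq"], block["group"], gene=gene, alpha=config.alpha
            )
            for _, row in res.pairwise.iterrows():
                tests.append(
                    {
                        "gene": gene,
                        "test_used": res.test_used,
                        "omnibus_p": res.omnibus_p,
                        **row.to_dict(),
                    }
                )
        pd.DataFrame(tests).to_csv(out / "expression_tests.tsv", sep="\t", index=False)

        genus = expression.genus_ttests(rel_l2, meta)
        _write(genus, out / "genus_ttests.tsv")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise

    cfg_dict = asdict(config)
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "rda_p": rda_res.p_value,
        "discovery_p": result.permutation_p,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
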