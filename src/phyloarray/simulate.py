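"""Synthetic duodenal-mucosa community and microarray data generator.

Real mucosal biopsy datasets of this kind are rarely deposited at the
probe level, so every downstream stage of the package is exercised on
synthetic data whose statistical structure matches what the analysis
assumes: strongly individual-specific compositional profiles at the
genus-like (L2) level, a miniature probe-level decomposition with
technical-replicate noise, and triplicate qPCR Ct values with an 18S
endogenous control.

The generative model is deliberately simple: per-group log-normal
abundances moment-matched to a curated reference table of 65 duodenal
genus-like groups (cohort mean +/- SD of relative abundance, plus Gram
stain, flagellation and genomic GC% annotations), renormalized to 100%
per sample. An optional "planted" differential signal multiplies a
chosen set of groups in one cohort before renormalization, which is how
parameter-recovery and null-calibration experiments are constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import rng_for

COHORTS = ("HC", "CD")

#: Genus-like groups used as the default planted differential sub-profile:
#: three enriched in celiac samples and five enriched in controls.
DEFAULT_PLANTED_GROUPS: tuple[str, ...] = (
    "Prevotella melaninogenica et rel",
    "Haemophilus",
    "Serratia",
    "Prevotella oralis et rel",
    "Ruminococcus bromii et rel",
    "Papillibacter cinnamivorans et rel",
    "Proteus et rel",
    "Clostridium stercorarium et rel",
)

CONTROL_GENE = "18S"


@dataclass(frozen=True)
class CommunityTemplate:
    """Reference community: 65 genus-like groups with cohort moments.

    ``table`` is indexed by group label with columns ``phylum_or_order``,
    ``hc_mean``, ``hc_sd``, ``cd_mean``, ``cd_sd``, ``gram`` (G+/G-),
    ``flagella`` (Y/N/Y/N) and ``gc_percent``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "phylum_or_order", "hc_mean", "hc_sd", "cd_mean", "cd_sd",
            "gram", "flagella", "gc_percent",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"template missing columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            raise ValueError("duplicate group labels in template")
        for col in ("hc_mean", "cd_mean"):
            if (self.table[col] < 0).any():
                raise ValueError(f"negative abundances in {col}")
            total = float(self.table[col].sum())
            if not (98.0 <= total <= 102.0):
                raise ValueError(
                    f"{col} sums to {total:.2f}, expected ~100"
                )

    @property
    def group_names(self) -> list[str]:
        return list(self.table.index)

    @property
    def annotations(self) -> pd.DataFrame:
        """Gram / flagella / GC% annotation block (one row per group)."""
        return self.table[["gram", "flagella", "gc_percent"]].copy()

    def means(self, cohort: str) -> pd.Series:
        return self.table[f"{cohort.lower()}_mean"].astype(float)

    def sds(self, cohort: str) -> pd.Series:
        return self.table[f"{cohort.lower()}_sd"].astype(float)


def load_reference_community() -> CommunityTemplate:
    """Load the packaged 65-group duodenal community reference table."""
    ref = resources.files("phyloarray").joinpath("data/community_reference.tsv")
    try:
        with resources.as_file(ref) as path:
            table = pd.read_csv(path, sep="\t", index_col="group")
    except FileNotFoundError as exc:  # pragma: no cover - packaging error
        raise FileNotFoundError(
            "packaged fixture data/community_reference.tsv not found"
        ) from exc
    return CommunityTemplate(table)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic cohort.

    ``shared_template_cohort`` controls the null structure: when set (the
    default, "HC"), both cohorts are drawn from that cohort's moments and
    any group difference comes only from ``effect_multiplier`` applied to
    ``planted_groups`` in ``effect_cohort``. When ``None``, each cohort is
    drawn from its own reference column.
    """

    n_hc: int = 9
    n_cd: int = 10
    planted_groups: tuple[str, ...] = DEFAULT_PLANTED_GROUPS
    effect_multiplier: float = 1.0
    effect_cohort: str = "CD"
    shared_template_cohort: str | None = "HC"
    probes_per_group: int = 5
    replicate_noise_sd: float = 0.10
    background_level: float = 50.0
    signal_scale: float = 100_000.0
    rare_mean_cutoff: float = 0.01
    abundance_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 1 or self.n_cd < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.effect_multiplier <= 0:
            raise ValueError("effect_multiplier must be > 0")
        if self.effect_cohort not in COHORTS:
            raise ValueError(f"effect_cohort must be one of {COHORTS}")
        if self.probes_per_group < 1:
            raise ValueError("probes_per_group must be >= 1")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")

    @property
    def threshold_default(self) -> float:
        """Default signal-intensity threshold: twice the background level."""
        return 2.0 * self.background_level

    def validate_against(self, template: CommunityTemplate) -> None:
        unknown = set(self.planted_groups) - set(template.group_names)
        if unknown:
            raise ValueError(f"planted groups not in template: {sorted(unknown)}")


def _lognormal_params(mean: np.ndarray, sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Moment-match (mu, sigma) of a log-normal to arithmetic mean/SD."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def sample_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: sample_id indexed, one ``group`` column (HC/CD)."""
    ids = [f"HC{i + 1}" for i in range(config.n_hc)]
    ids += [f"CD{i + 1}" for i in range(config.n_cd)]
    groups = ["HC"] * config.n_hc + ["CD"] * config.n_cd
    return pd.DataFrame({"group": groups}, index=pd.Index(ids, name="sample_id"))


def simulate_abundances(
    template: CommunityTemplate,
    config: SimulationConfig,
    max_retries: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample relative abundances (percent of total).

    Returns ``(abundances, metadata)`` where abundances is groups x samples
    and each column sums to 100. Per group, values are log-normal with
    moments matched to the template; groups rarer than ``rare_mean_cutoff``
    percent are zeroed in a sample whenever the draw falls below
    ``abundance_floor`` percent, emulating below-detection dropouts.
    """
    config.validate_against(template)
    rng = rng_for(config.seed, "abundances")
    meta = sample_metadata(config)
    groups = template.group_names
    planted = set(config.planted_groups)

    columns = {}
    for sample_id, cohort in meta["group"].items():
        source = config.shared_template_cohort or cohort
        mu, sigma = _lognormal_params(
            template.means(source).to_numpy(), template.sds(source).to_numpy()
        )
        for _ in range(max_retries):
            draw = np.where(
                np.isfinite(mu), np.exp(mu + sigma * rng.standard_normal(len(groups))), 0.0
            )
            rare = template.means(source).to_numpy() < config.rare_mean_cutoff
            draw[rare & (draw < config.abundance_floor)] = 0.0
            if config.effect_multiplier != 1.0 and cohort == config.effect_cohort:
                idx = [i for i, g in enumerate(groups) if g in planted]
                draw[idx] *= config.effect_multiplier
            total = draw.sum()
            if total > 0:
                columns[sample_id] = 100.0 * draw / total
                break
        else:
            raise RuntimeError(f"sample {sample_id}: zero total signal after retries")

    abund = pd.DataFrame(columns, index=pd.Index(groups, name="group"))
    return abund, meta


def abundances_to_probes(
    abundances: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decompose group abundances into a probe matrix with two replicates.

    Each group's signal is split over ``probes_per_group`` probes with
    fixed Dirichlet weights (drawn once from the seed, shared by all
    samples), scaled to fluorescence units, and a background offset is
    added. Two technical replicates per sample are emitted with
    multiplicative log-normal noise of scale ``replicate_noise_sd``.

    Returns ``(probe_matrix, taxonomy_map)``; probe matrix columns are
    ``<sample>_r1`` / ``<sample>_r2``; the taxonomy map has one synthetic
    phylotype per probe (columns: probe_id, phylotype_id, l2_group,
    l1_group, n_target_phylotypes).
    """
    rng = rng_for(config.seed, "probes")
    template = load_reference_community()
    l1_lookup = template.table["phylum_or_order"].to_dict()

    groups = list(abundances.index)
    k = config.probes_per_group
    weights = rng.dirichlet(np.ones(k), size=len(groups))  # rows sum to 1

    probe_ids, tax_rows = [], []
    rows = []
    for gi, group in enumerate(groups):
        for j in range(k):
            pid = f"probe_{gi + 1:03d}_{j + 1}"
            probe_ids.append(pid)
            tax_rows.append(
                {
                    "probe_id": pid,
                    "phylotype_id": f"phylotype_{gi + 1:03d}_{j + 1}",
                    "l2_group": group,
                    "l1_group": l1_lookup.get(group, "Unassigned"),
                    "n_target_phylotypes": 1,
                }
            )
            rows.append(
                abundances.loc[group].to_numpy() / 100.0 * config.signal_scale * weights[gi, j]
            )
    signal = np.asarray(rows)  # probes x samples

    cols = {}
    for rep in (1, 2):
        noise = np.exp(
            config.replicate_noise_sd * rng.standard_normal(signal.shape)
        )
        background = config.background_level * np.exp(
            0.2 * rng.standard_normal(signal.shape)
        )
        measured = signal * noise + background
        for si, sample in enumerate(abundances.columns):
            cols[f"{sample}_r{rep}"] = measured[:, si]

    probe_matrix = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))
    # interleave replicate columns per sample for readability
    order = [f"{s}_r{r}" for s in abundances.columns for r in (1, 2)]
    probe_matrix = probe_matrix[order]
    taxonomy = pd.DataFrame(tax_rows).set_index("probe_id")
    return probe_matrix, taxonomy


def simulate_ct_table(
    metadata: pd.DataFrame,
    genes: Sequence[str],
    shifts: Mapping[tuple[str, str], float] | None = None,
    baseline_delta_ct: Mapping[str, float] | None = None,
    replicate_sd: float = 0.15,
    control_ct: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Triplicate qPCR Ct values per sample x gene with an 18S control.

    ``shifts`` maps (cohort, gene) -> Ct offset added to that gene's mean
    Ct in that cohort; a negative shift means higher expression (fewer
    cycles to threshold). ``baseline_delta_ct`` gives each target gene's
    Ct distance from the 18S control (default 10 cycles).

    Returns a long table with columns sample_id, group, gene, replicate, ct.
    """
    genes = list(genes)
    if CONTROL_GENE not in genes:
        raise ValueError(f"gene list must contain the {CONTROL_GENE} endogenous control")
    shifts = dict(shifts or {})
    baseline_delta_ct = dict(baseline_delta_ct or {})
    rng = rng_for(seed, "ct")

    records = []
    for sample_id, cohort in metadata["group"].items():
        sample_offset = rng.normal(0.0, 0.3)  # cDNA-input variation, cancels in dCt
        for gene in genes:
            if gene == CONTROL_GENE:
                mean_ct = control_ct + sample_offset
            else:
                mean_ct = (
                    control_ct
                    + baseline_delta_ct.get(gene, 10.0)
                    + shifts.get((cohort, gene), 0.0)
                    + sample_offset
                )
            for rep in (1, 2, 3):
                ct = mean_ct + (rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0)
                records.append(
                    {
                        "sample_id": sample_id,
                        "group": cohort,
                        "gene": gene,
                        "replicate": rep,
                        "ct": ct,
                    }
                )
    return pd.DataFrame.from_records(records)
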