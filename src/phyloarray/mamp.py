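"""MAMP (microbe-associated molecular pattern) content estimation.

Toll-like receptors sense conserved microbial motifs: lipoteichoic acid
of Gram-positive walls (TLR2), lipopolysaccharide of Gram-negative
membranes (TLR4), flagellin (TLR5) and unmethylated CpG DNA (TLR9).
Given genus-like relative abundances and per-group annotations (Gram
stain, flagellation, genomic GC% of a representative species), the
community-level ligand loads are estimated as abundance-weighted
summaries: Gram+/Gram- fractions, the flagellated fraction (groups
annotated unambiguously flagellated; strain-variable "Y/N" groups are
excluded), the abundance-weighted mean genomic GC%, and the fraction of
high-GC (>58%) groups as a CpG-load proxy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HIGH_GC_CUTOFF = 58.0

_GRAM_ALIASES = {
    "positive": "G+", "negative": "G-", "g+": "G+", "g-": "G-",
}

_SUMMARY_COLUMNS = (
    "gram_positive_pct",
    "gram_negative_pct",
    "flagellated_pct",
    "mean_gc_pct",
    "high_gc_pct",
)


def _norm_gram(value: str) -> str:
    v = str(value).strip()
    return _GRAM_ALIASES.get(v.lower(), v)


def _check_annotated(abund: pd.Series, annotations: pd.DataFrame) -> pd.DataFrame:
    missing = abund.index.difference(annotations.index)
    if len(missing):
        raise KeyError(f"unannotated groups: {list(missing)}")
    return annotations.loc[abund.index]


def gram_fraction(abund: pd.Series, annotations: pd.DataFrame, which: str = "positive") -> float:
    """Summed relative abundance (%) of Gram-positive or -negative groups."""
    ann = _check_annotated(abund, annotations)
    target = _norm_gram("G+" if which in ("positive", "G+") else "G-")
    mask = ann["gram"].map(_norm_gram) == target
    return float(abund[mask.to_numpy()].sum())


def flagellated_fraction(abund: pd.Series, annotations: pd.DataFrame) -> float:
    """Summed abundance (%) of groups annotated flagellated ("Y" only)."""
    ann = _check_annotated(abund, annotations)
    mask = ann["flagella"].astype(str).str.strip() == "Y"
    return float(abund[mask.to_numpy()].sum())


def mean_gc(abund: pd.Series, annotations: pd.DataFrame) -> float:
    """Abundance-weighted mean genomic GC%, weights renormalized to 1."""
    ann = _check_annotated(abund, annotations)
    w = abund.to_numpy(dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("sample has zero total abundance")
    return float(np.dot(w / total, ann["gc_percent"].to_numpy(dtype=float)))


def high_gc_fraction(
    abund: pd.Series, annotations: pd.DataFrame, cutoff: float = HIGH_GC_CUTOFF
) -> float:
    """Summed abundance (%) of groups with genomic GC% strictly above cutoff."""
    ann = _check_annotated(abund, annotations)
    mask = ann["gc_percent"].to_numpy(dtype=float) > cutoff
    return float(abund[mask].sum())


def mamp_summary_per_sample(
    rel_abund: pd.DataFrame, annotations: pd.DataFrame, cutoff: float = HIGH_GC_CUTOFF
) -> pd.DataFrame:
    """All five MAMP statistics for every sample column."""
    rows = {}
    for sample in rel_abund.columns:
        abund = rel_abund[sample]
        rows[sample] = {
            "gram_positive_pct": gram_fraction(abund, annotations, "positive"),
            "gram_negative_pct": gram_fraction(abund, annotations, "negative"),
            "flagellated_pct": flagellated_fraction(abund, annotations),
            "mean_gc_pct": mean_gc(abund, annotations),
            "high_gc_pct": high_gc_fraction(abund, annotations, cutoff),
        }
    out = pd.DataFrame(rows).T[list(_SUMMARY_COLUMNS)]
    out.index.name = "sample_id"
    return out


def mamp_summary(
    rel_abund: pd.DataFrame,
    annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    cutoff: float = HIGH_GC_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample MAMP statistics plus cohort mean +/- SD summary.

    Returns ``(per_sample, per_cohort)``; the cohort frame is indexed by
    (cohort, statistic) with ``mean`` and ``sd`` columns.
    """
    per_sample = mamp_summary_per_sample(rel_abund, annotations, cutoff)
    joined = per_sample.join(metadata["group"])
    records = []
    for cohort, block in joined.groupby("group"):
        for stat in _SUMMARY_COLUMNS:
            records.append(
                {
                    "cohort": cohort,
                    "statistic": stat,
                    "mean": block[stat].mean(),
                    "sd": block[stat].std(ddof=1),
                }
            )
    per_cohort = pd.DataFrame.from_records(records).set_index(["cohort", "statistic"])
    return per_sample, per_cohort
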