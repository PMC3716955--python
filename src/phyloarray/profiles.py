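"""Probe-level preprocessing and taxon-profile aggregation.

Mirrors the standard phylogenetic-microarray workflow: technical
replicates are QC'd by Pearson correlation and averaged, samples are
min-max normalized against a common envelope, a signal-intensity
threshold suppresses background/cross-hybridization noise, and probe
signals are summed into genus-like (L2) and phylum-like (L1) profiles.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd


def split_replicate_columns(matrix: pd.DataFrame) -> dict[str, list[str]]:
    """Group columns named ``<sample>_r<k>`` by sample id.

    Columns without the replicate suffix are treated as single-replicate
    samples named by the full column label.
    """
    groups: dict[str, list[str]] = {}
    for col in matrix.columns:
        sample, sep, rep = col.rpartition("_r")
        if sep and rep.isdigit():
            groups.setdefault(sample, []).append(col)
        else:
            groups.setdefault(col, []).append(col)
    return groups


def filter_and_average_replicates(
    matrix: pd.DataFrame, min_r: float = 0.94
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average technical replicates of samples whose Pearson r exceeds ``min_r``.

    Samples failing the threshold are excluded; samples with a single
    replicate pass through with a warning flag. With more than two
    replicates, the best-correlating pair is kept and averaged.

    Returns ``(averaged_matrix, qc_report)``; the QC report has one row per
    sample with columns ``replicate_r`` (NaN for singletons) and ``kept``.
    """
    if not 0.0 < min_r < 1.0:
        raise ValueError("min_r must lie in (0, 1)")
    kept_cols: dict[str, np.ndarray] = {}
    qc_rows = []
    for sample, cols in split_replicate_columns(matrix).items():
        if len(cols) == 1:
            warnings.warn(f"sample {sample}: single replicate, passed through unchecked")
            kept_cols[sample] = matrix[cols[0]].to_numpy(dtype=float)
            qc_rows.append({"sample_id": sample, "replicate_r": np.nan, "kept": True})
            continue
        best_pair, best_r = None, -np.inf
        for a, b in combinations(cols, 2):
            r = float(np.corrcoef(matrix[a], matrix[b])[0, 1])
            if r > best_r:
                best_pair, best_r = (a, b), r
        kept = best_r > min_r
        qc_rows.append({"sample_id": sample, "replicate_r": best_r, "kept": kept})
        if kept:
            kept_cols[sample] = matrix[list(best_pair)].mean(axis=1).to_numpy()
    qc = pd.DataFrame(qc_rows).set_index("sample_id")
    averaged = pd.DataFrame(kept_cols, index=matrix.index)
    return averaged, qc


def min_max_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Affinely map each sample's intensities onto a common [min, max] envelope.

    The reference envelope is the median of per-sample minima to the median
    of per-sample maxima, so the transform is monotone within each sample
    and the normalized samples share their extremes.
    """
    if matrix.shape[1] < 2:
        raise ValueError("min-max normalization needs at least two samples")
    mins = matrix.min(axis=0)
    maxs = matrix.max(axis=0)
    flat = maxs[maxs <= mins]
    if len(flat):
        raise ValueError(f"constant-signal sample(s): {list(flat.index)}")
    ref_min = float(np.median(mins))
    ref_max = float(np.median(maxs))
    scaled = (matrix - mins) / (maxs - mins) * (ref_max - ref_min) + ref_min
    return scaled


def apply_threshold_log10(
    matrix: pd.DataFrame, threshold: float, log10: bool = False
) -> pd.DataFrame:
    """Zero out intensities at or below ``threshold``; optionally log10.

    The boundary is strict: only values strictly above the threshold
    survive. With ``log10=True`` surviving values are log10-transformed
    and suppressed ones remain exactly zero.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = matrix.where(matrix > threshold, 0.0)
    if log10:
        out = out.where(out == 0.0, np.log10(out.where(out > 0.0)))
    return out


def aggregate(matrix: pd.DataFrame, taxonomy: pd.DataFrame, level: str = "L2") -> pd.DataFrame:
    """Sum probe intensities into genus-like (L2) or phylum-like (L1) taxa.

    At L2 the probe intensities are summed per group directly; at L1 each
    probe's intensity is first divided by its number of known target
    phylotypes, so promiscuous probes are not over-counted at the
    coarser level.
    """
    if level not in ("L1", "L2"):
        raise ValueError("level must be 'L1' or 'L2'")
    unmapped = matrix.index.difference(taxonomy.index)
    if len(unmapped):
        raise KeyError(f"probes missing from taxonomy map: {list(unmapped)}")
    tax = taxonomy.loc[matrix.index]
    if level == "L2":
        grouped = matrix.groupby(tax["l2_group"]).sum()
    else:
        weighted = matrix.div(tax["n_target_phylotypes"].astype(float), axis=0)
        grouped = weighted.groupby(tax["l1_group"]).sum()
    grouped.index.name = "taxon"
    return grouped.sort_index()


def relative_abundance(profile: pd.DataFrame) -> pd.DataFrame:
    """Percent-of-total per sample (columns sum to 100)."""
    totals = profile.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return 100.0 * profile / totals


def group_mean_sd(rel_abund: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean +/- SD of per-sample relative abundances.

    Returns a taxa-indexed frame with ``<cohort>_mean`` / ``<cohort>_sd``
    columns for every cohort in ``metadata['group']``.
    """
    out = {}
    for cohort, members in metadata.groupby("group").groups.items():
        cols = [c for c in rel_abund.columns if c in set(members)]
        block = rel_abund[cols]
        out[f"{str(cohort).lower()}_mean"] = block.mean(axis=1)
        out[f"{str(cohort).lower()}_sd"] = block.std(axis=1, ddof=1)
    return pd.DataFrame(out)
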