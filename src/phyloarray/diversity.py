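"""Alpha diversity and (constrained) ordination.

Simpson's reciprocal index (1/D) and the Shannon index (natural log) are
computed on probe-level signal normalized to proportions. Unconstrained
structure is summarized by PCA on centered log10 profiles. Group
separation is tested with redundancy analysis (RDA): the profile matrix
is regressed on the group indicator, the constrained (between-group)
variance yields a pseudo-F statistic, and significance comes from a
seeded label-permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from ._seeds import rng_for


def _proportions(vector: np.ndarray) -> np.ndarray:
    v = np.asarray(vector, dtype=float)
    if (v < 0).any():
        raise ValueError("signal vector must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("signal vector sums to zero")
    return v / total


def simpson_reciprocal(vector) -> float:
    """Simpson's reciprocal diversity 1/D = 1 / sum(p_i^2)."""
    p = _proportions(np.asarray(vector))
    return float(1.0 / np.sum(p**2))


def shannon(vector) -> float:
    """Shannon index H = -sum(p_i ln p_i), zeros ignored."""
    p = _proportions(np.asarray(vector))
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def alpha_diversity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample 1/D and Shannon on a features x samples signal matrix."""
    rows = {
        sample: {
            "simpson_reciprocal": simpson_reciprocal(matrix[sample]),
            "shannon": shannon(matrix[sample]),
        }
        for sample in matrix.columns
    }
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    return out


@dataclass(frozen=True)
class OrdinationResult:
    """Sample scores plus per-axis variance fractions; RDA fields optional."""

    scores: pd.DataFrame
    proportion_explained: np.ndarray
    constrained_fraction: float | None = None
    pseudo_f: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None


def pca(profile: pd.DataFrame, n_components: int | None = None) -> OrdinationResult:
    """PCA of a taxa x samples profile (column-centered, unscaled).

    Input is expected on log10 scale; rows are features, columns samples.
    """
    X = profile.T.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ValueError("zero-variance input")
    n_components = n_components or min(X.shape[0] - 1, X.shape[1])
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    frame = pd.DataFrame(
        scores,
        index=profile.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return OrdinationResult(frame, model.explained_variance_ratio_)


def _group_design(labels: np.ndarray) -> np.ndarray:
    """Centered dummy design for group labels (full column rank)."""
    cats = np.unique(labels)
    design = np.stack([(labels == c).astype(float) for c in cats[:-1]], axis=1)
    return design - design.mean(axis=0)


def _constrained_ss(Y: np.ndarray, labels: np.ndarray) -> float:
    """Between-group sum of squares of a centered response matrix."""
    ss = 0.0
    for cat in np.unique(labels):
        block = Y[labels == cat]
        ss += len(block) * float(np.sum(block.mean(axis=0) ** 2))
    return ss


def rda_permutation(
    profile: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_perm: int = 50_000,
    seed: int = 0,
) -> OrdinationResult:
    """RDA of a taxa x samples profile constrained by group labels.

    The pseudo-F statistic is (SS_constrained/df_groups) /
    (SS_residual/df_residual); the permutation p-value uses the +1
    convention, p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so p is never
    exactly zero.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = np.asarray(pd.Series(labels).loc[list(profile.columns)] if isinstance(labels, pd.Series) else labels)
    if len(labels) != profile.shape[1]:
        raise ValueError("labels must match sample columns")
    cats, counts = np.unique(labels, return_counts=True)
    if len(cats) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")

    Y = profile.T.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    n = Y.shape[0]
    ss_total = float(np.sum(Y**2))
    if ss_total <= 0:
        raise ValueError("zero-variance input")
    df_c = len(cats) - 1
    df_r = n - len(cats)

    def pseudo_f(lab: np.ndarray) -> tuple[float, float]:
        ss_c = _constrained_ss(Y, lab)
        ss_r = ss_total - ss_c
        return ss_c, (ss_c / df_c) / (ss_r / df_r)

    ss_c_obs, f_obs = pseudo_f(labels)

    rng = rng_for(seed, "rda")
    exceed = 0
    for _ in range(n_perm):
        _, f_perm = pseudo_f(rng.permutation(labels))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)

    # constrained axis scores: SVD of the fitted (group-mean) part
    design = _group_design(labels)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    fitted = design @ beta
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    keep = s > 1e-12 * (s[0] if len(s) else 1.0)
    scores = pd.DataFrame(
        (u[:, keep] * s[keep]),
        index=profile.columns,
        columns=[f"RDA{i + 1}" for i in range(int(keep.sum()))],
    )
    axis_fractions = (s[keep] ** 2) / ss_total
    return OrdinationResult(
        scores,
        axis_fractions,
        constrained_fraction=ss_c_obs / ss_total,
        pseudo_f=f_obs,
        p_value=p,
        n_permutations=n_perm,
    )
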