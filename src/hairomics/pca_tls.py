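"""Variability analysis: PCA, Total Loading Scores, driver selection,
and tSNE embedding with permutation significance.

The Total Loading Score (TLS) summarises how strongly a protein drives
cohort variability: for each of the first five principal components the
protein's loading is weighted by that component's proportion of
variance, and the weighted scores are summed,

    weighted score = loading x proportion of variance
    TLS            = sum over PC1..PC5 of the weighted scores.

Loadings enter as absolute values by default — TLS is an importance
measure and signed summation would let opposite-signed loadings cancel —
with signed summation available behind ``magnitude=False``.  The
proteins in the top 5% of TLS are reported as the main drivers of
variability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .data import SpectralCountMatrix

__all__ = [
    "PCAResult",
    "pca",
    "total_loading_scores",
    "select_top_fraction",
    "variance_explained_by_subset",
    "tsne_embed",
    "tsne_group_significance",
    "TsneSignificance",
]


def _log1p_columns(matrix: SpectralCountMatrix, log_transform: bool) -> pd.DataFrame:
    x = matrix.counts.T.astype(float)  # subjects as observations
    return np.log1p(x) if log_transform else x


@dataclass
class PCAResult:
    """Exact PCA of subjects-by-proteins data.

    ``scores`` are subject coordinates, ``loadings`` the per-protein
    eigenvector entries ("loading scores"), ``variance_proportions`` the
    fraction of total variance per component.  Components carry a
    deterministic sign: the largest-magnitude loading of each component
    is positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_proportions: pd.Series


def pca(
    matrix: SpectralCountMatrix,
    log_transform: bool = True,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """Principal component analysis with subjects as observations.

    Computed by exact SVD of the (optionally log1p-transformed,
    centered, and variance-scaled) data matrix, equivalent to an
    eigendecomposition of the covariance (correlation when ``scale``)
    matrix.  Raises on a matrix with no variance.
    """
    x = _log1p_columns(matrix, log_transform).to_numpy()
    n_subj, n_prot = x.shape
    if n_subj < 2 or n_prot < 2:
        raise ValueError("PCA needs at least 2 subjects and 2 proteins")
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance protein(s) left unscaled", stacklevel=2
            )
            sd = np.where(zero, 1.0, sd)
        x = x / sd
    if not np.any(x != x.mean()):
        raise ValueError("matrix is constant: no variance to decompose")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2 / (n_subj - 1)
    total = var.sum()
    if total == 0:
        raise ValueError("matrix is constant: no variance to decompose")

    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1

    comp = [f"PC{i + 1}" for i in range(len(s))]
    subjects = matrix.counts.columns
    return PCAResult(
        scores=pd.DataFrame(u * s, index=subjects, columns=comp),
        loadings=pd.DataFrame(vt.T, index=matrix.counts.index, columns=comp),
        variance_proportions=pd.Series(var / total, index=comp, name="variance_proportion"),
    )


def total_loading_scores(
    pca_result: PCAResult,
    n_pcs: int = 5,
    magnitude: bool = True,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Per-protein Total Loading Scores over the first ``n_pcs`` components.

    Returns a DataFrame with the loadings and weighted scores for each
    used component, the ``tls`` column, a dense ``rank`` (1 = highest
    TLS, ties broken by protein id), and ``is_top`` marking the
    ``ceil(top_fraction x n_proteins)`` highest-TLS proteins.
    """
    if n_pcs > pca_result.loadings.shape[1]:
        raise ValueError(
            f"n_pcs={n_pcs} exceeds the {pca_result.loadings.shape[1]} available components"
        )
    comp = list(pca_result.loadings.columns[:n_pcs])
    loadings = pca_result.loadings[comp]
    weights = pca_result.variance_proportions[comp]
    base = loadings.abs() if magnitude else loadings
    weighted = base * weights  # broadcasts over columns
    tls = weighted.sum(axis=1)

    table = pd.concat(
        {
            "loading": loadings,
            "weighted": weighted,
        },
        axis=1,
    )
    table.columns = [f"{kind}_{pc.lower()}" for kind, pc in table.columns]
    table["tls"] = tls
    # rank with deterministic tie-break on protein id
    ordered_ids = sorted(table.index, key=lambda pid: (-table.at[pid, "tls"], pid))
    table["rank"] = pd.Series(range(1, len(ordered_ids) + 1), index=ordered_ids)
    n_top = math.ceil(top_fraction * len(table))
    table["is_top"] = table["rank"] <= n_top
    return table


def select_top_fraction(tls_table: pd.DataFrame, top_fraction: float = 0.05) -> list[str]:
    """Ids of the ``ceil(fraction x n)`` highest-TLS proteins.

    Ties at the cutoff are broken by protein id (lexicographically
    smaller id wins), so the selection is deterministic.
    """
    if tls_table.empty:
        raise ValueError("empty TLS table")
    if not (0 < top_fraction <= 1):
        raise ValueError(f"top_fraction must lie in (0, 1], got {top_fraction}")
    n_top = math.ceil(top_fraction * len(tls_table))
    ordered = sorted(tls_table.index, key=lambda pid: (-tls_table.at[pid, "tls"], pid))
    return ordered[:n_top]


def variance_explained_by_subset(
    matrix: SpectralCountMatrix, subset: Sequence[str], log_transform: bool = True
) -> float:
    """Percent of total per-protein variance carried by a protein subset.

    Defined as 100 x (sum of per-protein variances over the subset) /
    (sum over all proteins), on the same transformed scale the PCA saw.
    This is the package's operational definition of "percent of
    variability explained" by a driver set.
    """
    subset = list(subset)
    unknown = [p for p in subset if p not in matrix.counts.index]
    if unknown:
        raise KeyError(f"subset proteins not in matrix: {unknown[:5]}")
    if not subset:
        warnings.warn("empty subset explains 0% of variance", stacklevel=2)
        return 0.0
    x = _log1p_columns(matrix, log_transform)
    per_protein = x.var(axis=0, ddof=1)
    total = per_protein.sum()
    if total == 0:
        raise ValueError("matrix has no variance")
    return float(100.0 * per_protein.loc[subset].sum() / total)


def max_perplexity(n_subjects: int) -> int:
    """Largest perplexity the embedding accepts, floor((n-1)/3)."""
    return max(1, (n_subjects - 1) // 3)


def tsne_embed(
    matrix: SpectralCountMatrix,
    seed: Optional[int] = None,
    max_iter: int = 1000,
    perplexity: float | str = "max",
    n_repeats: int = 10,
    log_transform: bool = True,
) -> list[pd.DataFrame]:
    """Repeated 2-D tSNE embeddings of the subjects.

    tSNE is stochastic, so the computation is repeated ``n_repeats``
    times with distinct seeds derived from the master ``seed``;
    downstream interpretation should hold across repeats.  Perplexity
    ``"max"`` resolves to the largest value valid for the subject count
    (floor((n-1)/3)).
    """
    x = _log1p_columns(matrix, log_transform).to_numpy()
    n = x.shape[0]
    if n < 4:
        raise ValueError("tSNE needs at least 4 subjects")
    perp = float(max_perplexity(n)) if perplexity == "max" else float(perplexity)
    if not (0 < perp < n):
        raise ValueError(f"perplexity {perp} invalid for {n} subjects")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    out = []
    for rep_seed in child_seeds:
        # random init: each repeat is a genuinely independent embedding
        emb = TSNE(
            n_components=2,
            perplexity=perp,
            max_iter=max_iter,
            init="random",
            random_state=int(rep_seed),
        ).fit_transform(x)
        out.append(
            pd.DataFrame(emb, index=matrix.counts.columns, columns=["tsne1", "tsne2"])
        )
    return out


@dataclass
class TsneSignificance:
    """Observed statistic, label-permutation null, and empirical p."""

    observed_statistic: float
    null_values: np.ndarray
    empirical_p: float
    n_permutations: int
    embedding: pd.DataFrame


def tsne_group_significance(
    matrix: SpectralCountMatrix,
    group_labels: Sequence,
    statistic: str | Callable = "silhouette",
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    max_iter: int = 1000,
    perplexity: float | str = "max",
) -> TsneSignificance:
    """Permutation significance of a grouping in the tSNE embedding.

    The statistic (mean silhouette width of ``group_labels`` in the 2-D
    embedding by default, or any ``f(embedding, labels)`` callable) is
    computed on the observed labels and on ``n_permutations`` random
    label permutations over a fixed embedding; labels are exchangeable
    under the null, so permuting them is equivalent to permuting the
    dataset columns.  ``p = (1 + #{null >= observed}) / (1 + n)``.
    """
    labels = np.asarray(group_labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 distinct groups")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    ss = np.random.SeedSequence(seed)
    embed_seed = int(ss.generate_state(1)[0] % (2**31))
    emb = tsne_embed(
        matrix, seed=embed_seed, max_iter=max_iter, perplexity=perplexity, n_repeats=1
    )[0]

    if callable(statistic):
        stat = statistic
    elif statistic == "silhouette":
        stat = lambda e, lab: float(silhouette_score(e, lab))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    coords = emb.to_numpy()
    observed = float(stat(coords, labels))
    rng = np.random.default_rng(ss.spawn(1)[0])
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = stat(coords, rng.permutation(labels))
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_permutations)
    return TsneSignificance(observed, null, p, n_permutations, emb)
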