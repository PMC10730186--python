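"""Unconstrained and constrained ordination plus the ANOSIM permutation test.

PCoA embeds a dissimilarity matrix by Gower double-centering and
eigendecomposition; axes with negative eigenvalues are reported but carry no
coordinates.  ANOSIM contrasts between- vs within-group dissimilarity ranks,
with significance from seeded label permutations (or exhaustive enumeration
for small designs).  ``corr_axes`` reproduces the mothur ``corr.axes``
workflow: Spearman correlation of each taxon with an ordination axis.  CCA is
the classical ter Braak chi-square-weighted constrained ordination.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .tables_io import RelativeAbundanceTable
from .univariate_stats import spearman as _spearman

__all__ = [
    "OrdinationResult",
    "AnosimResult",
    "AxisCorrelation",
    "CCAResult",
    "pcoa",
    "anosim",
    "corr_axes",
    "cca",
]


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: pd.DataFrame        # samples x retained axes
    eigenvalues: np.ndarray          # all eigenvalues, sorted descending
    fit_r2: float                    # squared corr(original d, embedded d); NaN if undefined


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str = "permutation"      # or "exact"


@dataclass
class AxisCorrelation:
    taxon_id: str
    axis: int
    rho: float
    p_value: float

    @property
    def vector_length(self) -> float:
        """Arrow length when overlaid on an ordination plot."""
        return abs(self.rho)


@dataclass
class CCAResult:
    eigenvalues: np.ndarray          # constrained eigenvalues, descending
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    constraint_scores: pd.DataFrame
    total_inertia: float
    dropped_constraints: list[str] = field(default_factory=list)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinates analysis of a dissimilarity matrix.

    Negative eigenvalues (non-Euclidean input) are retained in
    ``eigenvalues`` but contribute no coordinate axes.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    dm = np.asarray(d.data, dtype=float)
    ids = list(d.ids)
    n = dm.shape[0]
    # Gower double-centering of -0.5 d^2
    a = -0.5 * dm ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals).max(initial=0.0))
    k = min(n_axes, int(pos.sum()))
    if k == 0:
        coords = pd.DataFrame(
            np.zeros((n, n_axes)), index=ids,
            columns=[f"PCo{i + 1}" for i in range(n_axes)],
        )
        return OrdinationResult(ids, coords, evals, float("nan"))
    coords_arr = np.zeros((n, n_axes))
    coords_arr[:, :k] = evecs[:, :k] * np.sqrt(evals[:k])
    coords = pd.DataFrame(coords_arr, index=ids,
                          columns=[f"PCo{i + 1}" for i in range(n_axes)])
    # goodness of fit: squared correlation of original vs embedded distances
    iu = np.triu_indices(n, 1)
    orig = dm[iu]
    emb = np.sqrt(((coords_arr[:, None, :] - coords_arr[None, :, :]) ** 2).sum(-1))[iu]
    if orig.std() == 0 or emb.std() == 0:
        fit_r2 = float("nan")
    else:
        fit_r2 = float(np.corrcoef(orig, emb)[0, 1] ** 2)
    return OrdinationResult(ids, coords, evals, fit_r2)


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    # Clarke's divisor M/2 with M = n(n-1)/2 ranked dissimilarities keeps R in [-1, 1]
    m = ranks.size
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)


def anosim(d: DistanceMatrix, labels, n_permutations: int = 999,
           seed: int | None = None, exact: bool = False) -> AnosimResult:
    """Analysis of similarities on a dissimilarity matrix.

    R = (mean between-group rank − mean within-group rank) / (n(n−1)/4),
    over the M = n(n−1)/2 dissimilarities ranked with mid-ranks.  The permutation
    p-value is (1 + #{permuted R ≥ observed}) / (n_permutations + 1); with
    ``exact=True`` every distinct label permutation is enumerated instead and
    p is the fraction of permutations with R ≥ observed.
    """
    labels = np.asarray(labels)
    ids = list(d.ids)
    if labels.size != len(ids):
        raise ValueError("labels must match the distance matrix samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(dm[iu])

    def within_mask(lab: np.ndarray) -> np.ndarray:
        return lab[iu[0]] == lab[iu[1]]

    r_obs = _anosim_r(ranks, within_mask(labels))

    if exact:
        perms = set(itertools.permutations(labels.tolist()))
        count = sum(_anosim_r(ranks, within_mask(np.asarray(p))) >= r_obs - 1e-12
                    for p in perms)
        return AnosimResult(float(r_obs), count / len(perms), len(perms), seed, "exact")

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, within_mask(perm)) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return AnosimResult(float(r_obs), p, n_permutations, seed)


def corr_axes(rel: RelativeAbundanceTable, ordination: OrdinationResult,
              axis: int = 1, alpha: float = 0.05,
              include_all: bool = False) -> list[AxisCorrelation]:
    """Spearman correlation of each taxon with an ordination axis.

    Returns the taxa with p ≤ ``alpha`` (all finite correlations when
    ``include_all``); constant taxa are skipped.
    """
    if list(rel.sample_ids) != list(ordination.sample_ids):
        raise ValueError("samples of the abundance table and ordination differ")
    coords = ordination.coordinates.iloc[:, axis - 1].to_numpy()
    out = []
    for taxon in rel.taxon_ids:
        x = rel.data[taxon].to_numpy()
        res = _spearman(x, coords)
        if np.isnan(res.statistic):
            continue  # constant taxon: correlation undefined
        if include_all or res.p_value <= alpha:
            out.append(AxisCorrelation(taxon, axis, res.statistic, res.p_value))
    return out


def cca(rel: RelativeAbundanceTable, constraints: pd.DataFrame) -> CCAResult:
    """Canonical correspondence analysis (ter Braak).

    The abundance table is chi-square transformed
    (Q = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2}); Q is regressed onto the
    row-weighted, standardized constraints and the fitted part is
    eigen-decomposed.  Total inertia equals the table's chi-square statistic
    divided by its grand total.  Collinear constraint columns are dropped
    with a warning.
    """
    if list(rel.sample_ids) != list(constraints.index):
        raise ValueError("constraint rows must align with the abundance samples")
    x = constraints.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("constraints contain missing values")
    y = rel.data.to_numpy(dtype=float)
    total = y.sum()
    p = y / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        raise ValueError("empty sample or taxon in the abundance table")
    q = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    total_inertia = float((q ** 2).sum())

    # weighted centering and standardization of constraints
    xw = x - (r[:, None] * x).sum(axis=0)
    sd = np.sqrt((r[:, None] * xw ** 2).sum(axis=0))
    keep = sd > 1e-12
    dropped = [str(col) for col, k in zip(constraints.columns, keep) if not k]
    xw = xw[:, keep] / sd[keep]
    cols = [str(col) for col, k in zip(constraints.columns, keep) if k]
    # weighted design matrix; drop collinear columns via pivoted QR
    b = np.sqrt(r)[:, None] * xw
    qq, rr, piv = _pivoted_qr(b)
    rank = int((np.abs(np.diag(rr)) > 1e-9 * max(1.0, abs(rr[0, 0]))).sum()) if rr.size else 0
    if rank < len(cols):
        dropped += [cols[i] for i in piv[rank:]]
        warnings.warn(f"dropping collinear constraints: {[cols[i] for i in piv[rank:]]}",
                      stacklevel=2)
    qq = qq[:, :rank]
    # project Q onto the constraint space and decompose the fitted part
    q_fit = qq @ (qq.T @ q)
    u, s, vt = np.linalg.svd(q_fit, full_matrices=False)
    eig = s ** 2
    order = np.argsort(eig)[::-1]
    n_axes = min(rank, (eig > 1e-12).sum())
    eig = eig[order][:n_axes]
    u = u[:, order][:, :n_axes]
    vt = vt[order][:n_axes]
    axes = [f"CCA{i + 1}" for i in range(n_axes)]
    # LC site scores and species scores in chi-square space
    site = (u * s[order][:n_axes]) / np.sqrt(r)[:, None]
    species = vt.T / np.sqrt(c)[:, None]
    site_df = pd.DataFrame(site, index=rel.sample_ids, columns=axes)
    species_df = pd.DataFrame(species, index=rel.taxon_ids, columns=axes)
    # biplot scores: weighted correlation of constraints with site scores
    kept_idx = [cols.index(cname) for cname in cols]
    constr = np.empty((len(cols), n_axes))
    for i in kept_idx:
        for j in range(n_axes):
            num = (r * xw[:, i] * site[:, j]).sum()
            den = np.sqrt((r * xw[:, i] ** 2).sum() * (r * site[:, j] ** 2).sum())
            constr[i, j] = num / den if den > 0 else 0.0
    constraint_df = pd.DataFrame(constr, index=cols, columns=axes)
    return CCAResult(eig, site_df, species_df, constraint_df, total_inertia, dropped)


def _pivoted_qr(b: np.ndarray):
    from scipy.linalg import qr
    if b.shape[1] == 0:
        return np.zeros((b.shape[0], 0)), np.zeros((0, 0)), np.array([], dtype=int)
    qq, rr, piv = qr(b, mode="economic", pivoting=True)
    return qq, rr, piv
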