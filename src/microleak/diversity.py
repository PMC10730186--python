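"""Alpha diversity (Shannon, Chao1) and Bray-Curtis beta diversity.

Shannon entropy uses the natural logarithm (mothur's convention); Chao1
defaults to the bias-corrected estimator S_obs + F1(F1−1)/(2(F2+1)).
Alpha diversity is intended to be computed on the rarefied count table so
that richness estimates are comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables_io import CountTable, RelativeAbundanceTable

__all__ = ["AlphaDiversityResult", "shannon", "chao1", "bray_curtis",
           "alpha_diversity", "write_distance_matrix", "read_distance_matrix"]


@dataclass
class AlphaDiversityResult:
    sample_id: str
    shannon: float
    chao1: float


def shannon(counts) -> float:
    """Shannon diversity H = −Σ p ln p in nats.

    Accepts counts or percents; only the proportions matter.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from integer counts.

    Bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) by default; the classic
    form S_obs + F1²/(2 F2) is available with ``bias_corrected=False`` (it is
    undefined when F2 = 0 and falls back to the bias-corrected form there).
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x != np.floor(x)) or np.any(x < 0):
        raise ValueError("Chao1 requires nonnegative integer counts")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1 * f1 / (2.0 * f2)


def alpha_diversity(table: CountTable, bias_corrected: bool = True) -> list[AlphaDiversityResult]:
    """Per-sample Shannon and Chao1 on a (rarefied) count table."""
    out = []
    for sid in table.sample_ids:
        row = table.data.loc[sid].to_numpy()
        out.append(AlphaDiversityResult(
            sample_id=sid,
            shannon=shannon(row),
            chao1=chao1(row, bias_corrected=bias_corrected),
        ))
    return out


def bray_curtis(table: RelativeAbundanceTable | CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities d = Σ|x−y| / Σ(x+y)."""
    if isinstance(table, CountTable):
        arr = table.data.to_numpy(dtype=float)
        ids = table.sample_ids
    else:
        arr = table.data.to_numpy(dtype=float)
        ids = table.sample_ids
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(d, ids=ids)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Write a square TSV with a header row and an id column."""
    import pandas as pd

    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])
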