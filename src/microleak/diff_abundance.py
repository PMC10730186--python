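"""Per-genus differential-abundance screening.

``kw_screen`` runs a Kruskal–Wallis test per taxon with Dunn pairwise letters
and reports group medians with interquartile ranges, the format genus summary
tables are conventionally printed in.  ``lefse`` is the classic LDA
effect-size procedure: a Kruskal–Wallis filter followed by bootstrapped
linear-discriminant effect sizes on a per-million abundance scale, keeping
taxa whose log10 score magnitude exceeds the threshold (4 by default, the
stringent setting used for strong biomarkers).  The subclass (pairwise
Wilcoxon) stage is omitted: the study design here has no subclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .tables_io import RelativeAbundanceTable
from .univariate_stats import TestResult, kruskal_wallis, posthoc_pairwise

__all__ = ["KwScreenRecord", "LefseRecord", "kw_screen", "lefse"]

# percent -> per-million scale used for LDA effect sizes
_PER_MILLION = 1e4


@dataclass
class KwScreenRecord:
    taxon_id: str
    result: TestResult
    medians: dict[str, float]
    iqrs: dict[str, tuple[float, float]]
    letters: dict[str, str] | None = None

    def format_median_iqr(self, group: str, digits: int = 2) -> str:
        """``median[q1-q3]`` display string for one group."""
        lo, hi = self.iqrs[group]
        return f"{round(self.medians[group], digits)}[{round(lo, digits)}-{round(hi, digits)}]"


@dataclass
class LefseRecord:
    taxon_id: str
    enriched_class: str
    kw_p_value: float
    lda_score: float  # log10 effect size, signed toward the enriched class


def _group_vectors(rel: RelativeAbundanceTable, labels) -> tuple[list[str], dict[str, np.ndarray]]:
    labels = np.asarray(labels)
    if labels.size != len(rel.sample_ids):
        raise ValueError("labels must match samples")
    groups = list(dict.fromkeys(labels.tolist()))
    masks = {g: labels == g for g in groups}
    return groups, masks


def kw_screen(rel: RelativeAbundanceTable, labels, alpha: float = 0.05) -> list[KwScreenRecord]:
    """Kruskal–Wallis per taxon with Dunn letters for significant taxa."""
    groups, masks = _group_vectors(rel, labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    records = []
    for taxon in rel.taxon_ids:
        x = rel.data[taxon].to_numpy()
        vectors = [x[masks[g]] for g in groups]
        res = kruskal_wallis(vectors)
        medians = {g: float(np.median(v)) for g, v in zip(groups, vectors)}
        iqrs = {g: (float(np.percentile(v, 25)), float(np.percentile(v, 75)))
                for g, v in zip(groups, vectors)}
        letters = None
        if res.p_value <= alpha:
            letters = posthoc_pairwise(vectors, method="dunn", labels=groups,
                                       alpha=alpha).letters
        records.append(KwScreenRecord(taxon, res, medians, iqrs, letters))
    return records


def lefse(rel: RelativeAbundanceTable, labels, alpha: float = 0.05,
          lda_threshold: float = 4.0, n_boot: int = 30,
          seed: int | None = None) -> list[LefseRecord]:
    """LDA effect-size biomarker discovery for a two-class comparison.

    Stage 1 keeps taxa with Kruskal–Wallis p ≤ ``alpha``.  Stage 2 fits a
    linear discriminant on bootstrap subsamples (2/3 of each class) of the
    per-million-scaled abundances; each taxon's effect size is the average of
    the raw between-class mean difference and the class-mean difference of
    the discriminant projection attributed back to the taxon, averaged over
    bootstraps.  The reported score is log10(1 + |effect|), signed toward the
    enriched class, and only taxa with |score| > ``lda_threshold`` survive.
    """
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("lefse expects exactly 2 classes (run one-vs-rest for more)")
    m0, m1 = (labels == classes[0], labels == classes[1])
    if m0.sum() < 3 or m1.sum() < 3:
        raise ValueError("each class needs at least 3 samples")

    # stage 1: KW filter
    kept = []
    kw_p = {}
    for taxon in rel.taxon_ids:
        x = rel.data[taxon].to_numpy()
        res = kruskal_wallis([x[m0], x[m1]])
        if res.p_value <= alpha:
            kept.append(taxon)
            kw_p[taxon] = res.p_value
    if not kept:
        return []

    feats = rel.data[kept].to_numpy() * _PER_MILLION
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(m0)
    idx1 = np.flatnonzero(m1)
    n0 = max(2, int(round(idx0.size * 2 / 3)))
    n1 = max(2, int(round(idx1.size * 2 / 3)))
    effects = np.zeros(len(kept))
    n_used = 0
    for _ in range(n_boot):
        s0 = rng.choice(idx0, size=n0, replace=False)
        s1 = rng.choice(idx1, size=n1, replace=False)
        sub = np.concatenate([s0, s1])
        xb = feats[sub]
        yb = np.concatenate([np.zeros(n0), np.ones(n1)])
        # jitter constant features so the within-class scatter is invertible
        const = xb.std(axis=0) < 1e-12
        if const.any():
            xb = xb.copy()
            xb[:, const] += rng.normal(0.0, 1e-6, size=(xb.shape[0], int(const.sum())))
        try:
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None)
            lda.fit(xb, yb)
        except np.linalg.LinAlgError:
            continue
        w = lda.coef_.ravel()
        norm = np.linalg.norm(w)
        if norm == 0 or not np.isfinite(norm):
            continue
        w_unit = w / norm
        mu0 = xb[yb == 0].mean(axis=0)
        mu1 = xb[yb == 1].mean(axis=0)
        proj_diff = float(w_unit @ (mu1 - mu0))
        # attribute the projected separation back to each taxon, then average
        # with the raw mean difference (classic formulation)
        effects += 0.5 * (w_unit * proj_diff + (mu1 - mu0))
        n_used += 1
    if n_used == 0:
        return []
    effects /= n_used

    out = []
    for taxon, eff in zip(kept, effects):
        score = float(np.log10(1.0 + abs(eff)))
        if score > lda_threshold:
            enriched = classes[1] if eff > 0 else classes[0]
            out.append(LefseRecord(taxon, enriched, kw_p[taxon],
                                   score if eff > 0 else -score))
    out.sort(key=lambda r: -abs(r.lda_score))
    return out
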