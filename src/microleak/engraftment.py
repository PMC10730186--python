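"""Bayesian source attribution of recipient communities after FMT.

A recipient ("sink") stool community is modeled as a mixture of known source
communities — the donor fecal slurry and the recipient's own baseline — plus
an "unknown" source whose taxon distribution is learned from the data.  Each
sink read arises from a latent source; known-source taxon distributions are
the Dirichlet-smoothed empirical source profiles, the unknown source carries
its own Dirichlet prior, and the mixing proportions carry a uniform Dirichlet
prior.  Posterior mixing proportions are estimated by a blocked Gibbs sampler
that alternates (a) multinomial reassignment of each taxon's reads to
sources, (b) a Dirichlet draw of the unknown-source distribution, and (c) a
Dirichlet draw of the mixing vector.  Reads of one taxon are exchangeable, so
step (a) vectorizes over reads.  Estimates average retained draws across
independent restarts.

The engraftment percentage reported for an FMT recipient is the posterior
mean proportion attributed to the donor-slurry source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .univariate_stats import TestResult, anova_oneway, posthoc_pairwise

__all__ = ["SourceProfile", "EngraftmentEstimate", "fit_sources", "engraftment_by_group"]


@dataclass
class SourceProfile:
    source_id: str
    counts: np.ndarray  # per-taxon counts, aligned with the sink's taxa

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError(f"source {self.source_id}: negative counts")
        if self.counts.sum() <= 0:
            raise ValueError(f"source {self.source_id}: empty profile")


@dataclass
class EngraftmentEstimate:
    sink_id: str
    proportions: dict[str, float]       # per source id + "unknown"; sums to 1
    std_devs: dict[str, float]
    burn_in: int
    n_draws: int
    thin: int
    restarts: int
    seed: int | None


def fit_sources(sink: Sequence[int] | np.ndarray,
                sources: Sequence[SourceProfile],
                alpha_prior: float = 0.001,
                beta_prior: float = 0.01,
                burn_in: int = 100,
                n_draws: int = 100,
                thin: int = 10,
                restarts: int = 10,
                seed: int | None = None,
                rarefaction_depth: int | None = 1000,
                sink_id: str = "") -> EngraftmentEstimate:
    """Estimate the mixing proportions of a sink over sources + unknown.

    ``alpha_prior`` smooths the fixed known-source taxon distributions;
    ``beta_prior`` is the Dirichlet prior on the learned unknown-source
    distribution.  Sinks deeper than ``rarefaction_depth`` reads are
    subsampled to that depth before fitting to bound runtime (pass ``None``
    to disable).
    """
    sink = np.asarray(sink, dtype=np.int64)
    if sink.sum() <= 0:
        raise ValueError("empty sink")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not sources:
        raise ValueError("need at least one source")
    n_taxa = sink.size
    for s in sources:
        if s.counts.size != n_taxa:
            raise ValueError(f"source {s.source_id}: taxon dimension mismatch")

    rng = np.random.default_rng(seed)
    if rarefaction_depth is not None and sink.sum() > rarefaction_depth:
        sink = rng.multivariate_hypergeometric(sink, rarefaction_depth)

    k = len(sources)
    names = [s.source_id for s in sources] + ["unknown"]
    # fixed Dirichlet-smoothed taxon distributions for the known sources
    phi_known = np.empty((k, n_taxa))
    for i, s in enumerate(sources):
        phi_known[i] = (s.counts + alpha_prior) / (s.counts.sum() + alpha_prior * n_taxa)

    n_total = int(sink.sum())
    active = np.flatnonzero(sink)
    draws = []
    for _ in range(restarts):
        # initialize mixing uniformly and the unknown source from its prior
        pi = np.full(k + 1, 1.0 / (k + 1))
        theta_u = rng.dirichlet(np.full(n_taxa, beta_prior) + 1e-12)
        kept = []
        n_iter = burn_in + n_draws * thin
        for it in range(n_iter):
            # (a) reassign each taxon's reads jointly (reads are exchangeable)
            assign = np.zeros((k + 1, n_taxa))
            for t in active:
                p = np.empty(k + 1)
                p[:k] = phi_known[:, t] * pi[:k]
                p[k] = theta_u[t] * pi[k]
                tot = p.sum()
                if tot <= 0:
                    p[:] = 1.0 / (k + 1)
                else:
                    p /= tot
                assign[:, t] = rng.multinomial(sink[t], p)
            n_per_source = assign.sum(axis=1)
            # (b) unknown-source distribution from its assigned reads
            theta_u = rng.dirichlet(assign[k] + beta_prior)
            # (c) mixing vector (uniform Dirichlet(1) prior)
            pi = rng.dirichlet(n_per_source + 1.0)
            if it >= burn_in and (it - burn_in) % thin == 0:
                kept.append(n_per_source / n_total)
        draws.extend(kept)
    draws = np.asarray(draws)
    mean = draws.mean(axis=0)
    mean = mean / mean.sum()
    sd = draws.std(axis=0, ddof=1) if draws.shape[0] > 1 else np.zeros(k + 1)
    return EngraftmentEstimate(
        sink_id=sink_id,
        proportions={name: float(m) for name, m in zip(names, mean)},
        std_devs={name: float(s) for name, s in zip(names, sd)},
        burn_in=burn_in, n_draws=n_draws, thin=thin, restarts=restarts,
        seed=seed,
    )


def engraftment_by_group(estimates: Sequence[EngraftmentEstimate],
                         metadata: pd.DataFrame,
                         donor_source: str = "donor") -> tuple[pd.DataFrame, TestResult, object]:
    """Summarize donor engraftment by group and timepoint; test timepoints.

    ``metadata`` must be indexed by sink sample id with ``group_label`` and
    ``timepoint`` columns.  Returns (summary table of mean ± sd donor
    proportion, ANOVA across timepoints on the pooled estimates, Tukey
    post-hoc result).
    """
    rows = []
    for est in estimates:
        if est.sink_id not in metadata.index:
            raise ValueError(f"no metadata for sink {est.sink_id}")
        rows.append({
            "sample_id": est.sink_id,
            "group_label": metadata.loc[est.sink_id, "group_label"],
            "timepoint": metadata.loc[est.sink_id, "timepoint"],
            "donor_proportion": est.proportions[donor_source],
        })
    df = pd.DataFrame(rows)
    summary = (df.groupby(["group_label", "timepoint"])["donor_proportion"]
                 .agg(["mean", "std", "count"]))
    timepoints = [tp for tp in df["timepoint"].unique()]
    if len(timepoints) < 2:
        raise ValueError("need estimates at >= 2 timepoints")
    groups = [df.loc[df["timepoint"] == tp, "donor_proportion"].to_numpy()
              for tp in timepoints]
    if all(np.allclose(g, groups[0][0]) for g in groups):
        anova = TestResult("anova", 0.0, 1.0)
        tukey = None
    else:
        anova = anova_oneway(groups)
        tukey = posthoc_pairwise(groups, method="tukey", labels=timepoints)
    return summary, anova, tukey
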