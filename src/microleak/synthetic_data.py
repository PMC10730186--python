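"""Synthetic study generator: a complete 4-group × 4-timepoint murine cohort.

Emulates a reciprocal-FMT colonic-anastomosis study: mice are fed a lean diet
(LD) or Western diet (WD) for ten weeks, gavaged on the day of surgery (DOS)
with PBS or the opposite diet's fecal slurry, and sampled at baseline, DOS,
postoperative day 4 (POD4), and POD7.  Counts are drawn from a
Dirichlet-multinomial centered on per-group genus median profiles — the
standard overdispersed model for 16S count data — with three structural
effects layered on top:

* an anastomotic-leak (AL) community shift at POD4 (Bacteroides and
  Akkermansia up; Alistipes, Clostridium sensu stricto, Lachnospiraceae spp.
  and Paramuribaculum down), applied as multiplicative fold-changes and
  renormalized;
* convex donor–recipient mixing for FMT mice at post-gavage timepoints,
  (1−f)·recipient + f·donor with per-timepoint engraftment fraction f;
* diet-dependent body weight at DOS.

Group sizes, leak rates, sequencing depth, engraftment fractions and the
genus profiles default to the observed study conditions, so clinical
contingency tables, community contrasts, and engraftment recovery all come
out with realistic structure.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables_io import CountTable, SampleMetadata

__all__ = [
    "SyntheticStudyConfig",
    "GROUP_MEDIAN_PROFILES",
    "default_config",
    "default_study_config",
    "generate_study",
    "generate_leak_separated_cohort",
    "profile_counts",
]

TAXA = (
    "Acetatifactor",
    "Akkermansia",
    "Alistipes",
    "Bacteroides",
    "Bifidobacterium",
    "Clostridiales spp.",
    "Clostridium sensu stricto",
    "Dubosiella",
    "Faecalibaculum",
    "Lachnospiraceae spp.",
    "Lactococcus",
    "Muribaculaceae spp.",
    "Paramuribaculum",
    "Parasutterella",
    "Ruminococcaceae spp.",
)

# median percent relative abundances of the predominant genera per group
# (AL = pooled leak mice from every treatment arm); a residual taxon absorbs
# the remainder to 100.
GROUP_MEDIAN_PROFILES: dict[str, dict[str, float]] = {
    "AL": {
        "Acetatifactor": 1.7, "Akkermansia": 17.72, "Alistipes": 4.39,
        "Bacteroides": 9.9, "Bifidobacterium": 0.52, "Clostridiales spp.": 3.42,
        "Clostridium sensu stricto": 1.93, "Dubosiella": 14.97,
        "Faecalibaculum": 0.0, "Lachnospiraceae spp.": 9.72, "Lactococcus": 0.0,
        "Muribaculaceae spp.": 9.14, "Paramuribaculum": 7.93,
        "Parasutterella": 1.37, "Ruminococcaceae spp.": 4.71,
    },
    "LD": {
        "Acetatifactor": 1.67, "Akkermansia": 9.93, "Alistipes": 7.31,
        "Bacteroides": 2.16, "Bifidobacterium": 1.06, "Clostridiales spp.": 4.23,
        "Clostridium sensu stricto": 4.0, "Dubosiella": 22.24,
        "Faecalibaculum": 0.0, "Lachnospiraceae spp.": 15.35, "Lactococcus": 0.0,
        "Muribaculaceae spp.": 8.92, "Paramuribaculum": 8.15,
        "Parasutterella": 1.63, "Ruminococcaceae spp.": 4.06,
    },
    "LD-wdFMT": {
        "Acetatifactor": 1.71, "Akkermansia": 13.21, "Alistipes": 7.01,
        "Bacteroides": 6.28, "Bifidobacterium": 1.79, "Clostridiales spp.": 3.58,
        "Clostridium sensu stricto": 2.09, "Dubosiella": 16.54,
        "Faecalibaculum": 0.0, "Lachnospiraceae spp.": 15.65, "Lactococcus": 0.0,
        "Muribaculaceae spp.": 8.27, "Paramuribaculum": 8.44,
        "Parasutterella": 1.08, "Ruminococcaceae spp.": 4.92,
    },
    "WD": {
        "Acetatifactor": 2.13, "Akkermansia": 17.67, "Alistipes": 6.05,
        "Bacteroides": 6.55, "Bifidobacterium": 0.48, "Clostridiales spp.": 2.33,
        "Clostridium sensu stricto": 3.72, "Dubosiella": 12.32,
        "Faecalibaculum": 0.0, "Lachnospiraceae spp.": 12.31, "Lactococcus": 0.0,
        "Muribaculaceae spp.": 8.14, "Paramuribaculum": 11.3,
        "Parasutterella": 1.29, "Ruminococcaceae spp.": 4.58,
    },
    "WD-ldFMT": {
        "Acetatifactor": 2.62, "Akkermansia": 16.39, "Alistipes": 6.41,
        "Bacteroides": 7.45, "Bifidobacterium": 0.35, "Clostridiales spp.": 4.41,
        "Clostridium sensu stricto": 4.1, "Dubosiella": 10.14,
        "Faecalibaculum": 0.05, "Lachnospiraceae spp.": 11.08, "Lactococcus": 0.0,
        "Muribaculaceae spp.": 8.83, "Paramuribaculum": 10.95,
        "Parasutterella": 0.92, "Ruminococcaceae spp.": 5.0,
    },
}

RESIDUAL_TAXON = "Other"
TIMEPOINTS = ("baseline", "DOS", "POD4", "POD7")
POST_GAVAGE = ("DOS", "POD4", "POD7")


@dataclass
class SyntheticStudyConfig:
    """Study conditions: profiles, dispersion, depth, group sizes, effects."""

    group_profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in GROUP_MEDIAN_PROFILES.items()})
    concentration: float = 200.0          # Dirichlet precision; larger = tighter
    depth: int = 35595                    # reads per sample
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"LD": 16, "WD": 16, "LD-wdFMT": 16, "WD-ldFMT": 16})
    deaths: dict[str, int] = field(
        default_factory=lambda: {"LD": 1, "WD": 1, "LD-wdFMT": 0, "WD-ldFMT": 3})
    al_counts: dict[str, int] = field(
        default_factory=lambda: {"LD": 6, "WD": 5, "LD-wdFMT": 4, "WD-ldFMT": 0})
    leak_multipliers: dict[str, float] = field(default_factory=lambda: {
        "Bacteroides": 2.2, "Akkermansia": 1.8, "Alistipes": 0.5,
        "Clostridium sensu stricto": 0.5, "Lachnospiraceae spp.": 0.6,
        "Paramuribaculum": 0.8,
    })
    engraftment_fractions: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "LD-wdFMT": {"DOS": 0.330, "POD4": 0.118, "POD7": 0.155},
        "WD-ldFMT": {"DOS": 0.106, "POD4": 0.051, "POD7": 0.098},
    })
    donor_groups: dict[str, str] = field(default_factory=lambda: {
        "LD-wdFMT": "WD", "WD-ldFMT": "LD"})
    weight_mean_sd: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "LD": (30.6, 2.6), "WD": (36.4, 4.0)})

    def __post_init__(self) -> None:
        for g, prof in self.group_profiles.items():
            if any(v < 0 for v in prof.values()):
                raise ValueError(f"group {g}: negative profile entries")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group {g}: negative size")
        for g, fr in self.engraftment_fractions.items():
            for tp, f in fr.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"engraftment fraction {f} for {g}/{tp} outside [0,1]")

    def taxa(self) -> list[str]:
        first = next(iter(self.group_profiles.values()))
        return list(first.keys()) + [RESIDUAL_TAXON]

    def full_profile(self, group: str) -> np.ndarray:
        """Group profile as a simplex over taxa + residual (sums to 1)."""
        prof = self.group_profiles[group]
        vals = np.array(list(prof.values()), dtype=float)
        residual = max(0.0, 100.0 - vals.sum())
        full = np.append(vals, residual)
        return full / full.sum()


def default_study_config() -> SyntheticStudyConfig:
    """Config seeded from the per-group genus median profiles."""
    return SyntheticStudyConfig()


default_config = default_study_config


def profile_counts(config: SyntheticStudyConfig, group: str, depth: int | None = None) -> np.ndarray:
    """Deterministic integer count profile for a group (largest-remainder)."""
    depth = depth or config.depth
    p = config.full_profile(group)
    raw = p * depth
    counts = np.floor(raw).astype(np.int64)
    short = depth - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def _apply_multipliers(profile: np.ndarray, taxa: list[str],
                       multipliers: dict[str, float], effect_size: float = 1.0) -> np.ndarray:
    out = profile.copy()
    for taxon, m in multipliers.items():
        if taxon in taxa:
            out[taxa.index(taxon)] *= m ** effect_size
    return out / out.sum()


def generate_study(config: SyntheticStudyConfig | None = None,
                   seed: int | None = None) -> tuple[CountTable, list[SampleMetadata]]:
    """Draw the full cohort: counts per mouse × timepoint plus metadata.

    Survivor mice contribute all four timepoints; mice that die
    perioperatively contribute only the baseline sample and carry an unknown
    leak status.  AL mice receive the leak fold-changes at POD4; FMT mice mix
    convexly with the donor profile from DOS onward.
    """
    config = config or default_study_config()
    rng = np.random.default_rng(seed)
    taxa = config.taxa()
    rows: dict[str, np.ndarray] = {}
    metadata: list[SampleMetadata] = []
    for group in config.group_sizes:
        n = config.group_sizes[group]
        n_dead = config.deaths.get(group, 0)
        n_al = config.al_counts.get(group, 0)
        diet = "LD" if group.startswith("LD") else "WD"
        gavage = "FMT" if group in config.donor_groups else "PBS"
        base = config.full_profile(group)
        donor = (config.full_profile(config.donor_groups[group])
                 if group in config.donor_groups else None)
        for i in range(n):
            mouse = f"{group}.m{i + 1:02d}"
            survived = i >= n_dead       # first `deaths` mice die perioperatively
            if survived:
                al = "yes" if i - n_dead < n_al else "no"
            else:
                al = "unknown"
            weight = float(rng.normal(*config.weight_mean_sd[diet]))
            timepoints = TIMEPOINTS if survived else ("baseline",)
            for tp in timepoints:
                profile = base
                if donor is not None and tp in POST_GAVAGE:
                    f = config.engraftment_fractions[group].get(tp, 0.0)
                    profile = (1.0 - f) * base + f * donor
                if al == "yes" and tp == "POD4":
                    profile = _apply_multipliers(profile, taxa, config.leak_multipliers)
                props = rng.dirichlet(np.maximum(profile, 1e-12) * config.concentration)
                counts = rng.multinomial(config.depth, props)
                sid = f"{mouse}.{tp}"
                rows[sid] = counts
                metadata.append(SampleMetadata(
                    sample_id=sid, mouse_id=mouse, diet=diet, gavage=gavage,
                    group_label=group, al_status=al, timepoint=tp,
                    survived=survived, body_weight=weight if tp == "DOS" else None,
                ))
    table = CountTable(pd.DataFrame.from_dict(rows, orient="index", columns=taxa))
    return table, metadata


def generate_leak_separated_cohort(n_leak: int, n_noleak: int,
                                   effect_size: float = 1.0,
                                   seed: int | None = None,
                                   config: SyntheticStudyConfig | None = None,
                                   base_group: str = "LD") -> tuple[CountTable, list[SampleMetadata]]:
    """A POD4-only two-class cohort with a tunable leak effect.

    Both classes draw from the ``base_group`` profile; the leak class applies
    the leak fold-changes raised to ``effect_size`` (0 makes the classes
    exchangeable, 1 reproduces the default leak shift).
    """
    if n_leak < 1 or n_noleak < 1:
        raise ValueError("need at least one sample per class")
    config = config or default_study_config()
    rng = np.random.default_rng(seed)
    taxa = config.taxa()
    base = config.full_profile(base_group)
    shifted = _apply_multipliers(base, taxa, config.leak_multipliers, effect_size)
    rows: dict[str, np.ndarray] = {}
    metadata: list[SampleMetadata] = []
    for label, count, profile in (("yes", n_leak, shifted), ("no", n_noleak, base)):
        for i in range(count):
            sid = f"leak{label}.m{i + 1:02d}.POD4"
            props = rng.dirichlet(np.maximum(profile, 1e-12) * config.concentration)
            rows[sid] = rng.multinomial(config.depth, props)
            metadata.append(SampleMetadata(
                sample_id=sid, mouse_id=sid.rsplit(".", 1)[0], diet=base_group[:2],
                gavage="PBS", group_label=base_group[:2], al_status=label,
                timepoint="POD4", survived=True,
            ))
    table = CountTable(pd.DataFrame.from_dict(rows, orient="index", columns=taxa))
    return table, metadata
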