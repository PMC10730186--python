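"""End-to-end orchestration of the leak-microbiome analysis.

``run_full_analysis`` mirrors the order of a surgical-microbiome study
report: clinical contingency tests → rarefaction and coverage → alpha
diversity → ordination and ANOSIM → axis correlations → (optional) CCA
against macronutrients → per-genus screening and LEfSe → FMT engraftment →
CART taxon selection → AL-index evaluation.  Every stage writes a TSV or
JSON artifact under the run directory, a manifest records inputs, seeds and
parameters, and identical configs with identical seeds produce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import diversity, ordination, tables_io
from .diff_abundance import kw_screen, lefse
from .engraftment import SourceProfile, engraftment_by_group, fit_sources
from .leak_model import al_index, candidate_taxa, cart_train, evaluate_index
from .synthetic_data import (SyntheticStudyConfig, default_study_config,
                             generate_study, profile_counts)
from .tables_io import (CountTable, SampleMetadata, metadata_frame,
                        read_counts, read_metadata)
from .univariate_stats import (ContingencyTable, anova_oneway, bonferroni_alpha,
                               chi_square_2x2, fisher_exact_2x2,
                               freeman_halton_exact, select_categorical_test)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_analysis", "clinical_tests"]

# printed clinical outcome tables of the study; rows are groups, columns
# survived/died or no-AL/AL.  These are inputs for the clinical-test stage
# when no metadata-derived tables are requested.
SURVIVAL_TABLE = {"LD": (15, 1), "WD": (15, 1), "WD-ldFMT": (16, 0), "LD-wdFMT": (13, 3)}
AL_TABLE = {"LD": (9, 6), "WD": (10, 5), "LD-wdFMT": (12, 4), "WD-ldFMT": (13, 0)}


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    counts_format: str = "tsv"
    metadata_path: str | None = None
    macronutrients_path: str | None = None   # sample x covariate TSV for CCA
    synthetic: SyntheticStudyConfig | None = None
    rarefaction_depth: int = 35500
    n_permutations: int = 999
    alpha: float = 0.05
    al_cutoff: float = 0.45
    seed: int = 0
    out_dir: str = "microleak_run"
    # engraftment sampler settings (kept modest so a full run stays quick)
    engraftment_restarts: int = 3
    engraftment_burn_in: int = 50
    engraftment_draws: int = 50
    engraftment_thin: int = 5
    engraftment_depth: int = 1000
    run_engraftment: bool = True
    run_cca: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a JSON or YAML document."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        config = cls(**raw)
        if syn is not None:
            from .synthetic_data import SyntheticStudyConfig
            config.synthetic = SyntheticStudyConfig(**syn)
        return config


def _contingency(table_dict: dict[str, tuple[int, int]], columns: tuple[str, str]) -> ContingencyTable:
    cells = np.array([list(v) for v in table_dict.values()])
    return ContingencyTable(cells, row_labels=list(table_dict),
                            column_labels=list(columns))


def clinical_tests(survival: dict[str, tuple[int, int]] | None = None,
                   al_tables: dict[str, dict[str, tuple[int, int]]] | None = None) -> dict[str, Any]:
    """Clinical outcome tests on survival and leak contingency tables.

    ``survival`` maps group → (survived, died); ``al_tables`` maps a
    comparison name → {group: (no_AL, AL)} two-row table.  Defaults are the
    study's printed tables.  Each leak comparison uses the chi-square test
    unless any cell is below 5, in which case the exact test is used.
    """
    survival = survival or SURVIVAL_TABLE
    if al_tables is None:
        al_tables = {
            "LD_vs_WD": {"LD": AL_TABLE["LD"], "WD": AL_TABLE["WD"]},
            "LD_vs_LD-wdFMT": {"LD": AL_TABLE["LD"], "LD-wdFMT": AL_TABLE["LD-wdFMT"]},
            "WD_vs_WD-ldFMT": {"WD": AL_TABLE["WD"], "WD-ldFMT": AL_TABLE["WD-ldFMT"]},
        }
    out: dict[str, Any] = {}
    surv_ct = _contingency(survival, ("survived", "died"))
    out["survival"] = {
        "table": {g: list(v) for g, v in survival.items()},
        "test": "freeman_halton",
        "p_value": freeman_halton_exact(surv_ct).p_value,
        "percent_survived": 100.0 * surv_ct.cells[:, 0].sum() / surv_ct.cells.sum(),
    }
    comparisons = {}
    for name, tab in al_tables.items():
        ct = _contingency(tab, ("no_AL", "AL"))
        test = select_categorical_test(ct)
        if test == "chi_square":
            res = chi_square_2x2(ct)
        elif test == "fisher":
            res = fisher_exact_2x2(ct)
        else:
            res = freeman_halton_exact(ct)
        comparisons[name] = {"table": {g: list(v) for g, v in tab.items()},
                             "test": res.method, "p_value": res.p_value}
    out["al_comparisons"] = comparisons
    return out


def _metadata_contingency(meta: pd.DataFrame) -> dict[str, Any]:
    """Derive survival / AL contingency tables from sample metadata."""
    mice = meta.drop_duplicates(subset=["mouse_id"]).set_index("mouse_id")
    order = ["LD", "WD", "WD-ldFMT", "LD-wdFMT"]
    groups = [g for g in order if g in set(mice["group_label"])]
    survival = {}
    al = {}
    for g in groups:
        sub = mice[mice["group_label"] == g]
        survival[g] = (int(sub["survived"].sum()), int((~sub["survived"]).sum()))
        surv = sub[sub["survived"]]
        al[g] = (int((surv["al_status"] == "no").sum()),
                 int((surv["al_status"] == "yes").sum()))
    al_tables = {}
    if {"LD", "WD"} <= set(groups):
        al_tables["LD_vs_WD"] = {"LD": al["LD"], "WD": al["WD"]}
    if {"LD", "LD-wdFMT"} <= set(groups):
        al_tables["LD_vs_LD-wdFMT"] = {"LD": al["LD"], "LD-wdFMT": al["LD-wdFMT"]}
    if {"WD", "WD-ldFMT"} <= set(groups):
        al_tables["WD_vs_WD-ldFMT"] = {"WD": al["WD"], "WD-ldFMT": al["WD-ldFMT"]}
    return clinical_tests(survival, al_tables)


def _pooled_label(meta_row) -> str:
    return "AL" if meta_row["al_status"] == "yes" else meta_row["group_label"]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_full_analysis(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle under ``config.out_dir``."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {}

    # ---- load or generate -------------------------------------------------
    if config.counts_path is not None:
        if config.metadata_path is None:
            raise ValueError("metadata_path is required with counts_path")
        table = read_counts(config.counts_path, format=config.counts_format)
        metadata = read_metadata(config.metadata_path)
        syn = None
    else:
        syn = config.synthetic or default_study_config()
        table, metadata = generate_study(syn, seed=config.seed)
    meta = metadata_frame(metadata)
    missing = [c for c in ("group_label", "al_status", "timepoint", "survived")
               if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required fields: {missing}")
    meta = meta.loc[table.sample_ids]

    def stage(name: str) -> None:
        logger.info("stage %-18s %6.1fs", name, time.time() - t0)

    # ---- clinical tests ---------------------------------------------------
    report["clinical"] = _metadata_contingency(meta)
    weights = meta[(meta["timepoint"] == "DOS") & meta["body_weight"].notna()]
    if not weights.empty:
        by_diet = [grp["body_weight"].to_numpy(dtype=float)
                   for _, grp in weights.groupby("diet")]
        if len(by_diet) == 2 and all(len(g) >= 2 for g in by_diet):
            res = anova_oneway(by_diet)
            report["clinical"]["body_weight_anova"] = {
                "F": res.statistic, "p_value": res.p_value,
                "means": {d: float(g["body_weight"].mean())
                          for d, g in weights.groupby("diet")},
            }
    stage("clinical")

    # ---- rarefaction, coverage, relative abundance ------------------------
    rare = tables_io.rarefy(table, config.rarefaction_depth, seed=config.seed + 1)
    meta = meta.loc[rare.sample_ids]
    coverage = tables_io.goods_coverage(table)
    report["coverage"] = {
        "mean": float(np.mean([c.coverage for c in coverage])),
        "sd": float(np.std([c.coverage for c in coverage], ddof=1)),
    }
    rel = tables_io.to_relative(rare)
    stage("rarefaction")

    # ---- alpha diversity --------------------------------------------------
    alpha_rows = []
    alpha = {a.sample_id: a for a in diversity.alpha_diversity(rare)}
    for tp, sub in meta.groupby("timepoint"):
        diets = {d: g.index.tolist() for d, g in sub.groupby("diet")}
        if len(diets) != 2 or any(len(v) < 2 for v in diets.values()):
            continue
        row: dict[str, Any] = {"timepoint": tp}
        for metric in ("shannon", "chao1"):
            vecs = [[getattr(alpha[s], metric) for s in ids] for ids in diets.values()]
            res = anova_oneway(vecs)
            for d, v in zip(diets, vecs):
                row[f"{metric}_{d}_mean"] = float(np.mean(v))
                row[f"{metric}_{d}_se"] = float(np.std(v, ddof=1) / np.sqrt(len(v)))
            row[f"{metric}_p"] = res.p_value
        alpha_rows.append(row)
    alpha_df = pd.DataFrame(alpha_rows)
    report["alpha_diversity"] = alpha_df
    stage("alpha")

    # ---- beta diversity / ordination --------------------------------------
    beta: dict[str, Any] = {}
    for tp in ("baseline", "POD4"):
        ids = meta.index[meta["timepoint"] == tp].tolist()
        if len(ids) < 4:
            continue
        sub_rel = tables_io.RelativeAbundanceTable(rel.data.loc[ids])
        dm = diversity.bray_curtis(sub_rel)
        labels = meta.loc[ids, "diet"].to_numpy()
        if len(set(labels)) >= 2 and min(np.bincount(pd.factorize(labels)[0])) >= 2:
            an = ordination.anosim(dm, labels, n_permutations=config.n_permutations,
                                   seed=config.seed + 2)
            ordn = ordination.pcoa(dm, n_axes=2)
            corr = ordination.corr_axes(sub_rel, ordn, axis=1, alpha=config.alpha)
            diversity.write_distance_matrix(dm, out_dir / f"bray_curtis_{tp}.tsv")
            ordn.coordinates.to_csv(out_dir / f"pcoa_{tp}.tsv", sep="\t")
            (out_dir / f"pcoa_{tp}_eigenvalues.json").write_text(
                json.dumps(ordn.eigenvalues.tolist()))
            pd.DataFrame(
                [{"taxon": c.taxon_id, "axis": c.axis, "rho": c.rho, "p": c.p_value}
                 for c in corr]
            ).to_csv(out_dir / f"corr_axes_{tp}.tsv", sep="\t", index=False)
            beta[tp] = {
                "anosim_R": an.R, "anosim_p": an.p_value,
                "pcoa_fit_r2": ordn.fit_r2,
                "axis_correlations": [
                    {"taxon": c.taxon_id, "rho": c.rho, "p": c.p_value}
                    for c in corr],
            }
    # POD4 leak clustering within the PBS control diets
    pod4 = meta[(meta["timepoint"] == "POD4") & (meta["gavage"] == "PBS")]
    for diet, sub in pod4.groupby("diet"):
        counts = sub["al_status"].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            continue
        sub_rel = tables_io.RelativeAbundanceTable(rel.data.loc[sub.index])
        dm = diversity.bray_curtis(sub_rel)
        an = ordination.anosim(dm, sub["al_status"].to_numpy(),
                               n_permutations=config.n_permutations,
                               seed=config.seed + 3)
        beta[f"POD4_leak_{diet}"] = {"anosim_R": an.R, "anosim_p": an.p_value}
    report["beta_diversity"] = beta
    stage("beta")

    # ---- CCA ---------------------------------------------------------------
    if config.run_cca and config.macronutrients_path is not None:
        constraints = pd.read_csv(config.macronutrients_path, sep="\t", index_col=0)
        ids = [s for s in rel.sample_ids if s in constraints.index]
        sub_rel = tables_io.RelativeAbundanceTable(rel.data.loc[ids])
        res = ordination.cca(sub_rel, constraints.loc[ids])
        report["cca"] = {
            "eigenvalues": res.eigenvalues,
            "total_inertia": res.total_inertia,
            "dropped_constraints": res.dropped_constraints,
        }
        stage("cca")

    # ---- per-genus screening on POD4, pooled-AL grouping -------------------
    pod4_ids = meta.index[(meta["timepoint"] == "POD4")
                          & (meta["al_status"] != "unknown")].tolist()
    pod4_rel = tables_io.RelativeAbundanceTable(rel.data.loc[pod4_ids])
    pooled = np.array([_pooled_label(meta.loc[s]) for s in pod4_ids])
    n_groups = len(set(pooled))
    kw_alpha = bonferroni_alpha(config.alpha, max(1, n_groups * (n_groups - 1) // 2))
    screen = kw_screen(pod4_rel, pooled, alpha=config.alpha)
    screen_rows = []
    for rec in screen:
        row = {"taxon": rec.taxon_id, "H": rec.result.statistic,
               "p": rec.result.p_value}
        for g in sorted(set(pooled)):
            row[g] = rec.format_median_iqr(g)
            if rec.letters:
                row[f"{g}_letter"] = rec.letters[g]
        screen_rows.append(row)
    report["kw_screen"] = pd.DataFrame(screen_rows)
    report["kw_screen_bonferroni_alpha"] = kw_alpha
    # LEfSe: leak vs no-leak on POD4
    leak_labels = np.where(pooled == "AL", "AL", "no_AL")
    if min((leak_labels == "AL").sum(), (leak_labels == "no_AL").sum()) >= 3:
        records = lefse(pod4_rel, leak_labels, alpha=config.alpha,
                        seed=config.seed + 4)
        report["lefse"] = [
            {"taxon": r.taxon_id, "class": r.enriched_class,
             "lda": r.lda_score, "p": r.kw_p_value}
            for r in records]
    stage("diff_abundance")

    # ---- engraftment -------------------------------------------------------
    if config.run_engraftment and syn is not None:
        estimates = []
        fmt_meta = meta[(meta["gavage"] == "FMT")
                        & meta["timepoint"].isin(["DOS", "POD4", "POD7"])]
        for j, sid in enumerate(fmt_meta.index):
            group = fmt_meta.loc[sid, "group_label"]
            donor_group = syn.donor_groups[group]
            sources = [
                SourceProfile("donor", profile_counts(syn, donor_group, depth=10000)),
                SourceProfile("baseline", profile_counts(syn, group, depth=10000)),
            ]
            estimates.append(fit_sources(
                rare.data.loc[sid].to_numpy(), sources,
                burn_in=config.engraftment_burn_in,
                n_draws=config.engraftment_draws,
                thin=config.engraftment_thin,
                restarts=config.engraftment_restarts,
                rarefaction_depth=config.engraftment_depth,
                seed=config.seed + 10 + j, sink_id=sid,
            ))
        if estimates:
            summary, an, tukey = engraftment_by_group(estimates, meta)
            report["engraftment"] = {
                "summary": summary.reset_index().to_dict(orient="records"),
                "anova_F": an.statistic, "anova_p": an.p_value,
            }
            pd.DataFrame(
                [{"sink": e.sink_id, "source": src, "proportion": p,
                  "sd": e.std_devs[src]}
                 for e in estimates for src, p in e.proportions.items()]
            ).to_csv(out_dir / "engraftment.tsv", sep="\t", index=False)
        stage("engraftment")

    # ---- CART + AL index ---------------------------------------------------
    cand = [t for t in candidate_taxa() if t in pod4_rel.taxon_ids]
    features = pod4_rel.data[cand]
    labels = np.where(pooled == "AL", "leak", "no_leak")
    if len(set(labels.tolist())) == 2:
        model, metrics, selected = cart_train(features, labels,
                                              seed=config.seed + 5,
                                              positive_class="leak")
        report["cart"] = {
            "selected_taxa": selected,
            "held_out": _jsonable(metrics) if metrics else None,
        }
        (out_dir / "cart_model.json").write_text(model.to_json())
    # pool leak mice as their own comparison group for the median-index table
    al_meta = [dataclasses.replace(m, group_label="AL") if m.al_status == "yes" else m
               for m in metadata if m.sample_id in pod4_ids]
    metrics, medians, results = evaluate_index(pod4_rel, al_meta,
                                               cutoff=config.al_cutoff)
    report["al_index"] = {
        "metrics": _jsonable(metrics),
        "group_medians": medians,
        "cutoff": config.al_cutoff,
    }
    al_rows = pd.DataFrame([
        {"sample_id": r.sample_id, "numerator": r.numerator,
         "denominator": r.denominator, "index": r.index,
         "predicted": r.predicted} for r in results])
    stage("leak_model")

    # ---- write bundle ------------------------------------------------------
    alpha_df.to_csv(out_dir / "alpha_diversity.tsv", sep="\t", index=False)
    report["kw_screen"].to_csv(out_dir / "kw_screen.tsv", sep="\t", index=False)
    al_rows.to_csv(out_dir / "al_index.tsv", sep="\t", index=False)
    medians.to_csv(out_dir / "al_index_group_medians.tsv", sep="\t")
    summary_json = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    (out_dir / "report.json").write_text(summary_json)
    manifest = {
        "seed": config.seed,
        "rarefaction_depth": config.rarefaction_depth,
        "n_permutations": config.n_permutations,
        "alpha": config.alpha,
        "al_cutoff": config.al_cutoff,
        "inputs": {"counts": config.counts_path, "metadata": config.metadata_path,
                   "synthetic": config.counts_path is None},
        "n_samples": len(table.sample_ids),
        "report_sha256": hashlib.sha256(summary_json.encode()).hexdigest(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report["manifest"] = manifest
    return report
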