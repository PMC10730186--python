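# microleak

Gut-microbiota analysis of anastomotic-leak risk after colonic surgery.

Anastomotic leak (AL) — failure of a surgical bowel reconnection to heal — is
associated with a dysbiotic gut community: elevated *Bacteroides* and
*Akkermansia*, depleted short-chain-fatty-acid producers such as *Alistipes*
and *Clostridium sensu stricto*. `microleak` implements the full
computational pathway from a genus-level 16S count table and per-animal
clinical metadata to:

- **community statistics** — rarefaction, Good's coverage, Shannon/Chao1
  alpha diversity, Bray-Curtis beta diversity, PCoA, ANOSIM with seeded
  permutations, taxon-to-axis Spearman correlations, and canonical
  correspondence analysis against dietary macronutrients;
- **clinical outcome tests** — uncorrected 2×2 chi-square, two-sided Fisher
  exact, and the Freeman–Halton exact test for K×2 tables, with the
  small-cell selection rule (exact test whenever a cell is < 5);
- **differential abundance** — per-genus Kruskal–Wallis screening with Dunn
  letters and a LEfSe-style LDA effect-size procedure (threshold |log₁₀| > 4);
- **the AL index** — the genus-ratio classifier at the core of the package:

  ```text
              Paramuribaculum + Clostridium sensu stricto + Alistipes
  AL index = --------------------------------------------------------
                     Dubosiella + Bacteroides + Akkermansia
  ```

  computed on percent relative abundances; an index below the cutoff
  (default 0.45) predicts a leak. CART models (greedy entropy /
  information-gain splits on a randomized stratified half split) select the
  predictive taxa;
- **FMT engraftment** — a Bayesian source-attribution Gibbs sampler that
  estimates what fraction of a recipient stool community is attributable to
  the donor slurry, the recipient baseline, or an unknown source;
- **a synthetic-study generator** — a Dirichlet-multinomial simulator of the
  full 4-group × 4-timepoint reciprocal-FMT murine study (group genus
  profiles, leak effect at POD4, convex donor–recipient mixing, survival and
  leak rates), so every stage runs end to end without any sequence download.

## Worked example

```python
import dataclasses
from microleak import (al_index, default_study_config, evaluate_index,
                       generate_study, to_relative)
from microleak.synthetic_data import GROUP_MEDIAN_PROFILES
from microleak.tables_io import RelativeAbundanceTable

# score the published per-group genus medians
res = al_index(GROUP_MEDIAN_PROFILES["AL"])
print(f"AL-group medians: index = {res.index:.3f} -> {res.predicted}")
res = al_index(GROUP_MEDIAN_PROFILES["LD"])
print(f"LD-group medians: index = {res.index:.3f} -> {res.predicted}")

# evaluate the index on a synthetic cohort at POD4
table, metadata = generate_study(default_study_config(), seed=1)
pod4 = [dataclasses.replace(m, group_label="AL") if m.al_status == "yes" else m
        for m in metadata if m.timepoint == "POD4" and m.al_status != "unknown"]
rel = to_relative(table)
sub = RelativeAbundanceTable(rel.data.loc[[m.sample_id for m in pod4]])
metrics, medians, _ = evaluate_index(sub, pod4, cutoff=0.45)
print(f"accuracy {metrics.accuracy:.2f}, sensitivity {metrics.sensitivity:.2f}, "
      f"specificity {metrics.specificity:.2f}")
print(medians.round(2))
```

prints

```text
AL-group medians: index = 0.335 -> leak
LD-group medians: index = 0.567 -> no_leak
accuracy 0.86, sensitivity 1.00, specificity 0.82
          median_index  iqr_low  iqr_high   n
group
AL                0.25     0.21      0.27  15
LD                0.72     0.56      0.74   9
WD                0.63     0.51      0.66  10
LD-wdFMT          0.45     0.40      0.47  12
WD-ldFMT          0.64     0.57      0.75  13
```

The leak-group medians sit well below the 0.45 cutoff while every leak-free
group scores at or above it: leak communities have shifted toward the
*Bacteroides*/*Akkermansia*-dominated assemblage, and the index detects that
shift with high sensitivity.

A command-line interface mirrors the library:

```bash
microleak simulate --seed 1 --out study/
microleak analyze --seed 1 --out run/           # full report bundle
microleak clinical-tests                        # exact tests on outcome tables
microleak al-index --counts study/counts.tsv
```

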