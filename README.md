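# scc2xpress

Analyses for studies of the budding-yeast cohesin loader **Scc2** (human
ortholog *NIPBL*, mutated in Cornelia de Lange syndrome) and its role in
gene expression and translational fidelity. Partial-loss-of-function *scc2*
mutants perturb ribosomal-protein, snoRNA and tDNA transcription, splicing,
ribosome assembly and translation; this package implements the quantitative
machinery such a study needs, end to end, with a seeded synthetic-data
module so every stage can be exercised without any external download.

## What it computes

* **Metagene ChIP profiles** — reads are extended to 150 bp, per-base
  coverage is normalized to reads per million (RPM), and for a gene group
  (e.g. 132 ribosomal-protein genes, 77 snoDNAs, 275 tDNAs) the coverage
  ±600 bp around each TSS is averaged per base pair, strand-aware.
* **Feature counting and RPKM** — reads per feature (any ≥ 1 bp overlap),
  RPKM = count · 10⁹ / (length · library size), and MA quantities
  M = log₂(mutant/WT), A = geometric mean of RPKM, with DE classification
  at adjusted *p* < 0.05 and an optional 1.5-fold (|log₂| ≈ 0.6) cutoff.
* **Splicing efficiency (PSO, percent spliced out)** — for every annotated
  intron, the number of split reads whose gap exactly matches the intron,
  divided by the mean per-base coverage of the two flanking exons, ×100;
  one-way ANOVA per splicing unit across genotypes with Benjamini–Hochberg
  correction across units.
* **Gene-set enrichment** — upper-tail hypergeometric over-representation
  with BH adjustment.
* **Cytometry distribution shifts** — Kolmogorov–Smirnov distance
  D = sup|F₁ − F₂| between per-cell GFP intensity ECDFs (~10,000 cells per
  sample). A genotype shift is only called when every between-genotype D
  exceeds the largest within-genotype (replicate) D *and* every between
  pair is significant — with n ≈ 10⁴ the KS test alone flags trivial
  differences.
* **Dual-luciferase translational fidelity** — firefly/renilla ratios give
  −1/+1 programmed ribosomal frameshifting efficiency (PRF construct vs
  0-frame control, ×100), stop-codon readthrough (stop vs sense reporter,
  ×100) and IRES activity (strain vs reference strain, ×100), plus
  two-tailed Student *t* comparisons between strains.
* **Growth rates** — maximal specific growth rate μ_max as the steepest
  sliding-window slope of ln(OD) vs time, with percentages relative to a
  reference strain.

## Worked example

```python
from scc2xpress import synthetic_data as sd
from scc2xpress.reporters import frameshift_efficiency
from scc2xpress.cytometry_ks import replicate_baseline_test

wells, truth = sd.gen_luciferase(sd.LuciferaseSimConfig(), seed=42)
by = {}
for m in wells:
    by.setdefault((m.strain, m.construct_role), []).append(m)
for strain in ("WT", "scc2-4"):
    r = frameshift_efficiency(by[(strain, "minus1_PRF")],
                              by[(strain, "zero_frame_control")])
    print(f"{strain}: -1 PRF efficiency = {r.value:.2f}% (SEM {r.sem:.2f}, n={r.n_replicates})")

samples = sd.gen_cytometry(sd.CytometrySimConfig(shift=(1.0, 1.5)), seed=42)
d = replicate_baseline_test(samples)[0]
print(f"KS: max within-genotype D = {d.max_within_d:.3f}, "
      f"min between-genotype D = {d.min_between_d:.3f} -> shift = {d.shift}")
```

prints

```
WT: -1 PRF efficiency = 0.97% (SEM 0.03, n=6)
scc2-4: -1 PRF efficiency = 3.47% (SEM 0.11, n=6)
KS: max within-genotype D = 0.014, min between-genotype D = 0.307 -> shift = True
```

The synthetic plate was generated with true efficiencies of 1.1 % (WT) and
3.4 % (mutant) and 10 % multiplicative well noise; the estimators recover
them within sampling error, a ~3-fold increase in −1 frameshifting. The
cytometry run simulates a 1.5× intensity shift in the mutant: replicate
distances stay near 0.01 while every between-genotype distance exceeds 0.3,
so a distribution shift is called.

## Command line

Every stage has a subcommand (`scc2xpress simulate|coverage|count|metagene|
pso|ma|enrich|ksflow|luciferase|growth`), and `scc2xpress run --config
run.yaml` drives a config-file end-to-end run that writes TSVs, a JSON
summary and a provenance log. See `--help` on any subcommand.

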