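# lpsprofiler

Functional-metagenomic profiling of gut-microbiome lipopolysaccharide (LPS)
acylation capacity, for researchers studying how the microbiome shapes
response to anti-PD-1 cancer immunotherapy.

Hexa-acylated lipid A — the endotoxic moiety of LPS — is a potent agonist
of human TLR4, while penta- and tetra-acylated forms are weak agonists or
antagonists. Whether a gut bacterium can build the hexa-acylated form is
encoded in its lipid A biosynthesis genes: *lpxA/B/C/D/K* (+ *waaA*) build
the tetra-acylated backbone, *lpxL* adds the fifth acyl chain, and *lpxM*
or *lpxJ* add the sixth. `lpsprofiler` turns that genetics into cohort
statistics:

1. **Structure prediction** — a species encodes a gene if ≥ 50% of its
   pangenome's genomes carry it (two annotation schemata merged by union,
   *lpxM* restricted to one schema); the gene set is classified into
   none / tetra / penta / hexa acylation capacity by the pathway rules.
2. **Quantification** — category abundances as fractions of classified
   reads; GCPM `(qᵢ/lᵢ)/Σⱼ(qⱼ/lⱼ)·10⁶` and CPM `Aᵢ/ΣA·10⁶`
   normalizations; CLR transforms; rare-feature and zero-sample filters;
   guarded hexa:penta and *lpxM*:*lpxL* ratios.
3. **Enterotyping** — sqrt Jensen–Shannon distances, PAM (k-medoids)
   clustering, Calinski–Harabasz model selection, between-class analysis
   and PCoA.
4. **Association** — Mann–Whitney, Kruskal–Wallis + Dunn/Bonferroni,
   one-tailed two-proportion Z-tests, NMDS (Kruskal stress-1, multi-restart
   with a Procrustes convergence check) and t-tests on NMDS axes.
5. **Synthetic cohorts** — a generator that plants known effects (doubled
   responder hexa:penta ratio, elevated non-responder LPS load, batch
   effects, overdispersed counts) so the whole pipeline is testable against
   ground truth.

See `docs/methods.md` for the model, defaults and limitations.

## Worked example

```python
from lpsprofiler import PipelineConfig, SimulationConfig, run_all

cfg = PipelineConfig(
    simulation=SimulationConfig(n_species=60, n_samples_per_arm=20, seed=7),
    n_restarts=10, seed=7,
)
manifest = run_all(cfg, "demo")
```

or equivalently from the shell: `lpsprofiler run-all --seed 7 --out demo`
(a JSON config can override any parameter). The run writes every stage
output plus a reproducible manifest into `demo/`. With this seed,
`demo/tallies.json` reports the predicted structure census of the 60
simulated species:

```
{"total_lps": 39, "kdo2": 39, "tetra": 8, "penta": 20,
 "hexa": 11, "hexa_lpxM": 7, "hexa_lpxJ": 4, "none": 21}
```

i.e. 39 of 60 species encode lipid IVA, of which 20 stop at
penta-acylation and 11 can hexa-acylate. `demo/association_report.json`
holds one record per statistical comparison; the key planted contrast —
the per-sample ratio of hexa- to penta-acylated-LPS-encoding taxa,
responders vs non-responders — comes out as

```
ratio_hexa_total_vs_penta_R_vs_NR:
  U = 396.0, p = 1.23e-07
  R:  n = 20, mean ratio 0.829
  NR: n = 20, mean ratio 0.415
```

an almost exactly two-fold responder enrichment, matching the planted
`hexa_fold_responder = 2.0` recorded in `demo/truth.json`. Enterotype
assignments, Calinski–Harabasz scores per k, NMDS/PCoA/BCA coordinates and
the batch-adjusted CPM matrix are written alongside.

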