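# cnvtrn

Copy-number-aware transcriptional regulatory network (TRN) analysis for
paired tumor expression / copy-number cohorts, with a synthetic-data
generator that plants known structure so every stage is testable.

## The problem

Given a gene-level expression matrix and per-sample DNA copy-number
profiles from the same patients, the pipeline asks how recurrent copy
number variation (CNV) disturbs transcriptional regulation:

1. **Recurrent CNV calling.** Marker-level log-ratios are segmented by a
   circular binary-segmentation scheme, collapsed to gene-level values,
   and recurrent amplified/deleted regions are called with a G-score
   statistic (per gene and direction, `G = Σ_samples max(0, x − 0.3)` for
   amplification, analogously for deletion at −0.3) against a
   within-sample permutation null, BH-corrected to q < 0.25. Genes and
   transcription factors (TFs) inside significant regions become
   CNV-genes and CNV-TFs.
2. **TRN inference (forward + reverse engineering).** A sequence-derived
   TF→gene prior edge list is screened by expression dependence: mutual
   information `MI(X,Y) = Σ_ij P(x_i,y_j) log [P(x_i,y_j) / (P(x_i)P(y_j))]`
   (plug-in estimate over equal-frequency bins), context-normalised as a
   CLR score `clr = sqrt(z_TF² + z_target²)` with per-endpoint z-scores
   floored at 0. A prior edge is retained when its CLR strictly exceeds
   the 95th percentile of 1000 randomly drawn non-prior pairs for the
   same TF. Retained edges grouped by TF form regulatory modules.
3. **CNV-related module selection.** Each module (TF plus first-layer
   targets) must be pathway-enriched (one-sided Fisher vs the
   expressed-gene background) and either regulated by a CNV-TF or
   enriched in CNV-genes (Fisher vs the network background), both screens
   BH-corrected at FDR < 0.05. Modules are typed `cnv_tf_only`,
   `cnv_gene_only` or `both`, and the network is tallied into 4 node and
   7 edge classes.
4. **Pathway integration.** Pathway nodes that carry CNV or are regulated
   by a CNV-TF are overlapped, their 1-hop pathway neighborhoods expanded,
   and regulatory and pathway edges merged into one attributed graph with
   a per-pathway disturbance fraction.
5. **Expression subtyping.** Samples are clustered on the selected
   network's genes by NMF consensus clustering (`V ≈ WH`, KL-divergence
   multiplicative updates, 30 random restarts, ranks k = 2..5), the rank
   chosen by the cophenetic coefficient of the consensus matrix; cluster
   robustness is checked by leave-one-out cross-validation (KNN,
   signal-to-noise weighted voting, CART) and clusters characterised by
   Welch-t differential expression (p < 0.001) and Fisher enrichment.

## Worked example

```python
from cnvtrn import synthetic_data as sim
from cnvtrn.trn_inference import infer_trn

ann = sim.simulate_annotation(n_genes=1100, n_tfs=8, n_chroms=1, seed=7)
prior = sim.simulate_prior(ann, targets_per_tf=25, seed=7)
expr, truth = sim.simulate_expression(ann, prior, n_samples=150,
                                      beta=2.0, noise_sd=0.1, seed=7)
trn, scored, nulls = infer_trn(expr, prior, null_size=1000, seed=7)
retained = trn.edge_pairs()
print(f"{len(retained)} edges retained in {len(trn.modules)} modules")
print(f"planted-edge recall: {len(retained & truth.planted_edges) / len(truth.planted_edges):.3f}")
```

prints

```
186 edges retained in 8 modules
planted-edge recall: 1.000
```

All 186 planted active edges (β = 2, i.e. target ≈ 2·TF + noise) pass the
per-TF null screen; inactive prior edges (here, the 14 edges whose target
is itself a TF) are subject only to the ~5% false-positive rate the
strict 95th-percentile cut implies, and none survive at this seed.

The same dataset can be produced from a shell:

```bash
cnvtrn simulate --genes 1100 --tfs 8 --samples 150 --seed 7 --outdir sim/
cnvtrn infer --expr sim/expression.tsv --prior sim/prior.sif --seed 7 --out-prefix run
```

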