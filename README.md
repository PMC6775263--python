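# gutlink

Analysis pipeline for three-group gut-microbiome studies of the
stress–microbiota–behavior axis (control / stress / stress+treatment), of
the kind used to ask whether a chronic-stress model perturbs the fecal
microbiota and whether an antidepressant restores it.

Starting from a finished taxon-by-sample count table, sample→group
metadata and per-animal behavioral indices, the package computes:

- **Alpha diversity** — Shannon–Wiener index H = −Σ pᵢ ln pᵢ (nats), with
  the Chao–Shen coverage-adjusted nonparametric estimator selectable.
- **Beta diversity** — Bray–Curtis dissimilarity
  d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) with classical PCoA (Gower
  double-centering + eigendecomposition).
- **Differential abundance** — per-taxon Kruskal–Wallis and pairwise Welch
  t / Mann–Whitney contrasts; an LDA-effect-size (LEfSe-style) screen; and
  a three-way response classification per taxon: *restored* (shifted by
  stress, reversed by the drug), *stress_only*, *drug_only*, *unchanged*.
- **Co-occurrence networks** — genera present in more than half the
  samples; non-random segregation tested with the checkerboard score
  C = mean over taxon pairs of (Rᵢ−Sᵢⱼ)(Rⱼ−Sᵢⱼ) under a fixed-fixed (SIM9)
  swap null model; edges are robust Spearman correlations (|ρ| > 0.7,
  p < 0.05, exact permutation p for n ≤ 9); network properties (V, E,
  density, clustering, modularity, path length) compared against 10,000
  Erdős–Rényi G(V, E) random graphs.
- **Behavior association** — sucrose preference
  SP(%) = sucrose/(sucrose+water)×100 and Spearman correlation heatmaps of
  taxa versus behavioral indices (SP, immobility time, open-arm time,
  center time) with *, **, *** significance stars.

Because studies of this design rarely release raw sequencing data, the
package ships a synthetic-data generator (`gutlink.simulate`) that
produces study-shaped inputs — 3 groups × 6 samples, Dirichlet-multinomial
counts — with *known* planted group effects, correlation modules and
taxon–behavior couplings, so every stage of the pipeline is testable
against ground truth.

## Worked example

```sh
gutlink simulate --seed 3 --out-dir demo
cd demo
gutlink diversity counts.tsv | head -3
gutlink network counts.tsv --n-null 999 --n-random 10000 --out-prefix pooled
gutlink diffabund counts.tsv metadata.tsv | cut -f1,3,4,10 | head -7
gutlink correlate counts.tsv behavior.tsv
```

The diversity command prints per-sample Shannon values in nats:

```
sample_id	shannon
Control_PBS_s1	1.8821750961958164
Control_PBS_s2	2.6695997932002244
```

The network command reports `V=9 E=15` for the pooled 18-sample network
and writes `pooled.report.json`: the C-score test is not significant here
(SES = 1.04, p = 0.479 — the planted structure is correlational, not
segregative, so presence–absence checkerboarding is absent), while the
observed clustering coefficient 0.688 is far above the Erdős–Rényi
ensemble (p ≈ 0.002), as expected for a planted correlation module.

The differential-abundance table recovers the planted responders — e.g.
at this seed `g01` (kw_p = 0.0031, LDA score 3.82) and `g02` are
classified *restored* and `g08` *drug_only*; one planted drug-only taxon
(`g07`) is misclassified at this seed, consistent with the ~95% average
category accuracy measured over seeds.

The correlation table shows the planted behavior couplings: `g01` versus
sucrose preference gives ρ = −0.69 (p = 0.0015, `**`) and versus
immobility time ρ = 0.72 (`***`).

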