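# fflnet

Analysis of miRNA–TF co-regulatory networks built from feed-forward
loops (FFLs), for studies that start from curated disease gene lists —
the reference use case is human cleft lip (CL), a common congenital
craniofacial defect — and ask which transcription factors (TFs) and
microRNAs (miRNAs) jointly drive the candidate genes.

Given four typed regulatory pair tables (TF→gene, TF→miRNA, miRNA→gene,
miRNA→TF), `fflnet`:

1. **enumerates 3-node FFLs** — triples (TF, miRNA, gene) in which both
   regulators target the same non-TF gene, classified exclusively by the
   regulator–regulator link: motif **A** (TF→miRNA), motif **B**
   (miRNA→TF), motif **C** (both; a TF/miRNA feedback pair);
2. **assembles** motif-specific and combined regulatory networks with
   composition statistics;
3. **ranks hubs** by Maximal Clique Centrality,
   MCC(v) = Σ_{C ∋ v} (|C| − 1)! over maximal cliques C of the
   undirected projection;
4. **partitions modules** with Markov clustering (MCL; expansion e = 2,
   inflation r = 2.0, modules < 3 nodes dropped);
5. **validates TF→gene edges** against an independent expression matrix:
   an edge is verified when |r| > 0.3, two-sided P < 0.05 and
   Benjamini–Hochberg FDR < 0.1 over the network's testable edges;
6. runs **hypergeometric gene-set enrichment** (upper-tail P, BH FDR)
   against GMT files;
7. extracts **pathway-seeded subnetworks**: all FFLs whose target gene is
   in a seed list (e.g. Wnt genes), split into connected components.

A synthetic-data generator plants FFLs of every motif class and
correlated TF–gene expression with known ground truth, so the whole
pipeline is testable offline.

## Worked example

```python
from collections import Counter
from fflnet import *

cfg = SimulationConfig(n_tf=12, n_mirna=8, n_gene=30,
                       planted_ffls={"A": 8, "B": 5, "C": 2},
                       background_edge_rates={"TF_gene": 0.05, "miRNA_gene": 0.04},
                       n_samples=35, rho=0.9, frac_correlated=0.65, seed=7)
tables, truth = generate_pair_tables(cfg)
ffls = enumerate_ffls([e for es in tables.values() for e in es])
print("FFLs by motif:", dict(Counter(f.motif_type for f in ffls)))

net = build_network(ffls)
print("combined:", network_stats(net).as_dict())
for r in top_k(mcc_scores(net), 5):
    print(f"  {r.rank}. {r.node} ({r.kind}) MCC={r.score}")

part = filter_modules(mcl(net), 3)
print("modules:", part.sizes())

matrix, expr_truth = generate_expression(net, cfg)
res, summ = validate_edges(net, matrix)
print(f"verified {summ.n_verified}/{summ.n_edges} TF-gene edges "
      f"({100*summ.fraction:.1f}%)")
```

prints

```
FFLs by motif: {'B': 5, 'C': 2, 'A': 8}
combined: {'n_mirna': 3, 'n_tf': 2, 'n_gene': 13, 'n_edges': 34,
           'edges_by_type': {'TF_gene': 15, 'TF_miRNA': 2,
                             'miRNA_gene': 15, 'miRNA_TF': 2}}
  1. TF006 (TF) MCC=16
  2. hsa-mir-s002 (miRNA) MCC=16
  3. TF001 (TF) MCC=14
  4. hsa-mir-s003 (miRNA) MCC=10
  5. GENE023 (gene) MCC=4
modules: [10, 8]
verified 10/15 TF-gene edges (66.7%)
```

All 15 planted loops are recovered (background edges create none extra
at these rates); the two joint regulators of the densest clique tie at
the top of the MCC ranking; MCL splits the network into its two flow
blocks; and the verified TF→gene edges are the 9 carrying planted
correlation at ρ = 0.9 plus one null edge whose sample correlation
(r = −0.35 at n = 35) cleared the thresholds by chance — exactly the
kind of borderline call the FDR gate is there to limit.

The same stages are available from the shell:

```sh
fflnet simulate --seed 7 --outdir sim/
fflnet enumerate --typed sim/pairs_TF_gene.tsv ... --out ffls.tsv
fflnet build --ffls ffls.tsv --out net.tsv
fflnet hubs --network net.tsv --k 10
fflnet cluster --network net.tsv --inflation 2.0 --min-size 3
fflnet validate --network net.tsv --expr sim/expression.tsv
fflnet run-all --config pipeline.yaml
```

`run-all` writes every stage artifact plus a `manifest.json` whose
content is a pure function of inputs + config (input checksums and all
parameters recorded; byte-identical on reruns).

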