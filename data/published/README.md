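# Published input tables (not distributed)

This directory is the expected location for the reference study's input
data, which is not redistributable with the package. The acceptance
tests that reproduce the published headline numbers read from here and
fail with a clear message while the files are absent.

Expected files (all plain TSV, `#` comment lines allowed):

| file | contents | source |
|------|----------|--------|
| `pairs_TF_gene.tsv`    | `TF<TAB>gene` pairs      | supplementary regulatory-pair workbook, TF-gene sheet |
| `pairs_TF_miRNA.tsv`   | `TF<TAB>miRNA` pairs     | same workbook, TF-miRNA sheet |
| `pairs_miRNA_gene.tsv` | `miRNA<TAB>gene` pairs   | same workbook, miRNA-gene sheet |
| `pairs_miRNA_TF.tsv`   | `miRNA<TAB>TF` pairs     | same workbook, miRNA-TF sheet |
| `gse7759_expression.tsv` | RMA-normalized expression, rows = mouse gene symbols (or probes), columns = the 35 maxillary-process samples | GEO accession GSE7759 |
| `gse7759_probe_map.tsv` | optional `probe<TAB>gene` map if the matrix is probe-level | array annotation |

Export each workbook sheet to TSV (symbols verbatim; miRNA names as
printed, e.g. `hsa-mir-27b`). For GSE7759, the Series-Matrix file also
works if converted to the expression TSV above, or place it as
`gse7759_series_matrix.txt` and pass `format="series_matrix"`.
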