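# florinet

Differential transcription-regulatory-network (TRN) analysis for floral
induction in the rootless duckweed *Wolffia australiana*, plus a k-mer survey
genome-size estimator — packaged as a tested, reusable pipeline with a fully
ground-truthed synthetic data generator.

## The scientific problem

*W. australiana* plantlets can be induced to flower with EDTA; single-plantlet
RNA-seq of **C**ontrol, **I**nduced-but-not-flowered and **F**lowered samples
asks which transcription factors (TFs) rewire the regulatory program during
floral organ initiation. The analysis builds one TRN per condition comparison
(C–I and C–F) and asks which nodes distinguish them, then tests whether a TF
family (e.g. AP2/ERF, TCP) is over-represented among those distinguishing
nodes.

### The method

1. **Promoters.** For every annotated gene, the window TSS −500 bp to +100 bp
   (600 bp, strand-aware, clipped at chromosome ends).
2. **Motif scan.** Each TF's position weight matrix `p(i,b)` is scored against
   a 0-order background `b(x)` as a pseudocounted log-odds sum
   `S = Σ_i log2(p̃(i, x_i)/b(x_i))`, and the *exact* p-value
   `P(S_null ≥ s)` is computed by dynamic programming over discretized column
   scores (1/1000-bit bins). Occurrences on either strand with `p ≤ 1e-5`
   connect a TF to a candidate target.
3. **Edge refinement.** A candidate TF→target edge is retained iff
   (i) the pair is coexpressed, Spearman `|ρ| > 0.9` over the comparison's
   samples; (ii) at least one of the pair is differentially expressed
   (`|FC| ≥ 2`, BH FDR ≤ 0.05, negative-binomial Wald test) in I-vs-C or
   F-vs-C; and (iii) at least one of the pair is on the curated floral gene
   list. The edge sign is the sign of ρ.
4. **Differential networks.** Nodes present in only one TRN, or present in
   both with different signed neighbour sets, are *distinguishing*. Family
   enrichment among distinguishing nodes uses the one-sided hypergeometric
   test `p = Σ_{j≥k} C(K,j)C(N−K,n−j)/C(N,n)` with the 2×2 odds ratio.
5. **Genome-size survey.** Canonical 17-mers of shotgun reads are counted;
   `genome size = total k-mers / k-mer depth`, with depth taken at the
   histogram peak above the error trough.

Because the study's deposited reads are far beyond desk scale, the package
ships a synthetic generator that plants all of this structure — promoter
motif sites, NB counts with TF-coupled targets, ≥2-fold condition effects and
a TF family wired only in the flowered program — with complete ground truth,
so every stage is scored against known answers.

## Worked example

```bash
echo 'simulate: {}' > cfg.yaml
florinet run --config cfg.yaml --seed 1 --out runs/demo
```

This simulates the default study (300 genes, 20 TFs, 150 planted edges,
3 conditions × 4 replicates), runs every stage, and prints the run report:

```
"deg_counts":   {"I-vs-C": 112, "F-vs-C": 159, "F-vs-I": 65},
"networks":     {"C-I": {"nodes": 123, "edges": 108},
                 "C-F": {"nodes": 139, "edges": 145}},
"n_distinguishing": 20,
"site_recovery": 1.0,
"edge_recovery": {"precision": 1.0, "recall": 0.967, "sign_agreement": 1.0},
"enrichment": [{"family": "AP2-ERF", "overlap": 6, "family_size": 6,
                "distinguishing": 20, "universe": 139,
                "odds_ratio": 107.1, "p_value": 4.3e-06, ...}, ...]
```

Reading: the C–F network recovers 145 of 150 planted regulatory edges with no
false edges and every recovered sign correct; 20 nodes distinguish the C–I and
C–F networks, and all 6 TFs of the planted rewired AP2-ERF family are among
them (hypergeometric p = 4.3e-06, odds ratio 107 with Haldane correction),
while the stable TCP control family shows no enrichment. Stage outputs
(`promoters.fasta`, `hits.tsv`, `de_*.tsv`, `trn_C-I.tsv`, `trn_C-F.tsv`,
`diff_report.tsv`) and a checksum manifest land under `runs/demo/`.

Each stage is also a standalone subcommand (`florinet simulate / promoters /
scan / de / trn / diff / kmersurvey`) over on-disk FASTA/GFF3/MEME/TSV files,
and every step is importable from Python (`florinet.motif_scan`,
`florinet.trn_build`, ...).

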