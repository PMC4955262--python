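# pepthla

Discovery and cross-reactivity prioritization of cancer-specific
peptide–HLA class I targets.

## The problem

Engineered T-cells and TCR-like antibodies can kill tumor cells by
recognizing a specific peptide presented by an HLA class I molecule (the
package focuses on 9-mers and HLA-A\*02:01, the most frequent class I
allele). The danger is cross-reactivity: a peptide from a normal-tissue
protein that *resembles* the target can be recognized too. Clinical trials
targeting the MAGEA3 peptide `KVAELVHFL` caused fatal neurotoxicity via the
MAGEA12 peptide `KMAELVHFL` (one mismatch), and an HLA-A\*01:01 MAGEA3
therapy caused fatal cardiotoxicity via the Titin peptide `ESDPIVAQY`
(four mismatches). `pepthla` implements an in-silico strategy that finds
candidate cancer-specific peptide–HLA targets in the proteome and ranks
them by their predicted off-target burden, so the safest candidates surface
first.

## The method

Four gates, each a module:

1. **Proteome mining** (`proteome`) — every overlapping 9-mer over the 20
   standard amino acids is enumerated from a canonical protein FASTA, with
   gene provenance; identical 9-mers from different proteins merge.
2. **Binding** (`affinity`) — a peptide–HLA pair is a putative complex when
   the predicted IC50 < 500 nM (strong binder < 50 nM). Predictions come
   from an external predictor's TSV output or a deterministic mock.
3. **Cancer specificity** (`expression`) — a peptide is specific to a
   cancer type when its gene's 75th-percentile RPKM across that type's
   tumor samples exceeds 5.0 while the maximum 75th-percentile RPKM over
   all *essential* normal tissues is below 0.5 (reproductive tissues are
   non-essential and ignored).
4. **Off-target search** (`similarity`, `structure_contacts`) — the degree
   of similarity (DoS) of two 9-mers is the number of identical residues at
   identical positions (9 − Hamming distance). Every proteome peptide with
   DoS ≥ 5 to a target that also binds the allele (IC50 < 500 nM) and is
   expressed in some essential normal tissue (95th-percentile RPKM > 0.5)
   is a predicted off-target. Optionally, crystal structures of
   peptide–HLA–TCR/antibody complexes vote on which of the 9 positions
   matter for TCR contact (hydrophobic contact: van der Waals gap within
   [0.0, 0.4] Å; hydrogen bond: donor–acceptor < 4 Å), and similar peptides
   sharing fewer than 3 identical *important* positions are discarded.

Targets are ranked by ascending off-target count at DoS ≥ 6, then at
DoS ≥ 5, then by descending tumor expression. The neighbor search is exact:
a pigeonhole block index (9 positions split into 5 blocks, so any peptide
within 4 mismatches matches the query in at least one block) proposes
candidates that are verified by full DoS. The importance predictor is
validated by structure-level leave-one-out ROC.

The `synthetic` module generates all four inputs with planted, verifiable
truth (targets, off-targets at prescribed DoS and tissue, toy 3-chain
structures realizing a prescribed contact pattern), so the entire pipeline
is testable without downloads.

## Worked example

Generate a small synthetic study (two planted targets, two planted
off-targets) and run the full pipeline on the written files:

```sh
pepthla fixtures-make --seed 3 --out fx
pepthla run --proteome fx/proteome.fasta --manifest fx/manifest.tsv \
    --affinity fx/affinity.tsv --expr fx/expression.tsv --meta fx/meta.tsv \
    --out out
```

The run log reports the stage counts:

```
{"n_peptides": 1177, "n_binders": 4, "n_targets": 2,
 "n_unique_target_peptides": 2, "n_offtarget_links": 2}
```

1,177 distinct 9-mers were mined, 4 bind HLA-A\*02:01 below 500 nM, 2 pass
the cancer-specificity gate, and the similarity search attaches 2
off-targets. `out/targets.tsv` holds the ranked targets:

```
rank  tumor  peptide    gene  IC50    RPKM.tumor  Sim.5  Sim.6
1     LAML   LTSMWSPAV  TGT2  279.13  28.3829     1      1
2     SKCM   SLSVMSSNV  TGT1  265.87  20.9304     1      1
```

Each row is one (peptide, cancer type) target with its predicted binding
affinity, 75th-percentile tumor expression, and off-target counts at
DoS ≥ 5 (`Sim.5`) and DoS ≥ 6 (`Sim.6`); both targets here carry one
off-target, so the tie is broken by tumor expression. `out/offtargets.tsv`
lists each off-target with its DoS, IC50, source gene and top expressing
essential tissues. Ad-hoc queries work directly on a FASTA:

```sh
pepthla similar --query SLSVMSSNV --index fx/proteome.fasta --min-dos 5
# query      candidate  dos  identical_positions  genes
# SLSVMSSNV  SLSVMYSCY  6    1,2,3,4,5,7          SYN_O1
```

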