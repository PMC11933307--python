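# iuorfkit

Detection of **internal upstream open reading frames (iuORFs)** — short,
out-of-frame ORFs inside an mRNA coding sequence that repress translation
initiation at a downstream internal in-frame TIS (the start codon of an
N-terminally truncated proteoform) — together with the supporting
computations such a screen needs:

* `iuorfkit.orfs` — frame arithmetic and ORF enumeration relative to the
  canonical TIS (de-novo AUG scanning or TIS-call driven).
* `iuorfkit.screen` — the candidate screen: pair short out-of-frame ORFs
  with internal in-frame TISs, apply the positional filters
  (≤ 100 codons, upstream spacer ≤ 30 nt or overlap), keep the
  best-scoring candidate per transcript, classify upstream vs overlapping.
* `iuorfkit.kozak` — Kozak-context extraction and tier classification
  (optimal / strong / adequate / weak / indeterminate from −3 and +4).
* `iuorfkit.conservation` — ortholog selection by alignment identity,
  position projection through pairwise alignments, per-species feature
  vectors and conservation flags, sORF peptide identity.
* `iuorfkit.stats` — plate-screen Z scores with two-sided normal P values
  and hit calling, Shapiro–Wilk gate, Benjamini–Hochberg FDR, and the
  ΔΔCt translation-initiation index with double background correction.
* `iuorfkit.simulate` — synthetic transcripts with *planted* iuORF
  geometry (certificate-checked to be decoy-free), ortholog trios,
  screen ratio tables with spiked hits, and replicate Ct tables.
* `iuorfkit.io` — FASTA, a strict TIS-call TSV dialect, candidate
  TSV/GFF3 output. Coordinates are 1-based inclusive on the mRNA;
  sequences are normalized to the RNA alphabet (T→U) on ingest.

## Command line

```sh
# screen transcripts for iuORF candidates
iuorfkit scan --fasta transcripts.fasta --tis-table tis_calls.tsv \
    --out-tsv candidates.tsv --out-gff3 candidates.gff3

# cross-species conservation of candidate features
# (ortholog FASTA ids are "<transcript_id>|<species>")
iuorfkit conserve --ref-fasta ref.fasta --ortholog-fasta orthologs.fasta \
    --candidates-tsv candidates.tsv --out-tsv conservation.tsv

# screen statistics and the ddCt initiation index
iuorfkit stats screen --ratios-tsv ratios.tsv --out-tsv zscores.tsv
iuorfkit stats ddct --ct-tsv ct.tsv --out-tsv index.tsv

# synthetic inputs with planted ground truth
iuorfkit simulate transcriptome --n 50 --seed 1 --outdir sim/
iuorfkit simulate orthologs --divergence 0.1 --seed 1 --outdir orth/
iuorfkit simulate screen --n 184 --n-hits 8 --seed 1 --out-tsv ratios.tsv
iuorfkit simulate ct --true-index 2.0 --noise 0.2 --out-tsv ct.tsv
```

Every subcommand writes a `<output>.manifest.json` with the parameters,
seed, input checksums and package version.

### TIS-call table

Tab-separated with header
`transcript_id  pos  codon  init_score  is_canonical`, where `pos` is the
1-based position of the start codon's first nucleotide and `codon` is one
of AUG/CUG/GUG/ACG/AUA/AUU/AUC/UUG (DNA spelling accepted). Exactly one
canonical call per transcript; transcripts without one are excluded from
the screen and counted.

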