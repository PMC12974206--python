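# uorftools

Upstream open reading frames (uORFs) — AUG codons in a transcript's 5ʹ UTR
followed by an in-frame stop — repress translation of the downstream primary
ORF (pORF). At loci like *BDNF*, where many transcript isoforms differ only
in their 5ʹ UTR exon content, uORFs shape protein output, and removing them
(by splice-mediated exon exclusion or by base-editing the uORF start codon)
can de-repress translation.

`uorftools` is a transcript-isoform-aware toolkit for designing and
quantifying such interventions:

* **transcript model** — spliced transcripts with exon segmentation and CDS
  offsets, loaded from FASTA + GFF3 (transcript- or genome-space, with
  minus-strand splicing) or a minimal TSV dialect; genome↔transcript
  coordinate mapping.
* **uORF scanner** — predicts uORFs (contained / CDS-overlapping /
  N-terminal extensions listed separately), classifies Kozak context by the
  discrete −3/+4 rule (strong: −3 ∈ {A,G} **and** +4 = G; weak: neither;
  intermediate: one), tallies uORFs per exon, and identifies *skippable
  exons* (5ʹ UTR exons hosting ≥1 uORF start that contain neither the TSS
  nor the pORF start codon).
* **construct design** — reporter 5ʹ UTR variant series: ATG→TTG start-codon
  disruption, whole-exon deletion with a re-scanned uORF diff, sequential
  deletion walks, positional segment insertion, and stem-loop summarization
  from externally computed dot-bracket structures (folding itself is the
  folding tool's job).
* **guide design** — SpCas9 (NGG) adenine-base-editor guides that place an
  editable adenosine of the uORF ATG in the editing window (default
  protospacer positions 4–8, PAM-distal = 1), with bystander adenosines
  reported over positions 1–10 and every post-edit allele enumerated and
  categorized (productive / non-productive / unedited).
* **edit quantification** — amplicon reads classified by exact string
  matching against the enumerated alleles (unmatched reads are "other"),
  pooled category fractions, and per-position A→G percentages from Sanger
  base-proportion tables (edit% = 100·G/(A+G)).
* **synthetic fixtures** — seeded generators of transcripts with planted
  uORFs, amplicon pools with planted allele fractions, and Sanger tables,
  so every analysis is testable offline against known truth.

## Worked example

The repo ships a two-exon fixture transcript (`examples/`) whose 5ʹ UTR
embeds the on-target protospacer 5ʹ-CACGATGTGACTCCGCCGCC-3ʹ with an AGG PAM.
Scan it:

```bash
uorftools scan --fasta examples/fixture.fa --tsv examples/fixture.tsv --out uorfs.tsv
```

`uorfs.tsv` contains one uORF:

```text
transcript_id      uorf_index start_1based stop_1based class     peptide_codons is_minimal kozak        host_exon
BDNF_like_fixture  1          9            14          contained 0              True       intermediate 1
```

a *minimal* uORF (ATG immediately followed by TGA) in intermediate Kozak
context (−3 = A, a purine; +4 = T, not G). Design guides against it:

```bash
uorftools design-guides --fasta examples/fixture.fa --tsv examples/fixture.tsv \
    --transcript BDNF_like_fixture --uorf 1 --out guides.tsv
```

```text
protospacer           pam strand target_pos bystanders rank predicted_productive_alleles
CACGATGTGACTCCGCCGCC  AGG sense  5          2,10       1    4
```

The target adenosine sits at protospacer position +5 with bystander
adenosines at +2 and +10: 2³ = 8 possible editing outcomes, of which 4 edit
the target (productive, uORF ablated), 3 edit only bystanders
(non-productive), and 1 is unedited. Classify a simulated amplicon pool and
quantify a Sanger table over the same three sites (amplicon coordinates
6/9/14 correspond to protospacer +2/+5/+10):

```bash
uorftools classify-amplicons --ref examples/fixture.fa --reads examples/reads.fastq \
    --target 9 --bystanders 6,14 --out summary.json
uorftools quant-sanger --table examples/sanger.csv --positions 6,9,14
```

```text
{"n": 200, "productive": 0.365, "non_productive": 0.01, "unedited": 0.625, "other": 0.0}

 position  edit_percent  low_confidence
        6          17.0           False
        9          28.3           False
       14           2.5           False
```

The shipped 200-read pool was generated at planted outcome fractions
0.367/0.011/0.622, and the Sanger table at planted per-position edit rates
17/28.3/2.5% — the classifier and quantifier recover them.

## Annotation TSV dialect

Besides GFF3, loaders accept a minimal tab-separated annotation with
columns `transcript_id`, `exon_lengths` (comma-separated, 5ʹ→3ʹ),
`cds_start`, `cds_end` (0-based half-open, transcript space) paired with a
transcript FASTA — see `examples/fixture.tsv`. All CLI output is 1-based.
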