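# Methods

## Transcript model and coordinates

A transcript is its spliced, sense-strand sequence plus an exon tiling and
the half-open CDS interval. Internally every coordinate is 0-based
half-open; reports and CLI output are 1-based closed, matching the
"+5"-style protospacer numbering used in base-editing work. Genomic
(minus-strand) input is reverse-complemented and exon-reordered at load
time, so every downstream operation sees only sense transcript space.
Load-time validation is strict: the CDS must begin with ATG and have length
divisible by 3, exons must tile the sequence exactly, and a missing CDS
feature is an error naming the transcript — a silently UTR-free transcript
would corrupt every downstream count. Codons containing N are treated as
neither start nor stop (conservative scanning).

## uORF scanning and classification

Every ATG strictly upstream of the CDS start is extended codon-by-codon to
its first in-frame stop. Three frame classes follow from half-open
arithmetic on the stop end *e* relative to the CDS start *c*:

* contained — *e* ≤ *c* (a stop codon straddling *c* cannot occur in the
  in-frame case, and out-of-frame straddling stops are classified
  overlapping by *e* > *c*, which keeps the rule unambiguous);
* overlapping — *e* > *c* with the start in a different frame from the pORF;
* N-terminal extension — in frame with the pORF with no intervening stop.
  Extensions produce longer proteins, not uORFs, so they are listed by a
  separate accessor and never counted in the predicted-uORF set.

Out-of-frame upstream ATGs with no stop anywhere before the transcript end
are not ORFs and are dropped. Nested and overlapping uORFs are reported
individually; a uORF is attributed to the exon containing the A of its ATG.

Kozak context uses the discrete two-position rule (−3 purine, +4 G; A of
AUG = +1): both conditions strong, neither weak, exactly one intermediate.
No position-weight matrix is used — the discrete labels are what the
application needs, and a PWM would imply unearned precision. When −3 or +4
falls outside the sequence the missing position fails its condition,
biasing truncated contexts toward weak; such contexts carry a `truncated`
flag. Over the 16 possible (−3, +4) combinations this yields exactly 2
strong, 8 intermediate and 6 weak classes, which the tests assert
exhaustively.

A *skippable exon* is a 5ʹ UTR exon that (i) is not exon 1 (transcription
start), (ii) does not contain the pORF start codon, (iii) lies entirely
within the 5ʹ UTR, and (iv) hosts at least one uORF start codon.

## Construct series

Start-codon disruption replaces ATG with TTG — same length, and exhaustive
enumeration of flanking 2-mers shows the T,T,G replacement bases can never
complete a new ATG, so disruption is always clean (the new-ATG warning
machinery exists for edits that can create one, such as exon junctions and
A→G conversions). Exon deletion re-scans the product and reports uORFs
lost/gained rather than assuming counts subtract, because junction effects
are real: a deleted junction can destroy a junction-spanning ATG or create
one, and structured elements can span exon boundaries. Deletion walks tile
a span from its 5ʹ end with a possibly-short final window; construct *i*
lacks exactly window *i*. Insertion offsets: cap-proximal 0, medial
⌊len/2⌋, cap-distal the UTR end — the qualitative positions made exact.

Every construct carries a provenance trail (operation, 1-based interval,
replacement); replaying the trail on the parent must reproduce the variant
byte-for-byte, and the constructors assert this.

## Hairpin summarization

Secondary structure is never computed here; dot-bracket strings come from
an external folding tool and only their geometry is summarized. Each
terminal (hairpin) loop yields one element; its stem counts all base pairs
on the path from that loop outward to the nearest branch point (a loop
enclosing more than one helix) or the exterior, so bulged single-branch
stems count as one stem. Reported per element: span (outermost pair's
enclosed width including both paired bases), stem base pairs, terminal-loop
length; span ≥ 2·stem + loop always, with bulges taking up the slack. A
supplied free energy describes the whole fold and is attached only when the
structure reduces to a single element. Multiloops therefore flatten into
one element per terminal loop — reproducible and oracle-checkable, and the
single-hairpin case is unaffected.

## ABE guide design

Protospacers are every 20-mer 5ʹ-adjacent to an NGG on either strand
(antisense hits report the reverse-complement protospacer and the
sense-strand interval covered). Positions are numbered 1 (PAM-distal) to
20, PAM at 21–23. A uORF ATG is ABE-editable two ways: a sense guide
placing the A in the window (ATG→GTG) or an antisense guide placing the A
opposite the T (ATG→ACG). The design window defaults to positions 4–8, the
high-efficiency range for ABE8e; the bystander reporting range defaults to
1–10 because meaningful bystander editing occurs outside the canonical
window (e.g. position +2). Both are configurable. Ranking: |target − 6|
ascending, then in-window bystander count ascending, then GC fraction
nearest 0.5 (ties broken by transcript offset for determinism). No
editing-efficiency model or genome-wide off-target scoring is attempted.

Allele prediction enumerates all 2^(1+k) subsets of {target} ∪ k
bystanders; a subset containing the target is productive (uORF ablated),
a non-empty subset without it non-productive, the empty set unedited —
exactly half productive and one unedited, which the tests assert as an
invariant. Each allele is applied to the transcript and re-scanned to flag
newly created upstream ATGs and changes to the pORF's −3/+4 context.

CBE (C→T) is exposed only as a validation mode: the sense ATG contains no
C, and the single antisense C (opposite the G; its edit gives ATG→ATA) is
actionable only when a PAM places it in the window — otherwise the check
reports that C→T cannot disrupt the site, making a CBE pairing with such a
guide a negative control.

## Amplicon classification and Sanger quantification

Expected amplicons are the 2^k A→G combinations over the editable
positions. Reads are matched exactly, in forward or reverse-complement
orientation; category follows the matched edited set, and any read of
atypical length or with a mismatch outside the editable positions is
"other" (a `max_mismatch`-style relaxation is deliberately absent from the
default path — exactness is what makes category fractions interpretable).
Fractions are counts/n and sum to 1 by construction.

Sanger quantification is proportion arithmetic over per-position A/C/G/T
base-call tables (rows must sum to 1 within 10⁻⁶): edit% = 100·G/(A+G) in
ABE mode, computed after the table is oriented to the protospacer strand.
Positions where A+G carries under half the signal are flagged
low-confidence rather than suppressed. Chromatogram peak-calling from raw
trace files is out of scope; the CSV table is the interface.

## Synthetic fixtures

Fixture generators are pure functions of (spec, seed) using a single
`numpy` Generator stream each; outputs are byte-identical across runs.

The transcript generator draws a uniform A/C/G/T background, plants the
CDS ATG and each requested uORF (start codon, Kozak −3/+4 bases, body
codons from an ATG/stop-free codon set, stop codon), then repairs the
background — unplanned UTR ATGs lose their T, premature in-frame stops in
open planted stretches lose their middle base — and finally re-scans,
returning only if the scan recovers exactly the planted truth; otherwise
it retries with a fresh background and ultimately raises. Infeasible
requests fail loudly: notably a minimal uORF can never have strong Kozak
context, because its +4 base is the T that every stop codon begins with.

The read simulator allocates allele counts deterministically
(largest-remainder apportionment of n·fraction) so that at zero error the
classifier recovers planted fractions exactly for any seed; the seed
drives read order and the noise processes. Substitution errors at editable
positions draw from {C,T} only — never the reference A or edited G — so an
error can never convert a read into a different enumerated allele: noisy
reads migrate to "other", never across productive/non-productive. Indels
insert or delete one base, producing atypical-length reads. The Sanger
generator splits each position's signal between A and G at the planted
rate, adds clipped Gaussian noise, and renormalizes.

These fixtures emulate structure (multi-exon UTRs, uORF classes, editable
sites, outcome mixes), not realistic base composition, splice-site motifs,
sequencing error spectra or trace chemistry; green recovery tests
demonstrate algorithmic correctness, not performance on real libraries.

## Problem sizes and defaults

The default verification suite uses 500 random transcripts (≤ 600 nt) for
scanner/oracle agreement, 200 random sequences for protospacer-enumeration
agreement, 2,000-read pools for fraction recovery, 100 seeded tables for
the Sanger Monte-Carlo, and 100 random fixture specs for planted-truth
recovery — sizes at which every check is exact or its sampling error is far
below the asserted tolerances, while the whole suite runs in seconds.
Planted pool fractions (36.7% productive, 1.1% non-productive) and Sanger
rates (28.3/17/2.5% at +5/+2/+10) mirror the editing-outcome magnitudes
reported for ABE disruption of a uORF start codon, so recovery is
demonstrated at realistic operating points.

## Known limitations

* Only AUG starts are scanned; near-cognate (CUG/GUG) initiation is out of
  scope, as is any Ribo-seq-based translation evidence.
* Real-accession workflows (RefSeq transcripts + genome annotation) are
  supported by the loaders but not exercised in the offline test suite;
  versioned accessions should be pinned by the user.
* The amplicon classifier is deliberately indel-unaware (no alignment);
  reads with indels are counted as "other", not resolved.
* The Kozak rule is discrete; it will disagree with PWM-based strength
  scores near class boundaries.
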