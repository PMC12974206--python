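"""Transcript representation and coordinate mapping.

A :class:`Transcript` holds the spliced, sense-strand sequence of an mRNA
together with its exon segmentation and the coordinates of the primary ORF
(pORF).  All downstream analyses — uORF scanning, construct design, guide
design — operate in spliced transcript space; minus-strand genomic
transcripts are reverse-complemented at load time so the rest of the
package never sees genomic strand.

Coordinates are 0-based half-open internally.  Reports and CLI output use
1-based closed intervals, which matches the conventional "+5"-style
protospacer numbering used when describing base-editing targets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

INTRONIC = "intronic"

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class TranscriptError(ValueError):
    """Raised when a transcript fails its structural invariants at load time."""


@dataclass(frozen=True)
class Exon:
    """One exon of a transcript, in transcript order.

    ``tx_start``/``tx_end`` are 0-based half-open coordinates in spliced
    transcript space.  ``genomic_start``/``genomic_end`` (0-based half-open
    on the contig) are optional: transcripts built directly from spliced
    sequence do not have them.
    """

    index: int  # 1-based ordinal in transcript order
    tx_start: int
    tx_end: int
    genomic_start: int | None = None
    genomic_end: int | None = None

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    def __post_init__(self) -> None:
        if self.tx_end <= self.tx_start:
            raise TranscriptError(f"exon {self.index}: empty or inverted tx interval")
        if (self.genomic_start is None) != (self.genomic_end is None):
            raise TranscriptError(f"exon {self.index}: partial genomic coordinates")
        if self.genomic_start is not None:
            glen = self.genomic_end - self.genomic_start
            if glen != self.length:
                raise TranscriptError(
                    f"exon {self.index}: genomic length {glen} != transcript length {self.length}"
                )


@dataclass(frozen=True)
class Transcript:
    """A spliced mRNA: sense-strand sequence, exon tiling, and pORF bounds.

    ``cds_start``/``cds_end`` are 0-based half-open transcript coordinates of
    the primary ORF.  The 5ʹ UTR is ``sequence[:cds_start]``.
    """

    id: str
    sequence: str
    exons: tuple[Exon, ...]
    cds_start: int
    cds_end: int
    strand: str | None = None  # genomic strand, "+" or "-", if known
    chrom: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise TranscriptError(f"{self.id}: non-nucleotide characters {bad}")
        if not (0 <= self.cds_start < self.cds_end <= len(seq)):
            raise TranscriptError(
                f"{self.id}: CDS [{self.cds_start},{self.cds_end}) outside sequence of length {len(seq)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise TranscriptError(f"{self.id}: CDS length not a multiple of 3")
        if seq[self.cds_start : self.cds_start + 3] != START_CODON:
            raise TranscriptError(
                f"{self.id}: CDS does not start with ATG "
                f"(found {seq[self.cds_start:self.cds_start + 3]!r} at {self.cds_start})"
            )
        if sum(e.length for e in self.exons) != len(seq):
            raise TranscriptError(
                f"{self.id}: exon lengths sum to {sum(e.length for e in self.exons)}, "
                f"sequence is {len(seq)} nt"
            )
        pos = 0
        for i, exon in enumerate(self.exons, start=1):
            if exon.index != i:
                raise TranscriptError(f"{self.id}: exon indices not 1..n in order")
            if exon.tx_start != pos:
                raise TranscriptError(f"{self.id}: exon {i} does not tile contiguously")
            pos = exon.tx_end

    # ------------------------------------------------------------------
    # convenience accessors

    @property
    def utr5(self) -> str:
        return self.sequence[: self.cds_start]

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def has_genomic_coords(self) -> bool:
        return all(e.genomic_start is not None for e in self.exons)

    def exon_of(self, tx_pos: int) -> int:
        """1-based index of the exon containing transcript position ``tx_pos``."""
        if not 0 <= tx_pos < len(self.sequence):
            raise IndexError(f"{self.id}: transcript position {tx_pos} out of range")
        for exon in self.exons:
            if exon.tx_start <= tx_pos < exon.tx_end:
                return exon.index
        raise AssertionError("exons do not tile the transcript")  # unreachable

    def cds_exon(self) -> int:
        """Index of the exon containing the pORF start codon."""
        return self.exon_of(self.cds_start)


@dataclass(frozen=True)
class UTRRegion:
    """The 5ʹ UTR of a transcript with its per-exon segmentation."""

    transcript_id: str
    sequence: str
    exon_segments: tuple[tuple[int, tuple[int, int]], ...]  # (exon index, (tx_start, tx_end))


def five_prime_utr(transcript: Transcript) -> UTRRegion:
    """Extract the 5ʹ UTR and the exon segments that compose it.

    A ``cds_start`` of 0 yields an empty UTR with no segments.
    """
    segments = []
    for exon in transcript.exons:
        if exon.tx_start >= transcript.cds_start:
            break
        segments.append((exon.index, (exon.tx_start, min(exon.tx_end, transcript.cds_start))))
    return UTRRegion(
        transcript_id=transcript.id,
        sequence=transcript.utr5,
        exon_segments=tuple(segments),
    )


# ----------------------------------------------------------------------
# coordinate mapping


def genome_to_transcript(transcript: Transcript, genomic_pos: int) -> int | str:
    """Map a 0-based genomic coordinate onto the spliced transcript.

    Returns the transcript coordinate, or the sentinel string ``"intronic"``
    for positions between exons.  Positions outside the transcript's genomic
    span raise ``ValueError``.
    """
    if not transcript.has_genomic_coords:
        raise ValueError(f"{transcript.id}: no genomic exon coordinates")
    span_lo = min(e.genomic_start for e in transcript.exons)
    span_hi = max(e.genomic_end for e in transcript.exons)
    if not span_lo <= genomic_pos < span_hi:
        raise ValueError(
            f"{transcript.id}: genomic position {genomic_pos} outside span [{span_lo},{span_hi})"
        )
    for exon in transcript.exons:
        if exon.genomic_start <= genomic_pos < exon.genomic_end:
            if transcript.strand == "-":
                return exon.tx_start + (exon.genomic_end - 1 - genomic_pos)
            return exon.tx_start + (genomic_pos - exon.genomic_start)
    return INTRONIC


def transcript_to_genome(transcript: Transcript, tx_pos: int) -> int:
    """Inverse of :func:`genome_to_transcript` for exonic positions."""
    if not transcript.has_genomic_coords:
        raise ValueError(f"{transcript.id}: no genomic exon coordinates")
    if not 0 <= tx_pos < len(transcript.sequence):
        raise ValueError(f"{transcript.id}: transcript position {tx_pos} out of range")
    for exon in transcript.exons:
        if exon.tx_start <= tx_pos < exon.tx_end:
            offset = tx_pos - exon.tx_start
            if transcript.strand == "-":
                return exon.genomic_end - 1 - offset
            return exon.genomic_start + offset
    raise AssertionError("exons do not tile the transcript")  # unreachable


# ----------------------------------------------------------------------
# construction helpers


def from_spliced(
    transcript_id: str,
    sequence: str,
    exon_lengths: Iterable[int],
    cds_start: int,
    cds_end: int,
) -> Transcript:
    """Build a Transcript directly from a spliced sequence and exon lengths."""
    exons = []
    pos = 0
    for i, length in enumerate(exon_lengths, start=1):
        exons.append(Exon(index=i, tx_start=pos, tx_end=pos + length))
        pos += length
    return Transcript(
        id=transcript_id,
        sequence=sequence,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
    )


def _splice_from_genome(
    transcript_id: str,
    chrom_seq: str,
    chrom: str,
    strand: str,
    exon_intervals: list[tuple[int, int]],  # 0-based half-open genomic, any order
    cds_genomic: tuple[int, int],  # 0-based half-open genomic CDS span
) -> Transcript:
    """Splice genomic exon intervals into a sense-strand Transcript.

    Minus-strand transcripts come out reverse-complemented with exons
    renumbered in transcript (5ʹ→3ʹ) order.
    """
    intervals = sorted(exon_intervals)
    if strand == "-":
        order = list(reversed(intervals))
    else:
        order = intervals
    exons: list[Exon] = []
    parts: list[str] = []
    pos = 0
    for i, (gs, ge) in enumerate(order, start=1):
        segment = chrom_seq[gs:ge]
        if strand == "-":
            segment = reverse_complement(segment)
        parts.append(segment)
        exons.append(Exon(index=i, tx_start=pos, tx_end=pos + (ge - gs), genomic_start=gs, genomic_end=ge))
        pos += ge - gs
    sequence = "".join(parts)

    stub = Transcript.__new__(Transcript)  # temporary object for coordinate mapping
    object.__setattr__(stub, "id", transcript_id)
    object.__setattr__(stub, "sequence", sequence)
    object.__setattr__(stub, "exons", tuple(exons))
    object.__setattr__(stub, "cds_start", 0)
    object.__setattr__(stub, "cds_end", len(sequence))
    object.__setattr__(stub, "strand", strand)
    object.__setattr__(stub, "chrom", chrom)

    g_lo, g_hi = cds_genomic
    if strand == "-":
        tx_a = genome_to_transcript(stub, g_hi - 1)
        tx_b = genome_to_transcript(stub, g_lo)
    else:
        tx_a = genome_to_transcript(stub, g_lo)
        tx_b = genome_to_transcript(stub, g_hi - 1)
    if tx_a == INTRONIC or tx_b == INTRONIC:
        raise TranscriptError(f"{transcript_id}: CDS boundary falls in an intron")
    return Transcript(
        id=transcript_id,
        sequence=sequence,
        exons=tuple(exons),
        cds_start=tx_a,
        cds_end=tx_b + 1,
        strand=strand,
        chrom=chrom,
    )


# ----------------------------------------------------------------------
# loaders


def _read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_transcripts(
    transcript_fasta: str | Path | None = None,
    annotation: str | Path | None = None,
    genome_fasta: str | Path | None = None,
) -> list[Transcript]:
    """Load transcripts from FASTA plus a GFF3 or TSV annotation.

    Two annotation dialects are accepted:

    * **GFF3** — either transcript-space (exon/CDS features whose seqid is
      the transcript FASTA id) or genome-space (features on genome contigs,
      grouped by ``Parent``/``transcript_id``; requires ``genome_fasta``).
    * **TSV** — columns ``transcript_id``, ``exon_lengths`` (comma-separated,
      5ʹ→3ʹ), ``cds_start``, ``cds_end`` (0-based half-open, transcript
      space), paired with the transcript FASTA.

    Missing CDS features, CDS codons not starting with ATG, and exon/sequence
    length mismatches are all load-time errors naming the transcript.
    """
    if annotation is None:
        raise ValueError("an annotation (GFF3 or TSV) is required")
    suffix = Path(annotation).suffix.lower()
    if suffix in {".tsv", ".txt", ".csv"}:
        if transcript_fasta is None:
            raise ValueError("TSV annotation requires a transcript FASTA")
        return _load_from_tsv(transcript_fasta, annotation)
    return _load_from_gff3(transcript_fasta, annotation, genome_fasta)


def _load_from_tsv(transcript_fasta: str | Path, tsv: str | Path) -> list[Transcript]:
    seqs = _read_fasta(transcript_fasta)
    transcripts = []
    with open(tsv, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            tid = row["transcript_id"]
            if tid not in seqs:
                raise TranscriptError(f"{tid}: not present in transcript FASTA")
            lengths = [int(x) for x in row["exon_lengths"].split(",") if x]
            transcripts.append(
                from_spliced(tid, seqs[tid], lengths, int(row["cds_start"]), int(row["cds_end"]))
            )
    return transcripts


def _load_from_gff3(
    transcript_fasta: str | Path | None,
    gff3: str | Path,
    genome_fasta: str | Path | None,
) -> list[Transcript]:
    import gffutils

    db = gffutils.create_db(
        str(gff3),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    tx_seqs = _read_fasta(transcript_fasta) if transcript_fasta else {}

    # Group exon/CDS features by the transcript they belong to.
    exons_by_tx: dict[str, list] = {}
    cds_by_tx: dict[str, list] = {}
    seqid_by_tx: dict[str, str] = {}
    strand_by_tx: dict[str, str] = {}

    def _tx_ids(feature) -> list[str]:
        parents = feature.attributes.get("Parent") or feature.attributes.get("transcript_id")
        if parents:
            return [p.split(":", 1)[-1] for p in parents]
        return [feature.seqid]

    for ftype, store in (("exon", exons_by_tx), ("CDS", cds_by_tx)):
        for feat in db.features_of_type(ftype):
            for tid in _tx_ids(feat):
                store.setdefault(tid, []).append(feat)
                seqid_by_tx[tid] = feat.seqid
                strand_by_tx[tid] = feat.strand

    transcripts = []
    for tid in sorted(exons_by_tx):
        if tid not in cds_by_tx:
            raise TranscriptError(f"{tid}: no CDS feature in annotation")
        exon_feats = exons_by_tx[tid]
        cds_feats = cds_by_tx[tid]
        seqid = seqid_by_tx[tid]
        transcript_space = seqid in tx_seqs and seqid == tid

        # GFF3 is 1-based closed: convert to 0-based half-open.
        exon_iv = [(f.start - 1, f.end) for f in exon_feats]
        cds_lo = min(f.start - 1 for f in cds_feats)
        cds_hi = max(f.end for f in cds_feats)

        if transcript_space:
            sequence = tx_seqs[tid]
            lengths = [e - s for s, e in sorted(exon_iv)]
            transcripts.append(from_spliced(tid, sequence, lengths, cds_lo, cds_hi))
        else:
            if genome_fasta is None:
                raise ValueError(
                    f"{tid}: annotation is genome-space (seqid {seqid!r}) but no genome FASTA given"
                )
            genome = _read_fasta(genome_fasta)
            if seqid not in genome:
                raise TranscriptError(f"{tid}: contig {seqid!r} absent from genome FASTA")
            transcripts.append(
                _splice_from_genome(
                    tid, genome[seqid], seqid, strand_by_tx[tid], exon_iv, (cds_lo, cds_hi)
                )
            )
    return transcripts


def transcript_table(transcripts: Iterable[Transcript]):
    """Normalized per-transcript summary as a pandas DataFrame.

    Columns: id, length, n_exons, cds_start_1based, utr5_length.
    """
    import pandas as pd

    rows = [
        {
            "id": t.id,
            "length": len(t.sequence),
            "n_exons": len(t.exons),
            "cds_start_1based": t.cds_start + 1,
            "utr5_length": t.cds_start,
        }
        for t in transcripts
    ]
    return pd.DataFrame(rows, columns=["id", "length", "n_exons", "cds_start_1based", "utr5_length"])
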