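"""uORF prediction, Kozak-context classification, and skippable-exon calls.

An upstream open reading frame (uORF) is an AUG in the 5ʹ UTR followed by an
in-frame stop codon.  uORFs repress translation of the downstream primary
ORF (pORF): scanning ribosomes initiate at the upstream AUG, translate the
short ORF, and frequently fail to reinitiate at the pORF start.  The
scanner reports three frame classes:

* ``contained`` — the stop codon ends at or before the pORF start;
* ``overlapping`` — the stop codon extends past the pORF start in a
  different reading frame;
* ``n_terminal_extension`` — an upstream AUG in frame with the pORF with no
  intervening stop.  These produce extended proteins rather than uORFs, so
  they are listed separately and never counted in the predicted-uORF set.

Kozak context is classed by the discrete −3/+4 rule: strong when −3 is a
purine AND +4 is G; weak when neither holds; intermediate otherwise.
Positions falling off the 5ʹ end of the sequence fail their condition,
biasing truncated contexts toward weak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .transcripts import START_CODON, STOP_CODONS, Transcript

FrameClass = Literal["contained", "overlapping", "n_terminal_extension"]
KozakClass = Literal["strong", "intermediate", "weak"]

PURINES = frozenset("AG")


@dataclass(frozen=True)
class KozakContext:
    """The −3 and +4 bases around an AUG (A of AUG = +1) and their class."""

    minus3: str | None  # None when the position falls off the sequence
    plus4: str | None
    kozak_class: KozakClass
    truncated: bool = False  # −3 (or +4) fell outside the sequence


@dataclass(frozen=True)
class UORF:
    """One predicted upstream ORF.

    ``start`` is the 0-based transcript coordinate of the A of AUG;
    ``stop_end`` the 0-based half-open end of the stop codon (``None`` for
    N-terminal extensions, which run into the pORF).  ``peptide_codons``
    counts codons strictly between start and stop: 0 for a minimal uORF
    (start codon immediately followed by a stop codon).
    """

    transcript_id: str
    start: int
    stop_end: int | None
    frame_class: FrameClass
    peptide_codons: int
    is_minimal: bool
    kozak_class: KozakClass
    host_exon: int | None


def classify_kozak(sequence: str, atg_pos: int) -> KozakContext:
    """Classify the Kozak context of the ATG at ``atg_pos`` (0-based).

    Raises ``ValueError`` when ``sequence[atg_pos:atg_pos+3]`` is not ATG.
    """
    sequence = sequence.upper()
    if sequence[atg_pos : atg_pos + 3] != START_CODON:
        raise ValueError(f"no ATG at position {atg_pos}")
    minus3 = sequence[atg_pos - 3] if atg_pos >= 3 else None
    plus4_idx = atg_pos + 3
    plus4 = sequence[plus4_idx] if plus4_idx < len(sequence) else None
    purine = minus3 in PURINES
    g4 = plus4 == "G"
    if purine and g4:
        cls: KozakClass = "strong"
    elif purine or g4:
        cls = "intermediate"
    else:
        cls = "weak"
    return KozakContext(
        minus3=minus3,
        plus4=plus4,
        kozak_class=cls,
        truncated=(minus3 is None or plus4 is None),
    )


def _codon(seq: str, pos: int) -> str | None:
    codon = seq[pos : pos + 3]
    return codon if len(codon) == 3 else None


def _first_inframe_stop(seq: str, start: int) -> int | None:
    """0-based start of the first in-frame stop codon after ``start``, or None.

    Codons containing N never count as stops.
    """
    pos = start + 3
    while True:
        codon = _codon(seq, pos)
        if codon is None:
            return None
        if codon in STOP_CODONS:
            return pos
        pos += 3


def find_uorfs(
    transcript: Transcript,
    include_overlapping: bool = True,
) -> list[UORF]:
    """Predict uORFs in the 5ʹ UTR of ``transcript``.

    Every ATG strictly upstream of ``cds_start`` is extended to its first
    in-frame stop codon.  Nested and overlapping uORFs are reported
    individually; results are sorted by start.  In-frame upstream AUGs with
    no intervening stop (N-terminal extensions) are excluded — retrieve them
    with :func:`find_n_terminal_extensions`.
    """
    results = []
    for uorf in _scan(transcript):
        if uorf.frame_class == "n_terminal_extension":
            continue
        if uorf.frame_class == "overlapping" and not include_overlapping:
            continue
        results.append(uorf)
    return results


def find_n_terminal_extensions(transcript: Transcript) -> list[UORF]:
    """Upstream in-frame AUGs with no stop before the pORF start."""
    return [u for u in _scan(transcript) if u.frame_class == "n_terminal_extension"]


def _scan(transcript: Transcript) -> list[UORF]:
    seq = transcript.sequence
    cds_start = transcript.cds_start
    out: list[UORF] = []
    for pos in range(cds_start):
        if _codon(seq, pos) != START_CODON:
            continue
        stop = _first_inframe_stop(seq, pos)
        in_frame_with_porf = (pos % 3) == (cds_start % 3)
        if in_frame_with_porf and (stop is None or stop >= cds_start):
            # no stop between the upstream AUG and the pORF start
            frame_class: FrameClass = "n_terminal_extension"
            stop_end: int | None = None
            peptide = (cds_start - pos - 3) // 3
        elif stop is None:
            continue  # out-of-frame AUG that never hits a stop: not an ORF
        else:
            stop_end = stop + 3
            peptide = (stop - pos - 3) // 3
            frame_class = "contained" if stop_end <= cds_start else "overlapping"
        kozak = classify_kozak(seq, pos)
        out.append(
            UORF(
                transcript_id=transcript.id,
                start=pos,
                stop_end=stop_end,
                frame_class=frame_class,
                peptide_codons=peptide,
                is_minimal=(frame_class != "n_terminal_extension" and peptide == 0),
                kozak_class=kozak.kozak_class,
                host_exon=transcript.exon_of(pos) if transcript.exons else None,
            )
        )
    return out


def count_uorfs_by_exon(
    transcript: Transcript, include_overlapping: bool = True
) -> dict[int, int]:
    """Number of predicted uORFs whose start codon lies in each exon.

    Every exon of the transcript appears as a key (zero where empty); values
    sum to the total predicted-uORF count.
    """
    counts = {exon.index: 0 for exon in transcript.exons}
    for uorf in find_uorfs(transcript, include_overlapping=include_overlapping):
        counts[uorf.host_exon] += 1
    return counts


def find_skippable_exons(
    transcript: Transcript, include_overlapping: bool = True
) -> list[int]:
    """Exons eligible for exclusion by splice modulation.

    A skippable exon is a 5ʹ UTR exon that contains neither the
    transcription start site (exon 1) nor the pORF start codon, lies
    entirely within the 5ʹ UTR, and hosts at least one uORF start codon.
    """
    counts = count_uorfs_by_exon(transcript, include_overlapping=include_overlapping)
    cds_exon = transcript.cds_exon()
    skippable = []
    for exon in transcript.exons:
        if exon.index == 1 or exon.index == cds_exon:
            continue
        if exon.tx_end > transcript.cds_start:
            continue  # not entirely within the 5' UTR
        if counts.get(exon.index, 0) >= 1:
            skippable.append(exon.index)
    return skippable
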