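"""SpCas9 adenine-base-editing guide design against uORF start codons.

An adenine base editor (ABE) converts A·T to G·C within a window of the
protospacer (positions numbered 1 at the PAM-distal end through 20, PAM at
21–23).  A uORF AUG can be ablated two ways:

* a **sense-strand** guide places the A of ATG in the window (ATG→GTG);
* an **antisense-strand** guide places the A complementary to the T of ATG
  in the window (sense ATG→ACG).

Candidates are every NGG-adjacent 20-mer, on either strand, that puts an
editable AUG adenosine inside the design window (default positions 4–8,
the high-efficiency range for ABE8e).  Other adenosines on the protospacer
strand within the reporting range (default 1–10) are bystanders: editing
them does not ablate the uORF but can alter flanking sequence.  The wider
reporting range exists because appreciable bystander editing is observed
outside the canonical window (e.g. at position +2).

Cytosine base editing (C→T) is exposed only as a validation mode: the
sense ATG contains no C, and the lone antisense C (opposite the G) is only
actionable when PAM placement allows — otherwise the check reports that
the site cannot be disrupted by CBE, making such a guide/editor pairing a
negative control.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

from . import scan as _scan
from .transcripts import Transcript, reverse_complement
from .scan import UORF

Strand = Literal["sense", "antisense"]

DEFAULT_WINDOW = (4, 8)
DEFAULT_REPORTING_RANGE = (1, 10)
PROTOSPACER_LEN = 20
PAM_LEN = 3

CBE_IMPOSSIBLE_MESSAGE = "cannot disrupt ATG by C->T on either strand at this site"


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt protospacer + NGG PAM targeting a uORF start-codon adenosine.

    ``target_pos`` and ``bystander_pos`` are 1-based protospacer positions
    (1 = PAM-distal).  ``tx_offset`` is the 0-based transcript coordinate of
    protospacer position 1; for antisense guides the protospacer runs
    3ʹ→5ʹ along the transcript, so position *p* sits at transcript
    coordinate ``tx_offset − (p − 1)``.
    """

    protospacer: str
    pam: str
    strand: Strand
    target_pos: int
    bystander_pos: tuple[int, ...]
    window: tuple[int, int] = DEFAULT_WINDOW
    reporting_range: tuple[int, int] = DEFAULT_REPORTING_RANGE
    tx_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.protospacer[self.target_pos - 1] != "A":
            raise ValueError(f"protospacer position {self.target_pos} is not A")
        for b in self.bystander_pos:
            if self.protospacer[b - 1] != "A":
                raise ValueError(f"bystander position {b} is not A")

    def tx_position(self, protospacer_pos: int) -> int:
        """Transcript coordinate (0-based) of a 1-based protospacer position."""
        if self.strand == "sense":
            return self.tx_offset + (protospacer_pos - 1)
        return self.tx_offset - (protospacer_pos - 1)

    @property
    def gc_fraction(self) -> float:
        return sum(1 for b in self.protospacer if b in "GC") / PROTOSPACER_LEN


@dataclass(frozen=True)
class PredictedAllele:
    """One possible editing outcome: A→G at a subset of editable positions.

    ``productive`` means the target adenosine was edited (uORF ablated);
    ``non_productive`` means only bystanders were edited; the empty subset
    is ``unedited``.  Flags record side effects found by re-scanning the
    edited UTR.
    """

    edited_positions: frozenset[int]
    local_sequence: str  # protospacer-strand 20-mer after edits
    category: Literal["productive", "non_productive", "unedited"]
    flags: frozenset[str]


def enumerate_protospacers(
    sequence: str,
) -> list[tuple[int, Strand, str, str]]:
    """All NGG-adjacent 20-mers on both strands of ``sequence``.

    Returns ``(offset, strand, protospacer, pam)`` tuples where ``offset``
    is the 0-based start of the sense-strand interval the protospacer
    covers.  Antisense hits report the reverse-complement protospacer.
    """
    sequence = sequence.upper()
    hits: list[tuple[int, Strand, str, str]] = []
    n = len(sequence)
    for o in range(n - PROTOSPACER_LEN - PAM_LEN + 1):
        pam = sequence[o + PROTOSPACER_LEN : o + PROTOSPACER_LEN + PAM_LEN]
        if pam[1:] == "GG":
            hits.append((o, "sense", sequence[o : o + PROTOSPACER_LEN], pam))
    for o in range(PAM_LEN, n - PROTOSPACER_LEN + 1):
        sense_pam_region = sequence[o - PAM_LEN : o]
        if sense_pam_region[:2] == "CC":  # CCN on sense = NGG on antisense
            hits.append(
                (
                    o,
                    "antisense",
                    reverse_complement(sequence[o : o + PROTOSPACER_LEN]),
                    reverse_complement(sense_pam_region),
                )
            )
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _adenosines_in_range(protospacer: str, rng: tuple[int, int]) -> list[int]:
    lo, hi = rng
    return [p for p in range(lo, hi + 1) if p <= PROTOSPACER_LEN and protospacer[p - 1] == "A"]


def design_abe_guides(
    transcript: Transcript,
    uorf: UORF,
    window: tuple[int, int] = DEFAULT_WINDOW,
    reporting_range: tuple[int, int] = DEFAULT_REPORTING_RANGE,
) -> list[GuideCandidate]:
    """Every guide placing an ABE-editable adenosine of the uORF ATG in the window.

    Sense-strand candidates edit the A of ATG (ATG→GTG); antisense
    candidates edit the A opposite the T (ATG→ACG).  Candidates are ranked
    by (1) |target_pos − 6| ascending, (2) bystander count inside the
    window ascending, (3) GC fraction nearest 0.5.  An empty list — not an
    error — is returned when no PAM supports the site.
    """
    if uorf.transcript_id != transcript.id:
        raise ValueError("uORF does not belong to this transcript")
    seq = transcript.sequence
    s = uorf.start  # A of ATG
    candidates: list[GuideCandidate] = []
    lo, hi = window

    for p in range(lo, hi + 1):
        # sense: protospacer position p covers transcript coordinate o + p - 1
        o = s - (p - 1)
        if o >= 0 and o + PROTOSPACER_LEN + PAM_LEN <= len(seq):
            pam = seq[o + PROTOSPACER_LEN : o + PROTOSPACER_LEN + PAM_LEN]
            if pam[1:] == "GG":
                proto = seq[o : o + PROTOSPACER_LEN]
                bystanders = tuple(b for b in _adenosines_in_range(proto, reporting_range) if b != p)
                candidates.append(
                    GuideCandidate(
                        protospacer=proto,
                        pam=pam,
                        strand="sense",
                        target_pos=p,
                        bystander_pos=bystanders,
                        window=window,
                        reporting_range=reporting_range,
                        tx_offset=o,
                    )
                )
        # antisense: protospacer position p covers transcript coordinate o + 20 - p;
        # the editable antisense A is opposite the sense T at s + 1
        o = (s + 1) + p - PROTOSPACER_LEN
        if o >= PAM_LEN and o + PROTOSPACER_LEN <= len(seq):
            sense_pam_region = seq[o - PAM_LEN : o]
            if sense_pam_region[:2] == "CC":
                proto = reverse_complement(seq[o : o + PROTOSPACER_LEN])
                bystanders = tuple(b for b in _adenosines_in_range(proto, reporting_range) if b != p)
                candidates.append(
                    GuideCandidate(
                        protospacer=proto,
                        pam=reverse_complement(sense_pam_region),
                        strand="antisense",
                        target_pos=p,
                        bystander_pos=bystanders,
                        window=window,
                        reporting_range=reporting_range,
                        tx_offset=o + PROTOSPACER_LEN - 1,
                    )
                )

    def _in_window(c: GuideCandidate, b: int) -> bool:
        return window[0] <= b <= window[1]

    candidates.sort(
        key=lambda c: (
            abs(c.target_pos - 6),
            sum(1 for b in c.bystander_pos if _in_window(c, b)),
            abs(c.gc_fraction - 0.5),
            c.tx_offset,
        )
    )
    return candidates


def apply_edits_to_transcript(
    guide: GuideCandidate, transcript: Transcript, edited_positions: frozenset[int]
) -> str:
    """Transcript sequence after A→G edits at protospacer-strand positions.

    Antisense-strand A→G appears on the sense transcript as T→C.
    """
    seq = list(transcript.sequence)
    for p in edited_positions:
        t = guide.tx_position(p)
        if guide.strand == "sense":
            if seq[t] != "A":
                raise ValueError(f"transcript position {t} is not A")
            seq[t] = "G"
        else:
            if seq[t] != "T":
                raise ValueError(f"transcript position {t} is not T")
            seq[t] = "C"
    return "".join(seq)


def predict_alleles(guide: GuideCandidate, transcript: Transcript) -> list[PredictedAllele]:
    """Enumerate all 2^(1+k) editing outcomes for a guide with k bystanders.

    Each subset of {target} ∪ bystanders yields one allele; exactly half
    are productive (target edited) and exactly one is unedited.  Flags are
    set by re-scanning the edited transcript: ``new_atg_created`` when an
    ATG appears in the 5ʹ UTR at a position without one before the edit,
    ``porf_kozak_altered`` when the −3/+4 context of the pORF start changed.
    """
    editable = [guide.target_pos, *guide.bystander_pos]
    parent_utr_atgs = _utr_atg_positions(transcript.sequence, transcript.cds_start)
    parent_kozak = _scan.classify_kozak(transcript.sequence, transcript.cds_start)

    alleles: list[PredictedAllele] = []
    for r in range(len(editable) + 1):
        for subset in combinations(editable, r):
            edited = frozenset(subset)
            edited_seq = apply_edits_to_transcript(guide, transcript, edited)
            local = list(guide.protospacer)
            for p in edited:
                local[p - 1] = "G"
            if not edited:
                category = "unedited"
            elif guide.target_pos in edited:
                category = "productive"
            else:
                category = "non_productive"
            flags = set()
            if _utr_atg_positions(edited_seq, transcript.cds_start) - parent_utr_atgs:
                flags.add("new_atg_created")
            new_kozak = _scan.classify_kozak(edited_seq, transcript.cds_start)
            if (new_kozak.minus3, new_kozak.plus4) != (parent_kozak.minus3, parent_kozak.plus4):
                flags.add("porf_kozak_altered")
            alleles.append(
                PredictedAllele(
                    edited_positions=edited,
                    local_sequence="".join(local),
                    category=category,
                    flags=frozenset(flags),
                )
            )
    return alleles


def _utr_atg_positions(sequence: str, cds_start: int) -> frozenset[int]:
    return frozenset(i for i in range(cds_start) if sequence[i : i + 3] == "ATG")


def design_cbe_guides(
    transcript: Transcript,
    uorf: UORF,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> tuple[list[dict], str | None]:
    """CBE (C→T) validation mode: can this uORF ATG be disrupted at all?

    The sense ATG contains no cytosine, so only the antisense C opposite
    the G (sense ATG→ATA) is ever actionable, and only when an NGG PAM
    places it in the window.  Returns ``(candidates, message)``; when no
    candidate exists the message states that C→T cannot disrupt the site.
    """
    seq = transcript.sequence
    s = uorf.start
    candidates = []
    lo, hi = window
    for p in range(lo, hi + 1):
        # antisense C opposite the sense G at s + 2
        o = (s + 2) + p - PROTOSPACER_LEN
        if o >= PAM_LEN and o + PROTOSPACER_LEN <= len(seq):
            if seq[o - PAM_LEN : o - 1] == "CC":
                proto = reverse_complement(seq[o : o + PROTOSPACER_LEN])
                # reuse GuideCandidate but target base is C here, so bypass its A checks
                candidates.append(
                    {
                        "protospacer": proto,
                        "pam": reverse_complement(seq[o - PAM_LEN : o]),
                        "strand": "antisense",
                        "target_pos": p,
                        "tx_offset": o + PROTOSPACER_LEN - 1,
                    }
                )
    if not candidates:
        return [], CBE_IMPOSSIBLE_MESSAGE
    return candidates, None
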