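"""Reporter 5ʹ UTR variant generation and hairpin summarization.

Implements the construct series used to dissect uORF- and structure-mediated
translational repression in reporter assays:

* start-codon disruption (ATG→TTG, ablating uORF initiation without
  changing UTR length),
* deletion of skippable 5ʹ UTR exons (simulating an exon-skipping outcome),
* sequential deletion walks (tiling windows removed one at a time to map a
  repressive region),
* segment insertion at cap-proximal / medial / cap-distal positions
  (testing position dependence of a structured element),
* summarization of stem-loop elements from externally computed dot-bracket
  structures.  Folding itself is never computed here: the dot-bracket
  string is the output of any folding tool (e.g. RNAfold).

Each variant is a :class:`Construct` carrying a provenance trail; replaying
the trail on the parent sequence reproduces the variant byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import scan
from .transcripts import Transcript, from_spliced

DISRUPTED_START = "TTG"


@dataclass(frozen=True)
class EditRecord:
    """One applied edit: operation name, 1-based closed interval, replacement."""

    operation: str
    start_1based: int
    end_1based: int
    replacement: str  # "" for deletions


@dataclass(frozen=True)
class Construct:
    """A derived 5ʹ UTR variant with its edit provenance.

    ``warnings`` carries non-fatal design notes (e.g. a substitution that
    created a new upstream ATG).
    """

    name: str
    sequence: str
    parent: str
    provenance: tuple[EditRecord, ...]
    warnings: tuple[str, ...] = ()


def replay(parent: str, provenance: tuple[EditRecord, ...]) -> str:
    """Apply a provenance trail to ``parent`` and return the result."""
    seq = parent
    for rec in provenance:
        lo, hi = rec.start_1based - 1, rec.end_1based
        seq = seq[:lo] + rec.replacement + seq[hi:]
    return seq


def _verify(construct: Construct) -> Construct:
    assert replay(construct.parent, construct.provenance) == construct.sequence
    return construct


# ----------------------------------------------------------------------
# variant operations


def disrupt_uorf_start(
    utr: str, uorf_start: int, name: str | None = None
) -> Construct:
    """Convert the ATG at ``uorf_start`` (0-based) to TTG.

    The uORF can no longer initiate; UTR length is unchanged.  TTG itself
    cannot form part of a new ATG through its own bases, but the A→T
    substitution at the first position can complete an ATG with the two
    preceding bases; such cases succeed with a warning.
    """
    utr = utr.upper()
    if utr[uorf_start : uorf_start + 3] != "ATG":
        raise ValueError(f"no ATG at position {uorf_start}")
    edited = utr[:uorf_start] + DISRUPTED_START + utr[uorf_start + 3 :]
    warnings = []
    before = {i for i in range(len(utr)) if utr[i : i + 3] == "ATG"}
    after = {i for i in range(len(edited)) if edited[i : i + 3] == "ATG"}
    new_atgs = sorted(after - before)
    if new_atgs:
        warnings.append(
            f"substitution created new ATG at 0-based position(s) {new_atgs}"
        )
    return _verify(
        Construct(
            name=name or f"dATG_{uorf_start + 1}",
            sequence=edited,
            parent=utr,
            provenance=(
                EditRecord("disrupt_uorf_start", uorf_start + 1, uorf_start + 3, DISRUPTED_START),
            ),
            warnings=tuple(warnings),
        )
    )


@dataclass(frozen=True)
class ExonDeletionResult:
    """An exon-deletion construct plus the uORF diff it caused.

    Junction effects are real: removing an exon can destroy a
    junction-spanning ATG or create a new one, so counts are re-scanned
    rather than assumed to subtract.
    """

    construct: Construct
    transcript: Transcript
    uorfs_lost: tuple[int, ...]  # parent-transcript 0-based start positions removed
    uorfs_gained: tuple[int, ...]  # new-transcript 0-based start positions gained


def delete_exons(
    transcript: Transcript,
    exon_indices: set[int] | frozenset[int],
    force: bool = False,
    name: str | None = None,
) -> ExonDeletionResult:
    """Delete whole exons from a transcript, returning the variant and a uORF diff.

    Without ``force``, only skippable-eligible UTR exons may be deleted:
    not exon 1, not the exon containing the pORF start, and entirely within
    the 5ʹ UTR.
    """
    exon_indices = set(exon_indices)
    valid = {e.index for e in transcript.exons}
    if not exon_indices <= valid:
        raise ValueError(f"unknown exon indices {sorted(exon_indices - valid)}")
    cds_exon = transcript.cds_exon()
    if not force:
        for idx in sorted(exon_indices):
            exon = transcript.exons[idx - 1]
            if idx == 1:
                raise ValueError("refusing to delete exon 1 (contains the TSS); use force")
            if idx == cds_exon:
                raise ValueError(
                    f"refusing to delete exon {idx} (contains the pORF start codon); use force"
                )
            if exon.tx_end > transcript.cds_start:
                raise ValueError(f"exon {idx} is not entirely within the 5' UTR; use force")

    kept = [e for e in transcript.exons if e.index not in exon_indices]
    new_seq = "".join(transcript.sequence[e.tx_start : e.tx_end] for e in kept)
    deleted_before_cds = sum(
        e.length for e in transcript.exons if e.index in exon_indices and e.tx_start < transcript.cds_start
    )
    new_tx = from_spliced(
        transcript.id + "_d" + "".join(str(i) for i in sorted(exon_indices)),
        new_seq,
        [e.length for e in kept],
        transcript.cds_start - deleted_before_cds,
        transcript.cds_end - deleted_before_cds,
    )

    # provenance: deletions applied 3'→5' so earlier intervals stay valid
    records = tuple(
        EditRecord("delete_exon", e.tx_start + 1, e.tx_end, "")
        for e in sorted(transcript.exons, key=lambda e: -e.tx_start)
        if e.index in exon_indices
    )
    construct = _verify(
        Construct(
            name=name or "dExon" + "+".join(str(i) for i in sorted(exon_indices)),
            sequence=new_seq,
            parent=transcript.sequence,
            provenance=records,
        )
    )

    parent_uorfs = {u.start for u in scan.find_uorfs(transcript)}
    child_uorfs = {u.start for u in scan.find_uorfs(new_tx)}

    # map parent uORF starts into the child coordinate frame where they survive
    def child_pos(parent_pos: int) -> int | None:
        shift = 0
        for e in transcript.exons:
            if e.index in exon_indices:
                if e.tx_start <= parent_pos < e.tx_end:
                    return None
                if e.tx_end <= parent_pos:
                    shift += e.length
        return parent_pos - shift

    surviving = {child_pos(p) for p in parent_uorfs} - {None}
    lost = tuple(sorted(p for p in parent_uorfs if child_pos(p) is None or child_pos(p) not in child_uorfs))
    gained = tuple(sorted(child_uorfs - surviving))
    return ExonDeletionResult(construct=construct, transcript=new_tx, uorfs_lost=lost, uorfs_gained=gained)


def deletion_walk(
    region: str,
    window_nt: int,
    span: tuple[int, int] | None = None,
    name_prefix: str = "del",
) -> list[Construct]:
    """Sequentially delete tiling windows across a region.

    Windows tile ``span`` (0-based half-open; whole region by default) from
    its 5ʹ end; the final window is the remainder and may be shorter.
    Construct *i* lacks exactly window *i*.
    """
    if window_nt < 1:
        raise ValueError("window_nt must be >= 1")
    lo, hi = span if span is not None else (0, len(region))
    if hi <= lo:
        raise ValueError("empty span")
    constructs = []
    for i, wstart in enumerate(range(lo, hi, window_nt), start=1):
        wend = min(wstart + window_nt, hi)
        edited = region[:wstart] + region[wend:]
        constructs.append(
            _verify(
                Construct(
                    name=f"{name_prefix}_{wstart + 1}-{wend}",
                    sequence=edited,
                    parent=region,
                    provenance=(EditRecord("delete_window", wstart + 1, wend, ""),),
                )
            )
        )
    return constructs


def insert_segment(
    utr: str,
    segment: str,
    position_mode: str | int = "medial",
    name: str | None = None,
) -> Construct:
    """Insert ``segment`` into a 5ʹ UTR at a named or explicit position.

    ``cap_proximal`` inserts at offset 0 (just after the 5ʹ cap), ``medial``
    at ``floor(len(utr)/2)``, ``cap_distal`` at the UTR end (immediately 5ʹ
    of the pORF ATG).  An integer is an explicit 0-based offset.
    """
    if not segment:
        raise ValueError("segment must be non-empty")
    if isinstance(position_mode, int):
        offset = position_mode
        if not 0 <= offset <= len(utr):
            raise ValueError(f"offset {offset} out of range for UTR of length {len(utr)}")
        mode = str(offset)
    elif position_mode == "cap_proximal":
        offset, mode = 0, position_mode
    elif position_mode == "medial":
        offset, mode = len(utr) // 2, position_mode
    elif position_mode == "cap_distal":
        offset, mode = len(utr), position_mode
    else:
        raise ValueError(f"unknown position mode {position_mode!r}")
    edited = utr[:offset] + segment + utr[offset:]
    return _verify(
        Construct(
            name=name or f"ins_{mode}",
            sequence=edited,
            parent=utr,
            provenance=(EditRecord("insert_segment", offset + 1, offset, segment),),
        )
    )


# ----------------------------------------------------------------------
# hairpin summarization from external dot-bracket


@dataclass(frozen=True)
class HairpinStats:
    """Geometry of one stem-loop element of a secondary structure.

    ``span_nt`` is the width enclosed by the outermost pair including both
    paired bases; ``stem_bp`` the number of base pairs on the path from the
    terminal loop to the nearest branch point; ``loop_nt`` the unpaired
    bases in the terminal loop.  Bulges account for
    ``span_nt >= 2*stem_bp + loop_nt`` slack.  Free energy, when supplied,
    is copied from the external folding output (kcal/mol).
    """

    outer_start_1based: int
    outer_end_1based: int
    span_nt: int
    stem_bp: int
    loop_nt: int
    free_energy_kcal_mol: float | None = None


def pair_table(dotbracket: str) -> list[int | None]:
    """Partner index for each position (None = unpaired); raises on imbalance."""
    partners: list[int | None] = [None] * len(dotbracket)
    stack: list[int] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket: unmatched ')' at {i}")
            j = stack.pop()
            partners[j] = i
            partners[i] = j
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r} at {i}")
    if stack:
        raise ValueError(f"unbalanced dot-bracket: unmatched '(' at {stack[-1]}")
    return partners


def summarize_hairpins(
    dotbracket: str,
    sequence: str | None = None,
    free_energy_kcal_mol: float | None = None,
) -> list[HairpinStats]:
    """Summarize stem-loop elements of a dot-bracket structure.

    Multiloops are flattened: each terminal (hairpin) loop yields one
    element whose stem counts all pairs on the path from that loop outward
    to the nearest branch point — a loop enclosing more than one helix — or
    to the exterior.  The single-hairpin case is unaffected by flattening.
    """
    if sequence is not None and len(sequence) != len(dotbracket):
        raise ValueError("sequence and dot-bracket lengths differ")
    partners = pair_table(dotbracket)
    n = len(dotbracket)

    def children_of(i: int, j: int) -> list[tuple[int, int]]:
        """Immediate child pairs strictly inside pair (i, j)."""
        kids = []
        k = i + 1
        while k < j:
            if partners[k] is not None and partners[k] > k:
                kids.append((k, partners[k]))
                k = partners[k] + 1
            else:
                k += 1
        return kids

    # terminal loops: innermost pairs enclosing no further pairs
    raw: list[tuple[int, int, int, int]] = []  # (lo, hi, stem_bp, loop_nt)
    for i in range(n):
        j = partners[i]
        if j is None or j < i or children_of(i, j):
            continue
        loop_nt = j - i - 1
        # walk outward while each enclosing pair holds exactly this one branch
        stem_bp = 1
        lo, hi = i, j
        while True:
            enclosing = _enclosing_pair(partners, lo, hi)
            if enclosing is None:
                break
            ei, ej = enclosing
            if len(children_of(ei, ej)) != 1:
                break  # branch point (multiloop): element ends here
            stem_bp += 1
            lo, hi = ei, ej
        raw.append((lo, hi, stem_bp, loop_nt))

    # the supplied free energy describes the whole fold: attach only when
    # the structure reduces to a single stem-loop element
    fe = free_energy_kcal_mol if len(raw) == 1 else None
    return [
        HairpinStats(
            outer_start_1based=lo + 1,
            outer_end_1based=hi + 1,
            span_nt=hi - lo + 1,
            stem_bp=stem_bp,
            loop_nt=loop_nt,
            free_energy_kcal_mol=fe,
        )
        for lo, hi, stem_bp, loop_nt in raw
    ]


def _enclosing_pair(partners: list[int | None], lo: int, hi: int) -> tuple[int, int] | None:
    """Nearest pair strictly enclosing [lo, hi], or None at the exterior."""
    i = lo - 1
    while i >= 0:
        j = partners[i]
        if j is None:
            i -= 1
        elif j > hi:
            return (i, j)
        else:  # closing bracket of a sibling helix entirely to the left: skip it
            i = j - 1
    return None
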