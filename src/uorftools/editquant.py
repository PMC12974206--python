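"""Editing-outcome classification from amplicon reads and Sanger proportions.

Amplicon reads are classified by exact string matching against the full set
of expected edited alleles (every A→G combination over the editable
positions), in either orientation.  A read matching an allele whose edited
set contains the target position is **productive** (the uORF ATG was
edited); a non-empty set without the target is **non-productive** (bystander
editing only); the reference itself is **unedited**; anything else —
atypical length or additional mismatches outside the editable positions —
is **other**.  No mismatches are tolerated outside the editable positions
by default.

Sanger quantification re-implements proportion arithmetic over per-position
base-call tables (trace peak areas normalized per position): the A→G edit
percentage at a position is 100·G/(A+G).  The table is oriented to the
protospacer strand before quantification; positions where A+G carries less
than half the signal are flagged low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Mapping

from .transcripts import reverse_complement

Category = Literal["productive", "non_productive", "unedited", "other"]
CATEGORIES: tuple[Category, ...] = ("productive", "non_productive", "unedited", "other")


@dataclass(frozen=True)
class ReadCall:
    """Classification of one amplicon read."""

    read_id: str
    category: Category
    matched_allele: frozenset[int] | None  # edited-position set; None for "other"


@dataclass(frozen=True)
class AmpliconSummary:
    """Pooled category counts and fractions over a read set."""

    n_reads: int
    counts: dict[Category, int]
    fractions: dict[Category, float]
    allele_counts: dict[frozenset[int], int]

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) == self.n_reads
        assert abs(sum(self.fractions.values()) - 1.0) < 1e-9


def enumerate_expected_amplicons(
    reference_amplicon: str,
    editable_positions: Iterable[int],
) -> dict[frozenset[int], str]:
    """All 2^k expected amplicons: A→G at every subset of editable positions.

    Positions are 0-based on the reference amplicon and must hold A
    (adenine-base-editing mode).
    """
    reference_amplicon = reference_amplicon.upper()
    positions = sorted(set(editable_positions))
    for p in positions:
        if not 0 <= p < len(reference_amplicon):
            raise ValueError(f"editable position {p} outside amplicon")
        if reference_amplicon[p] != "A":
            raise ValueError(f"editable position {p} is not A in ABE mode")
    alleles: dict[frozenset[int], str] = {}
    for r in range(len(positions) + 1):
        for subset in combinations(positions, r):
            seq = list(reference_amplicon)
            for p in subset:
                seq[p] = "G"
            alleles[frozenset(subset)] = "".join(seq)
    return alleles


def classify_read(
    read: str,
    allele_map: Mapping[frozenset[int], str],
    target_position: int,
    read_id: str = "",
) -> ReadCall:
    """Match one read against the enumerated alleles (either orientation).

    Exact match only: a read of atypical length or with any mismatch
    outside the editable positions is ``other``.
    """
    read = read.upper()
    rc = reverse_complement(read)
    for edited, allele in allele_map.items():
        if read == allele or rc == allele:
            if target_position in edited:
                category: Category = "productive"
            elif edited:
                category = "non_productive"
            else:
                category = "unedited"
            return ReadCall(read_id=read_id, category=category, matched_allele=edited)
    return ReadCall(read_id=read_id, category="other", matched_allele=None)


def classify_reads(
    reads: Iterable[tuple[str, str]],
    allele_map: Mapping[frozenset[int], str],
    target_position: int,
) -> list[ReadCall]:
    """Classify ``(read_id, sequence)`` pairs; see :func:`classify_read`."""
    return [classify_read(seq, allele_map, target_position, read_id=rid) for rid, seq in reads]


def summarize(calls: list[ReadCall]) -> AmpliconSummary:
    """Pool per-read calls into category counts and fractions."""
    if not calls:
        raise ValueError("no reads to summarize")
    counts: dict[Category, int] = {c: 0 for c in CATEGORIES}
    allele_counts: dict[frozenset[int], int] = {}
    for call in calls:
        counts[call.category] += 1
        if call.matched_allele is not None:
            allele_counts[call.matched_allele] = allele_counts.get(call.matched_allele, 0) + 1
    n = len(calls)
    fractions = {c: counts[c] / n for c in CATEGORIES}
    return AmpliconSummary(n_reads=n, counts=counts, fractions=fractions, allele_counts=allele_counts)


# ----------------------------------------------------------------------
# Sanger base-proportion quantification


@dataclass(frozen=True)
class BaseProportionTable:
    """Per-position A/C/G/T base-call proportions from Sanger trace peaks.

    Keys are 1-based positions; each row must sum to 1 (tolerance 1e-6).
    """

    rows: dict[int, dict[str, float]]

    def __post_init__(self) -> None:
        for pos, row in self.rows.items():
            if set(row) != set("ACGT"):
                raise ValueError(f"position {pos}: row must have A/C/G/T proportions")
            total = sum(row.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"position {pos}: proportions sum to {total}, not 1")


@dataclass(frozen=True)
class SangerEditCall:
    """A→G edit percentage at one position."""

    position: int  # 1-based
    edit_percent: float  # 100 * G / (A + G)
    low_confidence: bool  # A + G < 0.5 of the signal


def quantify_sanger(
    table: BaseProportionTable,
    positions: Iterable[int],
    mode: str = "ABE",
) -> list[SangerEditCall]:
    """A→G editing percentages at the requested positions.

    ``edit% = 100·G/(A+G)``; positions where A+G account for less than half
    the base-call signal are flagged low-confidence (the site is dominated
    by bases that neither the reference nor the edit explains).
    """
    if mode != "ABE":
        raise ValueError(f"unsupported mode {mode!r}; only ABE (A->G) is implemented")
    calls = []
    for pos in positions:
        if pos not in table.rows:
            raise KeyError(f"position {pos} absent from table")
        row = table.rows[pos]
        a, g = row["A"], row["G"]
        denom = a + g
        percent = 100.0 * g / denom if denom > 0 else 0.0
        calls.append(SangerEditCall(position=pos, edit_percent=percent, low_confidence=denom < 0.5))
    return calls


def read_base_proportion_csv(path) -> BaseProportionTable:
    """Load a ``position,A,C,G,T`` CSV into a :class:`BaseProportionTable`."""
    import pandas as pd

    df = pd.read_csv(path)
    expected = {"position", "A", "C", "G", "T"}
    if not expected <= set(df.columns):
        raise ValueError(f"CSV must have columns {sorted(expected)}")
    rows = {
        int(rec["position"]): {b: float(rec[b]) for b in "ACGT"} for rec in df.to_dict("records")
    }
    return BaseProportionTable(rows=rows)
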