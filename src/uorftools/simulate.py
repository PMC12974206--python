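"""Seeded synthetic fixtures: transcripts with planted uORFs, amplicon read
pools with planted allele fractions, and Sanger base-proportion tables.

Every generator is a pure function of its arguments and seed, so fixtures
are byte-identical across runs and platforms.  The transcript generator
plants uORFs of a requested frame class / Kozak class / minimality into a
random background, then repairs any accidental ATG or in-frame stop that
the background introduced, and finally re-verifies the planted truth by
re-scanning — the generator refuses to return a transcript whose scan does
not recover exactly the planted uORFs.

These fixtures emulate the *structure* of real 5ʹ UTRs (multi-exon
segmentation, uORF classes, editable sites) but not their base composition,
splice-site motifs, or sequencing quality profiles; recovery tests on them
demonstrate algorithmic correctness, not performance on real traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import scan as _scan
from .editquant import BaseProportionTable
from .transcripts import START_CODON, STOP_CODONS, Transcript, from_spliced

BASES = np.array(list("ACGT"))

#: the on-target protospacer printed for the worked example, with the A of
#: the uORF ATG at protospacer position 5 and bystander adenosines at 2 and 10
EXAMPLE_PROTOSPACER = "CACGATGTGACTCCGCCGCC"
EXAMPLE_NONTARGETING = "GAACAGCTCTGAACGAGACCC"


class InfeasibleSpecError(ValueError):
    """The requested fixture cannot exist (e.g. a strong-Kozak minimal uORF)."""


@dataclass(frozen=True)
class PlantedUORF:
    """Request for one planted uORF."""

    exon_index: int
    kozak_class: str  # strong | intermediate | weak
    is_minimal: bool
    frame_class: str = "contained"  # contained | overlapping | n_terminal_extension
    peptide_codons: int = 2  # ignored when is_minimal


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic multi-exon transcript fixture."""

    seed: int
    exon_lengths: tuple[int, ...]
    cds_start: int
    planted_uorfs: tuple[PlantedUORF, ...] = ()


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for a generated transcript."""

    starts: tuple[int, ...]  # 0-based, sorted, parallel to classes below
    frame_classes: tuple[str, ...]
    kozak_classes: tuple[str, ...]
    is_minimal: tuple[bool, ...]
    host_exons: tuple[int, ...]


# ----------------------------------------------------------------------
# transcript generator


def _kozak_bases(kozak_class: str, minimal: bool, rng: np.random.Generator) -> tuple[str, str | None]:
    """(−3 base, +4 base or None when +4 is fixed by a stop codon)."""
    if minimal:
        # +4 is the T of the stop codon, so strong (requires +4 G) is impossible
        if kozak_class == "strong":
            raise InfeasibleSpecError("a minimal uORF cannot have strong Kozak context (+4 is the stop codon's T)")
        if kozak_class == "intermediate":
            return rng.choice(["A", "G"]), None
        return rng.choice(["C", "T"]), None
    if kozak_class == "strong":
        return rng.choice(["A", "G"]), "G"
    if kozak_class == "intermediate":
        # exactly one condition: purine at -3 XOR G at +4
        if rng.random() < 0.5:
            return rng.choice(["A", "G"]), rng.choice(["A", "C", "T"])
        return rng.choice(["C", "T"]), "G"
    return rng.choice(["C", "T"]), rng.choice(["A", "C", "T"])


_SAFE_CODONS = ("CTC", "CCT", "GCT", "TCC")  # no ATG/stop internally or at junctions with each other


def make_transcript(spec: FixtureSpec, max_attempts: int = 50) -> tuple[Transcript, PlantedTruth]:
    """Generate a transcript whose scan recovers exactly the planted uORFs.

    Raises :class:`InfeasibleSpecError` when the spec cannot be satisfied
    (infeasible Kozak/minimality combination, an exon too short for its
    planted uORF, or repair repeatedly failing to converge).
    """
    total = sum(spec.exon_lengths)
    if not 0 <= spec.cds_start <= total - 6:
        raise InfeasibleSpecError("cds_start leaves no room for a CDS")
    cds_end = spec.cds_start + 3 * ((total - spec.cds_start) // 3)

    rng = np.random.default_rng(spec.seed)
    for _ in range(max_attempts):
        result = _try_generate(spec, cds_end, rng)
        if result is not None:
            return result
    raise InfeasibleSpecError(f"could not satisfy fixture spec after {max_attempts} attempts")


def _exon_bounds(exon_lengths: Sequence[int]) -> list[tuple[int, int]]:
    bounds, pos = [], 0
    for length in exon_lengths:
        bounds.append((pos, pos + length))
        pos += length
    return bounds


def _try_generate(spec: FixtureSpec, cds_end: int, rng: np.random.Generator):
    total = sum(spec.exon_lengths)
    seq = list(rng.choice(BASES, size=total))
    protected: set[int] = set()

    def plant(pos: int, text: str) -> None:
        for i, ch in enumerate(text):
            seq[pos + i] = ch
            protected.add(pos + i)

    plant(spec.cds_start, START_CODON)

    bounds = _exon_bounds(spec.exon_lengths)
    planted_records: list[tuple[int, PlantedUORF]] = []
    occupied: list[tuple[int, int]] = [(spec.cds_start - 3, spec.cds_start + 4)]

    for req in spec.planted_uorfs:
        if not 1 <= req.exon_index <= len(bounds):
            raise InfeasibleSpecError(f"exon {req.exon_index} does not exist")
        elo, ehi = bounds[req.exon_index - 1]
        ehi = min(ehi, spec.cds_start)
        minus3, plus4 = _kozak_bases(req.kozak_class, req.is_minimal, rng)

        if req.frame_class == "contained":
            body_len = 6 if req.is_minimal else 6 + 3 * req.peptide_codons
        else:
            body_len = 3  # only the ATG is placed in the exon; the stop lives downstream
        halo_lo, halo_hi = 3, body_len + 1  # room for −3 and +4

        lo = max(elo, halo_lo)
        hi = min(ehi, spec.cds_start) - body_len
        if req.frame_class in ("overlapping", "n_terminal_extension"):
            hi = min(hi, spec.cds_start - 3)  # keep the ATG clear of the pORF codon
        if hi < lo:
            raise InfeasibleSpecError(f"exon {req.exon_index} too short for the planted uORF")

        start = None
        for _ in range(200):
            cand = int(rng.integers(lo, hi + 1))
            if req.frame_class == "overlapping" and cand % 3 == spec.cds_start % 3:
                continue
            if req.frame_class == "n_terminal_extension" and cand % 3 != spec.cds_start % 3:
                continue
            window = (cand - halo_lo, cand + halo_hi)
            if all(window[1] <= o_lo or window[0] >= o_hi for o_lo, o_hi in occupied):
                start = cand
                break
        if start is None:
            return None  # crowded layout: retry with a fresh background

        occupied.append((start - halo_lo, start + halo_hi))
        plant(start - 3, minus3)
        if req.frame_class == "contained":
            body = START_CODON
            if req.is_minimal:
                body += str(rng.choice(["TAA", "TGA", "TAG"]))
            else:
                first = plus4 + _SAFE_CODONS[0][1:] if plus4 else _SAFE_CODONS[0]
                codons = [first] + [
                    str(rng.choice(_SAFE_CODONS)) for _ in range(req.peptide_codons - 1)
                ]
                body += "".join(codons) + str(rng.choice(["TAA", "TGA", "TAG"]))
            plant(start, body)
        else:
            plant(start, START_CODON)
            if plus4 is not None:
                plant(start + 3, plus4)
            if req.frame_class == "overlapping":
                # first in-frame stop must land beyond the pORF start codon
                p = spec.cds_start + 3
                while p % 3 != start % 3:
                    p += 1
                if p + 3 > total:
                    return None
                plant(p, str(rng.choice(["TAA", "TGA", "TAG"])))
        planted_records.append((start, req))

    if not _repair(seq, spec, planted_records, protected):
        return None

    transcript = from_spliced(
        f"synthetic_seed{spec.seed}",
        "".join(seq),
        spec.exon_lengths,
        spec.cds_start,
        cds_end,
    )
    truth = _verify_planted(transcript, planted_records)
    return (transcript, truth) if truth is not None else None


def _repair(
    seq: list[str],
    spec: FixtureSpec,
    planted: list[tuple[int, PlantedUORF]],
    protected: set[int],
    max_rounds: int = 20,
) -> bool:
    """Remove unplanned UTR ATGs and premature in-frame stops in place."""
    planted_starts = {s for s, _ in planted}
    for _ in range(max_rounds):
        dirty = False
        # unplanned ATGs anywhere in the 5' UTR
        for i in range(spec.cds_start):
            if "".join(seq[i : i + 3]) == START_CODON and i not in planted_starts:
                t = i + 1  # the T of ATG
                if t in protected:
                    return False
                seq[t] = "C"
                dirty = True
        # premature stops inside planted open stretches
        for start, req in planted:
            if req.frame_class == "contained":
                continue  # body fully planted
            limit = spec.cds_start if req.frame_class == "n_terminal_extension" else spec.cds_start + 3
            if req.frame_class == "overlapping":
                p = spec.cds_start + 3
                while p % 3 != start % 3:
                    p += 1
                limit = p
            for p in range(start + 3, limit, 3):
                if "".join(seq[p : p + 3]) in STOP_CODONS:
                    q = p + 1
                    if q in protected:
                        return False
                    seq[q] = "C"
                    dirty = True
        if not dirty:
            return True
    return False


def _verify_planted(
    transcript: Transcript, planted: list[tuple[int, PlantedUORF]]
) -> PlantedTruth | None:
    found = _scan.find_uorfs(transcript) + _scan.find_n_terminal_extensions(transcript)
    by_start = {u.start: u for u in found}
    expected = sorted(planted, key=lambda t: t[0])
    if set(by_start) != {s for s, _ in expected}:
        return None
    starts, fclasses, kclasses, minimal, hosts = [], [], [], [], []
    for start, req in expected:
        u = by_start[start]
        if u.frame_class != req.frame_class or u.kozak_class != req.kozak_class:
            return None
        if u.frame_class != "n_terminal_extension" and u.is_minimal != req.is_minimal:
            return None
        starts.append(start)
        fclasses.append(u.frame_class)
        kclasses.append(u.kozak_class)
        minimal.append(u.is_minimal)
        hosts.append(u.host_exon)
    return PlantedTruth(
        starts=tuple(starts),
        frame_classes=tuple(fclasses),
        kozak_classes=tuple(kclasses),
        is_minimal=tuple(minimal),
        host_exons=tuple(hosts),
    )


def random_transcript(
    rng: np.random.Generator, max_length: int = 600, n_exons: int | None = None
) -> Transcript:
    """An unconstrained random transcript for oracle-equivalence tests.

    Unlike :func:`make_transcript` nothing is planted or repaired — any
    ATG the background happens to contain is part of the test.
    """
    length = int(rng.integers(30, max_length + 1))
    cds_start = int(rng.integers(0, length - 6))
    cds_end = cds_start + 3 * ((length - cds_start) // 3)
    seq = list(rng.choice(BASES, size=length))
    seq[cds_start : cds_start + 3] = list(START_CODON)
    if n_exons is None:
        n_exons = int(rng.integers(1, 5))
    cuts = sorted(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    lengths = np.diff([0, *cuts, length]).tolist()
    return from_spliced(f"rand_{rng.integers(0, 2**31)}", "".join(seq), lengths, cds_start, cds_end)


# ----------------------------------------------------------------------
# amplicon read simulation


def simulate_reads(
    reference: str,
    allele_map: Mapping[frozenset, str],
    fractions: Mapping[frozenset, float],
    n: int,
    sub_error: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Draw ``n`` reads from enumerated alleles at the given fractions.

    Allele counts are allocated deterministically (largest-remainder
    apportionment of ``n * fraction``), so at zero error the classifier
    recovers the planted fractions exactly for any seed; the seed drives
    read order and the noise processes.  Substitution errors hit each base with
    probability ``sub_error``; at editable positions the substituted base is
    drawn so it never reproduces another enumerated allele (so errors always
    migrate a read to "other", never across categories).  With probability
    ``indel_rate`` a read receives a 1-nt insertion or deletion (atypical
    length → "other").
    """
    if n <= 0:
        raise ValueError("n must be positive")
    keys = sorted(fractions, key=sorted)
    probs = np.array([fractions[k] for k in keys], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("allele fractions must sum to 1")
    for k in keys:
        if k not in allele_map:
            raise ValueError(f"fraction key {set(k)} not in allele map")

    editable = sorted({p for k in allele_map for p in k})
    rng = np.random.default_rng(seed)
    counts = _apportion(n, probs)

    reads: list[tuple[str, str]] = []
    idx = 0
    for key, count in zip(keys, counts):
        template = allele_map[key]
        for _ in range(count):
            read = list(template)
            if sub_error > 0:
                hits = np.flatnonzero(rng.random(len(read)) < sub_error)
                for h in hits:
                    if int(h) in editable:
                        choices = [b for b in "ACGT" if b not in ("A", "G")]
                    else:
                        choices = [b for b in "ACGT" if b != read[h]]
                    read[h] = str(rng.choice(choices))
            seq = "".join(read)
            if indel_rate > 0 and rng.random() < indel_rate:
                pos = int(rng.integers(0, len(seq)))
                if rng.random() < 0.5:
                    seq = seq[:pos] + seq[pos + 1 :]
                else:
                    seq = seq[:pos] + str(rng.choice(BASES)) + seq[pos:]
            reads.append((f"read_{idx}", seq))
            idx += 1
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def _apportion(n: int, probs: np.ndarray) -> np.ndarray:
    """Integer counts summing to n, proportional to probs (largest remainder)."""
    raw = n * probs
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write simulated reads as FASTQ with uniform quality."""
    with open(path, "w") as handle:
        for rid, seq in reads:
            handle.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ----------------------------------------------------------------------
# Sanger table simulation


def make_sanger_table(
    true_rates: Mapping[int, float],
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_positions: int | None = None,
) -> BaseProportionTable:
    """Base-proportion table with planted A→G edit percentages.

    ``true_rates`` maps 1-based positions to edit percentages in [0, 100];
    unedited positions get pure A.  Gaussian noise of width ``noise_sigma``
    is added to each proportion, clipped at 0, and rows renormalized, so at
    σ=0 the quantifier recovers the rates exactly.
    """
    for pos, rate in true_rates.items():
        if not 0.0 <= rate <= 100.0:
            raise ValueError(f"position {pos}: rate {rate} outside [0, 100]")
    rng = np.random.default_rng(seed)
    positions = range(1, (n_positions or max(true_rates, default=1)) + 1)
    rows = {}
    for pos in positions:
        r = true_rates.get(pos, 0.0) / 100.0
        props = np.array([1.0 - r, 0.0, r, 0.0])  # A, C, G, T
        if noise_sigma > 0:
            props = np.clip(props + rng.normal(0.0, noise_sigma, size=4), 0.0, None)
        props = props / props.sum()
        rows[pos] = dict(zip("ACGT", props.tolist()))
    return BaseProportionTable(rows=rows)


# ----------------------------------------------------------------------
# the shipped worked example


def worked_example() -> tuple[Transcript, dict]:
    """The offline worked-example transcript embedding the printed protospacer.

    A two-exon transcript whose 5ʹ UTR contains one minimal uORF with
    intermediate Kozak context; the on-target protospacer sits on the sense
    strand with an AGG PAM, placing the uORF ATG adenosine at protospacer
    position 5 with bystander adenosines at positions 2 and 10.
    """
    exon1 = "GGGG" + EXAMPLE_PROTOSPACER + "AGG"  # 27 nt
    exon2 = "CTTCC" + "ATGGCTGAATAG"  # 5 nt UTR + 12 nt CDS
    sequence = exon1 + exon2
    transcript = from_spliced(
        "BDNF_like_fixture",
        sequence,
        [len(exon1), len(exon2)],
        cds_start=32,
        cds_end=44,
    )
    info = {
        "protospacer_offset": 4,  # transcript coordinate of protospacer position 1
        "uorf_start": 8,
        "target_protospacer_pos": 5,
        "bystander_protospacer_pos": (2, 10),
        "editable_tx_positions": (5, 8, 13),
    }
    return transcript, info
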