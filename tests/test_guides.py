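"""ABE guide design: protospacer enumeration, ranking, allele prediction."""

import numpy as np
import pytest

from uorftools import (
    design_abe_guides,
    design_cbe_guides,
    enumerate_protospacers,
    find_uorfs,
    from_spliced,
    predict_alleles,
)
from uorftools.guides import CBE_IMPOSSIBLE_MESSAGE, GuideCandidate
from uorftools.simulate import EXAMPLE_PROTOSPACER, random_transcript
from uorftools.transcripts import reverse_complement


def brute_force_protospacers(sequence):
    """Independent oracle: exhaustive two-strand 20-mer + NGG scan."""
    hits = []
    n = len(sequence)
    for o in range(n):
        if o + 23 <= n and sequence[o + 21 : o + 23] == "GG":
            hits.append((o, "sense", sequence[o : o + 20], sequence[o + 20 : o + 23]))
    rc = reverse_complement(sequence)
    for o in range(n):
        if o + 23 <= n and rc[o + 21 : o + 23] == "GG":
            sense_start = n - (o + 20)  # sense interval covered by the protospacer
            hits.append((sense_start, "antisense", rc[o : o + 20], rc[o + 20 : o + 23]))
    return sorted(hits, key=lambda h: (h[0], h[1]))


class TestEnumerateProtospacers:
    def test_printed_protospacer_found_with_agg_pam(self):
        seq = "GGGG" + EXAMPLE_PROTOSPACER + "AGG" + "TTTT"
        hits = enumerate_protospacers(seq)
        assert (4, "sense", EXAMPLE_PROTOSPACER, "AGG") in hits

    def test_too_short_sequence_yields_empty(self):
        assert enumerate_protospacers("AAAA") == []

    def test_both_strands_reported(self):
        # sense NGG at one end, CCN (antisense NGG) at the other
        seq = "CC" + "A" * 21 + "TGG"
        hits = enumerate_protospacers(seq)
        strands = {h[1] for h in hits}
        assert strands == {"sense", "antisense"}

    def test_oracle_equivalence_on_random_sequences(self, rng):
        """Exhaustive two-strand oracle agrees on 200 seeded sequences."""
        bases = list("ACGT")
        for _ in range(200):
            n = int(rng.integers(23, 120))
            seq = "".join(rng.choice(bases, size=n))
            assert enumerate_protospacers(seq) == brute_force_protospacers(seq)


def brute_force_abe_guides(transcript, uorf, window=(4, 8)):
    """Oracle: filter the exhaustive protospacer set for editable ATG adenosines."""
    s = uorf.start
    expected = set()
    for o, strand, proto, pam in brute_force_protospacers(transcript.sequence):
        if strand == "sense":
            p = s - o + 1  # protospacer position of the A of ATG
        else:
            p = o + 20 - (s + 1)  # position of the A opposite the T of ATG
        if window[0] <= p <= window[1] and proto[p - 1] == "A":
            expected.add((proto, pam, strand, p))
    return expected


class TestDesignAbeGuides:
    def test_worked_example_guide(self, example):
        tx, info = example
        (uorf,) = find_uorfs(tx)
        guides = design_abe_guides(tx, uorf)
        assert len(guides) == 1
        g = guides[0]
        assert g.protospacer == EXAMPLE_PROTOSPACER
        assert g.pam == "AGG"
        assert g.strand == "sense"
        assert g.target_pos == 5
        assert g.bystander_pos == (2, 10)

    def test_no_pam_support_yields_empty_list(self):
        tx = from_spliced("nopam", "CCATGTAACC" + "ATGGCTTAA", [19], 10, 19)
        (uorf,) = find_uorfs(tx)
        assert design_abe_guides(tx, uorf) == []

    def test_oracle_equivalence_on_random_transcripts(self, rng):
        """Candidate set equals brute-force enumeration on seeded 300-nt toys."""
        checked = 0
        for _ in range(60):
            tx = random_transcript(rng, max_length=300, n_exons=1)
            for uorf in find_uorfs(tx):
                got = {
                    (g.protospacer, g.pam, g.strand, g.target_pos)
                    for g in design_abe_guides(tx, uorf)
                }
                assert got == brute_force_abe_guides(tx, uorf)
                checked += 1
        assert checked > 20  # the sweep actually exercised guides

    def test_ranking_prefers_central_target_position(self, rng):
        for _ in range(40):
            tx = random_transcript(rng, max_length=300, n_exons=1)
            for uorf in find_uorfs(tx):
                guides = design_abe_guides(tx, uorf)
                dists = [abs(g.target_pos - 6) for g in guides]
                assert dists == sorted(dists)

    def test_target_edit_ablates_the_uorf(self, rng):
        """Applying the target edit and re-scanning drops the uORF count by
        exactly one — on toys where the edited base cannot touch anything
        but the targeted start codon (no overlapping ATGs, no other uORF's
        stop codon at the edited position, no upstream-AT context that the
        new G would complete into an ATG, no N-terminal extensions that a
        new stop could convert into a uORF)."""
        from uorftools import find_n_terminal_extensions
        from uorftools.guides import apply_edits_to_transcript

        checked = 0
        for _ in range(120):
            tx = random_transcript(rng, max_length=300, n_exons=1)
            uorfs = find_uorfs(tx)
            starts = [u.start for u in uorfs]
            if any(b - a < 3 for a, b in zip(starts, starts[1:])):
                continue
            if find_n_terminal_extensions(tx):
                continue
            for uorf in uorfs:
                for g in design_abe_guides(tx, uorf):
                    t = g.tx_position(g.target_pos)
                    if any(
                        u2.start != uorf.start
                        and u2.stop_end is not None
                        and u2.stop_end - 3 <= t < u2.stop_end
                        for u2 in uorfs
                    ):
                        continue
                    if g.strand == "sense" and tx.sequence[t - 2 : t] == "AT":
                        continue  # the new G would complete an upstream ATG
                    edited = apply_edits_to_transcript(g, tx, frozenset({g.target_pos}))
                    tx2 = from_spliced(
                        tx.id, edited, [e.length for e in tx.exons], tx.cds_start, tx.cds_end
                    )
                    remaining = find_uorfs(tx2)
                    assert uorf.start not in {u.start for u in remaining}
                    assert len(remaining) == len(uorfs) - 1
                    checked += 1
        assert checked > 10

    def test_uorf_transcript_mismatch(self, example):
        tx, _ = example
        (uorf,) = find_uorfs(tx)
        other = from_spliced("other", "CCATGTAACC" + "ATGGCTTAA", [19], 10, 19)
        with pytest.raises(ValueError, match="belong"):
            design_abe_guides(other, uorf)


class TestGuideCandidateInvariants:
    def test_bad_pam_rejected(self):
        with pytest.raises(ValueError, match="PAM"):
            GuideCandidate(
                protospacer="A" * 20, pam="ATT", strand="sense", target_pos=5, bystander_pos=()
            )

    def test_target_must_be_adenosine(self):
        with pytest.raises(ValueError, match="not A"):
            GuideCandidate(
                protospacer="C" * 20, pam="AGG", strand="sense", target_pos=5, bystander_pos=()
            )


class TestPredictAlleles:
    def test_allele_count_and_partition(self, example):
        tx, _ = example
        (uorf,) = find_uorfs(tx)
        (guide,) = design_abe_guides(tx, uorf)
        alleles = predict_alleles(guide, tx)
        k = len(guide.bystander_pos)
        assert len(alleles) == 2 ** (1 + k) == 8
        cats = [a.category for a in alleles]
        assert cats.count("productive") == 4
        assert cats.count("non_productive") == 3
        assert cats.count("unedited") == 1

    def test_target_edit_is_productive_gtg(self, example):
        tx, _ = example
        (uorf,) = find_uorfs(tx)
        (guide,) = design_abe_guides(tx, uorf)
        by_set = {a.edited_positions: a for a in predict_alleles(guide, tx)}
        productive = by_set[frozenset({5})]
        assert productive.category == "productive"
        # sense ATG -> GTG in the local protospacer sequence
        assert productive.local_sequence[4:7] == "GTG"

    def test_bystander_only_is_non_productive(self, example):
        tx, _ = example
        (uorf,) = find_uorfs(tx)
        (guide,) = design_abe_guides(tx, uorf)
        by_set = {a.edited_positions: a for a in predict_alleles(guide, tx)}
        assert by_set[frozenset({2})].category == "non_productive"
        assert by_set[frozenset()].category == "unedited"

    def test_partition_property_on_random_guides(self, rng):
        for _ in range(40):
            tx = random_transcript(rng, max_length=300, n_exons=1)
            for uorf in find_uorfs(tx):
                for g in design_abe_guides(tx, uorf)[:2]:
                    alleles = predict_alleles(g, tx)
                    n = len(alleles)
                    cats = [a.category for a in alleles]
                    assert n == 2 ** (1 + len(g.bystander_pos))
                    assert cats.count("productive") == n // 2
                    assert cats.count("unedited") == 1
                    assert cats.count("non_productive") == n // 2 - 1


class TestCbeValidationMode:
    def test_printed_site_cannot_be_cbe_disrupted(self, example):
        """The worked-example window holds no protospacer-strand C whose
        C->T edit would break the ATG, so CBE is a negative control here."""
        tx, _ = example
        (uorf,) = find_uorfs(tx)
        candidates, message = design_cbe_guides(tx, uorf)
        assert candidates == []
        assert message == CBE_IMPOSSIBLE_MESSAGE

    def test_cbe_possible_when_antisense_pam_exists(self):
        # antisense guide placing the C opposite the ATG's G in the window:
        # sense needs CC at [o-3, o-1) with o = (s+2) + p - 20
        s = 24  # ATG at 24 in a 60-nt toy
        for p in (4, 5, 6, 7, 8):
            o = s + 2 + p - 20
            seq = list("T" * 60)
            seq[s : s + 3] = "ATG"
            seq[s + 3 : s + 6] = "TAA"  # minimal uORF
            seq[o - 3 : o - 1] = "CC"
            seq[40:52] = "ATGGCTGAATAG"
            tx = from_spliced("cbe", "".join(seq), [60], 40, 52)
            uorf = [u for u in find_uorfs(tx) if u.start == s][0]
            candidates, message = design_cbe_guides(tx, uorf)
            assert message is None
            assert any(c["target_pos"] == p for c in candidates)
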