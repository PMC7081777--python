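"""Motif, homopolymer, microsatellite and tandem-repeat detection."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.motifs import (
    control_region_report,
    find_microsatellite,
    find_motif,
    find_tandem_repeats,
    longest_homopolymer,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)
at_rich = st.text(alphabet="AATTG", min_size=20, max_size=200)


# --- independent oracles -------------------------------------------------

def naive_find(region: str, motif: str) -> list[int]:
    """O(n*m) scan, overlapping occurrences, 1-based starts."""
    m = len(motif)
    return [i + 1 for i in range(len(region) - m + 1) if region[i : i + m] == motif]


def naive_primitive(unit: str) -> bool:
    return all(
        not (len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d))
        for d in range(1, len(unit))
    )


def naive_tandem(region: str, max_unit: int, min_total: int) -> set:
    """Tract enumeration via the period match-array, an independent route.

    For each unit size k, positions where region[i] == region[i-k] form
    maximal runs; each run is a periodic tract.  A tract is reported when
    its unit is primitive (k is the minimal period), it holds >= 2 full
    copies, and the full-copy span reaches min_total.
    """
    n = len(region)
    hits = set()
    for k in range(1, max_unit + 1):
        i = k
        while i < n:
            if region[i] == region[i - k]:
                j = i
                while j < n and region[j] == region[j - k]:
                    j += 1
                s = i - k  # tract spans [s, j)
                unit = region[s : s + k]
                copies = (j - s) // k
                if copies >= 2 and copies * k >= min_total and naive_primitive(unit):
                    hits.add((s + 1, unit, copies))
                i = j + 1
            else:
                i += 1
    return hits


class TestFindMotif:
    def test_whole_region_match(self):
        hits = find_motif("ATACTAA", "ATACTAA")
        assert [(h.start, h.length) for h in hits] == [(1, 7)]

    def test_overlapping_occurrences(self):
        assert [h.start for h in find_motif("AAAA", "AA")] == [1, 2, 3]

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            find_motif("ACGT", "")

    @given(dna, st.text(alphabet="ACGT", min_size=1, max_size=6))
    @settings(derandomize=True, max_examples=100)
    def test_agrees_with_naive_scan(self, region, motif):
        assert [h.start for h in find_motif(region, motif)] == naive_find(region, motif)

    @given(dna)
    @settings(derandomize=True, max_examples=50)
    def test_hits_within_bounds(self, region):
        for h in find_motif(region, "AT"):
            assert 1 <= h.start and h.end <= len(region)


class TestHomopolymer:
    def test_full_run(self):
        h = longest_homopolymer("TTTTT", "T")
        assert (h.start, h.length) == (1, 5)

    def test_leftmost_tie_break(self):
        h = longest_homopolymer("TTATT", "T")
        assert (h.start, h.length) == (1, 2)

    def test_absent_base_zero_hit(self):
        assert longest_homopolymer("ACAC", "T").length == 0

    @given(dna, st.sampled_from("ACGT"))
    @settings(derandomize=True, max_examples=80)
    def test_agrees_with_naive_runs(self, region, base):
        runs = []
        i = 0
        while i < len(region):
            if region[i] == base:
                j = i
                while j < len(region) and region[j] == base:
                    j += 1
                runs.append((j - i, -(i + 1)))
                i = j
            else:
                i += 1
        h = longest_homopolymer(region, base)
        if not runs:
            assert h.length == 0
        else:
            best = max(runs)
            assert (h.length, h.start) == (best[0], -best[1])


class TestMicrosatellite:
    def test_simple_run(self):
        (h,) = find_microsatellite("ATATATAT", "AT", 2)
        assert (h.start, h.copies, h.length) == (1, 4, 8)

    def test_partial_trailing_unit_not_counted(self):
        (h,) = find_microsatellite("ATATA", "AT", 2)
        assert h.copies == 2

    def test_min_copies_threshold(self):
        assert find_microsatellite("ATATCCC", "AT", 3) == []

    def test_runs_are_maximal(self):
        hits = find_microsatellite("GATATATG" + "C" + "ATAT", "AT", 2)
        assert [(h.start, h.copies) for h in hits] == [(2, 3), (10, 2)]


class TestTandemRepeats:
    def test_trinucleotide_run(self):
        (h,) = find_tandem_repeats("ACGACGACG", max_unit=3, min_total=6)
        assert (h.motif, h.copies, h.start) == ("ACG", 3, 1)

    def test_no_hit_below_threshold(self):
        assert find_tandem_repeats("ACGTACGA", max_unit=4, min_total=6) == []

    def test_homopolymer_not_duplicated_at_larger_units(self):
        hits = find_tandem_repeats("AAAAAA", max_unit=3, min_total=4)
        assert [(h.motif, h.copies) for h in hits] == [("A", 6)]

    @given(at_rich, st.integers(1, 5), st.integers(4, 8))
    @settings(derandomize=True, max_examples=100)
    def test_agrees_with_tract_enumeration(self, region, max_unit, min_total):
        got = {
            (h.start, h.motif, h.copies)
            for h in find_tandem_repeats(region, max_unit, min_total)
        }
        assert got == naive_tandem(region, max_unit, min_total)

    def test_oracle_on_long_at_rich_strings(self):
        rng = random.Random(11)
        for _ in range(20):
            region = "".join(rng.choices("AATTGC", k=400))
            got = {
                (h.start, h.motif, h.copies)
                for h in find_tandem_repeats(region, 6, 8)
            }
            assert got == naive_tandem(region, 6, 8)


class TestShiftEquivariance:
    """Rotating the scanned string shifts hits correspondingly."""

    def test_all_finders_shift(self):
        rng = random.Random(3)
        core = "".join(rng.choices("ACGT", k=120))
        pad = "G" * 10
        base = pad + core + pad
        for offset in (3, 7):
            shifted = ("C" * offset) + base
            for h, g in zip(
                find_motif(base, "ATA"), find_motif(shifted, "ATA")
            ):
                assert g.start == h.start + offset
            inner = [
                h for h in find_tandem_repeats(base, 4, 6)
                if 10 < h.start < len(base) - 10
            ]
            shifted_hits = {
                (h.start, h.motif, h.copies)
                for h in find_tandem_repeats(shifted, 4, 6)
            }
            for h in inner:
                assert (h.start + offset, h.motif, h.copies) in shifted_hits


class TestControlRegionReport:
    def test_planted_architecture_recovered(self, synthetic_genome):
        ann, ledger = synthetic_genome
        rep = control_region_report(ann)
        planted = {p["label"]: p for p in ledger["planted"]}
        assert any(h.start == planted["ATAGA"]["region_start"] for h in rep.ataga_hits)
        assert (rep.poly_t.start, rep.poly_t.length) == (
            planted["polyT"]["region_start"], 20
        )
        assert (rep.poly_a.start, rep.poly_a.length) == (
            planted["polyA"]["region_start"], 12
        )
        big = [h for h in rep.at_microsatellites if h.copies >= 10]
        assert [(h.start, h.copies) for h in big] == [
            (planted["AT_microsat"]["region_start"], 10)
        ]
        assert rep.poly_t_follows_ataga

    def test_spacer_motif_recovered(self, synthetic_genome):
        ann, ledger = synthetic_genome
        plant = next(p for p in ledger["planted"] if p["label"] == "ATACTAA")
        trns2 = ann.feature("trnS2")
        nad1 = ann.feature("nad1")
        spacer = ann.sequence[trns2.end : nad1.start - 1]
        assert len(spacer) == 22
        hits = find_motif(spacer, "ATACTAA")
        assert plant["region_start"] in [h.start for h in hits]

    def test_all_c_region_is_empty(self):
        from mitocomp.model import GeneFeature, MitoAnnotation

        ann = MitoAnnotation(
            genome_length=50,
            features=[GeneFeature("AT_rich", 11, 40, "J", "control")],
            sequence="A" * 10 + "C" * 30 + "A" * 10,
        )
        rep = control_region_report(ann)
        assert rep.ataga_hits == [] and rep.at_microsatellites == []
        assert rep.poly_t.length == 0 and not rep.poly_t_follows_ataga

    def test_requires_control_region(self, synthetic_ann):
        from mitocomp.synthetic import perturb

        broken = perturb(synthetic_ann, "delete_gene", "AT_rich")
        with pytest.raises(ValueError, match="control"):
            control_region_report(broken)
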