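"""Sequence-landmark detection for mitochondrial control regions.

Lepidopteran control regions carry a conserved architecture: the origin-
of-replication 'ATAGA' motif followed by a long poly-T stretch, an (AT)n
microsatellite, and a poly-A run upstream of trnM; a conserved 'ATACTAA'
motif sits in the trnS2-nad1 spacer.  This module finds those landmarks
plus perfect short tandem repeats.  Only exact matches and perfect
repeats are detected — a deliberate simplification relative to
mismatch-tolerant repeat finders.

All hits use 1-based coordinates *within the scanned region*.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import MitoAnnotation

__all__ = [
    "MotifHit",
    "find_motif",
    "longest_homopolymer",
    "find_microsatellite",
    "find_tandem_repeats",
    "control_region_report",
    "ControlRegionReport",
]


@dataclass(frozen=True)
class MotifHit:
    """One motif/repeat occurrence inside a scanned region (1-based)."""

    motif: str  # literal motif, or a pattern label (polyT, AT_microsat, ...)
    start: int
    length: int
    copies: int = 1

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def find_motif(region: str, motif: str) -> list[MotifHit]:
    """All exact occurrences of ``motif``, overlapping allowed."""
    if not motif:
        raise ValueError("empty motif")
    region, motif = region.upper(), motif.upper()
    hits = []
    i = region.find(motif)
    while i != -1:
        hits.append(MotifHit(motif=motif, start=i + 1, length=len(motif)))
        i = region.find(motif, i + 1)
    return hits


def longest_homopolymer(region: str, base: str) -> MotifHit:
    """Leftmost longest run of ``base``; a zero-length hit if absent."""
    if base not in "ACGT":
        raise ValueError(f"base must be one of ACGT, got {base!r}")
    region = region.upper()
    best_start, best_len = 0, 0
    i = 0
    n = len(region)
    while i < n:
        if region[i] == base:
            j = i
            while j < n and region[j] == base:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    label = f"poly{base}"
    if best_len == 0:
        return MotifHit(motif=label, start=1, length=0, copies=0)
    return MotifHit(motif=label, start=best_start + 1, length=best_len, copies=best_len)


def find_microsatellite(
    region: str, unit: str, min_copies: int = 2
) -> list[MotifHit]:
    """Maximal perfect tandem runs of ``unit`` with at least ``min_copies``.

    A run is maximal when it cannot be extended by a full copy of the
    unit on either side; a trailing partial unit is not counted
    (``copies = floor(run length / unit length)``).
    """
    if not unit:
        raise ValueError("empty unit")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    region, unit = region.upper(), unit.upper()
    k = len(unit)
    n = len(region)
    hits = []
    i = 0
    while i + 2 * k <= n:
        if region[i : i + k] != unit:
            i += 1
            continue
        # cannot extend left by a full copy
        if i >= k and region[i - k : i] == unit:
            i += 1
            continue
        copies = 1
        while region[i + copies * k : i + (copies + 1) * k] == unit:
            copies += 1
        if copies >= min_copies:
            hits.append(
                MotifHit(
                    motif=f"({unit})n", start=i + 1, length=copies * k, copies=copies
                )
            )
        i += copies * k
    return hits


def _is_primitive(unit: str) -> bool:
    """True when the unit is not itself a repetition of a shorter unit."""
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


def find_tandem_repeats(
    region: str, max_unit: int = 6, min_total: int = 6
) -> list[MotifHit]:
    """Perfect tandem runs for every unit size 1..``max_unit``.

    Each maximal perfectly periodic tract whose minimal period is
    k <= ``max_unit`` is reported exactly once, at its leftmost start,
    with ``copies = floor(tract length / k)`` (a trailing partial unit is
    not counted).  Only tracts with at least two full copies and
    ``copies * k >= min_total`` are kept.  Requiring the minimal period
    suppresses nested reports: a homopolymer run never reappears as a
    dinucleotide repeat.
    """
    if not 1 <= max_unit <= len(region):
        raise ValueError("max_unit out of range")
    region = region.upper()
    n = len(region)
    hits: list[MotifHit] = []
    for k in range(1, max_unit + 1):
        i = 0
        while i + 2 * k <= n:
            # extend the period-k tract beginning at i
            j = i + k
            while j < n and region[j] == region[j - k]:
                j += 1
            copies = (j - i) // k
            if copies >= 2:
                unit = region[i : i + k]
                # primitivity <=> k is the minimal period of the tract
                if copies * k >= min_total and _is_primitive(unit):
                    hits.append(
                        MotifHit(
                            motif=unit, start=i + 1, length=copies * k, copies=copies
                        )
                    )
                # the next tract of period k starts after j - k at the earliest
                i = max(i + 1, j - k + 1)
            else:
                i += 1
    return sorted(hits, key=lambda h: (h.start, len(h.motif)))


@dataclass
class ControlRegionReport:
    """Landmarks of the A+T-rich (control) region, in positional order."""

    region_length: int
    ataga_hits: list[MotifHit]
    poly_t: MotifHit
    at_microsatellites: list[MotifHit]
    poly_a: MotifHit
    poly_t_follows_ataga: bool

    @property
    def landmarks(self) -> list[MotifHit]:
        hits = list(self.ataga_hits) + list(self.at_microsatellites)
        for h in (self.poly_t, self.poly_a):
            if h.length > 0:
                hits.append(h)
        return sorted(hits, key=lambda h: h.start)


def control_region_report(
    ann: MitoAnnotation, min_at_copies: int = 5, adjacency_tolerance: int = 2
) -> ControlRegionReport:
    """Scan the control region for its conserved landmark architecture.

    Reports every 'ATAGA' hit, the longest poly-T and poly-A runs, and
    (AT)n microsatellites with at least ``min_at_copies`` copies, plus
    whether the poly-T stretch immediately follows an 'ATAGA' motif
    (gap <= ``adjacency_tolerance`` bp).  Scanning is on the J strand as
    annotated.
    """
    ctrl = ann.control_region
    if ctrl is None:
        raise ValueError("annotation has no control region")
    if ann.sequence is None:
        raise ValueError("no sequence attached to annotation")
    region = ann.sequence[ctrl.start - 1 : ctrl.end]
    ataga = find_motif(region, "ATAGA")
    poly_t = longest_homopolymer(region, "T")
    poly_a = longest_homopolymer(region, "A")
    microsats = find_microsatellite(region, "AT", min_copies=min_at_copies)
    follows = poly_t.length > 0 and any(
        0 <= poly_t.start - h.end - 1 <= adjacency_tolerance for h in ataga
    )
    return ControlRegionReport(
        region_length=len(region),
        ataga_hits=ataga,
        poly_t=poly_t,
        at_microsatellites=microsats,
        poly_a=poly_a,
        poly_t_follows_ataga=follows,
    )
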