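"""Circular-genome architecture: junctions, overlaps, spacers, lengths.

On a circular mitogenome every pair of consecutive features (in start
order, wrapping from the last feature back to the first) defines one
junction with a signed gap::

    signed_gap = start(downstream) - end(upstream) - 1      (+L on the wrap)

Negative gaps are gene overlaps, positive gaps intergenic spacers, zero
means abutting genes.  Feature lengths, spacers and overlaps obey the
circular conservation identity

    sum(lengths) + sum(spacers) - sum(overlaps) = genome length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import CANONICAL_GENES, MitoAnnotation

__all__ = [
    "Junction",
    "AdjacencyReport",
    "adjacency",
    "gene_lengths",
    "class_summary",
    "region_fraction",
    "validate_annotation",
]


@dataclass(frozen=True)
class Junction:
    """One junction between consecutive features on the circle."""

    upstream: str
    downstream: str
    signed_gap: int
    wraps_origin: bool = False


@dataclass
class AdjacencyReport:
    """All junctions of a circular annotation, with overlap/spacer totals."""

    junctions: list[Junction]

    @property
    def overlaps(self) -> list[Junction]:
        return [j for j in self.junctions if j.signed_gap < 0]

    @property
    def spacers(self) -> list[Junction]:
        return [j for j in self.junctions if j.signed_gap > 0]

    @property
    def overlap_total(self) -> int:
        return -sum(j.signed_gap for j in self.overlaps)

    @property
    def spacer_total(self) -> int:
        return sum(j.signed_gap for j in self.spacers)

    @property
    def spacer_range(self) -> tuple[int, int] | None:
        sizes = [j.signed_gap for j in self.spacers]
        return (min(sizes), max(sizes)) if sizes else None

    @property
    def overlap_range(self) -> tuple[int, int] | None:
        sizes = [-j.signed_gap for j in self.overlaps]
        return (min(sizes), max(sizes)) if sizes else None


def adjacency(ann: MitoAnnotation) -> AdjacencyReport:
    """Compute every pairwise junction of the circular annotation.

    Junctions follow genomic (start-coordinate) order regardless of
    strand; the wrap junction from the last feature back to the first is
    included, so junction count equals feature count.
    """
    if not ann.circular:
        raise ValueError("adjacency analysis requires a circular annotation")
    feats = ann.features
    if len(feats) < 2:
        raise ValueError("need at least two features")
    junctions = []
    for up, down in zip(feats, feats[1:]):
        junctions.append(
            Junction(up.name, down.name, down.start - up.end - 1)
        )
    last, first = feats[-1], feats[0]
    junctions.append(
        Junction(
            last.name,
            first.name,
            first.start + ann.genome_length - last.end - 1,
            wraps_origin=True,
        )
    )
    return AdjacencyReport(junctions=junctions)


def gene_lengths(ann: MitoAnnotation) -> dict[str, int]:
    """Coordinate length (``end - start + 1``) of every feature."""
    return {f.name: f.length for f in ann.features}


def class_summary(ann: MitoAnnotation) -> dict[str, dict]:
    """Per-class length accounting: totals, counts, min/max."""
    out: dict[str, dict] = {}
    for gclass in ("PCG", "tRNA", "rRNA", "control"):
        feats = ann.by_class(gclass)
        if not feats:
            continue
        lengths = {f.name: f.length for f in feats}
        out[gclass] = {
            "count": len(feats),
            "total_bp": sum(lengths.values()),
            "min": min(lengths.items(), key=lambda kv: kv[1]),
            "max": max(lengths.items(), key=lambda kv: kv[1]),
            "lengths": lengths,
        }
    return out


def region_fraction(ann: MitoAnnotation, gclass: str) -> float:
    """Percent of the genome covered by a feature class, 1 dp (half-up)."""
    from .composition import round_half_up

    total = sum(f.length for f in ann.by_class(gclass))
    return round_half_up(100.0 * total / ann.genome_length, 1)


@dataclass(frozen=True)
class Finding:
    """One validation finding (informational; coordinates never altered)."""

    kind: str
    message: str


def validate_annotation(ann: MitoAnnotation) -> list[Finding]:
    """Sanity-check an annotation against the canonical mitogenome layout.

    Reported findings: printed-length vs coordinate-length conflicts,
    genes missing from the canonical 37-gene set, duplicate names,
    missing control region, features exceeding the genome bounds.
    Findings are informational — input coordinates are never modified.
    """
    findings: list[Finding] = []
    names = [f.name for f in ann.features]
    for name in sorted({n for n in names if names.count(n) > 1}):
        findings.append(Finding("duplicate_name", f"feature {name} appears twice"))
    for f in ann.features:
        printed = ann.printed_lengths.get(f.name)
        if printed is not None and printed != f.length:
            findings.append(
                Finding(
                    "length_conflict",
                    f"{f.name}: printed length {printed} != coordinate length "
                    f"{f.length} ({f.start}..{f.end}); coordinates are authoritative",
                )
            )
    missing = CANONICAL_GENES - set(names)
    for name in sorted(missing):
        findings.append(Finding("missing_gene", f"canonical gene {name} not annotated"))
    if ann.control_region is None:
        findings.append(Finding("missing_control", "no control region annotated"))
    elif len(ann.by_class("control")) > 1:
        findings.append(Finding("extra_control", "multiple control-region features"))
    return findings
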