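"""Shared data model for annotated circular mitogenomes.

Coordinates are 1-based and both-ends inclusive, the convention used by
GenBank flat files and by mitogenome annotation tables.  The *J strand*
(majority strand) is the deposited/plus strand; *N* is its complement.
Features never wrap the origin: the control region is annotated as the
terminal block of the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "GeneFeature",
    "MitoAnnotation",
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "CANONICAL_GENES",
]

#: The 13 mitochondrial protein-coding genes of a typical metazoan.
PCG_NAMES = frozenset(
    {
        "atp6", "atp8",
        "cox1", "cox2", "cox3",
        "cob",
        "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
    }
)

#: The 22 tRNA genes; the two serine and two leucine isoacceptors are
#: distinguished by number (S1=AGN, S2=UCN, L1=CUN, L2=UUR).
TRNA_NAMES = frozenset(
    {
        "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
        "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
        "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
    }
)

RRNA_NAMES = frozenset({"rrnL", "rrnS"})

#: The canonical 37-gene complement of a metazoan mitogenome.
CANONICAL_GENES = PCG_NAMES | TRNA_NAMES | RRNA_NAMES

VALID_STRANDS = ("J", "N")
VALID_CLASSES = ("PCG", "tRNA", "rRNA", "control")


@dataclass
class GeneFeature:
    """One annotated gene (or the control region) on a circular mitogenome.

    Parameters
    ----------
    name:
        Gene identifier in the standard mitogenome vocabulary
        (``cox1``, ``trnS1``, ``rrnL``, ``AT_rich``, ...).
    start, end:
        1-based inclusive coordinates on the J strand, ``end >= start``.
    strand:
        ``"J"`` (majority/plus) or ``"N"`` (minority/minus).
    gclass:
        ``"PCG"``, ``"tRNA"``, ``"rRNA"`` or ``"control"``.
    anticodon:
        3-mer anticodon, tRNA features only.
    start_codon, stop_codon:
        Annotated initiation/termination codons, PCG features only.  A
        2-mer (or 1-mer) stop encodes an incomplete codon completed by
        post-transcriptional polyadenylation.
    """

    name: str
    start: int
    end: int
    strand: str
    gclass: str
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.name}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"{self.name}: strand must be J or N, got {self.strand!r}")
        if self.gclass not in VALID_CLASSES:
            raise ValueError(f"{self.name}: unknown feature class {self.gclass!r}")
        if self.gclass == "PCG" and self.start_codon is None:
            raise ValueError(f"{self.name}: PCG requires a start codon")
        if self.gclass != "PCG" and (self.start_codon or self.stop_codon):
            raise ValueError(f"{self.name}: only PCGs carry start/stop codons")
        if self.stop_codon is not None and len(self.stop_codon) not in (1, 2, 3):
            raise ValueError(f"{self.name}: stop codon must be 1-3 nt")
        if (self.anticodon is not None) != (self.gclass == "tRNA"):
            raise ValueError(f"{self.name}: anticodon present iff feature is a tRNA")

    @property
    def length(self) -> int:
        """Coordinate length in bp (``end - start + 1``)."""
        return self.end - self.start + 1

    def copy(self, **changes) -> "GeneFeature":
        return replace(self, **changes)


@dataclass
class MitoAnnotation:
    """A circular mitogenome: ordered gene features plus optional sequence.

    ``sequence`` is the J strand, 5'->3', over {A,C,G,T,N}.  Features are
    kept sorted by ``start`` (ties broken by ``end``).  ``printed_lengths``
    holds gene lengths as printed in the source table, when one was parsed;
    they are never used in computation (coordinates are authoritative) but
    are retained so validation can surface printed-vs-coordinate conflicts.
    """

    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    sequence: str | None = None
    printed_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > self.genome_length:
                raise ValueError(
                    f"{f.name}: end {f.end} exceeds genome length {self.genome_length}"
                )
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.genome_length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != genome_length "
                    f"{self.genome_length}"
                )
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise ValueError(f"sequence contains invalid characters {sorted(bad)}")

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_class(self, gclass: str) -> list[GeneFeature]:
        return [f for f in self.features if f.gclass == gclass]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.by_class("PCG")

    @property
    def control_region(self) -> GeneFeature | None:
        ctrl = self.by_class("control")
        return ctrl[0] if ctrl else None

    def copy(self, **changes) -> "MitoAnnotation":
        new = replace(self, **changes)
        if "features" not in changes:
            new.features = [f.copy() for f in self.features]
        if "printed_lengths" not in changes:
            new.printed_lengths = dict(self.printed_lengths)
        return new


def infer_gclass(name: str) -> str | None:
    """Guess the feature class from a normalized gene name; None if unknown."""
    if name in PCG_NAMES:
        return "PCG"
    if name in TRNA_NAMES or name.startswith("trn"):
        return "tRNA"
    if name in RRNA_NAMES or name.startswith("rrn"):
        return "rRNA"
    if name.lower().replace("-", "_").replace(" ", "_") in {
        "at_rich", "at_rich_region", "d_loop", "control_region", "cr",
    }:
        return "control"
    return None
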