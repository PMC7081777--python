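"""Codon-usage statistics under the invertebrate mitochondrial genetic code.

Implements the three summaries used in descriptive mitogenomics:

* amino-acid usage (pooled codon counts per amino acid);
* CDspT — codons per thousand codons, a per-mille codon frequency;
* RSCU — relative synonymous codon usage, a codon's count divided by the
  mean count of its synonymous family (1 = no bias within the family).

The default genetic code is NCBI translation table 5 (invertebrate
mitochondrial: AGA/AGG -> Ser, ATA -> Met, TGA -> Trp), under which a
lepidopteran mitogenome has 62 sense codons and 2 stop codons.

Conventions (switchable where noted): start codons are counted as read —
the non-canonical CGA initiator of cox1 stays in the Arg family; stop
codons are tracked but excluded from amino-acid totals, CDspT and RSCU;
a trailing partial codon (incomplete stop such as "TA") is excluded from
all counts and surfaced by the start/stop audit instead.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .annotation_io import extract_region
from .model import MitoAnnotation

log = logging.getLogger(__name__)

__all__ = [
    "GeneticCode",
    "CodingSequence",
    "CodonUsageTable",
    "GeneAudit",
    "coding_sequences",
    "codon_usage",
    "cdspt",
    "aa_cdspt",
    "codon_audit",
]

ALL_CODONS = ["".join(p) for p in itertools.product("TCAG", repeat=3)]


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon genetic code with its synonymous families."""

    code_id: str
    codon_to_aa: dict[str, str]  # total map; STOP encoded as "*"

    @classmethod
    def from_ncbi_id(cls, table_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        assert len(mapping) == 64
        return cls(code_id=table.names[0], codon_to_aa=mapping)

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")

    @property
    def sense_codons(self) -> list[str]:
        return [c for c in ALL_CODONS if self.codon_to_aa[c] != "*"]

    @property
    def synonymous_families(self) -> dict[str, list[str]]:
        """Partition of sense codons by encoded amino acid."""
        fams: dict[str, list[str]] = {}
        for c in ALL_CODONS:
            aa = self.codon_to_aa[c]
            if aa != "*":
                fams.setdefault(aa, []).append(c)
        return fams


INVERTEBRATE_MITO = GeneticCode.from_ncbi_id(5)


@dataclass
class CodingSequence:
    """A protein-coding gene read in coding sense, split into codons."""

    name: str
    sequence: str
    codons: list[str]
    remainder: str  # trailing partial codon ("" when length % 3 == 0)

    @property
    def incomplete(self) -> bool:
        return bool(self.remainder)


def _split_codons(seq: str) -> tuple[list[str], str]:
    n_full = len(seq) // 3
    return [seq[3 * i : 3 * i + 3] for i in range(n_full)], seq[3 * n_full :]


def coding_sequences(
    ann: MitoAnnotation, code: GeneticCode = INVERTEBRATE_MITO
) -> list[CodingSequence]:
    """Extract every PCG in coding sense and split it into codons.

    N-strand genes are reverse complemented.  Trailing partial codons
    (incomplete stops completed by polyadenylation) are flagged and kept
    out of the codon list.  An in-frame stop before the final codon is
    logged as a warning — imperfect annotations are common — not an error.
    """
    if ann.sequence is None:
        raise ValueError("no sequence attached to annotation")
    out = []
    for feat in ann.pcgs:
        seq = extract_region(ann, feat)
        codons, remainder = _split_codons(seq)
        for i, c in enumerate(codons[:-1]):
            if code.codon_to_aa.get(c) == "*":
                log.warning(
                    "%s: internal stop codon %s at codon %d", feat.name, c, i + 1
                )
        out.append(
            CodingSequence(
                name=feat.name, sequence=seq, codons=codons, remainder=remainder
            )
        )
    return out


@dataclass
class CodonUsageTable:
    """Pooled codon usage with CDspT and RSCU columns.

    ``counts`` covers every full codon read, stops included;
    ``total_codons`` counts sense codons only, the denominator for CDspT
    and RSCU.  A codon in a family with zero total has no defined RSCU
    and is absent from ``rscu``.
    """

    code: GeneticCode
    counts: dict[str, int]
    skipped_ambiguous: int = 0

    @property
    def total_codons(self) -> int:
        return sum(n for c, n in self.counts.items() if self.code.codon_to_aa[c] != "*")

    @property
    def stop_counts(self) -> dict[str, int]:
        return {c: n for c, n in self.counts.items() if self.code.codon_to_aa[c] == "*"}

    @property
    def aa_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c, n in self.counts.items():
            aa = self.code.codon_to_aa[c]
            if aa != "*":
                out[aa] = out.get(aa, 0) + n
        return out

    @property
    def cdspt(self) -> dict[str, float]:
        total = self.total_codons
        if total == 0:
            raise ValueError("empty codon table")
        return {
            c: 1000.0 * self.counts.get(c, 0) / total for c in self.code.sense_codons
        }

    @property
    def rscu(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for fam in self.code.synonymous_families.values():
            fam_total = sum(self.counts.get(c, 0) for c in fam)
            if fam_total == 0:
                continue  # RSCU undefined for the whole family
            for c in fam:
                out[c] = self.counts.get(c, 0) * len(fam) / fam_total
        return out

    @property
    def absent_codons(self) -> set[str]:
        """Sense codons never observed."""
        return {c for c in self.code.sense_codons if self.counts.get(c, 0) == 0}


def codon_usage(
    cds_list: list[CodingSequence | str], code: GeneticCode = INVERTEBRATE_MITO
) -> CodonUsageTable:
    """Pool codon counts over a set of coding sequences.

    Accepts :class:`CodingSequence` objects or plain coding-sense strings
    (length >= 3); trailing partial codons are dropped, codons containing
    N are skipped and tallied separately.
    """
    counts: dict[str, int] = {}
    skipped = 0
    for cds in cds_list:
        if isinstance(cds, str):
            if len(cds) < 3:
                raise ValueError("coding sequence shorter than one codon")
            codons, _ = _split_codons(cds.upper())
        else:
            codons = cds.codons
        for c in codons:
            if c in code.codon_to_aa:
                counts[c] = counts.get(c, 0) + 1
            else:
                skipped += 1
    return CodonUsageTable(code=code, counts=counts, skipped_ambiguous=skipped)


def cdspt(table: CodonUsageTable) -> dict[str, float]:
    """Codons per thousand codons; sums to 1000 over sense codons."""
    return table.cdspt


def aa_cdspt(table: CodonUsageTable) -> dict[str, float]:
    """CDspT aggregated per amino acid."""
    total = table.total_codons
    if total == 0:
        raise ValueError("empty codon table")
    return {aa: 1000.0 * n / total for aa, n in table.aa_counts.items()}


CANONICAL_STARTS = {"ATA", "ATT", "ATG", "ATC"}  # the ATN set
CANONICAL_STOPS = {"TAA", "TAG"}
INCOMPLETE_STOPS = {"TA", "T"}


@dataclass
class GeneAudit:
    """Start/stop codon audit for one protein-coding gene."""

    gene: str
    strand: str
    annotated_start: str | None
    observed_start: str
    annotated_stop: str | None
    observed_stop: str
    start_canonical: bool = field(init=False)
    stop_canonical: bool = field(init=False)
    incomplete_stop: bool = field(init=False)
    start_mismatch: bool = field(init=False)
    stop_mismatch: bool = field(init=False)

    def __post_init__(self) -> None:
        self.start_canonical = self.observed_start in CANONICAL_STARTS
        self.incomplete_stop = len(self.observed_stop) < 3
        self.stop_canonical = (
            self.observed_stop in CANONICAL_STOPS
            or self.observed_stop in INCOMPLETE_STOPS
        )
        self.start_mismatch = (
            self.annotated_start is not None
            and self.annotated_start != self.observed_start
        )
        self.stop_mismatch = (
            self.annotated_stop is not None
            and self.annotated_stop != self.observed_stop
        )


def codon_audit(
    ann: MitoAnnotation, code: GeneticCode = INVERTEBRATE_MITO
) -> list[GeneAudit]:
    """Audit observed vs annotated start/stop codons for every PCG.

    The observed stop is read from the gene's 3' end: when the annotation
    declares a 1- or 2-mer (incomplete, polyadenylation-completed) stop
    the matching-length suffix is compared; otherwise the in-frame
    trailing partial codon (if any) or the final full codon is used.
    Non-canonical starts (outside ATN, e.g. the CGA of cox1) are flagged
    but allowed.
    """
    audits = []
    for cds in coding_sequences(ann, code):
        feat = ann.feature(cds.name)
        ann_stop = feat.stop_codon
        if ann_stop is not None and len(ann_stop) < 3:
            observed_stop = cds.sequence[-len(ann_stop):]
        elif cds.remainder:
            observed_stop = cds.remainder
        else:
            observed_stop = cds.codons[-1] if cds.codons else ""
        audits.append(
            GeneAudit(
                gene=cds.name,
                strand=feat.strand,
                annotated_start=feat.start_codon,
                observed_start=cds.sequence[:3],
                annotated_stop=ann_stop,
                observed_stop=observed_stop,
            )
        )
    return audits
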