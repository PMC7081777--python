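"""Readers and writers for annotated mitogenomes.

Three on-disk forms are supported:

* a tab-separated *feature table* mirroring the layout of published
  mitogenome annotation tables (columns ``Gene name / Start / Stop /
  Strand / Length / Anticodon / Start codon / End codon / Intergenic
  nucleotides``);
* GenBank flat files (any annotated lepidopteran record);
* plain FASTA for the genome sequence (70-column wrap).

On input the derived columns (Length, Intergenic nucleotides) are ignored
— coordinates are authoritative and the derived quantities are recomputed
— but printed lengths are retained on the annotation so that validation
can flag printed-vs-coordinate conflicts.  Thousands separators and
Unicode minus signs are normalized.
"""

from __future__ import annotations

import logging
import re
import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GeneFeature, MitoAnnotation, infer_gclass

log = logging.getLogger(__name__)

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_genbank",
    "read_fasta",
    "write_fasta",
    "extract_region",
    "revcomp",
]

FEATURE_TABLE_COLUMNS = [
    "Gene name", "Start", "Stop", "Strand", "Length",
    "Anticodon", "Start codon", "End codon", "Intergenic nucleotides",
]

_REQUIRED_KEYS = [
    "genename", "start", "stop", "strand",
    "anticodon", "startcodon", "endcodon",
]

# one-letter amino acid of each tRNA anticodon cannot separate the two Ser
# (or Leu) isoacceptors; the anticodon can.
_SER_LEU_BY_ANTICODON = {
    "GCT": "trnS1",  # AGN serine
    "TGA": "trnS2",  # UCN serine
    "TAG": "trnL1",  # CUN leucine
    "TAA": "trnL2",  # UUR leucine
}

_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

_PCG_ALIASES = {
    "cox1": "cox1", "coi": "cox1", "co1": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3",
    "cob": "cob", "cytb": "cob", "cb": "cob",
    "nad1": "nad1", "nd1": "nad1", "nad2": "nad2", "nd2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nad4": "nad4", "nd4": "nad4",
    "nad4l": "nad4l", "nd4l": "nad4l",
    "nad5": "nad5", "nd5": "nad5", "nad6": "nad6", "nd6": "nad6",
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _norm_key(header_cell: str) -> str:
    return re.sub(r"[^a-z0-9]", "", header_cell.lower())


def _norm_number(cell: str) -> str:
    """Strip thousands separators; map Unicode minus to ASCII hyphen."""
    return cell.replace(",", "").replace("−", "-").replace("–", "-").strip()


def _parse_int(cell: str, row: int, col: str) -> int:
    text = _norm_number(cell)
    if not re.fullmatch(r"-?\d+", text):
        raise ValueError(f"row {row}: non-numeric {col} value {cell!r}")
    return int(text)


def _cell(value: str) -> str | None:
    value = value.strip()
    return None if value in ("", "/", "-", "NA") else value


def read_feature_table(path: str | Path) -> MitoAnnotation:
    """Parse a tab-separated annotation table into a :class:`MitoAnnotation`.

    The genome length is taken as the maximum feature end.  ``Length`` and
    ``Intergenic nucleotides`` columns are ignored on input (recomputed
    from coordinates), apart from retaining printed lengths for
    validation.  A strand cell of ``/`` (used for the non-genic control
    region) is stored as J.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty feature table")
    header = [_norm_key(c) for c in lines[0].split("\t")]
    missing = [k for k in _REQUIRED_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    idx = {k: header.index(k) for k in header}

    features: list[GeneFeature] = []
    printed_lengths: dict[str, int] = {}
    seen: set[str] = set()
    for row_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")

        def get(key: str) -> str:
            i = idx.get(key)
            return cells[i] if i is not None and i < len(cells) else ""

        name = get("genename").strip().strip("*")
        if not name:
            raise ValueError(f"row {row_no}: missing gene name")
        gclass = infer_gclass(name)
        if gclass == "control":
            name = "AT_rich"
        if name in seen:
            raise ValueError(f"row {row_no}: duplicate feature name {name!r}")
        seen.add(name)
        start = _parse_int(get("start"), row_no, "Start")
        stop = _parse_int(get("stop"), row_no, "Stop")
        strand = _cell(get("strand")) or "J"
        if strand not in ("J", "N"):
            raise ValueError(f"row {row_no}: strand must be J or N, got {strand!r}")
        anticodon = _cell(get("anticodon"))
        start_codon = _cell(get("startcodon"))
        end_codon = _cell(get("endcodon"))
        if gclass is None:
            # fall back on codon metadata; a bare feature with neither is
            # treated as non-genic
            gclass = "tRNA" if anticodon else ("PCG" if start_codon else "control")
        if "length" in idx and _cell(get("length")):
            printed_lengths[name] = _parse_int(get("length"), row_no, "Length")
        features.append(
            GeneFeature(
                name=name, start=start, end=stop, strand=strand, gclass=gclass,
                anticodon=anticodon, start_codon=start_codon, stop_codon=end_codon,
            )
        )
    genome_length = max(f.end for f in features)
    return MitoAnnotation(
        genome_length=genome_length,
        features=features,
        printed_lengths=printed_lengths,
    )


def write_feature_table(ann: MitoAnnotation, path: str | Path) -> None:
    """Write an annotation as a feature table with recomputed derived columns.

    ``Length`` is ``end - start + 1``; ``Intergenic nucleotides`` is the
    signed gap to the next feature on the circle (blank ``/`` on the
    control-region row, matching published convention).  Reading the file
    back reproduces coordinates, strands and codon annotations exactly.
    """
    from .architecture import adjacency  # local import: avoid cycle

    gaps: dict[str, str] = {}
    if ann.circular and len(ann.features) > 1:
        for j in adjacency(ann).junctions:
            up = ann.feature(j.upstream)
            gaps[j.upstream] = "/" if up.gclass == "control" else str(j.signed_gap)

    rows = ["\t".join(FEATURE_TABLE_COLUMNS)]
    for f in ann.features:
        rows.append(
            "\t".join(
                [
                    f.name, str(f.start), str(f.end),
                    "/" if f.gclass == "control" else f.strand,
                    str(f.length),
                    f.anticodon or "/", f.start_codon or "/", f.stop_codon or "/",
                    gaps.get(f.name, "/"),
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


def _normalize_gene_name(raw: str, anticodon: str | None, ftype: str) -> str | None:
    """Map a GenBank gene/product label onto the standard vocabulary."""
    key = re.sub(r"[^a-z0-9]", "", raw.lower())
    if ftype == "CDS":
        if key in _PCG_ALIASES:
            return _PCG_ALIASES[key]
        for alias, name in _PCG_ALIASES.items():
            if key.startswith(alias):
                return name
        return None
    if ftype == "rRNA":
        if re.search(r"16s|rrnl|largesubunit|lrrna", key):
            return "rrnL"
        if re.search(r"12s|rrns|smallsubunit|srrna", key):
            return "rrnS"
        return None
    if ftype == "tRNA":
        m = re.match(r"trna(?P<aa3>[a-z]{3})|trn(?P<aa1>[a-z])", key)
        aa1 = None
        if m:
            if m.group("aa3") and m.group("aa3").capitalize() in _AA3_TO_1:
                aa1 = _AA3_TO_1[m.group("aa3").capitalize()]
            elif m.group("aa1"):
                aa1 = m.group("aa1").upper()
        if aa1 in ("S", "L"):
            if anticodon and anticodon.upper() in _SER_LEU_BY_ANTICODON:
                return _SER_LEU_BY_ANTICODON[anticodon.upper()]
            m2 = re.search(r"([sl])([12])", key)
            if m2:
                return f"trn{m2.group(1).upper()}{m2.group(2)}"
            return None
        if aa1:
            return f"trn{aa1}"
    return None


def read_genbank(path: str | Path) -> MitoAnnotation:
    """Read a GenBank flat file into the shared annotation model.

    Plus-strand features map to J, minus-strand to N.  Gene names are
    normalized to the standard mitogenome vocabulary; a name that cannot
    be normalized is kept verbatim with a warning.  An unannotated gap
    between ``rrnS`` and ``trnM`` is labeled as the control region.
    Records without an origin sequence yield an annotation with
    ``sequence=None`` and a warning.
    """
    record: SeqRecord = SeqIO.read(str(path), "genbank")
    try:
        sequence = str(record.seq).upper()
        if not sequence:
            raise ValueError("empty")
    except Exception:
        warnings.warn(f"{path}: record has no origin sequence")
        sequence = None
    genome_length = len(sequence) if sequence else int(
        record.annotations.get("sequence_length", 0)
    ) or max(int(f.location.end) for f in record.features)

    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature"):
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or [feat.type])[0]
        if feat.type in ("D-loop", "misc_feature"):
            if not re.search(r"a\+?t[- ]?rich|control", raw, re.I) and feat.type != "D-loop":
                continue
            name, gclass, anticodon = "AT_rich", "control", None
        else:
            anticodon = None
            if "anticodon" in quals:
                m = re.search(r"seq:([acgtu]{3})", quals["anticodon"][0], re.I)
                if m:
                    anticodon = m.group(1).upper().replace("U", "T")
            name = _normalize_gene_name(raw, anticodon, feat.type)
            gclass = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}[feat.type]
            if name is None:
                warnings.warn(f"{path}: could not normalize gene name {raw!r}")
                name = raw
            if gclass == "tRNA" and anticodon is None:
                anticodon = "NNN"  # unannotated anticodon placeholder
        start = int(feat.location.start) + 1  # to 1-based inclusive
        end = int(feat.location.end)
        strand = "N" if feat.location.strand == -1 else "J"
        start_codon = stop_codon = None
        if gclass == "PCG" and sequence:
            cds = sequence[start - 1 : end]
            if strand == "N":
                cds = revcomp(cds)
            start_codon = cds[:3]
            tail = len(cds) % 3
            stop_codon = cds[-tail:] if tail else cds[-3:]
        elif gclass == "PCG":
            start_codon = "NNN"
        features.append(
            GeneFeature(
                name=name, start=start, end=end, strand=strand, gclass=gclass,
                anticodon=anticodon, start_codon=start_codon, stop_codon=stop_codon,
            )
        )

    ann = MitoAnnotation(
        genome_length=genome_length, features=features, sequence=sequence
    )
    if ann.control_region is None:
        _label_control_gap(ann)
    return ann


def _label_control_gap(ann: MitoAnnotation) -> None:
    """Label the unannotated rrnS->trnM gap (wrapping allowed) as control."""
    try:
        rrns, trnm = ann.feature("rrnS"), ann.feature("trnM")
    except KeyError:
        return
    start = rrns.end + 1
    end = trnm.start - 1
    if end < start:  # gap wraps the origin: take the terminal block only
        if rrns.end >= ann.genome_length:
            return
        start, end = rrns.end + 1, ann.genome_length
    ann.features.append(
        GeneFeature(name="AT_rich", start=start, end=end, strand="J", gclass="control")
    )
    ann.features.sort(key=lambda f: (f.start, f.end))


def read_fasta(path: str | Path) -> str:
    """Read the first record of a FASTA file; returns the sequence string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def write_fasta(sequence: str, path: str | Path, name: str = "mitogenome") -> None:
    """Write a single-record FASTA file with 70-column line wrap."""
    from Bio.SeqIO.FastaIO import FastaWriter

    record = SeqRecord(Seq(sequence), id=name, description="")
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file([record])


def extract_region(ann: MitoAnnotation, feature: GeneFeature) -> str:
    """Return the feature's sequence reading 5'->3' in its coding sense.

    J-strand features are the plain slice ``sequence[start..end]``;
    N-strand features are the reverse complement of that slice.
    """
    if ann.sequence is None:
        raise ValueError("no sequence attached to annotation")
    if feature.end > ann.genome_length:
        raise ValueError(
            f"{feature.name}: end {feature.end} exceeds genome length"
        )
    chunk = ann.sequence[feature.start - 1 : feature.end]
    return revcomp(chunk) if feature.strand == "N" else chunk
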