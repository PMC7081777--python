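"""Strand-aware nucleotide composition and skew statistics.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed on
the J strand (the majority strand).  Because the ratio is scale
invariant, the same formula applies to raw counts or to percentages.
All statistics are computed at full precision; rounding to report
precision (percentages 2 dp, skews 3 dp, half-up) happens only at output.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .model import MitoAnnotation

__all__ = [
    "CompositionStats",
    "skew",
    "composition",
    "pcg_concat",
    "pcg_concat_stats",
    "at_rich_stats",
    "composition_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def skew(plus: float, minus: float) -> float | None:
    """Compositional skew ``(plus - minus) / (plus + minus)``.

    Accepts counts or percentages (the ratio is scale invariant).
    Returns None when both inputs are zero (the skew is undefined, and
    reporting 0 would wrongly suggest perfect balance).
    """
    total = plus + minus
    if total == 0:
        return None
    return (plus - minus) / total


@dataclass
class CompositionStats:
    """Base composition of one genomic region (one row of a skew table)."""

    region_label: str
    n: int
    countA: int
    countT: int
    countG: int
    countC: int

    @property
    def pctA(self) -> float:
        return 100.0 * self.countA / self.n

    @property
    def pctT(self) -> float:
        return 100.0 * self.countT / self.n

    @property
    def pctG(self) -> float:
        return 100.0 * self.countG / self.n

    @property
    def pctC(self) -> float:
        return 100.0 * self.countC / self.n

    @property
    def at_content(self) -> float:
        return self.pctA + self.pctT

    @property
    def at_skew(self) -> float | None:
        return skew(self.countA, self.countT)

    @property
    def gc_skew(self) -> float | None:
        return skew(self.countG, self.countC)


def composition(seq: str, label: str = "custom") -> CompositionStats:
    """Count bases and compute composition statistics for one region.

    N bases are excluded from all counts but included in ``n``; any other
    ambiguity code is rejected.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"ambiguity codes other than N not supported: {sorted(bad)}")
    return CompositionStats(
        region_label=label,
        n=len(seq),
        countA=seq.count("A"),
        countT=seq.count("T"),
        countG=seq.count("G"),
        countC=seq.count("C"),
    )


def pcg_concat(ann: MitoAnnotation, strand_mode: str = "j_strand") -> str:
    """Concatenate the 13 protein-coding genes in annotation order.

    ``strand_mode="j_strand"`` (default) takes every gene's J-strand
    projection — N-strand genes are NOT reverse complemented — matching
    the convention of computing all skews on the majority strand.
    ``"coding_sense"`` reverse-complements N-strand genes instead.
    Overlapping genes contribute their shared bases once per gene, so the
    concatenation length is the plain sum of gene lengths.
    """
    if ann.sequence is None:
        raise ValueError("no sequence attached to annotation")
    if strand_mode not in ("j_strand", "coding_sense"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    from .annotation_io import extract_region

    parts = []
    for f in ann.pcgs:
        if strand_mode == "coding_sense":
            parts.append(extract_region(ann, f))
        else:
            parts.append(ann.sequence[f.start - 1 : f.end])
    return "".join(parts)


def pcg_concat_stats(
    ann: MitoAnnotation, strand_mode: str = "j_strand"
) -> CompositionStats:
    """Composition statistics over the concatenated protein-coding genes."""
    missing = {"atp6", "atp8", "cox1", "cox2", "cox3", "cob",
               "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6"} - {
        f.name for f in ann.pcgs
    }
    if missing:
        raise ValueError(f"missing PCGs: {sorted(missing)}")
    return composition(pcg_concat(ann, strand_mode), label="PCGs")


def at_rich_stats(ann: MitoAnnotation) -> CompositionStats:
    """Composition statistics of the control (A+T-rich) region."""
    ctrl = ann.control_region
    if ctrl is None:
        raise ValueError("annotation has no control region")
    if ann.sequence is None:
        raise ValueError("no sequence attached to annotation")
    return composition(ann.sequence[ctrl.start - 1 : ctrl.end], label="AT_rich")


def _fmt_skew(value: float | None) -> float | None:
    return None if value is None else round_half_up(value, 3)


def composition_table(
    anns: list[tuple[str, MitoAnnotation]], strand_mode: str = "j_strand"
) -> pd.DataFrame:
    """Comparative composition table: one row per species per region block.

    Rows follow the published layout (whole genome, concatenated PCGs,
    A+T-rich region), percentages rounded half-up to 2 dp and skews to
    3 dp.  Species whose annotation lacks a control region get no A+T-rich
    row (a warning is logged).
    """
    import logging

    log = logging.getLogger(__name__)
    rows = []
    for label, ann in anns:
        if ann.sequence is None:
            raise ValueError(f"{label}: no sequence attached")
        blocks = [composition(ann.sequence, label="whole"), pcg_concat_stats(ann, strand_mode)]
        if ann.control_region is not None:
            blocks.append(at_rich_stats(ann))
        else:
            log.warning("%s: no control region annotated; A+T-rich row omitted", label)
        for st in blocks:
            rows.append(
                {
                    "species": label,
                    "region": st.region_label,
                    "size_bp": st.n,
                    "pctA": round_half_up(st.pctA, 2),
                    "pctG": round_half_up(st.pctG, 2),
                    "pctT": round_half_up(st.pctT, 2),
                    "pctC": round_half_up(st.pctC, 2),
                    "at_content": round_half_up(st.at_content, 2),
                    "at_skew": _fmt_skew(st.at_skew),
                    "gc_skew": _fmt_skew(st.gc_skew),
                }
            )
    df = pd.DataFrame(rows)
    order = {"whole": 0, "PCGs": 1, "AT_rich": 2}
    return df.sort_values(
        by=["region", "species"], key=lambda s: s.map(order) if s.name == "region" else s,
        kind="stable",
    ).reset_index(drop=True)
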