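"""Synthetic circular mitogenomes with controlled composition and landmarks.

The generator emulates a heavily A+T-biased (~80% A+T) lepidopteran
mitogenome laid out like the *D. stuposa* annotation (13 PCGs, 22 tRNAs,
2 rRNAs, one control region).  Background bases are drawn i.i.d. from
per-base probabilities solved from the target A+T fraction and the
target J-strand AT/GC skews::

    pA = at (1 + sAT) / 2      pT = at (1 - sAT) / 2
    pG = (1 - at)(1 + sGC) / 2  pC = (1 - at)(1 - sGC) / 2

Protein-coding regions are then overwritten with valid ORFs in coding
sense (planned start codon, internal sense codons only, planned stop,
honoring strand), and finally the requested landmarks (the 'ATAGA'
motif, poly-T stretch, (AT)n microsatellite, poly-A run, and the
'ATACTAA' spacer motif) are written at fixed offsets.  A JSON-able
ledger records the exact planted coordinates and final base counts, so
downstream statistics can be checked against generator bookkeeping.
Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation_io import revcomp
from .codon_usage import INVERTEBRATE_MITO, GeneticCode
from .model import GeneFeature, MitoAnnotation

__all__ = ["PlantedMotif", "GenomeSpec", "generate", "perturb", "default_planted_motifs"]


@dataclass(frozen=True)
class PlantedMotif:
    """A literal pattern written at a fixed offset inside a named region.

    ``region`` is ``"control"``, ``"spacer:<up>-<down>"`` (the intergenic
    spacer between two genes) or a gene name; ``offset`` is 1-based
    within the region.  With ``guard=True`` the flanking bases are
    adjusted, if needed, so the planted repeat cannot be extended by the
    random background (keeps planted coordinates exactly recoverable).
    """

    region: str
    pattern: str
    offset: int
    label: str = ""
    guard: bool = False


def default_planted_motifs() -> list[PlantedMotif]:
    """The control-region landmark architecture plus the spacer motif."""
    return [
        PlantedMotif("control", "ATAGA", 11, label="ATAGA"),
        PlantedMotif("control", "T" * 20, 16, label="polyT", guard=True),
        PlantedMotif("control", "AT" * 10, 61, label="AT_microsat", guard=True),
        PlantedMotif("control", "A" * 12, 381, label="polyA", guard=True),
        PlantedMotif("spacer:trnS2-nad1", "ATACTAA", 8, label="ATACTAA"),
    ]


@dataclass
class GenomeSpec:
    """Parameters of one synthetic mitogenome.

    Defaults reproduce the study conditions: the published 38-feature
    layout, A+T fraction 0.80, whole-genome AT skew -0.005 and GC skew
    -0.236, per-gene start/stop codons as annotated (CGA start for cox1,
    incomplete "TA" stop for nad4), and the full set of control-region
    landmarks.
    """

    template: MitoAnnotation | None = None  # None -> published D. stuposa layout
    genome_length: int | None = None  # bare circle when template has no features
    at_target: float = 0.80
    at_skew_target: float = -0.005
    gc_skew_target: float = -0.236
    planted_motifs: list[PlantedMotif] = field(default_factory=default_planted_motifs)
    start_codon_plan: dict[str, str] = field(default_factory=dict)
    stop_codon_plan: dict[str, str] = field(default_factory=dict)
    code: GeneticCode = field(default=INVERTEBRATE_MITO)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.at_target < 1.0:
            raise ValueError("at_target must be in (0, 1)")
        for s in (self.at_skew_target, self.gc_skew_target):
            if not -1.0 <= s <= 1.0:
                raise ValueError("skew targets must lie in [-1, 1]")

    def base_probabilities(self) -> dict[str, float]:
        at, gc = self.at_target, 1.0 - self.at_target
        return {
            "A": at * (1 + self.at_skew_target) / 2,
            "T": at * (1 - self.at_skew_target) / 2,
            "G": gc * (1 + self.gc_skew_target) / 2,
            "C": gc * (1 - self.gc_skew_target) / 2,
        }


def _template(spec: GenomeSpec) -> MitoAnnotation:
    if spec.template is not None:
        return spec.template
    if spec.genome_length is not None:
        return MitoAnnotation(genome_length=spec.genome_length, features=[])
    from .refdata import dstuposa_annotation

    return dstuposa_annotation()


def _resolve_region(ann: MitoAnnotation, region: str) -> tuple[int, int]:
    """1-based inclusive genome coordinates of a plantable region."""
    if region == "control":
        ctrl = ann.control_region
        if ctrl is None:
            raise ValueError("template has no control region")
        return ctrl.start, ctrl.end
    if region.startswith("spacer:"):
        up_name, down_name = region.removeprefix("spacer:").split("-", 1)
        up, down = ann.feature(up_name), ann.feature(down_name)
        if down.start - up.end < 2:
            raise ValueError(f"no spacer between {up_name} and {down_name}")
        return up.end + 1, down.start - 1
    feat = ann.feature(region)
    return feat.start, feat.end


def _sample_orf(
    rng: np.random.Generator,
    length: int,
    start: str,
    stop: str,
    code: GeneticCode,
    base_probs: dict[str, float],
) -> str:
    """A coding-sense gene: planned start, sense interior, planned stop.

    Interior codons are drawn from the sense codons with probability
    proportional to the product of the per-base probabilities, so coding
    regions keep (approximately) the genome-wide A+T bias; excluding the
    two stop codons perturbs the realized composition only slightly.
    The assembly is resampled if truncation creates an in-frame stop.
    """
    if length < len(start) + len(stop):
        raise ValueError("gene too short for its start/stop plan")
    sense = code.sense_codons
    w = np.array([np.prod([base_probs[b] for b in c]) for c in sense])
    w /= w.sum()
    interior_len = length - len(start) - len(stop)
    for _ in range(100):
        n_codons = -(-interior_len // 3)
        interior = "".join(rng.choice(sense, size=n_codons, p=w)) if n_codons else ""
        seq = start + interior[:interior_len] + stop
        frame_codons = [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]
        if not any(code.codon_to_aa[c] == "*" for c in frame_codons[1:-1]):
            return seq
    raise RuntimeError("could not sample a stop-free interior")


def generate(spec: GenomeSpec) -> tuple[MitoAnnotation, dict]:
    """Generate one synthetic mitogenome and its bookkeeping ledger.

    Returns the annotation (with sequence attached and feature codon
    metadata set to the realized plans) and a ledger recording the seed,
    sampling probabilities, planted landmark coordinates (region-local
    and absolute) and final base counts.
    """
    template = _template(spec)
    n = template.genome_length
    rng = np.random.default_rng(spec.seed)
    probs = spec.base_probabilities()
    bases = np.array(list("ATGC"))
    p = np.array([probs[b] for b in "ATGC"])
    seq = rng.choice(bases, size=n, p=p / p.sum())

    # --- overwrite PCGs with valid ORFs -------------------------------
    features: list[GeneFeature] = []
    pcg_plan: dict[str, dict[str, str]] = {}
    pcg_spans: list[tuple[int, int, str]] = []
    for feat in template.features:
        if feat.gclass != "PCG":
            features.append(feat.copy())
            continue
        start_codon = spec.start_codon_plan.get(feat.name, feat.start_codon or "ATT")
        stop_codon = spec.stop_codon_plan.get(feat.name, feat.stop_codon or "TAA")
        coding = _sample_orf(
            rng, feat.length, start_codon, stop_codon, spec.code, probs
        )
        chunk = coding if feat.strand == "J" else revcomp(coding)
        seq[feat.start - 1 : feat.end] = list(chunk)
        features.append(feat.copy(start_codon=start_codon, stop_codon=stop_codon))
        pcg_plan[feat.name] = {"start": start_codon, "stop": stop_codon}
        pcg_spans.append((feat.start, feat.end, feat.name))

    # Overlapping PCGs (atp8/atp6 in the standard layout) share bases, so
    # a later ORF write can clobber an earlier gene's terminus; re-assert
    # every planned start/stop so the codon audit sees the plan.
    for feat in features:
        if feat.gclass != "PCG":
            continue
        start_c, stop_c = feat.start_codon, feat.stop_codon
        if feat.strand == "J":
            seq[feat.start - 1 : feat.start + 2] = list(start_c)
            seq[feat.end - len(stop_c) : feat.end] = list(stop_c)
        else:
            seq[feat.end - 3 : feat.end] = list(revcomp(start_c))
            seq[feat.start - 1 : feat.start - 1 + len(stop_c)] = list(revcomp(stop_c))

    # --- plant landmarks (written last) -------------------------------
    planted_log = []
    planted_spans: list[tuple[int, int, str]] = []
    for motif in spec.planted_motifs:
        r_start, r_end = _resolve_region(template, motif.region)
        g_start = r_start + motif.offset - 1
        g_end = g_start + len(motif.pattern) - 1
        if motif.offset < 1 or g_end > r_end:
            raise ValueError(
                f"{motif.label or motif.pattern}: does not fit inside {motif.region}"
            )
        for s, e, name in pcg_spans:
            if g_start <= e and g_end >= s:
                raise ValueError(
                    f"planted motif {motif.label or motif.pattern} collides with "
                    f"coding gene {name}"
                )
        for s, e, lbl in planted_spans:
            if g_start <= e and g_end >= s:
                raise ValueError(
                    f"planted motif {motif.label or motif.pattern} collides with "
                    f"planted motif {lbl}"
                )
        seq[g_start - 1 : g_end] = list(motif.pattern)
        if motif.guard:
            _guard_flanks(seq, g_start, g_end, motif.pattern, planted_spans, pcg_spans)
        planted_spans.append((g_start, g_end, motif.label or motif.pattern))
        planted_log.append(
            {
                "region": motif.region,
                "label": motif.label or motif.pattern,
                "pattern": motif.pattern,
                "region_start": motif.offset,
                "genome_start": g_start,
                "length": len(motif.pattern),
            }
        )

    sequence = "".join(seq)
    ledger = {
        "seed": spec.seed,
        "genome_length": n,
        "base_probabilities": probs,
        "at_target": spec.at_target,
        "at_skew_target": spec.at_skew_target,
        "gc_skew_target": spec.gc_skew_target,
        "base_counts": {b: sequence.count(b) for b in "ACGT"},
        "pcg_plan": pcg_plan,
        "planted": planted_log,
    }
    ann = MitoAnnotation(
        genome_length=n,
        features=features,
        sequence=sequence,
        circular=template.circular,
    )
    return ann, ledger


def _guard_flanks(seq, g_start: int, g_end: int, pattern: str, planted, pcgs) -> None:
    """Break accidental extension of a planted repeat by the background.

    The base immediately left of the plant must differ from the
    pattern's last base, and the base immediately right from its first
    base; offending random bases are flipped (never inside another
    planted motif or a coding gene).
    """
    n = len(seq)

    def protected(pos: int) -> bool:
        return any(s <= pos <= e for s, e, _ in list(planted) + list(pcgs))

    for pos, clash in ((g_start - 1, pattern[-1]), (g_end + 1, pattern[0])):
        if 1 <= pos <= n and not protected(pos) and seq[pos - 1] == clash:
            seq[pos - 1] = "C" if clash != "C" else "G"


def perturb(
    ann: MitoAnnotation, op: str, gene: str, shift: int = 1
) -> MitoAnnotation:
    """Return a defective copy of an annotation for negative-path tests.

    ``shift_gene`` moves a feature's coordinates without moving the
    sequence (the audit then sees frame-shifted codons); ``delete_gene``
    drops the feature (validation reports it missing); ``break_stop``
    rewrites a PCG's stop codon in the sequence to CCC (the audit then
    sees a non-canonical stop).
    """
    feat = ann.feature(gene)
    if op == "shift_gene":
        new_feat = feat.copy(start=feat.start + shift, end=feat.end + shift)
        others = [f.copy() for f in ann.features if f.name != gene]
        return ann.copy(features=others + [new_feat])
    if op == "delete_gene":
        return ann.copy(features=[f.copy() for f in ann.features if f.name != gene])
    if op == "break_stop":
        if feat.gclass != "PCG" or ann.sequence is None:
            raise ValueError("break_stop requires a PCG and a sequence")
        stop_len = min(3, feat.length)
        seq = list(ann.sequence)
        if feat.strand == "J":
            seq[feat.end - stop_len : feat.end] = list("CCC"[:stop_len])
        else:
            seq[feat.start - 1 : feat.start - 1 + stop_len] = list(
                revcomp("CCC"[:stop_len])
            )
        return ann.copy(sequence="".join(seq))
    raise ValueError(f"unknown perturbation {op!r}")
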