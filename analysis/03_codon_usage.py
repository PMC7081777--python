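#!/usr/bin/env python
"""Codon usage of the synthetic genome: counts, CDspT, RSCU, audit.

Writes the long-format codon table and the per-gene start/stop audit, and
prints the most/least used amino acids and any absent codons.
"""

from pathlib import Path

import pandas as pd

from mitocomp.annotation_io import read_fasta, read_feature_table
from mitocomp.cli import codon_table
from mitocomp.codon_usage import aa_cdspt, codon_audit, codon_usage, coding_sequences

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    syn = RESULTS / "synthetic"
    ann = read_feature_table(syn / "features.tsv")
    seq = read_fasta(syn / "genome.fasta")
    ann = ann.copy(sequence=seq, genome_length=len(seq))

    codon_table(ann).to_csv(RESULTS / "codon_usage.tsv", sep="\t", index=False)
    table = codon_usage(coding_sequences(ann))
    per_aa = sorted(aa_cdspt(table).items(), key=lambda kv: -kv[1])
    print(f"total sense codons: {table.total_codons}")
    print("top amino acids (CDspT):",
          ", ".join(f"{aa} {v:.0f}" for aa, v in per_aa[:6]))
    print("rarest amino acid:", per_aa[-1][0])
    print("absent codons:", sorted(table.absent_codons) or "none")

    audit = pd.DataFrame(
        [
            {
                "gene": a.gene, "strand": a.strand,
                "start": a.observed_start, "start_canonical": a.start_canonical,
                "stop": a.observed_stop, "incomplete_stop": a.incomplete_stop,
                "mismatch": a.start_mismatch or a.stop_mismatch,
            }
            for a in codon_audit(ann)
        ]
    )
    audit.to_csv(RESULTS / "codon_audit.tsv", sep="\t", index=False)
    flagged = audit[~audit.start_canonical | audit.incomplete_stop]
    print("non-canonical starts / incomplete stops:")
    print(flagged.to_string(index=False))


if __name__ == "__main__":
    main()
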