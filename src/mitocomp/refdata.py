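"""Bundled reference tables for *Dysgonia stuposa* and related Noctuoidea.

Two small published tables ship with the package:

* the 38-row annotation table of the *D. stuposa* mitogenome
  (37 genes + control region, genome length 15,721 bp);
* the composition/skew comparison across seven Noctuoidea species
  (whole genome / concatenated PCGs / A+T-rich region), as printed,
  i.e. percentages at 2 dp and skews at 3 dp.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotation_io import read_feature_table
from .model import MitoAnnotation

__all__ = ["dstuposa_annotation", "noctuoidea_composition"]


def _data_path(filename: str):
    return resources.files("mitocomp.data").joinpath(filename)


def dstuposa_annotation() -> MitoAnnotation:
    """The published *D. stuposa* annotation (coordinates, no sequence)."""
    with resources.as_file(_data_path("dstuposa_feature_table.tsv")) as p:
        return read_feature_table(p)


def noctuoidea_composition() -> pd.DataFrame:
    """Printed composition/skew table for seven Noctuoidea mitogenomes.

    Columns: species, region (whole|PCGs|AT_rich), size_bp, pctA, pctG,
    pctT, pctC, at_content, at_skew, gc_skew.
    """
    with resources.as_file(_data_path("noctuoidea_composition.tsv")) as p:
        return pd.read_csv(p, sep="\t")
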