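"""Bundled reference tables for the bioluminescent-protein analyses.

Four small per-residue TSV tables ship with the package: the published
amino-acid propensity scores and class compositions of the BLP-vs-non-BLP
and luciferase-vs-fluorescent-protein scoring cards, the four AAindex-derived
physicochemical property scales used to characterize BLPs, and the
compositions of integral membrane and nuclear proteins used in the
localization analysis. All tables are indexed by one-letter residue code
in alphabetical order; compositions are percentages.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .alphabet import AMINO_ACIDS
from .analyze import PropertyTable

__all__ = [
    "blp_scorecard_reference",
    "lfp_scorecard_reference",
    "blp_localization_reference",
    "aa_property_reference",
]


def _load(name: str) -> pd.DataFrame:
    path = resources.files("seqscm.data").joinpath(name)
    with resources.as_file(path) as p:
        frame = pd.read_csv(p, sep="\t", comment="#", index_col="residue")
    assert list(frame.index) == sorted(AMINO_ACIDS)
    return frame


def blp_scorecard_reference() -> pd.DataFrame:
    """Amino-acid scores and class compositions, BLP vs non-BLP task.

    Columns: ``score`` (propensity in [0, 1000]), ``comp_pos`` /
    ``comp_neg`` (class amino-acid composition, percent).
    """
    return _load("blp_scorecard_reference.tsv")


def lfp_scorecard_reference() -> pd.DataFrame:
    """Amino-acid scores and compositions, luciferase vs FP task.

    Columns: ``score``, ``comp_pos`` (luciferases), ``comp_neg``
    (fluorescent proteins), ``comp_membrane`` (integral membrane
    proteins), all compositions in percent.
    """
    return _load("lfp_scorecard_reference.tsv")


def blp_localization_reference() -> pd.DataFrame:
    """Compositions of BLPs, membrane proteins and nuclear proteins (%)."""
    return _load("blp_localization_reference.tsv")


def aa_property_reference() -> PropertyTable:
    """Four physicochemical property scales as a :class:`PropertyTable`."""
    return PropertyTable(_load("aa_property_reference.tsv"))
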