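"""Bundled published reference tables.

Small plain-text tables from the original adzuki bean weevil
(*Callosobruchus chinensis*) marker-development survey, shipped with the
package so the summary arithmetic the survey reports — across-locus
diversity means, filtering effective rate, genome base composition and
the primer-screen polymorphism rate — can be recomputed from the printed
inputs without any external download.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd


def _data(name: str):
    return resources.files("ssrforge").joinpath("data", name)


def load_marker_diversity() -> pd.DataFrame:
    """Per-locus diversity of the 20 validated markers across 18 populations.

    Columns: locus, na (allele count), he (expected heterozygosity),
    ho (observed heterozygosity), shannon_i (Shannon's information index).
    """
    with resources.as_file(_data("marker_diversity.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_sequencing_summary() -> dict:
    """Raw/clean read counts per lane, genome base counts, and the
    500-primer validation screen tallies."""
    with resources.as_file(_data("sequencing_summary.json")) as p:
        return json.loads(p.read_text())
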