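"""Bundled published reference tables for desk-scale regression checks.

These are the printed association tables from the oral-cancer metabolite
screening study the package is modelled on: the mediation-pathway effect
table, the per-association heterogeneity (Cochran's Q) p-values, and the
Steiger directionality p-values. They serve as fixed inputs for verifying
the mediation arithmetic and report parsing, not as computed outputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("mrmediate").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_mediation_reference() -> pd.DataFrame:
    """15 published exposure -> mediator -> outcome pathways.

    Columns: exposure, mediator, outcome_id, beta_all (total effect),
    beta_mediation (printed to 3 significant figures), reported_ratio.
    """
    return _load("mediation_pathways.tsv")


def load_heterogeneity_reference() -> pd.DataFrame:
    """Published Cochran's Q p-values per metabolite-outcome association."""
    return _load("heterogeneity_qpvals.tsv")


def load_steiger_reference() -> pd.DataFrame:
    """Published Steiger directionality results per association."""
    return _load("steiger_directionality.tsv")
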