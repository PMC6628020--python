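"""Bundled example data.

``chga_colon_tables()`` returns the five published 2x2 diagnostic tables for
chromogranin-A (CHGA) expression as an early colon-cancer marker: logistic
classification of four GEO microarray cohorts (GSE44076 contributing two
control arms — healthy donors and patients' normal adjacent mucosa).  They
are the canonical small input for the meta-analysis and SROC stages and need
no expression data.
"""

from __future__ import annotations

from importlib import resources

from .classify import ConfusionTable, read_tables

__all__ = ["chga_colon_tables"]


def chga_colon_tables() -> list[ConfusionTable]:
    """Five CHGA colon-cancer confusion tables (TP, FP, FN, TN per cohort)."""
    ref = resources.files("dtameta.data").joinpath("chga_colon_2x2.csv")
    with resources.as_file(ref) as path:
        return read_tables(path)
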