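"""AP-MS high-confidence interactor calling from spectral-count tables.

Bait pull-downs are compared with a control pull-down.  After removing
flagged external contaminants (keratins, albumin, casein, immunoglobulins,
protease carry-over, ...), a protein is called a high-confidence interactor
iff

* it was seen only in the bait experiments (control sequences = 0,
  bait sequences > 0), OR its bait sequence count is at least ``ratio``
  (default 3) times the control count; AND
* it was identified by more than one high-confidence peptide in at least
  one replicate (``min_peptides`` = 2 by default).

"Sequences" are summed matched-sequence (spectral) counts per experiment
arm, pooled across replicates.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["remove_contaminants", "call_interactors", "peptide_columns"]


def peptide_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("peptides_rep")]
    if not cols:
        raise ValueError("table has no peptides_rep<i> columns")
    return cols


def remove_contaminants(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows flagged as external contaminants; others untouched."""
    if "is_contaminant" not in table.columns:
        raise ValueError("table has no is_contaminant column")
    return table[~table["is_contaminant"].astype(bool)].reset_index(drop=True)


def call_interactors(
    table: pd.DataFrame, ratio: float = 3.0, min_peptides: int = 2
) -> pd.DataFrame:
    """Apply the bait-only / >=ratio rule plus the replicate peptide rule.

    Expects contaminants already removed.  Returns the table with an
    ``interactor`` boolean column; exactly ratio-fold counts as passing.
    """
    if ratio <= 1:
        raise ValueError("ratio must be > 1")
    if table["is_contaminant"].astype(bool).any():
        raise ValueError("remove contaminants before calling interactors")
    bait = table["bait_sequences"].to_numpy()
    ctrl = table["control_sequences"].to_numpy()
    if (bait < 0).any() or (ctrl < 0).any():
        raise ValueError("negative sequence counts")
    bait_only = (ctrl == 0) & (bait > 0)
    enriched = (ctrl > 0) & (bait >= ratio * ctrl)
    pep = table[peptide_columns(table)].to_numpy()
    peptide_ok = (pep >= min_peptides).any(axis=1)
    out = table.copy()
    out["interactor"] = (bait_only | enriched) & peptide_ok
    return out
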