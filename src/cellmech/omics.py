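"""Fold-change filters for gene and metabolite tables.

Input tables carry pre-normalized control/treated levels per feature.
Genes pass at a symmetric fold-change cutoff (ratio or its reciprocal
above 3 by default, so down-regulation is treated like up-regulation);
metabolites pass when the absolute relative change exceeds 20% by
default.  Flagged features are exported as a combined node table for
downstream network tools.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

NODE_COLUMNS = ["feature_id", "feature_class", "direction", "magnitude"]


def _validate_levels(table: pd.DataFrame) -> pd.Series:
    """Boolean validity per row; warns about non-positive levels."""
    valid = (table["control"] > 0) & (table["treated"] > 0)
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("%d feature(s) with non-positive levels skipped", n_bad)
    return valid


def fold_change_filter(table: pd.DataFrame, gene_cutoff: float = 3.0) -> pd.DataFrame:
    """Flag genes whose symmetric fold change exceeds the cutoff.

    Adds ``fold_change`` (treated/control), ``symmetric_fold_change``
    (``max(r, 1/r)``), ``direction``, ``valid`` and ``passes_filter``.
    A gene passes iff ``symmetric_fold_change > gene_cutoff`` (strict),
    so both 4-fold up and 4-fold down pass the default 3-fold cutoff.
    Features with non-positive levels are marked invalid and never
    pass; they are counted in a warning, not dropped.
    """
    if gene_cutoff < 1:
        raise ValueError("gene_cutoff is a ratio and must be >= 1")
    out = table.copy()
    valid = _validate_levels(out)
    ratio = np.where(valid, out["treated"] / out["control"], np.nan)
    out["fold_change"] = ratio
    out["symmetric_fold_change"] = np.where(valid, np.maximum(ratio, 1 / ratio), np.nan)
    out["direction"] = np.where(ratio >= 1, "up", "down")
    out["valid"] = valid
    out["passes_filter"] = valid & (out["symmetric_fold_change"] > gene_cutoff)
    return out


def metabolite_change_filter(table: pd.DataFrame, cutoff: float = 0.20) -> pd.DataFrame:
    """Flag metabolites whose absolute relative change exceeds the cutoff.

    Adds ``pct_change`` (``(treated - control) / control``), ``direction``,
    ``valid`` and ``passes_filter``; a metabolite passes iff
    ``|pct_change| > cutoff`` (20% by default, either direction).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    out = table.copy()
    valid = _validate_levels(out)
    change = np.where(valid, (out["treated"] - out["control"]) / out["control"], np.nan)
    out["pct_change"] = change
    out["direction"] = np.where(change >= 0, "up", "down")
    out["valid"] = valid
    out["passes_filter"] = valid & (np.abs(change) > cutoff)
    return out


def export_network_nodes(
    gene_table: pd.DataFrame,
    metabolite_table: pd.DataFrame,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Combine flagged features into one node table (id, class, direction, magnitude).

    Gene magnitude is the symmetric fold change; metabolite magnitude is
    the absolute relative change.  Written as CSV when ``path`` is given
    (an empty table still gets its header).
    """
    genes = gene_table[gene_table["passes_filter"]]
    mets = metabolite_table[metabolite_table["passes_filter"]]
    rows = []
    for _, r in genes.iterrows():
        rows.append((r["feature_id"], "gene", r["direction"], float(r["symmetric_fold_change"])))
    for _, r in mets.iterrows():
        rows.append((r["feature_id"], "metabolite", r["direction"], float(abs(r["pct_change"]))))
    nodes = pd.DataFrame(rows, columns=NODE_COLUMNS)
    if path is not None:
        nodes.to_csv(path, index=False)
    return nodes
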