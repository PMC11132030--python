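"""Consensus aggregation of ligand-receptor interaction (LRI) calls.

Three upstream inference methods emit tables in different dialects:

* CellPhoneDB-like: pooled table with a p-value per interaction; an
  interaction is significant when p < 0.05 (strict).
* NATMI-like: no p-value; interactions are ranked by the geometric mean of
  edge weight and specificity, and the top 20% per receiving cell type are
  taken as true (ceil rounding, ties broken by score then ligand/receptor
  name).
* Scriabin-like: one table per patient, each with p-values; an interaction
  counts when it is significant (p < 0.05) in at least 3 distinct patients.

The consensus table reports, per (ligand, receptor, sender, receiver), how
many of the three methods called the interaction (method_count 0-3).
"""

from __future__ import annotations

from math import ceil

import numpy as np
import pandas as pd

__all__ = [
    "KEY",
    "filter_cpdb",
    "filter_natmi",
    "filter_scriabin",
    "consensus",
]

KEY = ["ligand", "receptor", "sender", "receiver"]


def _normalize_keys(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    missing = set(KEY) - set(out.columns)
    if missing:
        raise ValueError(f"LRI table missing key columns: {sorted(missing)}")
    for col in KEY:
        out[col] = out[col].astype(str).str.strip().str.upper()
    return out


def _key_tuples(table: pd.DataFrame) -> set[tuple[str, ...]]:
    return set(map(tuple, table[KEY].itertuples(index=False, name=None)))


def filter_cpdb(table: pd.DataFrame, alpha: float = 0.05) -> set[tuple[str, ...]]:
    """Interactions with p strictly below alpha."""
    t = _normalize_keys(table)
    return _key_tuples(t[t["p_value"].astype(float) < alpha])


def natmi_score(weight, specificity):
    """Geometric mean of edge weight and specificity."""
    w = np.asarray(weight, dtype=float)
    s = np.asarray(specificity, dtype=float)
    if (w < 0).any() or (s < 0).any():
        raise ValueError("weight and specificity must be non-negative")
    return np.sqrt(w * s)


def filter_natmi(table: pd.DataFrame, top_fraction: float = 0.2) -> set[tuple[str, ...]]:
    """Top-``top_fraction`` interactions per receiving cell type.

    Rank within each receiver by geometric mean of weight and specificity;
    keep rank <= ceil(top_fraction * n). Ties break by score (descending)
    then (ligand, receptor) lexicographically for determinism.
    """
    t = _normalize_keys(table)
    t = t.assign(_score=natmi_score(t["weight"], t["specificity"]))
    kept: set[tuple[str, ...]] = set()
    for _, grp in t.groupby("receiver", sort=False):
        k = ceil(top_fraction * len(grp))
        ordered = grp.sort_values(
            by=["_score", "ligand", "receptor"], ascending=[False, True, True]
        )
        kept |= _key_tuples(ordered.head(k))
    return kept


def filter_scriabin(
    per_patient_tables: dict[str, pd.DataFrame] | list[pd.DataFrame],
    alpha: float = 0.05,
    min_patients: int = 3,
) -> set[tuple[str, ...]]:
    """Interactions significant (p < alpha) in at least ``min_patients`` patients.

    Only significant detections count toward the recurrence rule: an
    interaction present in 3 patients but significant in only 2 is dropped.
    """
    if isinstance(per_patient_tables, dict):
        tables = list(per_patient_tables.values())
    else:
        tables = list(per_patient_tables)
    if len(tables) < min_patients:
        raise ValueError(
            f"need per-patient tables from >= {min_patients} patients, got {len(tables)}"
        )
    counts: dict[tuple[str, ...], int] = {}
    for tab in tables:
        t = _normalize_keys(tab)
        sig = _key_tuples(t[t["p_value"].astype(float) < alpha])
        for key in sig:  # one count per patient regardless of duplicate rows
            counts[key] = counts.get(key, 0) + 1
    return {k for k, c in counts.items() if c >= min_patients}


def consensus(
    cpdb_table: pd.DataFrame,
    natmi_table: pd.DataFrame,
    scriabin_tables: dict[str, pd.DataFrame] | list[pd.DataFrame],
    alpha: float = 0.05,
    min_patients: int = 3,
) -> pd.DataFrame:
    """Method-count consensus over the union of all reported interactions.

    method_count is the number of methods (0-3) whose filtering rule keeps
    the interaction; the table is sorted by (method_count desc, NATMI score
    desc) and is independent of input row order.
    """
    cpdb_set = filter_cpdb(cpdb_table, alpha)
    natmi_set = filter_natmi(natmi_table)
    scriabin_set = filter_scriabin(scriabin_tables, alpha, min_patients)

    nat = _normalize_keys(natmi_table)
    nat_scores = (
        nat.assign(_score=natmi_score(nat["weight"], nat["specificity"]))
        .groupby(KEY)["_score"]
        .max()
    )

    universe = _key_tuples(_normalize_keys(cpdb_table)) | _key_tuples(nat)
    if isinstance(scriabin_tables, dict):
        scr_list = list(scriabin_tables.values())
    else:
        scr_list = list(scriabin_tables)
    for tab in scr_list:
        universe |= _key_tuples(_normalize_keys(tab))

    rows = []
    for key in sorted(universe):
        in_cpdb = key in cpdb_set
        in_natmi = key in natmi_set
        in_scriabin = key in scriabin_set
        rows.append(
            {
                **dict(zip(KEY, key)),
                "in_cpdb": in_cpdb,
                "in_natmi": in_natmi,
                "in_scriabin": in_scriabin,
                "natmi_score": float(nat_scores.get(key, np.nan)),
                "method_count": int(in_cpdb) + int(in_natmi) + int(in_scriabin),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=KEY + ["in_cpdb", "in_natmi", "in_scriabin", "natmi_score", "method_count"],
    )
    return out.sort_values(
        by=["method_count", "natmi_score"] + KEY,
        ascending=[False, False] + [True] * len(KEY),
        na_position="last",
    ).reset_index(drop=True)
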