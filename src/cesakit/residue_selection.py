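"""Strong-contact residue selection and side-chain chemistry classes.

The selection rule mirrors the mutagenesis-guidance criterion of the study
this pipeline supports: a residue is selected when its total contact time
is at least a threshold (default 80%, inclusive) for at least a minimum
number (default 2) of the three monomer channels of the homotrimer.

The five-way side-chain chemistry partition covers all 20 standard
residues.  Histidine is classified cationic here even though it is treated
as a π ring by the CH-π detector; the two tables are independent and the
assignment is config-overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CHEMICAL_CLASSES",
    "SelectionReport",
    "strong_contact_filter",
    "classify_side_chain",
    "build_summary",
]

CHEMICAL_CLASSES: dict[str, str] = {
    **{r: "cationic" for r in ("ARG", "LYS", "HIS")},
    **{r: "anionic" for r in ("ASP", "GLU")},
    **{r: "aromatic" for r in ("PHE", "TRP", "TYR")},
    **{r: "polar-uncharged" for r in ("SER", "THR", "ASN", "GLN", "CYS")},
    **{r: "non-polar-aliphatic" for r in ("GLY", "ALA", "VAL", "LEU", "ILE",
                                          "PRO", "MET")},
}

CLASS_ORDER = ["cationic", "anionic", "polar-uncharged", "aromatic",
               "non-polar-aliphatic"]


@dataclass
class SelectionReport:
    selected: list[int]
    unselected: list[int]
    class_counts: dict[str, int]
    table: pd.DataFrame
    threshold: float = 80.0
    min_chains: int = 2


def classify_side_chain(residue_name: str,
                        overrides: dict[str, str] | None = None) -> str:
    """Chemical class of a standard 3-letter residue code."""
    code = residue_name.upper()
    if overrides and code in overrides:
        return overrides[code]
    try:
        return CHEMICAL_CLASSES[code]
    except KeyError:
        raise ValueError(f"unknown residue code {residue_name!r}") from None


def strong_contact_filter(records: pd.DataFrame, threshold: float = 80.0,
                          min_chains: int = 2) -> list[int]:
    """Residue indices passing the strong-contact criterion.

    ``records`` is a tidy table with one row per residue×monomer-chain and
    columns ``residue_index`` and ``total_contact_time`` (percent).  A
    residue passes when at least ``min_chains`` of its chain values are
    ≥ ``threshold`` (both comparisons inclusive).
    """
    if records.empty:
        raise ValueError("no contact records to filter")
    required = {"residue_index", "total_contact_time"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    selected = []
    for resid, grp in records.groupby("residue_index"):
        values = grp["total_contact_time"].to_numpy(dtype=float)
        if np.any((values < 0) | (values > 100)):
            raise ValueError(f"total_contact_time outside [0, 100] for {resid}")
        if len(values) < min_chains:
            warnings.warn(
                f"residue {resid} has only {len(values)} chain values; "
                f"unselectable with min_chains={min_chains}", stacklevel=2,
            )
            continue
        if int((values >= threshold).sum()) >= min_chains:
            selected.append(int(resid))
    return sorted(selected)


def build_summary(records: pd.DataFrame, threshold: float = 80.0,
                  min_chains: int = 2,
                  regions: pd.DataFrame | None = None,
                  extra_metrics: pd.DataFrame | None = None,
                  class_overrides: dict[str, str] | None = None
                  ) -> SelectionReport:
    """Join metric tables, apply the filter, and classify the selected set.

    ``records`` needs residue_index, residue_name, total_contact_time (one
    row per residue×chain).  ``regions`` optionally maps residue ranges to
    annotations (columns residue_start, residue_end, region).
    ``extra_metrics`` rows are joined on (residue_index, chain) when given;
    unknown keys raise with the orphan list.
    """
    required = {"residue_index", "residue_name", "total_contact_time"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    table = records.copy()
    if extra_metrics is not None:
        join_keys = [k for k in ("residue_index", "chain") if
                     k in table.columns and k in extra_metrics.columns]
        if not join_keys:
            raise ValueError("extra_metrics shares no join keys with records")
        orphans = set(map(tuple, extra_metrics[join_keys].values)) - \
            set(map(tuple, table[join_keys].values))
        if orphans:
            raise ValueError(f"extra_metrics rows with no matching record: "
                             f"{sorted(orphans)[:10]}")
        table = table.merge(extra_metrics, on=join_keys, how="left")
    if regions is not None:
        def annotate(resid: int) -> str:
            hit = regions[(regions["residue_start"] <= resid) &
                          (resid <= regions["residue_end"])]
            return str(hit["region"].iloc[0]) if len(hit) else "other"
        table["region"] = table["residue_index"].map(annotate)
    selected = strong_contact_filter(table, threshold, min_chains)
    all_residues = sorted(int(r) for r in table["residue_index"].unique())
    unselected = [r for r in all_residues if r not in set(selected)]
    names = (table.drop_duplicates("residue_index")
             .set_index("residue_index")["residue_name"].to_dict())
    counts = {c: 0 for c in CLASS_ORDER}
    for resid in selected:
        counts[classify_side_chain(names[resid], class_overrides)] += 1
    table = table.sort_values(["residue_index", *(
        ["chain"] if "chain" in table.columns else [])]).reset_index(drop=True)
    return SelectionReport(selected=selected, unselected=unselected,
                           class_counts=counts, table=table,
                           threshold=threshold, min_chains=min_chains)
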