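"""Parcellation tables: ROI -> network membership.

The default table emulates a 454-parcel scheme (400 cortical parcels spread
over the seven canonical cortical networks, plus 54 subcortical parcels), the
standard input space for frame-wise co-activation pattern analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical cortical network labels (7-network scheme) and the approximate
#: share of cortical parcels each holds in the 400-parcel atlas.
CORTICAL_NETWORKS = (
    "Vis",
    "SomMot",
    "DorsAttn",
    "SalVentAttn",
    "Limbic",
    "Cont",
    "Default",
)
_CORTICAL_SHARES = np.array([61, 77, 46, 47, 26, 52, 91], dtype=float)

SUBCORTICAL = "subcortical"

PARCEL_COLUMNS = ["parcel_id", "name", "network", "source"]


def default_parcel_table(n_cortical: int = 400, n_subcortical: int = 54) -> pd.DataFrame:
    """Build the default parcel table.

    Parameters
    ----------
    n_cortical, n_subcortical : int
        Number of cortical / subcortical parcels. Cortical parcels are divided
        across the seven networks proportionally to the canonical atlas
        (largest-remainder rounding), so reduced-size tables keep every
        network populated.
    """
    if n_cortical < len(CORTICAL_NETWORKS):
        raise ValueError(
            f"need at least {len(CORTICAL_NETWORKS)} cortical parcels, got {n_cortical}"
        )
    if n_subcortical < 0:
        raise ValueError("n_subcortical must be non-negative")

    raw = _CORTICAL_SHARES / _CORTICAL_SHARES.sum() * n_cortical
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    # distribute the remainder by largest fractional part
    rema = n_cortical - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    i = 0
    while rema != 0:
        j = order[i % len(counts)]
        if rema > 0:
            counts[j] += 1
            rema -= 1
        elif counts[j] > 1:
            counts[j] -= 1
            rema += 1
        i += 1

    rows = []
    pid = 1
    for net, c in zip(CORTICAL_NETWORKS, counts):
        for k in range(c):
            rows.append((pid, f"{net}_{k + 1}", net, "cortical"))
            pid += 1
    for k in range(n_subcortical):
        rows.append((pid, f"Subcort_{k + 1}", SUBCORTICAL, "subcortical"))
        pid += 1
    return pd.DataFrame(rows, columns=PARCEL_COLUMNS)


def parcel_table_for_size(n_rois: int) -> pd.DataFrame:
    """Default table for a total ROI count, keeping the ~400:54 cortical to
    subcortical proportion of the full atlas."""
    n_sub = int(round(n_rois * 54 / 454))
    return default_parcel_table(n_rois - n_sub, n_sub)


def validate_parcel_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PARCEL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"parcel table missing columns: {missing}")
    if table["parcel_id"].duplicated().any():
        raise ValueError("duplicate parcel_id in parcel table")
    return table


def network_indicators(table: pd.DataFrame) -> pd.DataFrame:
    """Binary indicator vector (ROIs x networks), one column per network.

    Raises if any network label has zero parcels (a labeling against it would
    be undefined).
    """
    validate_parcel_table(table)
    nets = list(dict.fromkeys(table["network"]))
    out = {}
    for net in nets:
        ind = (table["network"] == net).to_numpy().astype(float)
        if ind.sum() == 0:
            raise ValueError(f"network {net!r} has no parcels")
        out[net] = ind
    return pd.DataFrame(out, index=table["parcel_id"].to_numpy())


def read_parcel_table(path) -> pd.DataFrame:
    return validate_parcel_table(pd.read_csv(path, sep="\t"))


def write_parcel_table(path, table: pd.DataFrame) -> None:
    validate_parcel_table(table).to_csv(path, sep="\t", index=False)
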