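"""Neurovascular contact census: tabular bookkeeping of annotated
neuron-to-vessel contacts (layer, vascular element, neuronal class).

Operates on annotation exports only — contact detection in the EM volumes
was manual and is out of scope.  Percentages are reported rounded to the
nearest integer alongside the raw fractions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .io import SheathQuantError

LAYERS = ("SVP", "IVP", "DVP", "linker")
ELEMENTS = ("pericyte", "endothelium")
CELL_CLASSES = ("bipolar", "horizontal", "amacrine", "ganglion", "other")
SITES = ("soma", "process", "spine")

REQUIRED_COLUMNS = ("contact_id", "layer", "element", "cell_class")


def validate_contacts(table: pd.DataFrame) -> pd.DataFrame:
    """Check vocabulary and id uniqueness of a contact table."""
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise SheathQuantError(f"contact table missing columns: {sorted(missing)}")
    if table["contact_id"].duplicated().any():
        raise SheathQuantError("contact ids are not unique")
    for col, vocab in (("layer", LAYERS), ("element", ELEMENTS), ("cell_class", CELL_CLASSES)):
        bad = set(table[col].unique()) - set(vocab)
        if bad:
            raise SheathQuantError(f"unknown {col} values: {sorted(bad)}")
    if "site" in table.columns:
        bad = set(table["site"].unique()) - set(SITES)
        if bad:
            raise SheathQuantError(f"unknown site values: {sorted(bad)}")
    return table


def load_contacts(path: str) -> pd.DataFrame:
    return validate_contacts(pd.read_csv(path))


def _require_nonempty(table: pd.DataFrame) -> None:
    if len(table) == 0:
        raise SheathQuantError("contact table is empty")


def fraction_by_element(table: pd.DataFrame) -> pd.DataFrame:
    """Counts, raw fractions and rounded percentages per vascular element."""
    _require_nonempty(table)
    counts = table["element"].value_counts().reindex(list(ELEMENTS), fill_value=0)
    total = int(counts.sum())
    frac = counts / total
    return pd.DataFrame(
        {
            "count": counts.astype(int),
            "fraction": frac,
            "percent": np.rint(frac * 100).astype(int),
        }
    ).rename_axis("element")


def counts_by_layer(table: pd.DataFrame) -> pd.Series:
    """Contact count per vascular layer, zero-filled for absent layers."""
    _require_nonempty(table)
    return (
        table["layer"].value_counts().reindex(list(LAYERS), fill_value=0).astype(int)
        .rename_axis("layer").rename("count")
    )


def crosstab_class_element(table: pd.DataFrame) -> pd.DataFrame:
    """Cell class x vascular element contingency counts with per-class
    (row) element fractions appended as ``frac_<element>`` columns."""
    _require_nonempty(table)
    ct = pd.crosstab(table["cell_class"], table["element"])
    ct = ct.reindex(columns=list(ELEMENTS), fill_value=0)
    row_totals = ct.sum(axis=1)
    out = ct.copy()
    for el in ELEMENTS:
        out[f"frac_{el}"] = ct[el] / row_totals
    return out


# ---------------------------------------------------------------------------
# synthetic tables (fixtures for tests and worked examples)
# ---------------------------------------------------------------------------

def synthetic_contact_table(
    n_pericyte: int = 946,
    n_endothelium: int = 685,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic contact table with a given pericyte/endothelium split.

    Layers and cell classes are drawn with IVP-dominated weights; only the
    element split is controlled.
    """
    rng = np.random.default_rng(seed)
    n = n_pericyte + n_endothelium
    element = ["pericyte"] * n_pericyte + ["endothelium"] * n_endothelium
    layer = rng.choice(["IVP", "linker"], p=[0.97, 0.03], size=n)
    cell_class = rng.choice(
        ["bipolar", "horizontal", "amacrine", "ganglion", "other"],
        p=[0.35, 0.1, 0.3, 0.2, 0.05],
        size=n,
    )
    site = rng.choice(["soma", "process", "spine"], p=[0.4, 0.35, 0.25], size=n)
    return validate_contacts(
        pd.DataFrame(
            {
                "contact_id": np.arange(n),
                "layer": layer,
                "element": element,
                "cell_class": cell_class,
                "cell_type": "synthetic",
                "site": site,
            }
        )
    )


def synthetic_gap_table(ivp: int = 245, dvp: int = 17, svp: int = 2) -> pd.DataFrame:
    """Synthetic sheath-gap table with given per-layer counts."""
    layer = ["IVP"] * ivp + ["DVP"] * dvp + ["SVP"] * svp
    n = len(layer)
    return validate_contacts(
        pd.DataFrame(
            {
                "contact_id": np.arange(n),
                "layer": layer,
                "element": "endothelium",
                "cell_class": "ganglion",
                "cell_type": "RGC axon",
                "site": "process",
            }
        )
    )
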