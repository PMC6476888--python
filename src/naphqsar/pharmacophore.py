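"""Pharmacophore-map aggregation of IVE-PLS selections across resamplings.

Columns retained by the q2-optimal IVE-PLS subset of each train/test
sampling are tallied; the cumulative counts are normalized to [0, 1],
thresholded at a cutoff (0.8 by default), further reduced to the top 20%
by weight for display, and color-classified by the sign of the mean
regression coefficient crossed with the sign of the mean partial charge
near the column's spatial anchor on the template molecule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from naphqsar.ive import EliminationTrace
from naphqsar.structures import Conformer

#: color class labels -> numeric code written to the PDB B-factor column
CLASS_CODES = {"+/+": 1, "+/-": 2, "-/+": 3, "-/-": 4, "0": 0}


@dataclass(frozen=True)
class ImportanceField:
    """Per-descriptor-column importance table.

    ``table`` columns: count, weight in [0,1], optional mean_coef,
    local_charge, color_class; ``anchors`` holds one xyz per column (grid
    point or SOM-neuron codebook position mapped to template space).
    """

    table: pd.DataFrame
    anchors: np.ndarray | None = None

    @property
    def weights(self) -> pd.Series:
        return self.table["weight"]


def aggregate_importance(traces: Iterable[EliminationTrace], n_columns: int) -> ImportanceField:
    """Count optimal-subset membership per column and normalize by the max."""
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one elimination trace")
    counts = np.zeros(n_columns, dtype=int)
    for trace in traces:
        for col in trace.selected_columns:
            counts[col] += 1
    if counts.max() == 0:
        warnings.warn("all optimal subsets empty; importance field is all-zero", stacklevel=2)
        weights = counts.astype(float)
    else:
        weights = counts / counts.max()
    table = pd.DataFrame({"count": counts, "weight": weights})
    table.index.name = "column"
    return ImportanceField(table=table)


def apply_cutoff(
    field: ImportanceField, cutoff: float = 0.8, display_quantile: float = 0.8
) -> ImportanceField:
    """Keep columns with weight > cutoff, then the top (1 - quantile) share.

    The two stages mirror the reference display pipeline: a hard cutoff on
    the normalized cumulative weight, then discarding the given fraction of
    the survivors with the smallest statistical significance.
    """
    surv = field.table[field.table.weight > cutoff]
    if not surv.empty and 0.0 < display_quantile < 1.0:
        k = math.ceil((1.0 - display_quantile) * len(surv))
        surv = surv.sort_values("weight", ascending=False, kind="stable").head(k).sort_index()
    if surv.empty:
        warnings.warn(f"no column above cutoff {cutoff}; map is empty", stacklevel=2)
    anchors = None
    if field.anchors is not None:
        anchors = field.anchors[surv.index.to_numpy()]
    return ImportanceField(table=surv, anchors=anchors)


def _sign_label(b: float, q: float) -> str:
    if b == 0 or q == 0:
        return "0"
    return f"{'+' if b > 0 else '-'}/{'+' if q > 0 else '-'}"


def classify_colors(
    field: ImportanceField,
    mean_coefs: Sequence[float],
    template: Conformer | None = None,
    anchors: np.ndarray | None = None,
    neighborhood: float = 3.0,
) -> ImportanceField:
    """Attach +/-x+/- color classes from coefficient and local-charge signs.

    ``mean_coefs`` gives the mean regression coefficient per retained column
    (in the field's index order).  The local charge is the mean Gasteiger
    charge of template atoms within ``neighborhood`` angstroms of the
    column's spatial anchor; a zero mean on either axis yields the neutral
    class "0".
    """
    anchors = field.anchors if anchors is None else np.asarray(anchors, dtype=float)
    mean_coefs = np.asarray(mean_coefs, dtype=float)
    if len(mean_coefs) != len(field.table):
        raise ValueError("mean_coefs must align with the retained columns")
    if anchors is None or template is None:
        charges = np.zeros(len(field.table))
    else:
        txyz, tq = template.coords, template.charges
        charges = np.empty(len(anchors))
        for i, a in enumerate(anchors):
            near = np.linalg.norm(txyz - a, axis=1) <= neighborhood
            charges[i] = tq[near].mean() if near.any() else 0.0
    table = field.table.copy()
    table["mean_coef"] = mean_coefs
    table["local_charge"] = charges
    table["color_class"] = [_sign_label(b, q) for b, q in zip(mean_coefs, charges)]
    return replace(field, table=table)


def export_pdb(field: ImportanceField, path: str | Path) -> None:
    """Write map points as PDB pseudo-atoms: occupancy = weight,
    B-factor = color-class code — renderable in any molecular viewer."""
    if field.anchors is None:
        raise ValueError("field has no spatial anchors to export")
    lines = []
    for n, (idx, row) in enumerate(field.table.iterrows(), start=1):
        x, y, z = field.anchors[list(field.table.index).index(idx)]
        code = CLASS_CODES.get(row.get("color_class", "0"), 0)
        lines.append(
            f"HETATM{n:5d}  MAP PSD A{n % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{row.weight:6.2f}{float(code):6.2f}          He"
        )
    Path(path).write_text("\n".join(lines) + "\nEND\n")
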