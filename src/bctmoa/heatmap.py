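"""Clustered heat map of the BCT x MoA p-value matrix.

Rows (techniques) and columns (mechanisms) are independently reordered by
average-linkage hierarchical clustering so that techniques linked to similar
mechanisms sit together. Cells hold the enrichment p-values; darker shades
mean smaller p (a more frequently described link, relative to marginal
usage). Cells for links never described in the corpus are a sentinel (NaN),
rendered in a distinct background so "never described" is visually distinct
from "described but weak".

Determinism is guaranteed for the data artifacts (ordered-matrix CSV, order
JSON); raster bytes may differ across font stacks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BctMoaError, DegenerateInputError
from .link_test import LinkTestResult, _code_key

TRANSFORM_RAW = "raw-p"
TRANSFORM_NEGLOG = "neg-log10-p"
TRANSFORMS = (TRANSFORM_RAW, TRANSFORM_NEGLOG)

#: p-values are clamped below at this floor before -log10, capping the
#: transformed scale at 16.
P_FLOOR = 1e-16


@dataclass
class PMatrix:
    """Dense p-value matrix over described links; NaN marks untested cells."""

    rows: list[str]  # BCT codes
    cols: list[int]  # MoA ids
    values: np.ndarray  # shape (len(rows), len(cols))
    transform: str

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError("matrix shape inconsistent with row/col lists")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.cols)


@dataclass
class DendrogramOrder:
    """Leaf orders (index permutations) and merge trees for both axes."""

    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        return {
            "row_order": list(map(int, self.row_order)),
            "col_order": list(map(int, self.col_order)),
            "row_linkage": None if self.row_linkage is None else self.row_linkage.tolist(),
            "col_linkage": None if self.col_linkage is None else self.col_linkage.tolist(),
        }


def build_p_matrix(
    results: Sequence[LinkTestResult], transform: str = TRANSFORM_RAW
) -> PMatrix:
    """Arrange test results as a dense matrix, one cell per tested link.

    Rows are BCT codes in numeric taxonomy order, columns MoA ids ascending.
    Under the neg-log10-p transform values are -log10(max(p, 1e-16)).
    """
    if transform not in TRANSFORMS:
        raise BctMoaError(f"transform must be one of {TRANSFORMS}")
    seen: set[tuple[str, int]] = set()
    for r in results:
        key = (r.bct_code, r.moa_id)
        if key in seen:
            raise BctMoaError(f"duplicate result for cell {key}")
        seen.add(key)
    rows = sorted({r.bct_code for r in results}, key=_code_key)
    cols = sorted({r.moa_id for r in results})
    values = np.full((len(rows), len(cols)), np.nan)
    ri = {b: i for i, b in enumerate(rows)}
    ci = {m: j for j, m in enumerate(cols)}
    for r in results:
        p = r.p
        if transform == TRANSFORM_NEGLOG:
            p = -np.log10(max(p, P_FLOOR))
        values[ri[r.bct_code], ci[r.moa_id]] = p
    return PMatrix(rows=rows, cols=cols, values=values, transform=transform)


def _neglog_values(matrix: PMatrix) -> np.ndarray:
    """Matrix on the -log10(p) scale with untested cells imputed as p = 1."""
    if matrix.transform == TRANSFORM_NEGLOG:
        vals = matrix.values.copy()
        vals[np.isnan(vals)] = 0.0
        return vals
    vals = matrix.values.copy()
    vals[np.isnan(vals)] = 1.0
    return -np.log10(np.clip(vals, P_FLOOR, 1.0))


def cluster_orders(
    matrix: PMatrix, metric: str = "euclidean", method: str = "average"
) -> DendrogramOrder:
    """Cluster rows and columns independently; return leaf orders.

    Distances are computed on the -log10(p) scale (untested cells imputed at
    p = 1, i.e. zero evidence), emphasizing strong links while the clamp at
    1e-16 bounds the scale. Average linkage by default; SciPy's agglomeration
    is deterministic for fixed input order, and ties merge lowest-index
    first.
    """
    from scipy.cluster import hierarchy

    if np.all(np.isnan(matrix.values)):
        raise DegenerateInputError("cannot cluster an all-sentinel matrix")
    vals = _neglog_values(matrix)

    def axis_order(data: np.ndarray) -> tuple[list[int], np.ndarray | None]:
        if data.shape[0] <= 1:
            return list(range(data.shape[0])), None
        link = hierarchy.linkage(data, method=method, metric=metric)
        return list(hierarchy.leaves_list(link)), link

    row_order, row_link = axis_order(vals)
    col_order, col_link = axis_order(vals.T)
    return DendrogramOrder(
        row_order=row_order, col_order=col_order,
        row_linkage=row_link, col_linkage=col_link,
    )


def render_heatmap(
    matrix: PMatrix,
    orders: DendrogramOrder,
    out_stem: str | Path,
    bct_registry=None,
    moa_registry=None,
) -> dict[str, Path]:
    """Render the clustered heat map and write its data artifacts.

    Writes ``<stem>.png``, ``<stem>.svg``, the reordered matrix as
    ``<stem>.csv`` (rows/cols in clustered order, labels attached), and the
    orders plus merge trees as ``<stem>.json``. Returns the paths written.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from . import registry as reg

    if sorted(orders.row_order) != list(range(len(matrix.rows))) or sorted(
        orders.col_order
    ) != list(range(len(matrix.cols))):
        raise BctMoaError("orders are not permutations of the matrix axes")

    bct_registry = bct_registry if bct_registry is not None else reg.load_bct_registry()
    moa_registry = moa_registry if moa_registry is not None else reg.load_moa_registry()

    out_stem = Path(out_stem)
    out_stem.parent.mkdir(parents=True, exist_ok=True)

    ordered = matrix.values[np.ix_(orders.row_order, orders.col_order)]
    row_labels = [
        f"{bct_registry[matrix.rows[i]].label} ({matrix.rows[i]})"
        for i in orders.row_order
    ]
    col_labels = [moa_registry[matrix.cols[j]].label for j in orders.col_order]

    # CSV data artifact: byte-deterministic for identical inputs.
    csv_path = out_stem.with_suffix(".csv")
    pd.DataFrame(ordered, index=row_labels, columns=col_labels).to_csv(csv_path)

    json_path = out_stem.with_suffix(".json")
    json_path.write_text(
        json.dumps(orders.to_json_dict(), indent=2) + "\n", encoding="utf-8"
    )

    # Color scale: darker = smaller p. On the raw-p scale "gray" maps 0 to
    # black directly; on the -log10 scale large values mean small p, so the
    # map is reversed.
    if matrix.transform == TRANSFORM_RAW:
        cmap_name, vmin, vmax = "gray", 0.0, 1.0
    else:
        cmap_name, vmin, vmax = "gray_r", 0.0, float(np.nanmax(ordered) or 1.0)
    cmap = plt.get_cmap(cmap_name).copy()
    cmap.set_bad(color="#f2e8dc")  # untested cells: off-white, distinct from any p

    n_rows, n_cols = ordered.shape
    fig_h = max(3.0, 0.22 * n_rows + 1.5)
    fig_w = max(4.0, 0.45 * n_cols + 3.0)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    im = ax.imshow(ordered, cmap=cmap, vmin=vmin, vmax=vmax, aspect="auto")
    ax.set_xticks(range(n_cols), labels=col_labels, rotation=90, fontsize=6)
    ax.set_yticks(range(n_rows), labels=row_labels, fontsize=6)
    label = "p value" if matrix.transform == TRANSFORM_RAW else "-log10(p)"
    fig.colorbar(im, ax=ax, label=label, shrink=0.6)
    ax.set_xlabel("Mechanism of action")
    ax.set_ylabel("Behavior change technique")
    fig.tight_layout()
    png_path, svg_path = out_stem.with_suffix(".png"), out_stem.with_suffix(".svg")
    fig.savefig(png_path, dpi=150)
    fig.savefig(svg_path)
    plt.close(fig)

    return {"png": png_path, "svg": svg_path, "csv": csv_path, "json": json_path}
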