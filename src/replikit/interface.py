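"""Map pair scores to reference residue numbers and pick candidate residues.

DCA scores live in concatenated-alignment column coordinates.  For
interpretation against the original proteins they are renumbered into the
1-based ungapped coordinates of each family's reference sequence (columns
where the reference is gapped carry no residue and are dropped), the best
`k` residues per protein are selected, and a dense residue-by-residue score
matrix is exported for heat-map display.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from replikit.concat import PairedAlignment, PAIR_AB, classify_pair

logger = logging.getLogger(__name__)


def to_reference_coordinates(scores: pd.DataFrame, pa: PairedAlignment) -> pd.DataFrame:
    """Renumber inter-protein pair scores into reference residue numbers.

    ``scores`` must be an AB-filtered pair table computed on ``pa`` (columns
    ``i, j, di, mi`` in concatenated coordinates).  Each retained row gains
    ``res_a``/``res_b``: 1-based positions in the ungapped reference
    sequences of families A and B.  Rows whose column falls on a reference
    gap are dropped with a logged count.  The original columns are kept as
    ``col_a``/``col_b`` provenance.
    """
    if pa.column_map_a is None or pa.column_map_b is None:
        raise ValueError("paired alignment has no reference column maps")
    if len(scores):
        cols = pd.concat([scores["i"], scores["j"]])
        if cols.min() < 1 or cols.max() > pa.total_length:
            raise ValueError("pair table columns out of range for this alignment")
        bad = [
            (i, j)
            for i, j in zip(scores["i"], scores["j"])
            if classify_pair(int(i), int(j), pa) != PAIR_AB
        ]
        if bad:
            raise ValueError(
                f"pair table contains {len(bad)} non-inter-protein rows "
                "(was it computed on this alignment with the AB filter?)"
            )

    offset = pa.b_offset()
    records = []
    n_dropped = 0
    for i, j, di, mi in scores[["i", "j", "di", "mi"]].itertuples(index=False):
        col_a, col_b = int(i), int(j)
        res_a = pa.column_map_a.ref_index(col_a)
        res_b = pa.column_map_b.ref_index(col_b - offset)
        if res_a is None or res_b is None:
            n_dropped += 1
            continue
        records.append((res_a, res_b, di, mi, col_a, col_b))
    if n_dropped:
        logger.info("dropped %d pairs falling on reference gaps", n_dropped)
    return pd.DataFrame(
        records, columns=["res_a", "res_b", "di", "mi", "col_a", "col_b"]
    )


def top_k_residues(
    ipt: pd.DataFrame,
    k: int = 10,
    metric: str = "di",
    aggregate: str = "max",
) -> dict[str, pd.DataFrame]:
    """Select the ``k`` best candidate interface residues per protein.

    Each residue's aggregate score is the ``max`` (default) or ``sum`` of
    the chosen metric over all its cross-protein partner pairs.  Returns
    ``{"A": ..., "B": ...}``, each a frame of (residue, score) sorted by
    descending score with ties broken by lower residue number; at most
    ``min(k, available residues)`` rows each.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if metric not in ("di", "mi"):
        raise ValueError(f"metric must be 'di' or 'mi', got {metric!r}")
    if aggregate not in ("max", "sum"):
        raise ValueError(f"aggregate must be 'max' or 'sum', got {aggregate!r}")
    if ipt.empty:
        raise ValueError("empty inter-protein pair table")

    out: dict[str, pd.DataFrame] = {}
    for side, col in (("A", "res_a"), ("B", "res_b")):
        agg = (
            ipt.groupby(col)[metric]
            .agg(aggregate)
            .rename("score")
            .reset_index()
            .rename(columns={col: "residue"})
        )
        agg = agg.sort_values(
            ["score", "residue"], ascending=[False, True], kind="mergesort"
        ).head(k)
        out[side] = agg.reset_index(drop=True)
    return out


def heatmap_matrix(
    ipt: pd.DataFrame,
    pa: PairedAlignment | None = None,
    metric: str = "mi",
) -> pd.DataFrame:
    """Dense residue-pair score matrix, family B on rows, family A on columns.

    Follows the display convention of putting the helicase-primase family
    (B) on the y-axis.  When ``pa`` is given the matrix spans the full
    gapless reference lengths regardless of which pairs were scored;
    unscored cells are NaN.  Default metric is MI, the quantity usually
    shown as a covariation heat map.
    """
    if metric not in ("di", "mi"):
        raise ValueError(f"metric must be 'di' or 'mi', got {metric!r}")
    if pa is not None:
        if pa.column_map_a is None or pa.column_map_b is None:
            raise ValueError("paired alignment has no reference column maps")
        n_a = pa.column_map_a.reference_length
        n_b = pa.column_map_b.reference_length
    else:
        n_a = int(ipt["res_a"].max()) if len(ipt) else 0
        n_b = int(ipt["res_b"].max()) if len(ipt) else 0
    mat = np.full((n_b, n_a), np.nan)
    for res_a, res_b, val in ipt[["res_a", "res_b", metric]].itertuples(index=False):
        mat[int(res_b) - 1, int(res_a) - 1] = val
    return pd.DataFrame(
        mat, index=pd.RangeIndex(1, n_b + 1, name="res_b"),
        columns=pd.RangeIndex(1, n_a + 1, name="res_a"),
    )


def write_inter_pair_table(ipt: pd.DataFrame, path: str | Path) -> None:
    ipt.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_candidates(
    cand: dict[str, pd.DataFrame],
    path_a: str | Path,
    path_b: str | Path,
    pa: PairedAlignment | None = None,
) -> None:
    """Write per-protein candidate tables; adds the reference amino acid
    letter for each residue when the paired alignment is available."""
    for side, path in (("A", path_a), ("B", path_b)):
        df = cand[side].copy()
        seq = _reference_segment(pa, side) if pa is not None else None
        if seq is not None:
            df["amino_acid"] = [
                seq[r - 1] if 0 < r <= len(seq) else "?" for r in df["residue"]
            ]
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _reference_segment(pa: PairedAlignment, side: str) -> str | None:
    """Ungapped reference sequence of one family, from the stored rows."""
    if pa.reference_species is None:
        return None
    for sp, row in pa.rows:
        if sp == pa.reference_species:
            a_part, b_part = pa.split_row(row)
            return (a_part if side == "A" else b_part).replace("-", "")
    return None


def write_heatmap_tsv(mat: pd.DataFrame, path: str | Path) -> None:
    """Export the heat-map matrix as TSV; missing pairs are written as NaN."""
    mat.to_csv(path, sep="\t", float_format="%.10g", na_rep="NaN")


def plot_heatmap(mat: pd.DataFrame, path: str | Path, metric_label: str = "MI") -> None:
    """Render the score matrix as a PNG heat map (family B on the y-axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(
        mat.to_numpy(),
        origin="lower",
        aspect="auto",
        interpolation="nearest",
        extent=(0.5, mat.shape[1] + 0.5, 0.5, mat.shape[0] + 0.5),
    )
    ax.set_xlabel("family A residue")
    ax.set_ylabel("family B residue")
    fig.colorbar(im, ax=ax, label=metric_label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
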