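"""Per-cell species assignment for barnyard (mixed-species) experiments.

Each barcode is called human or mouse from the relative UMI content of the
two genome blocks of the combined reference; transgene UMIs belong to
neither genome and are excluded from both totals.  Calls are cross-validated
with an independent classifier built on orthologous gene pairs: for each
cell the normalized expression summed over the human members of the ortholog
map is compared with the sum over the mouse members, and the sign of the
difference gives a second species call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

DEFAULT_T_HIGH = 0.9
DEFAULT_T_LOW = 0.1


@dataclass
class OrthologMap:
    """One-to-one human/mouse ortholog gene-id pairs."""

    human_ids: list[str]
    mouse_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.human_ids) != len(self.mouse_ids):
            raise ValueError("ortholog lists must have equal length")
        if len(self.human_ids) == 0:
            raise ValueError("ortholog map is empty")
        all_ids = list(self.human_ids) + list(self.mouse_ids)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("a gene appears in more than one ortholog pair")

    def __len__(self) -> int:
        return len(self.human_ids)

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        return cls(df[0].tolist(), df[1].tolist())


def assign_species(
    matrix: CountMatrix,
    t_high: float = DEFAULT_T_HIGH,
    t_low: float = DEFAULT_T_LOW,
) -> pd.DataFrame:
    """Call each barcode human/mouse/ambiguous from relative UMI counts.

    A cell is called human when ``fraction_human >= t_high``, mouse when
    ``fraction_human <= t_low`` and ambiguous otherwise (including cells
    with zero species UMIs).  Returns one row per barcode with columns
    ``barcode, human_umi, mouse_umi, fraction_human, call``.
    """
    if not 0 <= t_low < t_high <= 1:
        raise ValueError(f"need 0 <= t_low < t_high <= 1, got {t_low}, {t_high}")
    human_mask = matrix.genes.mask("human")
    mouse_mask = matrix.genes.mask("mouse")
    if not human_mask.any() or not mouse_mask.any():
        raise ValueError("matrix must contain both human and mouse gene blocks")

    counts = matrix.counts.tocsc()
    human_umi = np.asarray(counts[human_mask].sum(axis=0)).ravel().astype(int)
    mouse_umi = np.asarray(counts[mouse_mask].sum(axis=0)).ravel().astype(int)
    total = human_umi + mouse_umi
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, human_umi / np.maximum(total, 1), np.nan)

    call = np.full(matrix.n_cells, "ambiguous", dtype=object)
    call[(total > 0) & (frac >= t_high)] = "human"
    call[(total > 0) & (frac <= t_low)] = "mouse"

    return pd.DataFrame({
        "barcode": matrix.barcodes,
        "human_umi": human_umi,
        "mouse_umi": mouse_umi,
        "fraction_human": frac,
        "call": call,
    })


def ortholog_crosscheck(
    matrix: CountMatrix,
    calls: pd.DataFrame,
    ortholog_map: OrthologMap,
    min_pairs: int = 5,
) -> dict:
    """Cross-validate UMI-ratio species calls with ortholog expression.

    For every non-ambiguous cell, normalized (counts-per-10k, log1p)
    expression is summed over the human and the mouse members of the
    ortholog pairs; the sign of the difference gives an independent call
    (equal sums -> crosscheck ambiguous, excluded from the agreement
    denominator).

    Returns a dict with ``per_cell`` (DataFrame: barcode, primary_call,
    crosscheck_call, agree) and ``agreement`` (fraction of comparable cells
    on which the two classifiers agree).
    """
    id_to_row = {gid: i for i, gid in enumerate(matrix.genes.gene_id)}
    h_rows, m_rows = [], []
    for h, m in zip(ortholog_map.human_ids, ortholog_map.mouse_ids):
        if h in id_to_row and m in id_to_row:
            h_rows.append(id_to_row[h])
            m_rows.append(id_to_row[m])
    if len(h_rows) < min_pairs:
        raise ValueError(
            f"only {len(h_rows)} ortholog pairs present (minimum {min_pairs})")

    counts = matrix.counts.tocsc().astype(float)
    depth = np.asarray(counts.sum(axis=0)).ravel()
    inv = np.where(depth > 0, 1e4 / np.maximum(depth, 1), 0.0)
    norm = counts.multiply(inv).tocsr()
    norm.data = np.log1p(norm.data)

    h_score = np.asarray(norm[h_rows].sum(axis=0)).ravel()
    m_score = np.asarray(norm[m_rows].sum(axis=0)).ravel()
    diff = h_score - m_score
    cross = np.full(matrix.n_cells, "ambiguous", dtype=object)
    cross[diff > 0] = "human"
    cross[diff < 0] = "mouse"

    per_cell = pd.DataFrame({
        "barcode": matrix.barcodes,
        "primary_call": calls.set_index("barcode").loc[matrix.barcodes, "call"].to_numpy(),
        "crosscheck_call": cross,
    })
    comparable = ((per_cell["primary_call"] != "ambiguous")
                  & (per_cell["crosscheck_call"] != "ambiguous"))
    per_cell["agree"] = np.where(
        comparable, per_cell["primary_call"] == per_cell["crosscheck_call"], np.nan)
    n_comp = int(comparable.sum())
    agreement = float(per_cell.loc[comparable, "agree"].mean()) if n_comp else np.nan
    return {"per_cell": per_cell, "agreement": agreement, "n_comparable": n_comp}
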