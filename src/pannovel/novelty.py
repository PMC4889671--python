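"""The Novelty Metric: per-query, per-strain gene novelty scoring.

For a query gene q and genome G, with B(q, G) the bit score of the
best translated-search hit of q in G (0 when there is no hit),

    NM(q, G) = (B(q, G) - B(q, ref)) / max over the panel of B(q, .)

where ``ref`` is the reference-role genome (the laboratory reference
strain in the original application).  A genome carrying a close
homolog of a non-reference gene scores near 1, a genome whose best
match is no better than the reference's scores near 0, and the value
is undefined (NA) for queries with no hit anywhere in the panel.  By
construction the reference column is exactly zero wherever defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import GenomeAssembly
from .search import ScoringScheme, DEFAULT_SCHEME, best_bit_scores


@dataclass
class NoveltyMatrix:
    """Query-gene x strain matrix of Novelty Metric values.

    ``values`` has query ids as rows and genome ids as columns
    (matching the heatmap orientation: query genes are rows, genomes
    searched are columns); NA marks queries whose best bit score is 0
    across the whole panel.  ``denominators`` holds the per-query
    panel-max bit score used for normalization.
    """

    values: pd.DataFrame
    reference_id: str
    denominators: pd.Series

    @property
    def query_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.values.columns)


def novelty_metric(
    query_id: str,
    genome_id: str,
    scores: Mapping[str, float],
    reference_id: str,
) -> float:
    """NM for one (query, genome) cell from per-genome best bit scores.

    ``scores`` maps genome id -> best bit score of the query in that
    genome, covering the full panel; a missing reference entry counts
    as 0.  Returns NaN when the panel maximum is 0.
    """
    if genome_id not in scores:
        raise KeyError(f"genome {genome_id!r} not in panel for query {query_id!r}")
    denom = max(scores.values())
    if denom <= 0:
        return float("nan")
    b_ref = scores.get(reference_id, 0.0)
    return (scores[genome_id] - b_ref) / denom


def build_matrix(
    scores: pd.DataFrame,
    reference_id: str,
) -> NoveltyMatrix:
    """Assemble the full Novelty Matrix from a best-bit-score table.

    ``scores`` has query rows and genome columns (see
    :func:`pannovel.search.best_bit_scores`); the reference genome must
    be one of the columns.  Raises on duplicate query ids.
    """
    if scores.index.duplicated().any():
        dupes = scores.index[scores.index.duplicated()].tolist()
        raise ValueError(f"duplicate query ids: {dupes}")
    if reference_id not in scores.columns:
        raise ValueError(f"reference {reference_id!r} not in panel")
    denom = scores.max(axis=1)
    b_ref = scores[reference_id]
    values = scores.sub(b_ref, axis=0).div(denom, axis=0)
    values.loc[denom <= 0, :] = np.nan
    return NoveltyMatrix(values=values, reference_id=reference_id, denominators=denom)


def build_matrix_from_panel(
    queries: dict[str, str],
    panel: list[GenomeAssembly],
    reference_id: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    raw_floor: float | None = None,
) -> NoveltyMatrix:
    """Run the translated search for every query/genome pair, then
    assemble the matrix."""
    scores = best_bit_scores(queries, panel, scheme, raw_floor)
    return build_matrix(scores, reference_id)


def cluster_strains(matrix: NoveltyMatrix) -> tuple[list[str], np.ndarray | None]:
    """Unsupervised clustering of the strains by gene content.

    Average-linkage hierarchical clustering on Euclidean distance
    between strain columns, with NA treated as 0.  Columns are sorted
    lexicographically before linkage so the leaf order is deterministic
    and invariant to the input column order.  With fewer than two
    strains the identity ordering is returned with no linkage.
    """
    cols = sorted(matrix.genome_ids)
    if len(cols) < 2:
        return list(matrix.genome_ids), None
    filled = matrix.values[cols].fillna(0.0)
    dists = pdist(filled.to_numpy().T, metric="euclidean")
    link = linkage(dists, method="average")
    order = leaves_list(link)
    return [cols[i] for i in order], link


def export_heatmap_table(
    matrix: NoveltyMatrix,
    path: str | Path,
    ordering: list[str] | None = None,
) -> None:
    """Write the matrix as a wide TSV (NA literal "NA"), optionally with
    columns in a clustering order."""
    df = matrix.values if ordering is None else matrix.values[ordering]
    df.to_csv(path, sep="\t", na_rep="NA", index_label="query")


def read_heatmap_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="query", na_values=["NA"])


def plot_heatmap(matrix: NoveltyMatrix, path: str | Path, ordering: list[str] | None = None):
    """Optional heatmap rendering (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix.values if ordering is None else matrix.values[ordering]
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * df.shape[1]), max(3, 0.2 * df.shape[0])))
    masked = np.ma.masked_invalid(df.to_numpy())
    im = ax.imshow(masked, aspect="auto", cmap="viridis", vmin=-1, vmax=1)
    ax.set_xticks(range(df.shape[1]), df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(df.shape[0]), df.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Novelty Metric")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
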