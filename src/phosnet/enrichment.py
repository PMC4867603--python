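"""Annotation-term enrichment per direction group and heat-map assembly.

Each gene set (e.g. proteins with up- or down-regulated phosphosites) is
tested against GMT annotation terms with the same hypergeometric upper tail
used for kinase enrichment, over a user-supplied background.  Terms are
retained when, in at least one group, p < 0.005 with at least three
overlapping genes; retained -log10 p values are arranged by agglomerative
clustering (Euclidean distance, average/UPGMA linkage) into a heat-map
matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import ParameterError
from .kinase import hypergeometric_upper_tail

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentCell:
    """Enrichment of one term in one direction group."""

    term: str
    group: str
    p_value: float
    n_genes: int


@dataclass
class HeatmapMatrix:
    """-log10 p per retained term (rows, dendrogram leaf order) and group."""

    values: pd.DataFrame

    @property
    def terms(self) -> list[str]:
        return list(self.values.index)


def enrich_terms(
    gene_set: Iterable[str],
    annotation: Mapping[str, tuple[str, Sequence[str]]] | Mapping[str, Sequence[str]],
    background: Iterable[str],
    group: str = "",
) -> list[EnrichmentCell]:
    """Hypergeometric upper-tail enrichment of ``gene_set`` in every term.

    For each term: N = |background|, K = |term ∩ background|,
    n = |gene_set|, k = |term ∩ gene_set|.  ``annotation`` maps term ->
    gene list (optionally with a leading description, as parsed from GMT).
    """
    bg = set(background)
    if not bg:
        raise ParameterError("background must be non-empty")
    genes = set(gene_set)
    if not genes <= bg:
        raise ParameterError("gene_set must be a subset of the background")
    cells = []
    for term in sorted(annotation):
        entry = annotation[term]
        members = entry[1] if isinstance(entry, tuple) else entry
        term_bg = set(members) & bg
        k = len(term_bg & genes)
        p = hypergeometric_upper_tail(k, len(term_bg), len(genes), len(bg))
        cells.append(EnrichmentCell(term=term, group=group, p_value=p, n_genes=k))
    return cells


def build_heatmap(
    cells: Sequence[EnrichmentCell],
    p_max: float = 0.005,
    min_genes: int = 3,
) -> HeatmapMatrix:
    """Filter enrichment cells and cluster terms into a heat-map matrix.

    A term is retained iff some group has p < ``p_max`` (strict) and at
    least ``min_genes`` overlapping genes.  Values are -log10 p; a term
    untested in a group is encoded as 0 (p = 1) so distances stay defined.
    Rows follow the UPGMA dendrogram leaf order (Euclidean distance), with
    ties broken by term identifier via a pre-sort.
    """
    groups = sorted({c.group for c in cells})
    # conventional column order when the groups are direction labels
    if set(groups) == {"up", "down"}:
        groups = ["up", "down"]
    p = pd.DataFrame(1.0, index=sorted({c.term for c in cells}), columns=groups)
    n = pd.DataFrame(0, index=p.index, columns=groups)
    for c in cells:
        p.at[c.term, c.group] = c.p_value
        n.at[c.term, c.group] = c.n_genes
    keep = ((p < p_max) & (n >= min_genes)).any(axis=1)
    retained = p[keep]
    if retained.empty:
        logger.warning("build_heatmap: no terms survive the filters")
        return HeatmapMatrix(values=-np.log10(retained))
    values = -np.log10(retained)
    if len(values) >= 2:
        link = hierarchy.linkage(values.to_numpy(), method="average", metric="euclidean")
        order = hierarchy.leaves_list(link)
        values = values.iloc[order]
    return HeatmapMatrix(values=values)


def plot_heatmap(heatmap: HeatmapMatrix, path) -> None:
    """Static rendering of the clustered -log10 p matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = heatmap.values
    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * values.shape[1], 1 + 0.25 * max(1, values.shape[0]))
    )
    if values.empty:
        ax.text(0.5, 0.5, "no enriched terms", ha="center", va="center")
        ax.axis("off")
    else:
        im = ax.imshow(values.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(values.shape[1]), values.columns)
        ax.set_yticks(range(values.shape[0]), values.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
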