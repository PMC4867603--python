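"""End-to-end orchestration of the downstream inference chain.

Wires the stage modules together in the order the analysis runs on real
data: FLR filtering -> spectral counting -> differential calling ->
kinase-substrate filtering and enrichment (with KSEA disambiguation) ->
multi-source network integration with kinase mapping, topology and module
detection -> annotation-term enrichment heat map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import differential as diff
from . import enrichment as enr
from . import kinase as kin
from . import network as net
from . import quant
from .simulate import SimulatedStudy

LN2 = math.log(2.0)


@dataclass
class PipelineResult:
    """All intermediate and final products of one pipeline run."""

    matrix: quant.SiteCountMatrix
    diff_results: list[diff.DifferentialSite]
    up_units: set[str]
    down_units: set[str]
    kinase_results: list[kin.KinaseResult]
    background_units: set[str]
    network: net.IntegratedNetwork | None = None
    topology: net.TopologySummary | None = None
    clusters: list[net.ClusterResult] = field(default_factory=list)
    heatmap: enr.HeatmapMatrix | None = None
    enrichment_cells: list[enr.EnrichmentCell] = field(default_factory=list)

    @property
    def significant_kinases(self) -> list[kin.KinaseResult]:
        return [r for r in self.kinase_results if r.significant]


def site_to_units(matrix: quant.SiteCountMatrix) -> dict[str, list[str]]:
    """Map protein-qualified site ids to the unit keys containing them."""
    mapping: dict[str, list[str]] = {}
    for key, unit in matrix.units.items():
        for sid in unit.site_ids:
            mapping.setdefault(sid, []).append(key)
    return mapping


def expand_ksr_to_units(
    ksr: pd.DataFrame, matrix: quant.SiteCountMatrix
) -> pd.DataFrame:
    """Resolve KSR site predictions to quantification units.

    Each predicted (kinase, site) pair is expanded to every unit whose
    localized site set contains the site; predictions on undetected sites
    are dropped.
    """
    mapping = site_to_units(matrix)
    rows = []
    for r in ksr.itertuples(index=False):
        for unit_key in mapping.get(str(r.site_id), ()):
            rows.append(
                (r.kinase, unit_key, r.source, r.networkin_score, r.netphorest_probability)
            )
    return pd.DataFrame(
        rows,
        columns=["kinase", "substrate", "source", "networkin_score", "netphorest_probability"],
    )


def run_kinase_stage(
    ksr: pd.DataFrame,
    matrix: quant.SiteCountMatrix,
    diff_results: Sequence[diff.DifferentialSite],
    up_units: set[str],
    down_units: set[str],
    detected_kinases: Sequence[str] | None = None,
    alpha: float = 1e-4,
    score_min: float = kin.NETWORKIN_SCORE_MIN,
    prob_min: float = kin.NETPHOREST_PROB_MIN,
) -> tuple[list[kin.KinaseResult], set[str], pd.DataFrame]:
    """Filter predictions, enrich per kinase, disambiguate with KSEA.

    Background = detected units carrying at least one retained prediction.
    Returns the kinase results, the background unit set, and the filtered
    unit-resolved KSR table (reused for kinase-edge mapping).
    """
    detected = (
        set(detected_kinases) if detected_kinases is not None else set(ksr["kinase"])
    )
    filtered = kin.filter_ksrs(ksr, detected, score_min=score_min, prob_min=prob_min)
    ksr_units = expand_ksr_to_units(filtered, matrix)
    background = set(ksr_units["substrate"])
    if not background:
        return [], set(), ksr_units
    results = kin.enrich_kinases(
        ksr_units,
        up_units & background,
        down_units & background,
        background,
        alpha=alpha,
    )
    ambiguous = {r.kinase for r in results if r.assigned_condition == "ambiguous"}
    if ambiguous:
        log2fc = {
            r.unit_key: r.log_fold_change / LN2
            for r in diff_results
            if r.unit_key in background
        }
        all_vals = list(log2fc.values())
        zs = {}
        for kinase in ambiguous:
            subs = set(
                ksr_units.loc[ksr_units["kinase"] == kinase, "substrate"]
            ) & set(log2fc)
            zs[kinase] = kin.ksea_score([log2fc[u] for u in sorted(subs)], all_vals)
        results = kin.assign_activity(results, zs)
    return results, background, ksr_units


def protein_directions(
    matrix: quant.SiteCountMatrix,
    diff_results: Sequence[diff.DifferentialSite],
    up_units: set[str],
    down_units: set[str],
) -> dict[str, str]:
    """Protein-level direction labels for network annotation.

    A protein carrying both up and down units takes the direction of its
    largest-magnitude fold change (deterministic tie-break toward 'up').
    """
    best: dict[str, tuple[float, str]] = {}
    lfc = {r.unit_key: r.log_fold_change for r in diff_results}
    for key in up_units | down_units:
        protein = matrix.units[key].protein
        direction = "up" if key in up_units else "down"
        magnitude = abs(lfc.get(key, 0.0))
        prev = best.get(protein)
        if (
            prev is None
            or magnitude > prev[0]
            or (magnitude == prev[0] and direction == "up" and prev[1] == "down")
        ):
            best[protein] = (magnitude, direction)
    return {p: d for p, (_, d) in best.items()}


def run_pipeline(
    study: SimulatedStudy,
    flr_max: float = 0.01,
    fold_min: float = 2.0,
    fdr_max: float = 0.10,
    alpha: float = 1e-4,
    string_score_min: float = net.STRING_SCORE_MIN,
    cluster_penalty: float = 2.0,
    cluster_p_max: float = 0.05,
    enrich_p_max: float = 0.005,
    min_genes: int = 3,
    with_network: bool = True,
    with_enrichment: bool = True,
) -> PipelineResult:
    """Run the full downstream chain on one simulated study."""
    psms = quant.filter_by_flr(quant.psms_from_frame(study.psms), flr_max)
    matrix = quant.count_spectra(psms)
    results = diff.test_differential(
        matrix, fold_min=fold_min, fdr_max=fdr_max
    )
    up, down = diff.classify_regulated(results, fold_min=fold_min, fdr_max=fdr_max)
    kinase_results, background, ksr_units = run_kinase_stage(
        study.ksr, matrix, results, up, down, alpha=alpha
    )
    out = PipelineResult(
        matrix=matrix,
        diff_results=results,
        up_units=up,
        down_units=down,
        kinase_results=kinase_results,
        background_units=background,
    )

    if with_network:
        directions = protein_directions(matrix, results, up, down)
        regulated_proteins = set(directions)
        sources = [
            (study.edges["string_db"], "string_db"),
            (study.edges["reactome_fi"], "reactome_fi"),
            (study.edges["metacore"], "metacore"),
        ]
        merged = net.merge_edge_sources(
            sources,
            string_score_min=string_score_min,
            allowed_nodes=regulated_proteins,
            node_directions=directions,
        )
        significant = [r for r in kinase_results if r.significant]
        full = net.add_kinase_edges(merged, significant, ksr_units)
        out.network = full
        if full.n_nodes:
            out.topology = net.topology_summary(full)
            out.clusters = net.find_clusters(
                full, penalty=cluster_penalty, p_max=cluster_p_max
            )

    if with_enrichment:
        bg_proteins = {u.protein for u in matrix.units.values()}
        up_genes = {matrix.units[k].protein for k in up}
        down_genes = {matrix.units[k].protein for k in down}
        cells = enr.enrich_terms(
            up_genes & bg_proteins, study.annotations, bg_proteins, group="up"
        ) + enr.enrich_terms(
            down_genes & bg_proteins, study.annotations, bg_proteins, group="down"
        )
        out.enrichment_cells = cells
        out.heatmap = enr.build_heatmap(cells, p_max=enrich_p_max, min_genes=min_genes)
    return out
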