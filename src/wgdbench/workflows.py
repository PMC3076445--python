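"""End-to-end inference workflows shared by the CLI, scripts and tests."""
from __future__ import annotations

from .clustering import build_pair_graph, cluster
from .model import Orthogroup, SpeciesMap
from .pairwise import RsdParams, apply_r_filter, rbh_pairs, rsd_pairs
from .similarity import ScoringParams, best_hits, filter_hits, score_all_vs_all

__all__ = ["infer_crbh", "infer_crsd", "internal_hits"]


def internal_hits(records, scoring: ScoringParams | None = None):
    """All-vs-all hits from the internal global-alignment scorer."""
    return score_all_vs_all(records, params=scoring)


def infer_crbh(
    hits,
    records,
    species_map: SpeciesMap,
    r: float | None = None,
    evalue_cutoff: float = 1e-5,
) -> list[Orthogroup]:
    """Clustering RBH: filter -> best hits -> reciprocal pairs -> optional
    r filter -> conflict-resolving clustering."""
    filtered = filter_hits(hits, species_map, evalue_cutoff)
    best = best_hits(filtered, species_map)
    pairs = rbh_pairs(best, species_map)
    if r is not None:
        index = {rec.gene_id: rec for rec in records}
        pairs = apply_r_filter(pairs, index, best, species_map, r)
    return cluster(build_pair_graph(pairs, species_map))


def infer_crsd(
    hits,
    records,
    species_map: SpeciesMap,
    params: RsdParams | None = None,
) -> list[Orthogroup]:
    """Clustering RSD: filter -> reciprocal smallest-distance pairs ->
    conflict-resolving clustering."""
    p = params or RsdParams()
    filtered = filter_hits(hits, species_map, p.evalue_cutoff)
    index = {rec.gene_id: rec for rec in records}
    pairs = rsd_pairs(filtered, index, species_map, p)
    return cluster(build_pair_graph(pairs, species_map))
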