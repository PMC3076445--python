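"""Pairwise ortholog inference.

Two reciprocal criteria are implemented:

* **RBH** — reciprocal best hit: X and Y are orthologs when each is the
  other's best hit in the partner species. An optional filtering parameter
  ``r`` in [0, 1] discards pairs whose sequence lengths or alignment
  coverage disagree: a pair is retained iff

      min(L_X, L_Y) / max(L_X, L_Y) >= r   and
      aln_length    / max(L_X, L_Y) >= r

  so r = 0 (or unset, the default) keeps every reciprocal pair and values
  near 1 keep only near-full-length matches.

* **RSD** — reciprocal smallest distance: for each query the top few hits
  into a target species are globally re-aligned and the candidate with the
  smallest evolutionary distance is taken; a pair is emitted when the
  relation is reciprocal. The distance is a gamma-rate-corrected Poisson
  estimate from the mismatch fraction p of aligned residue columns:

      d = a * ((1 - p)**(-1/a) - 1)

  with gamma shape a (default 0.5); as a -> infinity this tends to the
  Poisson correction -ln(1 - p).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .model import OrthologPair, ProteinRecord, SimilarityHit, SpeciesMap
from .similarity import (
    BestHitTable,
    ScoringParams,
    _hit_order_key,
    alignment_stats,
    make_aligner,
)

__all__ = [
    "OrthologPair",
    "RsdParams",
    "rbh_pairs",
    "apply_r_filter",
    "gamma_distance",
    "rsd_pairs",
]


@dataclass(frozen=True)
class RsdParams:
    """RSD settings: gamma shape ``a`` (default 0.5), how many top hits per
    (query, target species) to re-align, and the E-value cutoff already
    applied to the hit stream."""

    a: float = 0.5
    top_n: int = 3
    evalue_cutoff: float = 1e-5
    scoring: ScoringParams = ScoringParams()

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("gamma shape a must be > 0")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


# ---------------------------------------------------------------------------
# RBH
# ---------------------------------------------------------------------------

def rbh_pairs(best: BestHitTable, species_map: SpeciesMap) -> list[OrthologPair]:
    """Emit every mutual best-hit pair; support is the mean of the two
    directional bitscores."""
    pairs: dict[tuple[str, str], OrthologPair] = {}
    for (query, _target_sp), hit in best.items():
        x, y = query, hit.subject_id
        back = best.get(y, species_map.species_of(x))
        if back is None or back.subject_id != x:
            continue
        key = (min(x, y), max(x, y))
        if key not in pairs:
            support = 0.5 * (hit.bitscore + back.bitscore)
            pairs[key] = OrthologPair(x, y, support, "rbh")
    return [pairs[k] for k in sorted(pairs)]


def apply_r_filter(
    pairs,
    records: dict[str, ProteinRecord],
    best: BestHitTable,
    species_map: SpeciesMap,
    r: float | None,
) -> list[OrthologPair]:
    """Drop pairs failing the length-ratio / alignment-coverage rule.

    ``r`` unset (None) disables the filter, matching the default mode. The
    alignment length is read from the best hit in the direction smaller id
    -> larger id, which is deterministic for the unordered pair.
    """
    if r is None:
        return list(pairs)
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    kept = []
    for pair in pairs:
        x, y = pair.genes  # x < y by construction
        try:
            lx = records[x].length
            ly = records[y].length
        except KeyError as exc:
            raise ValueError(f"missing sequence record for pair ({x}, {y}): {exc}")
        hit = best.get(x, species_map.species_of(y))
        if hit is None or hit.subject_id != y:
            raise ValueError(f"missing best hit {x} -> {y} needed by the r filter")
        longer = max(lx, ly)
        if min(lx, ly) / longer >= r and hit.aln_length / longer >= r:
            kept.append(pair)
    return kept


# ---------------------------------------------------------------------------
# RSD
# ---------------------------------------------------------------------------

def gamma_distance(p: float, a: float) -> float:
    """Gamma-corrected Poisson distance from a mismatch fraction.

    Strictly increasing in p with d(0, a) = 0; for fixed p it decreases in
    the shape a towards the Poisson limit -ln(1 - p).
    """
    if a <= 0:
        raise ValueError("gamma shape a must be > 0")
    if not 0.0 <= p < 1.0:
        raise ValueError(f"mismatch fraction must lie in [0, 1), got {p}")
    return a * ((1.0 - p) ** (-1.0 / a) - 1.0)


def mismatch_fraction(seq_x: str, seq_y: str, aligner=None) -> float:
    """Fraction of mismatched residue columns in the global alignment of two
    sequences; columns with a gap in either sequence are excluded."""
    aligner = aligner or make_aligner()
    aln = aligner.align(seq_x, seq_y)[0]
    aligned, _ident, mism, _go = alignment_stats(aln)
    if aligned == 0:
        return 1.0  # no comparable columns: treat as saturated
    return mism / aligned


def rsd_pairs(
    hits,
    records: dict[str, ProteinRecord],
    species_map: SpeciesMap,
    params: RsdParams | None = None,
) -> list[OrthologPair]:
    """Reciprocal smallest-distance pairs.

    For each gene and each target species the ``top_n`` hits by bitscore are
    globally re-aligned; the nearest candidate minimises the gamma distance
    (ties by smaller gene id; saturated alignments, p >= 1, are treated as
    infinitely distant). A pair is emitted iff the nearest relation holds in
    both directions; support is the distance.
    """
    p = params or RsdParams()
    aligner = make_aligner(p.scoring)

    top: dict[tuple[str, str], list[SimilarityHit]] = {}
    for h in hits:
        key = (h.query_id, species_map.species_of(h.subject_id))
        top.setdefault(key, []).append(h)

    dist_cache: dict[tuple[str, str], float] = {}

    def distance(g1: str, g2: str) -> float:
        key = (min(g1, g2), max(g1, g2))
        if key not in dist_cache:
            frac = mismatch_fraction(
                records[key[0]].sequence, records[key[1]].sequence, aligner
            )
            try:
                dist_cache[key] = gamma_distance(frac, p.a)
            except ValueError:
                dist_cache[key] = math.inf
        return dist_cache[key]

    nearest: dict[tuple[str, str], str] = {}
    for (query, target_sp), candidates in top.items():
        candidates.sort(key=_hit_order_key)
        best_gene: str | None = None
        best_d = math.inf
        for h in candidates[: p.top_n]:
            d = distance(query, h.subject_id)
            if d < best_d or (d == best_d and (best_gene is None or h.subject_id < best_gene)):
                best_gene, best_d = h.subject_id, d
        if best_gene is not None and best_d < math.inf:
            nearest[(query, target_sp)] = best_gene

    pairs: dict[tuple[str, str], OrthologPair] = {}
    for (query, _target_sp), subject in nearest.items():
        back = nearest.get((subject, species_map.species_of(query)))
        if back != query:
            continue
        key = (min(query, subject), max(query, subject))
        if key not in pairs:
            pairs[key] = OrthologPair(key[0], key[1], distance(*key), "rsd")
    return [pairs[k] for k in sorted(pairs)]
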