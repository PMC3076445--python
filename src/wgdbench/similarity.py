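"""All-vs-all protein similarity.

The primary input path is precomputed 12-column tabular hits from an external
search tool. For synthetic data the module also scores proteomes internally:
exact global (Needleman-Wunsch/Gotoh) alignment under BLOSUM62 with affine
gaps (open 11, extend 1), converted to a bit score with fixed
Karlin-Altschul-style constants and to a synthetic E-value

    E = m * n * 2**(-bitscore)

where m and n are the full query and subject lengths. Only the ordering of
scores and the E-value cutoff semantics matter downstream; the internal
E-value is documented as synthetic-only and is not comparable to a database
search E-value.

Within-species hits are discarded everywhere: the clustering algorithms
predict single-copy cross-species groups.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .model import ProteinRecord, SimilarityHit, SpeciesMap

__all__ = [
    "SimilarityHit",
    "BestHitTable",
    "ScoringParams",
    "filter_hits",
    "best_hits",
    "score_all_vs_all",
    "make_aligner",
    "alignment_stats",
]

# residue order used by the vectorised prescreen
_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class ScoringParams:
    """Internal scorer configuration.

    lambda_/k are fixed gapped-BLOSUM62 Karlin-Altschul constants used only
    to put raw scores on a bit scale. ``prescreen_top`` bounds how many
    candidate subjects per (query, target species) are rescored with the
    exact affine-gap aligner; candidates are ranked by an exact ungapped
    global score, which dominates the affine score ordering for the
    full-length proteins this scorer is meant for. ``evalue_emit_max`` plays
    the role of a search tool's report threshold.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = 0.267
    k: float = 0.041
    prescreen_top: int = 5
    evalue_emit_max: float = 1e-3


def make_aligner(params: ScoringParams | None = None) -> Align.PairwiseAligner:
    """Global affine-gap aligner matching the toolkit's scoring scheme."""
    p = params or ScoringParams()
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(p.matrix)
    aligner.mode = "global"
    # a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(p.gap_open + p.gap_extend)
    aligner.extend_gap_score = -p.gap_extend
    return aligner


def alignment_stats(alignment) -> tuple[int, int, int, int]:
    """(aligned_columns, identities, mismatches, gap_openings) of one
    pairwise alignment; aligned_columns excludes gap columns."""
    c = alignment.counts()
    gapopen = (
        c.open_left_insertions
        + c.open_left_deletions
        + c.open_internal_insertions
        + c.open_internal_deletions
        + c.open_right_insertions
        + c.open_right_deletions
    )
    return c.aligned, c.identities, c.mismatches, gapopen


# ---------------------------------------------------------------------------
# Hit filtering and best-hit tables
# ---------------------------------------------------------------------------

def filter_hits(
    hits,
    species_map: SpeciesMap,
    evalue_cutoff: float = 1e-5,
) -> list[SimilarityHit]:
    """Keep cross-species, non-self hits with E-value <= cutoff."""
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    kept = []
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if species_map.species_of(h.query_id) == species_map.species_of(h.subject_id):
            continue
        if h.evalue <= evalue_cutoff:
            kept.append(h)
    return kept


def _hit_order_key(h: SimilarityHit):
    # higher bitscore, then lower evalue, then smaller subject id
    return (-h.bitscore, h.evalue, h.subject_id)


class BestHitTable:
    """At most one hit per (query, target species): the best under the total
    ordering (bitscore desc, evalue asc, subject id asc)."""

    def __init__(self, entries: dict[tuple[str, str], SimilarityHit] | None = None):
        self._entries: dict[tuple[str, str], SimilarityHit] = dict(entries or {})

    def get(self, query_id: str, target_species: str) -> SimilarityHit | None:
        return self._entries.get((query_id, target_species))

    def items(self):
        return self._entries.items()

    def hits(self):
        return list(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, BestHitTable) and self._entries == other._entries


def best_hits(hits, species_map: SpeciesMap) -> BestHitTable:
    """Reduce a filtered hit list to the best hit per (query, target species)."""
    table: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query_id, species_map.species_of(h.subject_id))
        prev = table.get(key)
        if prev is None or _hit_order_key(h) < _hit_order_key(prev):
            table[key] = h
    return BestHitTable(table)


# ---------------------------------------------------------------------------
# Internal scorer
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError:
        bad = sorted(set(seq) - set(_ALPHABET))
        raise ValueError(f"sequence contains non-amino-acid letters {bad}") from None


def _substitution_array(matrix_name: str) -> np.ndarray:
    m = substitution_matrices.load(matrix_name)
    n = len(_ALPHABET)
    arr = np.zeros((n, n), dtype=np.float64)
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            arr[i, j] = m[a, b]
    return arr


def _ungapped_score(qi: np.ndarray, block: np.ndarray, sub: np.ndarray,
                    gap_open: float, gap_extend: float) -> np.ndarray:
    """Exact ungapped global score of one encoded query against an equal-
    length block; for a longer/shorter block the overlap is scored and the
    length difference charged as one terminal gap (a ranking bound only)."""
    L = min(len(qi), block.shape[1])
    scores = sub[qi[None, :L], block[:, :L]].sum(axis=1)
    dL = abs(len(qi) - block.shape[1])
    if dL:
        scores = scores - (gap_open + gap_extend * dL)
    return scores


def score_all_vs_all(
    records,
    params: ScoringParams | None = None,
    species_map: SpeciesMap | None = None,
) -> list[SimilarityHit]:
    """Score every cross-species pair and emit hits for the candidates that
    clear ``evalue_emit_max``.

    Candidates per (query, target species) are the ``prescreen_top`` subjects
    by exact ungapped score; each is rescored with the affine-gap global
    aligner, so every emitted bitscore is a true alignment score. Candidate
    pairs are pooled over both directions and both directions of a surviving
    pair are emitted, so the output is exactly symmetric.
    """
    p = params or ScoringParams()
    records = list(records)
    for rec in records:
        if rec.length == 0:
            raise ValueError(f"zero-length sequence for gene {rec.gene_id!r}")
    sm = species_map or SpeciesMap.from_records(records)
    by_species: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species_id, []).append(rec)
    if len(by_species) < 2:
        raise ValueError("need proteomes from at least 2 species")
    for recs in by_species.values():
        recs.sort(key=lambda r: r.gene_id)

    sub = _substitution_array(p.matrix)
    enc = {rec.gene_id: _encode(rec.sequence) for rec in records}
    seqs = {rec.gene_id: rec.sequence for rec in records}
    aligner = make_aligner(p)

    # group each species' genes by length so the prescreen vectorises
    length_blocks: dict[str, list[tuple[np.ndarray, list[str]]]] = {}
    for sp, recs in by_species.items():
        blocks: dict[int, list[str]] = {}
        for rec in recs:
            blocks.setdefault(rec.length, []).append(rec.gene_id)
        length_blocks[sp] = [
            (np.stack([enc[g] for g in ids]), ids) for _, ids in sorted(blocks.items())
        ]

    def candidates(query_ids: list[str], target_sp: str) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for q in query_ids:
            qi = enc[q]
            scored: list[tuple[float, str]] = []
            for block, ids in length_blocks[target_sp]:
                sc = _ungapped_score(qi, block, sub, p.gap_open, p.gap_extend)
                scored.extend(zip(sc.tolist(), ids))
            scored.sort(key=lambda t: (-t[0], t[1]))
            for _, s in scored[: p.prescreen_top]:
                out.add((min(q, s), max(q, s)))
        return out

    hits: list[SimilarityHit] = []
    species = sorted(by_species)
    for i, sp_a in enumerate(species):
        ids_a = [r.gene_id for r in by_species[sp_a]]
        for sp_b in species[i + 1 :]:
            ids_b = [r.gene_id for r in by_species[sp_b]]
            pairs = candidates(ids_a, sp_b) | candidates(ids_b, sp_a)
            for g1, g2 in sorted(pairs):
                s1, s2 = seqs[g1], seqs[g2]
                raw = aligner.score(s1, s2)
                bitscore = (p.lambda_ * raw - np.log(p.k)) / np.log(2.0)
                evalue = len(s1) * len(s2) * 2.0 ** (-bitscore)
                if evalue > p.evalue_emit_max:
                    continue
                aln = aligner.align(s1, s2)[0]
                aligned, ident, mism, gapopen = alignment_stats(aln)
                aln_length = aln.shape[1]  # columns, gaps included
                pident = 100.0 * ident / aln_length if aln_length else 0.0
                for q, s in ((g1, g2), (g2, g1)):
                    hits.append(
                        SimilarityHit(
                            query_id=q,
                            subject_id=s,
                            pident=round(pident, 2),
                            aln_length=aln_length,
                            mismatch=mism,
                            gapopen=gapopen,
                            qstart=1,
                            qend=len(seqs[q]),
                            sstart=1,
                            send=len(seqs[s]),
                            evalue=float(evalue),
                            bitscore=round(float(bitscore), 1),
                        )
                    )
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits
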