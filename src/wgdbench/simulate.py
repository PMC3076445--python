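"""Synthetic WGD clade: six proteomes plus ground-truth pillars.

The generative model mirrors a small yeast-like clade: three pre-WGD
lineages and three post-WGD lineages whose common ancestor underwent a
single whole-genome duplication, leaving every homologous group with up to
two post-WGD gene copies, one per chromosomal track (A / B). For each pillar
an ancestral protein is drawn uniformly over the 20 amino acids and evolved
along the fixed topology

    root -> pre1, pre2, pre3                 (branch_divergence each)
    root -> WGD -> track-A / track-B ancestors (wgd_divergence / 2 each)
    track ancestor -> post1, post2, post3    (branch_divergence each)

by a Poisson substitution process: the number of substitutions on a branch
of expected length t subs/site is Poisson(L * t); each substitution picks a
uniform site and replaces the residue with one of the other 19 uniformly
(so repeat hits can partially revert, and the expected observed mismatch
fraction after divergence t is p(t) = (19/20) * (1 - exp(-20 t / 19))).

Each pillar is then assigned a loss class (0-IV) drawn from the configured
proportions, and a loss pattern is drawn uniformly among the patterns
consistent with that class; the lost post-WGD copies are deleted. Unrelated
random singleton proteins are added per species to exercise the true-negative
side of the evaluation. No indels are simulated, so every homologous pair
aligns end to end.

Everything is deterministic under the configured seed.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .benchmark import classify_pillar, stratified_eval
from .model import GoldPillar, ProteinRecord, SpeciesMap

__all__ = ["SimConfig", "SimResult", "simulate", "trap_rate", "write_result"]

PRE_SPECIES = ("pre1", "pre2", "pre3")
POST_SPECIES = ("post1", "post2", "post3")

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)


def _default_proportions() -> dict[str, float]:
    # the curated class frequencies are not published; a neutral uniform
    # mixture exercises every retention pattern equally
    return {"0": 0.2, "I": 0.2, "II": 0.2, "III": 0.2, "IV": 0.2}


@dataclass
class SimConfig:
    """Study conditions for one synthetic clade.

    Divergences are expected substitutions per site: ``branch_divergence``
    for each terminal lineage branch and ``wgd_divergence`` for the total
    separation between the two track ancestors.
    """

    n_pillars: int = 100
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    seq_length: int = 300
    branch_divergence: float = 0.2
    wgd_divergence: float = 0.3
    n_background_genes: int = 50
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if self.branch_divergence < 0 or self.wgd_divergence < 0:
            raise ValueError("divergences must be >= 0")
        unknown = set(self.class_proportions) - {"0", "I", "II", "III", "IV"}
        if unknown:
            raise ValueError(f"unknown loss classes {sorted(unknown)}")


@dataclass
class SimResult:
    proteomes: dict[str, list[ProteinRecord]]
    pillars: list[GoldPillar]
    provenance: dict

    @property
    def records(self) -> list[ProteinRecord]:
        return [r for sp in sorted(self.proteomes) for r in self.proteomes[sp]]

    @property
    def species_map(self) -> SpeciesMap:
        sm = SpeciesMap.from_records(self.records)
        sm.pre_species = set(PRE_SPECIES)
        sm.post_species = set(POST_SPECIES)
        return sm

    @property
    def n_total_genes(self) -> int:
        return sum(len(v) for v in self.proteomes.values())


# loss patterns: the six post-WGD duplicate slots are (species, track) pairs
_SLOTS = [(sp, t) for t in "AB" for sp in POST_SPECIES]


def _patterns_for_class(cls: str) -> list[frozenset]:
    """All sets of lost slots whose retention pattern has the given class."""
    out = []
    for n_lost in range(len(_SLOTS) + 1):
        for lost in itertools.combinations(_SLOTS, n_lost):
            lost_a = sum(1 for _, t in lost if t == "A")
            lost_b = n_lost - lost_a
            if n_lost == 0:
                c = "0"
            elif n_lost == 1:
                c = "I"
            elif n_lost == 2:
                c = "II"
            elif n_lost == 3:
                c = "IV" if lost_a == 0 or lost_b == 0 else "III"
            else:
                c = "unclassified"
            if c == cls:
                out.append(frozenset(lost))
    return out


_PATTERNS = {cls: _patterns_for_class(cls) for cls in ("0", "I", "II", "III", "IV")}


def _mutate(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson(L*t) substitutions, each to one of the other 19 residues."""
    seq = seq.copy()
    n_sub = rng.poisson(len(seq) * t)
    for _ in range(n_sub):
        site = rng.integers(len(seq))
        offset = rng.integers(1, 20)
        seq[site] = _AA[(np.searchsorted(_AA, seq[site]) + offset) % 20]
    return seq


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


def simulate(config: SimConfig) -> SimResult:
    """Generate the clade's proteomes and the matching ground-truth pillars."""
    rng = np.random.default_rng(config.seed)
    proteomes: dict[str, list[ProteinRecord]] = {
        sp: [] for sp in PRE_SPECIES + POST_SPECIES
    }
    pillars: list[GoldPillar] = []

    classes = sorted(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])

    for i in range(config.n_pillars):
        root = rng.choice(_AA, size=config.seq_length)
        cls = classes[rng.choice(len(classes), p=probs)]
        patterns = _PATTERNS[cls]
        lost = patterns[rng.integers(len(patterns))]

        pillar = GoldPillar(f"P{i:04d}", loss_class=cls)
        for sp in PRE_SPECIES:
            gene = f"{sp}_P{i:04d}"
            seq = _mutate(root, config.branch_divergence, rng)
            proteomes[sp].append(ProteinRecord(gene, sp, _to_str(seq)))
            pillar.pre_genes[sp] = gene
        anc_a = _mutate(root, config.wgd_divergence / 2.0, rng)
        anc_b = _mutate(root, config.wgd_divergence / 2.0, rng)
        for track, anc, slot in (("A", anc_a, pillar.track_a), ("B", anc_b, pillar.track_b)):
            for sp in POST_SPECIES:
                if (sp, track) in lost:
                    continue
                gene = f"{sp}_P{i:04d}{track.lower()}"
                seq = _mutate(anc, config.branch_divergence, rng)
                proteomes[sp].append(ProteinRecord(gene, sp, _to_str(seq)))
                slot[sp] = gene
        got = classify_pillar(pillar)
        if got != cls:
            raise AssertionError(
                f"pillar {pillar.pillar_id}: sampled class {cls} but pattern "
                f"classifies as {got}"
            )
        pillars.append(pillar)

    for sp in PRE_SPECIES + POST_SPECIES:
        for j in range(config.n_background_genes):
            seq = rng.choice(_AA, size=config.seq_length)
            proteomes[sp].append(
                ProteinRecord(f"{sp}_B{j:04d}", sp, _to_str(seq))
            )

    provenance = {
        "seed": config.seed,
        "n_pillars": config.n_pillars,
        "class_proportions": dict(sorted(config.class_proportions.items())),
        "seq_length": config.seq_length,
        "branch_divergence": config.branch_divergence,
        "wgd_divergence": config.wgd_divergence,
        "n_background_genes": config.n_background_genes,
    }
    return SimResult(proteomes, pillars, provenance)


def trap_rate(result: SimResult, groups) -> dict[str, float | None]:
    """Per-loss-class false discovery rate of a prediction on simulated data."""
    strata = stratified_eval(
        groups, result.pillars, result.n_total_genes
    )
    return {cls: ms.fdr for cls, (_totals, ms) in strata.items()}


def write_result(result: SimResult, out_dir) -> None:
    """FASTA per species + pillar TSV + JSON provenance sidecar."""
    out = Path(out_dir)
    (out / "fasta").mkdir(parents=True, exist_ok=True)
    for sp in sorted(result.proteomes):
        io_formats.write_fasta(result.proteomes[sp], out / "fasta" / f"{sp}.fasta")
    io_formats.write_pillars(result.pillars, out / "pillars.tsv")
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
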