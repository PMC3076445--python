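"""Gold-group benchmarking of orthogroup predictions.

The evaluation truth is a table of curated homolog pillars from a WGD clade:
each pillar carries up to one gene per pre-WGD species and up to two genes
(track A / track B) per post-WGD species. Because the post-WGD genes on the
two tracks are paralogs of one another, each pillar is split into two
single-copy *gold subgroups* — the pre-WGD genes plus one track — and every
prediction is scored only against the best-matching subgroup of a pillar, so
pre-WGD genes are never counted twice.

A predicted (test) group sharing at least two genes with some subgroup is
*defined*; its shared genes are true positives and its remaining genes false
positives. False negatives are gold genes absent from every test group.
Because the curated pillars cover only part of the true orthology, defined
counts are extrapolated to the undefined remainder with the ratio

    rho = (# genes in undefined test groups) / (# genes in defined test groups)

giving TP* = TP * rho (FP*, FN* likewise), totals tTP = TP + TP* etc., and
tTN = total genes - tTP - tFP - tFN. The four derived metrics are

    sensitivity = tTP / (tTP + tFN)      specificity = tTN / (tTN + tFP)
    accuracy    = (tTP + tTN) / (tTP + tTN + tFP + tFN)
    fdr         = tFP / (tFP + tTP)

Loss classes 0-IV stratify pillars by their pattern of post-WGD duplicate
loss; class III (three losses spanning both tracks) is the classic trap that
lures single-copy orthology methods into mixing paralogs from the two tracks.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .model import (
    GoldPillar,
    GoldSubgroup,
    GroupMatch,
    Orthogroup,
    POST_WGD_SLOTS,
    SpeciesMap,
)

__all__ = [
    "ConfusionTotals",
    "MetricSet",
    "classify_pillar",
    "split_pillars",
    "match_groups",
    "score_confusion",
    "metrics",
    "evaluate",
    "stratified_eval",
    "subset_sweep",
    "parameter_sweep",
]


@dataclass(frozen=True)
class ConfusionTotals:
    tp: int
    fp: int
    fn: int
    tp_x: float
    fp_x: float
    fn_x: float
    t_tp: float
    t_fp: float
    t_fn: float
    t_tn: float
    n_defined_genes: int
    n_undefined_genes: int
    n_total_genes: int

    @classmethod
    def from_counts(
        cls,
        tp: int,
        fp: int,
        fn: int,
        n_defined_genes: int,
        n_undefined_genes: int,
        n_total_genes: int,
    ) -> "ConfusionTotals":
        """Apply the undefined/defined extrapolation and the tTN identity."""
        if n_defined_genes == 0:
            if n_undefined_genes > 0:
                raise ValueError(
                    "extrapolation undefined: no genes in defined groups but "
                    f"{n_undefined_genes} genes in undefined groups"
                )
            rho = 0.0
        else:
            rho = n_undefined_genes / n_defined_genes
        tp_x, fp_x, fn_x = tp * rho, fp * rho, fn * rho
        t_tp, t_fp, t_fn = tp + tp_x, fp + fp_x, fn + fn_x
        t_tn = n_total_genes - t_tp - t_fp - t_fn
        if t_tn < 0:
            raise ValueError(
                f"negative tTN ({t_tn:.2f}): n_total_genes={n_total_genes} is "
                "smaller than the extrapolated confusion totals"
            )
        return cls(
            tp, fp, fn, tp_x, fp_x, fn_x, t_tp, t_fp, t_fn, t_tn,
            n_defined_genes, n_undefined_genes, n_total_genes,
        )


@dataclass(frozen=True)
class MetricSet:
    """The four derived metrics; a metric with a zero denominator is None."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    fdr: float | None


# ---------------------------------------------------------------------------
# Gold groups
# ---------------------------------------------------------------------------

def classify_pillar(pillar: GoldPillar, n_post_slots: int = POST_WGD_SLOTS) -> str:
    """Loss class from the post-WGD retention pattern.

    With 2 * n_post_slots duplicate slots: 0 losses -> class 0, 1 -> I,
    2 -> II, 3 spanning both tracks -> III, 3 all on one track -> IV,
    more -> unclassified.
    """
    retained = len(pillar.track_a) + len(pillar.track_b)
    losses = 2 * n_post_slots - retained
    if losses == 0:
        return "0"
    if losses == 1:
        return "I"
    if losses == 2:
        return "II"
    if losses == 3:
        lost_a = n_post_slots - len(pillar.track_a)
        lost_b = losses - lost_a
        return "IV" if lost_a == 0 or lost_b == 0 else "III"
    return "unclassified"


def split_pillars(pillars) -> list[GoldSubgroup]:
    """Two single-copy subgroups per pillar (pre-WGD genes + one track);
    a subgroup whose track is empty still carries the pre-WGD genes."""
    seen_ids: set[str] = set()
    subgroups: list[GoldSubgroup] = []
    for p in pillars:
        if p.pillar_id in seen_ids:
            raise ValueError(f"duplicate pillar id {p.pillar_id!r}")
        seen_ids.add(p.pillar_id)
        both = set(p.track_a.values()) & set(p.track_b.values())
        if both:
            raise ValueError(
                f"pillar {p.pillar_id!r}: genes on both tracks: {sorted(both)}"
            )
        pre = set(p.pre_genes.values())
        subgroups.append(
            GoldSubgroup(p.pillar_id, "A", frozenset(pre | set(p.track_a.values())))
        )
        subgroups.append(
            GoldSubgroup(p.pillar_id, "B", frozenset(pre | set(p.track_b.values())))
        )
    return subgroups


# ---------------------------------------------------------------------------
# Matching and confusion counting
# ---------------------------------------------------------------------------

def match_groups(test_groups, subgroups) -> list[GroupMatch]:
    """Best gold-subgroup match per test group.

    Each pillar offers only its better-matching subgroup (pre-WGD genes are
    shared by both halves and must not be counted twice). Ties are broken by
    the larger fraction of the test group shared, then the smaller subgroup
    id. Defined means >= 2 shared genes.
    """
    # gene -> subgroups index for sub-quadratic matching
    gene_index: dict[str, list[GoldSubgroup]] = {}
    for sg in subgroups:
        for gene in sg.members:
            gene_index.setdefault(gene, []).append(sg)

    matches: list[GroupMatch] = []
    for tg in sorted(test_groups, key=lambda g: g.group_id):
        shared_count: dict[str, int] = {}
        by_id: dict[str, GoldSubgroup] = {}
        for gene in tg.members:
            for sg in gene_index.get(gene, ()):
                shared_count[sg.subgroup_id] = shared_count.get(sg.subgroup_id, 0) + 1
                by_id[sg.subgroup_id] = sg
        # per pillar keep only the better subgroup
        per_pillar: dict[str, str] = {}
        for sgid, n in shared_count.items():
            pid = by_id[sgid].pillar_id
            prev = per_pillar.get(pid)
            if prev is None or _match_key(n, tg, sgid) < _match_key(
                shared_count[prev], tg, prev
            ):
                per_pillar[pid] = sgid
        if per_pillar:
            best = min(
                per_pillar.values(), key=lambda sgid: _match_key(shared_count[sgid], tg, sgid)
            )
            shared = shared_count[best]
        else:
            best, shared = None, 0
        if shared >= 2:
            matches.append(GroupMatch(tg.group_id, best, shared, "defined"))
        else:
            matches.append(GroupMatch(tg.group_id, None, shared, "undefined"))
    return matches


def _match_key(shared: int, test_group: Orthogroup, subgroup_id: str):
    # sort ascending: more shared first, larger shared fraction of the test
    # group first, then lexicographic subgroup id
    return (-shared, -shared / len(test_group.members), subgroup_id)


def score_confusion(
    matches,
    test_groups,
    subgroups,
    n_total_genes: int,
) -> ConfusionTotals:
    """Gene-level confusion counts over defined groups, extrapolated to the
    undefined remainder (see module docstring for the counting rules)."""
    groups_by_id = {g.group_id: g for g in test_groups}
    subgroups_by_id = {sg.subgroup_id: sg for sg in subgroups}
    gold_universe: set[str] = set()
    for sg in subgroups:
        gold_universe |= sg.members

    tp = fp = 0
    n_defined = n_undefined = 0
    predicted_genes: set[str] = set()
    for g in test_groups:
        predicted_genes |= g.members
    for m in matches:
        tg = groups_by_id[m.group_id]
        if m.status == "defined":
            sg = subgroups_by_id[m.subgroup_id]
            tp += len(tg.members & sg.members)
            fp += len(tg.members - sg.members)
            n_defined += len(tg.members)
        else:
            n_undefined += len(tg.members)
    fn = len(gold_universe - predicted_genes)
    return ConfusionTotals.from_counts(
        tp, fp, fn, n_defined, n_undefined, n_total_genes
    )


def metrics(c: ConfusionTotals) -> MetricSet:
    def ratio(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    return MetricSet(
        sensitivity=ratio(c.t_tp, c.t_tp + c.t_fn),
        specificity=ratio(c.t_tn, c.t_tn + c.t_fp),
        accuracy=ratio(c.t_tp + c.t_tn, c.t_tp + c.t_tn + c.t_fp + c.t_fn),
        fdr=ratio(c.t_fp, c.t_fp + c.t_tp),
    )


# ---------------------------------------------------------------------------
# Whole-pipeline conveniences
# ---------------------------------------------------------------------------

def evaluate(
    test_groups,
    pillars,
    n_total_genes: int,
) -> tuple[ConfusionTotals, MetricSet]:
    """split -> match -> count -> metrics on the full pillar set."""
    subgroups = split_pillars(pillars)
    matches = match_groups(test_groups, subgroups)
    totals = score_confusion(matches, test_groups, subgroups, n_total_genes)
    return totals, metrics(totals)


def stratified_eval(
    test_groups,
    pillars,
    n_total_genes: int,
    classes=None,
) -> dict[str, tuple[ConfusionTotals, MetricSet]]:
    """The full pipeline restricted to pillars of one loss class at a time.

    ``classes`` defaults to the classes present. The gold universe, matching
    and extrapolation are all recomputed within each stratum; the gene
    universe (n_total_genes) stays global. Passing a single pseudo-stratum
    containing every pillar reproduces the global evaluation.
    """
    for p in pillars:
        cls = classify_pillar(p)
        if p.loss_class != cls:
            raise ValueError(
                f"pillar {p.pillar_id!r}: stored class {p.loss_class!r} does not "
                f"match retention pattern ({cls!r})"
            )
    present = sorted({p.loss_class for p in pillars})
    wanted = list(classes) if classes is not None else present
    out: dict[str, tuple[ConfusionTotals, MetricSet]] = {}
    for cls in wanted:
        stratum = [p for p in pillars if p.loss_class == cls]
        if not stratum:
            continue
        out[cls] = evaluate(test_groups, stratum, n_total_genes)
    return out


def restrict_pillars(pillars, species_subset) -> list[GoldPillar]:
    """Pillars restricted to a species subset; pillars left with fewer than
    two genes (both subgroups degenerate) are dropped."""
    kept = []
    for p in pillars:
        rp = p.restrict(species_subset)
        rp.loss_class = classify_pillar(rp)
        sizes = [
            len(set(rp.pre_genes.values()) | set(rp.track_a.values())),
            len(set(rp.pre_genes.values()) | set(rp.track_b.values())),
        ]
        if max(sizes) >= 2:
            kept.append(rp)
    return kept


def subset_sweep(
    records,
    hits,
    pillars,
    k: int,
    infer,
    species_map: SpeciesMap,
) -> pd.DataFrame:
    """Re-run inference and evaluation on every k-species subset.

    ``infer(hits_subset, records_subset, species_map_subset) -> groups`` is
    the prediction callback. Gold subgroups are rebuilt restricted to the
    subset (dropping pillars left with < 2 genes); the gene universe is the
    subset's proteome size. Returns one row per subset plus a ``mean`` row.
    """
    species = sorted(species_map.species)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(species):
        raise ValueError(f"k={k} exceeds the {len(species)} species present")
    rows = []
    for subset in itertools.combinations(species, k):
        keep = set(subset)
        sub_map = species_map.restrict(keep)
        sub_records = [r for r in records if r.species_id in keep]
        sub_hits = [
            h
            for h in hits
            if species_map.species_of(h.query_id) in keep
            and species_map.species_of(h.subject_id) in keep
        ]
        groups = infer(sub_hits, sub_records, sub_map)
        sub_pillars = restrict_pillars(pillars, keep)
        totals, ms = evaluate(groups, sub_pillars, len(sub_records))
        rows.append(
            {
                "subset": "+".join(subset),
                "k": k,
                "n_groups": len(groups),
                **_totals_row(totals),
                **_metrics_row(ms),
            }
        )
    frame = pd.DataFrame(rows)
    mean = frame.drop(columns=["subset"]).mean(numeric_only=True).to_dict()
    frame = pd.concat(
        [frame, pd.DataFrame([{"subset": "mean", **mean}])], ignore_index=True
    )
    return frame


def parameter_sweep(
    grid,
    infer_for_param,
    pillars,
    n_total_genes: int,
) -> pd.DataFrame:
    """One evaluation per grid value plus ROC coordinates.

    ``infer_for_param(value) -> groups``. Rows keep the grid order; the ROC
    point is (1 - specificity, sensitivity).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("parameter grid must be non-empty")
    rows = []
    for value in grid:
        groups = infer_for_param(value)
        totals, ms = evaluate(groups, pillars, n_total_genes)
        fpr = None if ms.specificity is None else 1.0 - ms.specificity
        rows.append(
            {
                "param": "unset" if value is None else value,
                "n_groups": len(groups),
                **_totals_row(totals),
                **_metrics_row(ms),
                "one_minus_specificity": fpr,
            }
        )
    return pd.DataFrame(rows)


def _totals_row(c: ConfusionTotals) -> dict:
    return {
        "TP": c.tp, "FP": c.fp, "FN": c.fn,
        "TPx": c.tp_x, "FPx": c.fp_x, "FNx": c.fn_x,
        "tTP": c.t_tp, "tFP": c.t_fp, "tFN": c.t_fn, "tTN": c.t_tn,
        "defined_genes": c.n_defined_genes,
        "undefined_genes": c.n_undefined_genes,
        "total_genes": c.n_total_genes,
    }


def _metrics_row(m: MetricSet) -> dict:
    return {
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "accuracy": m.accuracy,
        "fdr": m.fdr,
    }
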