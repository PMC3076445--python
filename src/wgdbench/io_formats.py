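"""Readers and writers for every on-disk representation the toolkit touches.

Formats
-------
* FASTA proteomes, one file per species (species id = file stem, overridable
  by an explicit two-column mapping file).
* 12-column BLAST tabular hits (qseqid sseqid pident length mismatch gapopen
  qstart qend sstart send evalue bitscore); lines starting ``#`` are skipped.
* Orthogroup files: native TSV ``group_id<TAB>gene_id<TAB>species_id``,
  the OrthoMCL ``groups.txt`` dialect (``GROUP: sp|gene sp|gene ...``), and a
  generic one-group-per-line whitespace format.
* Pillar tables: TSV ``pillar_id<TAB>species_id<TAB>track<TAB>gene_id`` with
  track in {PRE, A, B}.
* YAML run configuration for the CLI.

Gene ids are case-sensitive and compared exactly.
"""
from __future__ import annotations

from pathlib import Path

import yaml
from Bio import SeqIO

from .model import (
    GoldPillar,
    Orthogroup,
    ProteinRecord,
    SimilarityHit,
    SpeciesMap,
)

GROUP_FORMATS = ("native-tsv", "orthomcl-groups", "generic")

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


# ---------------------------------------------------------------------------
# FASTA proteomes
# ---------------------------------------------------------------------------

def read_fasta(path, species_id: str | None = None) -> list[ProteinRecord]:
    """Read one species' proteome. The header token before the first
    whitespace is the gene id; ``species_id`` defaults to the file stem."""
    path = Path(path)
    if species_id is None:
        species_id = path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        seq = str(rec.seq).upper()
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r} in {path}")
        if not seq:
            raise ValueError(f"empty sequence for gene {gene_id!r} in {path}")
        seen.add(gene_id)
        records.append(ProteinRecord(gene_id, species_id, seq))
    return records


def read_proteomes(
    fasta_paths, species_names: dict[str, str] | None = None
) -> tuple[list[ProteinRecord], SpeciesMap]:
    """Read several one-per-species FASTA files into a single gene universe.

    ``species_names`` optionally maps file stem -> species id (the on-disk
    form of the two-column mapping file). Duplicate gene ids across files are
    a hard error.
    """
    records: list[ProteinRecord] = []
    by_id: dict[str, str] = {}
    for path in sorted(Path(p) for p in fasta_paths):
        sp = (species_names or {}).get(path.stem, path.stem)
        for rec in read_fasta(path, species_id=sp):
            if rec.gene_id in by_id:
                raise ValueError(
                    f"duplicate gene id {rec.gene_id!r}: appears in species "
                    f"{by_id[rec.gene_id]!r} and {sp!r}"
                )
            by_id[rec.gene_id] = sp
            records.append(rec)
    return records, SpeciesMap.from_records(records)


def read_species_mapping(path) -> dict[str, str]:
    """Two-column TSV: file stem -> species id."""
    mapping = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        stem, sp = line.split("\t")
        mapping[stem] = sp
    return mapping


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular hits
# ---------------------------------------------------------------------------

def read_blast_tab(path, species_map: SpeciesMap) -> list[SimilarityHit]:
    """Parse 12-column tabular hits. Self-hits are retained (consumers
    filter them); gene ids missing from ``species_map`` are an error."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            for gid in (q, s):
                if gid not in species_map:
                    raise ValueError(
                        f"{path}:{lineno}: gene id {gid!r} not present in "
                        "any proteome"
                    )
            try:
                hit = SimilarityHit(
                    query_id=q,
                    subject_id=s,
                    pident=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
            hits.append(hit)
    return hits


def write_blast_tab(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident:.2f}\t{h.aln_length}"
                f"\t{h.mismatch}\t{h.gapopen}\t{h.qstart}\t{h.qend}"
                f"\t{h.sstart}\t{h.send}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Orthogroup files
# ---------------------------------------------------------------------------

def _finish_group(
    group_id: str,
    genes: list[tuple[str, str]],
    source: str,
) -> Orthogroup:
    seen: set[str] = set()
    species_seen: dict[str, int] = {}
    for gid, sp in genes:
        if gid in seen:
            raise ValueError(
                f"{source}: gene {gid!r} appears twice in group {group_id!r}"
            )
        seen.add(gid)
        species_seen[sp] = species_seen.get(sp, 0) + 1
    multi = any(n > 1 for n in species_seen.values())
    return Orthogroup(group_id, frozenset(seen), multi_copy=multi)


def read_groups(
    path,
    format: str = "native-tsv",
    species_map: SpeciesMap | None = None,
) -> list[Orthogroup]:
    """Read orthogroups in one of the supported dialects.

    Third-party groups may carry more than one gene per species and are
    flagged ``multi_copy``; native cRBH/cRSD output never is.
    """
    if format not in GROUP_FORMATS:
        raise ValueError(f"unknown group format {format!r}; use one of {GROUP_FORMATS}")
    path = Path(path)
    lines = path.read_text().splitlines()

    def resolve(gid: str, lineno: int, sp_hint: str | None = None) -> str:
        if species_map is not None:
            try:
                return species_map.species_of(gid)
            except KeyError:
                raise ValueError(
                    f"{path}:{lineno}: unresolvable gene id {gid!r}"
                ) from None
        if sp_hint is None:
            raise ValueError(
                f"{path}:{lineno}: gene id {gid!r} needs a species map to resolve"
            )
        return sp_hint

    groups: list[Orthogroup] = []
    if format == "native-tsv":
        rows: dict[str, list[tuple[str, str]]] = {}
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            group_id, gid, sp = parts
            sp = resolve(gid, lineno, sp_hint=sp)
            rows.setdefault(group_id, []).append((gid, sp))
        for group_id in sorted(rows):
            groups.append(_finish_group(group_id, rows[group_id], str(path)))
    elif format == "orthomcl-groups":
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            head, _, rest = line.partition(":")
            group_id = head.strip()
            genes = []
            for token in rest.split():
                sp_tag, _, gid = token.partition("|")
                if not gid:  # bare gene id, no species prefix
                    gid, sp_tag = sp_tag, None
                sp = resolve(gid, lineno, sp_hint=sp_tag)
                genes.append((gid, sp))
            groups.append(_finish_group(group_id, genes, str(path)))
    else:  # generic
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            genes = [(gid, resolve(gid, lineno)) for gid in line.split()]
            groups.append(_finish_group(f"G{lineno}", genes, str(path)))
    return groups


def write_groups(groups, path, species_map: SpeciesMap) -> None:
    """Write native TSV, rows sorted (group then gene) for byte stability."""
    with open(path, "w") as fh:
        for g in sorted(groups, key=lambda g: g.group_id):
            for gid in sorted(g.members):
                fh.write(f"{g.group_id}\t{gid}\t{species_map.species_of(gid)}\n")


# ---------------------------------------------------------------------------
# Pillar tables
# ---------------------------------------------------------------------------

def read_pillars(path) -> list[GoldPillar]:
    """TSV columns: pillar_id, species_id, track (PRE|A|B), gene_id."""
    path = Path(path)
    pillars: dict[str, GoldPillar] = {}
    order: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        pid, sp, track, gid = parts
        if pid not in pillars:
            pillars[pid] = GoldPillar(pid)
            order.append(pid)
        p = pillars[pid]
        slot = {"PRE": p.pre_genes, "A": p.track_a, "B": p.track_b}.get(track)
        if slot is None:
            raise ValueError(f"{path}:{lineno}: track must be PRE, A or B, got {track!r}")
        if sp in slot:
            raise ValueError(
                f"{path}:{lineno}: duplicate slot ({pid}, {sp}, {track})"
            )
        slot[sp] = gid
    # classify on load so the stored tag is always consistent
    from .benchmark import classify_pillar

    for p in pillars.values():
        p.loss_class = classify_pillar(p)
    return [pillars[pid] for pid in order]


def write_pillars(pillars, path) -> None:
    with open(path, "w") as fh:
        for p in pillars:
            for sp in sorted(p.pre_genes):
                fh.write(f"{p.pillar_id}\t{sp}\tPRE\t{p.pre_genes[sp]}\n")
            for sp in sorted(p.track_a):
                fh.write(f"{p.pillar_id}\t{sp}\tA\t{p.track_a[sp]}\n")
            for sp in sorted(p.track_b):
                fh.write(f"{p.pillar_id}\t{sp}\tB\t{p.track_b[sp]}\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
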