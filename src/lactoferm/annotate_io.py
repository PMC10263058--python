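"""Reading and filtering of genome annotations and homology hit tables.

Annotations come in as GFF3 CDS features carrying functional identifiers in
their attribute column; homology evidence comes in as BLAST-outfmt-6-like TSV
tables with an appended query-coverage column.  The only filtering applied to
hits is the inclusive percent-identity / query-coverage threshold pair used
for tblastn homologue searches (defaults ≥25% identity, ≥75% coverage).

GFF attribute dialect (configurable, JGI-style): EC numbers are read from
``ec_number``/``EC_number``, KEGG orthology ids from ``ko``/``KO``, COG ids
from ``cog``/``COG``, the free-text product from ``product``.  Multiple
values may be comma-separated.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "HomologyHit",
    "GffParseError",
    "parse_gff",
    "read_hit_table",
    "write_hit_table",
    "filter_hits",
    "evidence_index",
    "HIT_TABLE_COLUMNS",
]

# BLAST outfmt-6-like layout with an extra qcovs column; order is fixed.
HIT_TABLE_COLUMNS = (
    "query_id",
    "genome_id",
    "subject_locus",
    "percent_identity",
    "query_coverage",
    "evalue",
)

_EC_KEYS = ("ec_number", "EC_number")
_KO_KEYS = ("ko", "KO")
_COG_KEYS = ("cog", "COG")


class GffParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneAnnotation:
    """One called gene (CDS) on a contig; coordinates 1-based inclusive."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    product: str = ""
    ec_numbers: frozenset[str] = frozenset()
    ko_ids: frozenset[str] = frozenset()
    cog_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start < 1:
            raise GffParseError(f"{self.locus_tag}: start < 1")
        if self.end < self.start:
            raise GffParseError(f"{self.locus_tag}: end < start")
        if not self.locus_tag:
            raise GffParseError("empty locus_tag")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HomologyHit:
    """One filtered-search hit of a reference query protein onto a genome locus."""

    query_id: str
    genome_id: str
    subject_locus: str
    percent_identity: float
    query_coverage: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity outside [0, 100]")
        if not 0 <= self.query_coverage <= 100:
            raise ValueError("query_coverage outside [0, 100]")


def _multi_attr(feature, keys: Sequence[str]) -> frozenset[str]:
    values: set[str] = set()
    for key in keys:
        for raw in feature.attributes.get(key, []):
            values.update(v.strip() for v in raw.split(",") if v.strip())
    return frozenset(values)


def parse_gff(path: str | Path, genome_id: str | None = None) -> list[GeneAnnotation]:
    """Parse GFF3 CDS features into :class:`GeneAnnotation` records.

    ``genome_id`` defaults to the file stem.  Records are returned sorted by
    (contig_id, start).  Malformed lines raise :class:`GffParseError` naming
    the line number; a feature with end < start raises naming the locus.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    # validate the tabular shape up front so errors carry line numbers
    has_features = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        has_features = True
        n_cols = len(line.split("\t"))
        if n_cols != 9:
            raise GffParseError(
                f"{path.name}:{lineno}: expected 9 tab-separated columns, got {n_cols}"
            )
    if not has_features:
        return []
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types
        raise GffParseError(f"{path.name}: unparseable GFF3 ({exc})") from exc

    records: list[GeneAnnotation] = []
    for feat in db.features_of_type("CDS"):
        locus = (feat.attributes.get("locus_tag") or feat.attributes.get("ID") or [""])[0]
        product = (feat.attributes.get("product") or [""])[0]
        records.append(
            GeneAnnotation(
                genome_id=genome_id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                locus_tag=locus,
                product=product,
                ec_numbers=_multi_attr(feat, _EC_KEYS),
                ko_ids=_multi_attr(feat, _KO_KEYS),
                cog_ids=_multi_attr(feat, _COG_KEYS),
            )
        )
    records.sort(key=lambda r: (r.contig_id, r.start))
    seen: set[str] = set()
    for rec in records:
        if rec.locus_tag in seen:
            raise GffParseError(f"duplicate locus_tag {rec.locus_tag!r} in {path.name}")
        seen.add(rec.locus_tag)
    return records


def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Read a homology hit TSV (columns :data:`HIT_TABLE_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(HIT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return [
        HomologyHit(
            query_id=str(row.query_id),
            genome_id=str(row.genome_id),
            subject_locus=str(row.subject_locus),
            percent_identity=float(row.percent_identity),
            query_coverage=float(row.query_coverage),
            evalue=float(row.evalue),
        )
        for row in df.itertuples(index=False)
    ]


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (h.query_id, h.genome_id, h.subject_locus, h.percent_identity,
             h.query_coverage, h.evalue)
            for h in hits
        ],
        columns=list(HIT_TABLE_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def filter_hits(
    hits: Sequence[HomologyHit],
    min_pid: float = 25.0,
    min_qcov: float = 75.0,
) -> list[HomologyHit]:
    """Keep hits with percent_identity ≥ min_pid and query_coverage ≥ min_qcov.

    Boundaries are inclusive; input order is preserved; idempotent.
    """
    if not (0 <= min_pid <= 100 and 0 <= min_qcov <= 100):
        raise ValueError("thresholds must lie in [0, 100]")
    return [
        h for h in hits
        if h.percent_identity >= min_pid and h.query_coverage >= min_qcov
    ]


def evidence_index(
    annotations: Sequence[GeneAnnotation],
    filtered_hits: Sequence[HomologyHit],
) -> dict[str, dict[str, list[str]]]:
    """Join hit evidence onto annotations: genome -> query -> sorted locus_tags.

    Every hit's subject locus must exist among the annotations of its genome;
    dangling loci raise a ValueError listing the orphans.
    """
    known: dict[str, set[str]] = {}
    for ann in annotations:
        known.setdefault(ann.genome_id, set()).add(ann.locus_tag)
    orphans = [
        f"{h.genome_id}:{h.subject_locus}"
        for h in filtered_hits
        if h.subject_locus not in known.get(h.genome_id, set())
    ]
    if orphans:
        raise ValueError(f"hits reference unknown loci: {', '.join(sorted(set(orphans)))}")
    index: dict[str, dict[str, list[str]]] = {}
    for h in filtered_hits:
        bucket = index.setdefault(h.genome_id, {}).setdefault(h.query_id, [])
        if h.subject_locus not in bucket:
            bucket.append(h.subject_locus)
    for per_genome in index.values():
        for loci in per_genome.values():
            loci.sort()
    return index
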