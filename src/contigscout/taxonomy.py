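"""Homology hit tables, per-ORF hit ranking and per-contig taxon summaries.

The hit table is the extended tabular homology-search dialect: tab-separated,
no header, eight columns per row::

    qseqid  sseqid  pident  length  evalue  bitscore  stitle  staxlineage

``staxlineage`` is a pre-resolved, semicolon-joined lineage, domain first
(domain;phylum;class;order;family;genus;species); strings with fewer than
seven fields are padded with ``unclassified``. Query ids follow the
``<contig_id>_<1-based serial>`` convention, which is how hits are attributed
to contigs.

Per-contig classification uses the top hit of each hit-bearing ORF only;
ORFs without any database hit are counted but never dilute taxon fractions.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .errors import FormatError, InputError, ParameterError

RANKS: Tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)
CANONICAL_DOMAINS = frozenset(
    ("Bacteria", "Archaea", "Eukaryota", "Viruses", "unclassified")
)
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class TaxLineage:
    """A seven-rank lineage: domain, phylum, class, order, family, genus,
    species. Missing ranks hold the placeholder ``unclassified``."""

    ranks: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ParameterError(
                f"lineage must have {len(RANKS)} ranks, got {len(self.ranks)}"
            )

    @classmethod
    def from_string(cls, text: str) -> "TaxLineage":
        parts = [p.strip() or UNCLASSIFIED for p in text.split(";")]
        parts = parts[: len(RANKS)]
        parts += [UNCLASSIFIED] * (len(RANKS) - len(parts))
        return cls(tuple(parts))

    @classmethod
    def make(cls, **kwargs: str) -> "TaxLineage":
        """Build a lineage from rank keyword arguments, e.g.
        ``TaxLineage.make(domain="Bacteria", genus="Pseudomonas")``."""
        unknown = set(kwargs) - set(RANKS)
        if unknown:
            raise ParameterError(f"unknown ranks: {sorted(unknown)}")
        return cls(tuple(kwargs.get(r, UNCLASSIFIED) for r in RANKS))

    def at(self, rank: str) -> str:
        if rank not in RANKS:
            raise ParameterError(f"unknown rank: '{rank}'")
        return self.ranks[RANKS.index(rank)]

    @property
    def domain(self) -> str:
        return self.ranks[0]

    @property
    def genus(self) -> str:
        return self.ranks[5]

    @property
    def species(self) -> str:
        return self.ranks[6]

    def is_prokaryotic(self) -> bool:
        return self.domain in ("Bacteria", "Archaea")

    def __str__(self) -> str:
        return ";".join(self.ranks)


@dataclass
class HitRecord:
    """One homology hit of an ORF against the reference database."""

    orf_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    subject_title: str
    lineage: TaxLineage

    def to_line(self) -> str:
        return "\t".join(
            (
                self.orf_id,
                self.subject_id,
                f"{self.percent_identity:g}",
                str(self.aln_length),
                f"{self.evalue:g}",
                f"{self.bitscore:g}",
                self.subject_title,
                str(self.lineage),
            )
        )


@dataclass
class HitGroup:
    """The ranked hits of one ORF: bitscore desc, then e-value asc, then
    input order (stable)."""

    orf_id: str
    hits: List[HitRecord]

    @classmethod
    def from_hits(cls, orf_id: str, hits: Sequence[HitRecord]) -> "HitGroup":
        ranked = sorted(
            range(len(hits)),
            key=lambda i: (-hits[i].bitscore, hits[i].evalue, i),
        )
        return cls(orf_id, [hits[i] for i in ranked])

    def top(self) -> HitRecord:
        return self.hits[0]

    @property
    def contig_id(self) -> str:
        return contig_of_orf(self.orf_id)


def contig_of_orf(orf_id: str) -> str:
    """Contig id from an ``<contig_id>_<serial>`` query id."""
    return orf_id.rsplit("_", 1)[0]


def _orf_serial(orf_id: str) -> int:
    try:
        return int(orf_id.rsplit("_", 1)[1])
    except (IndexError, ValueError):
        return 0


N_HIT_COLUMNS = 8


def parse_hit_table(path) -> "OrderedDict[str, HitGroup]":
    """Parse a ``.blast`` hit table into HitGroups keyed by ORF id, in order
    of first appearance."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"hit table not found: {p}")
    raw: "OrderedDict[str, List[HitRecord]]" = OrderedDict()
    with open(p) as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != N_HIT_COLUMNS:
                raise FormatError(
                    f"line {line_number}: expected {N_HIT_COLUMNS} "
                    f"tab-separated columns, found {len(fields)}"
                )
            qseqid, sseqid, pident, length, evalue, bitscore, stitle, lineage = fields
            try:
                hit = HitRecord(
                    orf_id=qseqid,
                    subject_id=sseqid,
                    percent_identity=float(pident),
                    aln_length=int(length),
                    evalue=float(evalue),
                    bitscore=float(bitscore),
                    subject_title=stitle,
                    lineage=TaxLineage.from_string(lineage),
                )
            except ValueError:
                raise FormatError(
                    f"line {line_number}: unparsable numeric field"
                ) from None
            raw.setdefault(qseqid, []).append(hit)
    return OrderedDict(
        (orf_id, HitGroup.from_hits(orf_id, hits)) for orf_id, hits in raw.items()
    )


def write_hit_table(groups: Mapping[str, HitGroup], path) -> None:
    """Serialize hit groups back to the tabular dialect, in rank order."""
    with open(path, "w") as handle:
        for group in groups.values():
            for hit in group.hits:
                handle.write(hit.to_line() + "\n")


def top_hits(group: HitGroup, n: int = 100) -> HitGroup:
    """The first ``min(n, available)`` hits in rank order."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    return HitGroup(group.orf_id, group.hits[:n])


@dataclass
class ContigTaxonSummary:
    """Top-hit taxonomy of one contig.

    ``top_hits`` holds the best hit of every hit-bearing ORF, in ORF serial
    order; taxon fractions at any rank are computed over these.
    """

    contig_id: str
    n_orfs: int
    top_hits: List[HitRecord] = field(default_factory=list)

    @property
    def n_orfs_with_hits(self) -> int:
        return len(self.top_hits)

    @property
    def n_orfs_without_hits(self) -> int:
        return max(0, self.n_orfs - self.n_orfs_with_hits)

    @property
    def mean_aai(self) -> Optional[float]:
        """Mean percent identity of the per-ORF top hits (None if no hits)."""
        if not self.top_hits:
            return None
        return sum(h.percent_identity for h in self.top_hits) / len(self.top_hits)

    def taxon_fractions(self, rank: str) -> Dict[str, float]:
        if rank not in RANKS:
            raise ParameterError(f"unknown rank: '{rank}'")
        if not self.top_hits:
            return {}
        counts: Dict[str, int] = {}
        for hit in self.top_hits:
            taxon = hit.lineage.at(rank)
            counts[taxon] = counts.get(taxon, 0) + 1
        n = len(self.top_hits)
        return {t: c / n for t, c in counts.items()}

    def fraction(self, taxon: str, rank: str) -> float:
        """Fraction of hit-bearing ORFs whose top hit carries ``taxon`` at
        ``rank`` (case-insensitive exact match)."""
        fractions = self.taxon_fractions(rank)
        taxon_lower = taxon.lower()
        return sum(f for t, f in fractions.items() if t.lower() == taxon_lower)


def summarize_contig(
    contig_id: str,
    hit_groups: Sequence[HitGroup],
    n_orfs: int,
) -> ContigTaxonSummary:
    """Aggregate the hit groups of one contig's ORFs into a summary."""
    ordered = sorted(hit_groups, key=lambda g: _orf_serial(g.orf_id))
    tops = [g.top() for g in ordered if g.hits]
    return ContigTaxonSummary(contig_id=contig_id, n_orfs=n_orfs, top_hits=tops)


def classify_contig(
    summary: ContigTaxonSummary,
    taxon: str,
    rank: str,
    perc: float = 50.0,
    phage: bool = False,
) -> bool:
    """True iff strictly more than ``perc`` percent of the contig's
    hit-bearing ORFs have a top hit matching ``taxon`` at ``rank``.

    With ``phage=True`` a hit matches if its domain is Viruses AND the taxon
    token appears (case-insensitively) in the subject title or anywhere in
    the lineage — phage subjects are usually named after their bacterial
    host genus rather than carrying it as a rank.
    """
    if rank not in RANKS:
        raise ParameterError(f"unknown rank: '{rank}'")
    if not 0 < perc <= 100:
        raise ParameterError("perc must be in (0, 100]")
    if not summary.top_hits:
        return False
    if phage:
        token = taxon.lower()
        n_match = sum(
            1
            for hit in summary.top_hits
            if hit.lineage.domain == "Viruses"
            and (
                token in hit.subject_title.lower()
                or any(token == r.lower() for r in hit.lineage.ranks)
            )
        )
        frac = n_match / len(summary.top_hits)
    else:
        frac = summary.fraction(taxon, rank)
    return frac * 100.0 > perc
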