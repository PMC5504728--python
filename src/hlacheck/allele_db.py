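"""HLA allele definitions and their projection onto SNP markers.

The IPD-IMGT/HLA database distributes, per gene, a cDNA nucleotide alignment
(the ``*_nuc.txt`` dialect) in which the first allele row is the reference
sequence and every other row is written relative to it: ``-`` means identical
to the reference, ``*`` means the base is unknown (many alleles are sequenced
only over exons 2-3), ``.`` is an indel placeholder, and any other letter is a
substitution.  This module parses that dialect, projects alleles onto a set of
biallelic SNP markers (handling reverse-strand genes by complementing), and
collapses allele names to one- or two-field resolution.

All projected bases are stored on the *chip strand*, i.e. the strand on which
the marker's two alleles (alleleA/alleleB) are reported, so that downstream
comparison with genotype posteriors needs no further strand logic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an undetermined base in an allele definition.
UNKNOWN = "?"

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", UNKNOWN: UNKNOWN}

_NAME_RE = re.compile(
    r"^(?:HLA-)?(?P<gene>[A-Z][A-Za-z0-9]*)\*(?P<fields>[0-9A-Z]+(?::[0-9A-Z]+)*)$"
)


class AlleleParseError(ValueError):
    """Raised when an allele name or alignment row cannot be interpreted."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """A parsed HLA allele name such as ``A*01:01`` or ``HLA-B*57:01``.

    ``gene`` is normalized to the long form (``HLA-A``); ``raw`` keeps the
    original string and is excluded from equality so that ``A*01:01`` and
    ``HLA-A*01:01`` compare equal.
    """

    gene: str
    fields: tuple[str, ...]
    raw: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not self.gene:
            raise AlleleParseError("allele name has empty gene symbol")
        if not self.fields:
            raise AlleleParseError(f"allele name {self.raw!r} has no fields")
        if not self.raw:
            object.__setattr__(self, "raw", str(self))

    @classmethod
    def parse(cls, text: str) -> "AlleleName":
        m = _NAME_RE.match(text.strip())
        if m is None:
            raise AlleleParseError(f"cannot parse HLA allele name {text!r}")
        gene = m.group("gene")
        return cls(
            gene=normalize_gene(gene),
            fields=tuple(m.group("fields").split(":")),
            raw=text.strip(),
        )

    def truncate(self, n_fields: int) -> "AlleleName":
        """Name restricted to its first ``n_fields`` fields."""
        if n_fields < 1 or n_fields > len(self.fields):
            raise ValueError(f"cannot truncate {self} to {n_fields} fields")
        short = self.fields[:n_fields]
        return AlleleName(gene=self.gene, fields=short)

    @property
    def short_gene(self) -> str:
        return self.gene.removeprefix("HLA-")

    def __str__(self) -> str:
        return f"{self.short_gene}*{':'.join(self.fields)}"


def normalize_gene(gene: str) -> str:
    """Normalize a gene symbol to the ``HLA-`` prefixed long form."""
    gene = gene.strip()
    if not gene:
        raise AlleleParseError("empty gene symbol")
    return gene if gene.startswith("HLA-") else f"HLA-{gene}"


#: An unordered diploid allele pair, canonicalized as a sorted 2-tuple.
AllelePair = tuple[AlleleName, AlleleName]


def make_pair(a: AlleleName, b: AlleleName) -> AllelePair:
    """Canonical (order-insensitive) form of a diploid allele pair."""
    return (a, b) if a <= b else (b, a)


def format_pair(pair: AllelePair) -> str:
    return f"{pair[0]}/{pair[1]}"


@dataclass(frozen=True)
class SnpMarker:
    """An exonic biallelic SNP used to interrogate one HLA gene.

    ``cdna_pos`` is 1-based in the gene's gapless cDNA reference frame;
    ``strand`` is the orientation of that cDNA relative to the chip strand,
    and ``alleleA``/``alleleB`` are the two chip-strand nucleotides.
    """

    id: str
    gene: str
    cdna_pos: int
    strand: str
    alleleA: str
    alleleB: str

    def __post_init__(self) -> None:
        if self.cdna_pos < 1:
            raise ValueError(f"marker {self.id}: cdna_pos must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"marker {self.id}: strand must be '+' or '-'")
        if self.alleleA not in _VALID_BASES or self.alleleB not in _VALID_BASES:
            raise ValueError(f"marker {self.id}: alleles must be A/C/G/T")
        if self.alleleA == self.alleleB:
            raise ValueError(f"marker {self.id}: alleleA == alleleB")
        object.__setattr__(self, "gene", normalize_gene(self.gene))


@dataclass(frozen=True)
class AlleleDefinition:
    """One allele's chip-strand base at each marker of its gene."""

    name: AlleleName
    bases: Mapping[str, str]

    def coverage(self, markers: Sequence[SnpMarker]) -> float:
        """Fraction of ``markers`` at which this allele's base is known."""
        known = sum(1 for m in markers if self.bases.get(m.id, UNKNOWN) != UNKNOWN)
        return known / len(markers) if markers else 0.0


@dataclass(frozen=True)
class AlleleTable:
    """All allele definitions of one gene projected onto one marker panel."""

    gene: str
    markers: tuple[SnpMarker, ...]
    alleles: tuple[AlleleDefinition, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene(self.gene))
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "alleles", tuple(self.alleles))
        marker_ids = {m.id for m in self.markers}
        names = set()
        for m in self.markers:
            if m.gene != self.gene:
                raise ValueError(f"marker {m.id} belongs to {m.gene}, not {self.gene}")
        for a in self.alleles:
            if a.name.gene != self.gene:
                raise ValueError(f"allele {a.name} belongs to {a.name.gene}, not {self.gene}")
            if a.name in names:
                raise ValueError(f"duplicate allele name {a.name}")
            names.add(a.name)
            extra = set(a.bases) - marker_ids
            if extra:
                raise ValueError(f"allele {a.name} keyed by unknown markers {sorted(extra)}")

    @property
    def resolution(self) -> int:
        return max(len(a.name.fields) for a in self.alleles)

    def allele(self, name: AlleleName) -> AlleleDefinition:
        for a in self.alleles:
            if a.name == name:
                return a
        raise KeyError(f"allele {name} not in table for {self.gene}")

    def __contains__(self, name: AlleleName) -> bool:
        return any(a.name == name for a in self.alleles)

    def marker_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.markers)}


# ---------------------------------------------------------------------------
# IMGT cDNA nucleotide-alignment dialect
# ---------------------------------------------------------------------------

def parse_nuc_alignment(
    text: str | TextIO, gene: str
) -> list[tuple[AlleleName, list[str]]]:
    """Expand an IMGT-style cDNA nucleotide alignment into full sequences.

    The first allele row encountered is the reference.  Rows may be split
    across blocks (as in real ``*_nuc.txt`` files); chunks are concatenated
    per allele.  Exon-boundary pipes are ignored.  Returns, per allele, the
    sequence in the gapless cDNA reference frame: columns where the reference
    carries ``.`` (insertions relative to the reference) are dropped, and an
    allele's ``.`` at a reference position (a deletion) becomes UNKNOWN, as
    does ``*``.

    ``-`` or ``*`` in the reference row, or allele rows whose total length
    differs from the reference's, are parse errors.
    """
    if hasattr(text, "read"):
        text = text.read()
    gene = normalize_gene(gene)

    order: list[AlleleName] = []
    chunks: dict[AlleleName, list[str]] = {}
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        head, *rest = stripped.split()
        try:
            name = AlleleName.parse(head)
        except AlleleParseError:
            continue  # ruler / header line such as 'cDNA  101'
        if name.gene != gene:
            continue
        seq = "".join(rest).replace("|", "").upper()
        if name not in chunks:
            order.append(name)
            chunks[name] = []
        chunks[name].append(seq)
    if not order:
        raise AlleleParseError(f"no allele rows for {gene} found in alignment")

    aligned = {name: "".join(parts) for name, parts in chunks.items()}
    ref_name = order[0]
    ref_row = aligned[ref_name]
    if any(c in "-*" for c in ref_row):
        raise AlleleParseError(
            f"reference allele {ref_name} contains '-' or '*' placeholders"
        )
    n_cols = len(ref_row)

    out: list[tuple[AlleleName, list[str]]] = []
    keep = [i for i, r in enumerate(ref_row) if r != "."]
    for name in order:
        row = aligned[name]
        if len(row) != n_cols:
            raise AlleleParseError(
                f"allele {name}: alignment row has {len(row)} columns, "
                f"reference has {n_cols}"
            )
        seq: list[str] = []
        for i in keep:
            r, c = ref_row[i], row[i]
            if c == "-":
                seq.append(r)
            elif c in _VALID_BASES:
                seq.append(c)
            else:  # '*' unknown, '.' deletion, or any ambiguity code
                seq.append(UNKNOWN)
        out.append((name, seq))
    return out


def project_to_markers(
    seqs: Iterable[tuple[AlleleName, Sequence[str]]],
    markers: Sequence[SnpMarker],
) -> AlleleTable:
    """Project full cDNA sequences onto a marker panel, onto the chip strand.

    For a ``-`` strand marker the cDNA base is complemented so every stored
    base is directly comparable with the marker's alleleA/alleleB.  A
    projected base outside {alleleA, alleleB} is kept (it means no diploid
    pair containing that allele can match there) but logged.
    """
    markers = tuple(markers)
    if not markers:
        raise ValueError("empty marker list")
    genes = {m.gene for m in markers}
    if len(genes) != 1:
        raise ValueError(f"markers span multiple genes: {sorted(genes)}")
    (gene,) = genes

    alleles = []
    n_offpanel = 0
    for name, seq in seqs:
        bases: dict[str, str] = {}
        for m in markers:
            if m.cdna_pos > len(seq):
                raise ValueError(
                    f"marker {m.id}: cdna_pos {m.cdna_pos} beyond sequence "
                    f"length {len(seq)} of allele {name}"
                )
            base = seq[m.cdna_pos - 1]
            if m.strand == "-":
                base = _COMPLEMENT[base]
            if base != UNKNOWN and base not in (m.alleleA, m.alleleB):
                n_offpanel += 1
                logger.debug(
                    "allele %s carries %s at marker %s (panel alleles %s/%s)",
                    name, base, m.id, m.alleleA, m.alleleB,
                )
            bases[m.id] = base
        alleles.append(AlleleDefinition(name=name, bases=bases))
    if n_offpanel:
        logger.info(
            "%d allele/marker bases fall outside the chip allele pair", n_offpanel
        )
    return AlleleTable(gene=gene, markers=markers, alleles=tuple(alleles))


def collapse_resolution(table: AlleleTable, n_fields: int) -> AlleleTable:
    """Collapse allele names to ``n_fields`` fields (1 or 2).

    Alleles sharing a truncated name are represented by the member with the
    lexicographically smallest full name (conventionally the first-numbered
    allele, which defines the group's protein sequence).
    """
    if n_fields not in (1, 2):
        raise ValueError("n_fields must be 1 or 2")
    if n_fields > table.resolution:
        raise ValueError(
            f"cannot collapse to {n_fields} fields: table resolution is "
            f"{table.resolution}"
        )
    groups: dict[AlleleName, AlleleDefinition] = {}
    for a in sorted(table.alleles, key=lambda a: a.name.fields):
        short = a.name.truncate(min(n_fields, len(a.name.fields)))
        if short not in groups:  # first in sort order = representative
            groups[short] = AlleleDefinition(name=short, bases=dict(a.bases))
    return AlleleTable(gene=table.gene, markers=table.markers,
                       alleles=tuple(groups.values()))


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def read_marker_map(path_or_buf) -> list[SnpMarker]:
    """Read the marker-mapping TSV.

    Columns: marker_id, gene, cdna_pos, strand, alleleA, alleleB.  Lines
    starting with ``#`` are comments.
    """
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str)
    required = ["marker_id", "gene", "cdna_pos", "strand", "alleleA", "alleleB"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"marker map missing columns: {missing}")
    return [
        SnpMarker(
            id=row.marker_id, gene=row.gene, cdna_pos=int(row.cdna_pos),
            strand=row.strand, alleleA=row.alleleA, alleleB=row.alleleB,
        )
        for row in df.itertuples()
    ]


def write_marker_map(markers: Sequence[SnpMarker], path_or_buf) -> None:
    df = pd.DataFrame(
        {
            "marker_id": [m.id for m in markers],
            "gene": [m.gene for m in markers],
            "cdna_pos": [m.cdna_pos for m in markers],
            "strand": [m.strand for m in markers],
            "alleleA": [m.alleleA for m in markers],
            "alleleB": [m.alleleB for m in markers],
        }
    )
    df.to_csv(path_or_buf, sep="\t", index=False)


def read_projected_table(path_or_buf, markers: Sequence[SnpMarker]) -> AlleleTable:
    """Read a pre-projected allele x marker TSV against a known marker panel.

    First column ``allele``; one column per marker id; values A/C/G/T or
    ``?`` for unknown.
    """
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str)
    if "allele" not in df.columns:
        raise ValueError("projected allele table must have an 'allele' column")
    marker_ids = [m.id for m in markers]
    missing = [mid for mid in marker_ids if mid not in df.columns]
    if missing:
        raise ValueError(f"projected allele table missing marker columns: {missing}")
    alleles = []
    for row in df.itertuples():
        name = AlleleName.parse(row.allele)
        bases = {mid: df.at[row.Index, mid] for mid in marker_ids}
        for mid, b in bases.items():
            if b != UNKNOWN and b not in _VALID_BASES:
                raise ValueError(f"allele {name}, marker {mid}: bad base {b!r}")
        alleles.append(AlleleDefinition(name=name, bases=bases))
    return AlleleTable(gene=markers[0].gene, markers=tuple(markers),
                       alleles=tuple(alleles))


def write_projected_table(table: AlleleTable, path_or_buf) -> None:
    data = {"allele": [str(a.name) for a in table.alleles]}
    for m in table.markers:
        data[m.id] = [a.bases.get(m.id, UNKNOWN) for a in table.alleles]
    pd.DataFrame(data).to_csv(path_or_buf, sep="\t", index=False)
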