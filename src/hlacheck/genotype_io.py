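"""Readers for genotype posteriors, HLA assignments and HLA-marker dosages.

Genotype posteriors arrive in the IMPUTE2 GEN + SAMPLE dialect: each GEN row
carries five leading columns (snp id, rsid, position, alleleA, alleleB)
followed by one probability triplet p(AA), p(AB), p(BB) per individual.  The
triplet may sum to less than 1 — imputation output legitimately leaves
probability mass unassigned — and is used as-is, never renormalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .allele_db import AlleleName, AllelePair, SnpMarker, make_pair, normalize_gene

logger = logging.getLogger(__name__)

_PROB_EPS = 1e-6


@dataclass(frozen=True)
class GenotypePosterior:
    """Posterior probabilities of the three chip-strand genotypes at a marker.

    ``p_AA`` is the probability of the alleleA homozygote, ``p_AB`` the
    heterozygote, ``p_BB`` the alleleB homozygote.
    """

    p_AA: float
    p_AB: float
    p_BB: float

    def __post_init__(self) -> None:
        for p in (self.p_AA, self.p_AB, self.p_BB):
            if not (-_PROB_EPS <= p <= 1 + _PROB_EPS):
                raise ValueError(f"posterior probability {p} outside [0,1]")
        if self.p_AA + self.p_AB + self.p_BB > 1 + _PROB_EPS:
            raise ValueError("posterior probabilities sum to more than 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_AA, self.p_AB, self.p_BB)


@dataclass(frozen=True)
class IndividualGenotypes:
    """One individual's genotype posteriors keyed by marker id."""

    individual_id: str
    posteriors: Mapping[str, GenotypePosterior] = field(default_factory=dict)


@dataclass(frozen=True)
class HlaAssignment:
    """An attributed (typed or imputed) allele pair for one individual+gene."""

    individual_id: str
    gene: str
    pair: AllelePair
    source: str = "typed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene(self.gene))
        object.__setattr__(self, "pair", make_pair(*self.pair))
        for a in self.pair:
            if a.gene != self.gene:
                raise ValueError(
                    f"{self.individual_id}: allele {a} does not belong to {self.gene}"
                )


@dataclass(frozen=True)
class HlaMarkerDosage:
    """Posterior expected copy count of one HLA allele for one individual.

    HLA alleles imputed as binary presence/absence markers come back as a
    dosage in [0, 2].
    """

    individual_id: str
    allele: AlleleName
    posterior_dosage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.posterior_dosage <= 2.0):
            raise ValueError(
                f"dosage {self.posterior_dosage} for {self.allele} outside [0,2]"
            )


class GenFormatError(ValueError):
    """Raised when a GEN/SAMPLE stream violates the dialect."""


def read_sample(path_or_buf) -> list[str]:
    """Read individual ids (ID_2 column) from an IMPUTE2 SAMPLE file."""
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    rows = [ln.split() for ln in lines if ln.strip()]
    if len(rows) < 2 or rows[0][0] != "ID_1":
        raise GenFormatError("SAMPLE file must start with the standard two header rows")
    return [r[1] for r in rows[2:]]


def read_gen(
    gen_path_or_buf,
    sample_path_or_buf,
    marker_map: Sequence[SnpMarker],
) -> list[IndividualGenotypes]:
    """Read an IMPUTE2 GEN + SAMPLE pair into per-individual posteriors.

    Markers absent from ``marker_map`` are skipped (logged in aggregate);
    rows whose alleleA/alleleB disagree with the marker map indicate a
    strand or allele mix-up and raise.
    """
    sample_ids = read_sample(sample_path_or_buf)
    by_id = {m.id: m for m in marker_map}

    if hasattr(gen_path_or_buf, "read"):
        lines = gen_path_or_buf.read().splitlines()
    else:
        with open(gen_path_or_buf) as fh:
            lines = fh.read().splitlines()

    posteriors: list[dict[str, GenotypePosterior]] = [{} for _ in sample_ids]
    n_skipped = 0
    for ln_no, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        cols = line.split()
        if len(cols) != 5 + 3 * len(sample_ids):
            raise GenFormatError(
                f"GEN line {ln_no}: {len(cols)} columns, expected "
                f"{5 + 3 * len(sample_ids)} for {len(sample_ids)} samples"
            )
        _, rsid, _, a, b = cols[:5]
        marker = by_id.get(rsid)
        if marker is None:
            n_skipped += 1
            continue
        if {a, b} != {marker.alleleA, marker.alleleB} or a != marker.alleleA:
            raise GenFormatError(
                f"GEN line {ln_no}: marker {rsid} alleles {a}/{b} do not match "
                f"marker map {marker.alleleA}/{marker.alleleB} "
                "(strand or allele mismatch)"
            )
        for i in range(len(sample_ids)):
            trip = cols[5 + 3 * i : 8 + 3 * i]
            try:
                p = GenotypePosterior(*(float(x) for x in trip))
            except ValueError as exc:
                raise GenFormatError(f"GEN line {ln_no}, sample {i + 1}: {exc}") from exc
            posteriors[i][rsid] = p
    if n_skipped:
        logger.info("skipped %d GEN markers absent from the marker map", n_skipped)
    return [
        IndividualGenotypes(individual_id=sid, posteriors=post)
        for sid, post in zip(sample_ids, posteriors)
    ]


def write_gen(
    individuals: Sequence[IndividualGenotypes],
    markers: Sequence[SnpMarker],
    gen_path_or_buf,
    sample_path_or_buf,
    chrom: str = "6",
) -> None:
    """Write posteriors back out in the GEN + SAMPLE dialect (6 decimals).

    Markers missing for an individual are written as the 0 0 0 triplet, the
    conventional encoding for missing data in GEN files.
    """
    sample_lines = ["ID_1 ID_2 missing", "0 0 0"]
    sample_lines += [f"{ind.individual_id} {ind.individual_id} 0" for ind in individuals]
    _write_text(sample_path_or_buf, "\n".join(sample_lines) + "\n")

    rows = []
    for pos, m in enumerate(markers, start=1):
        cols = [chrom, m.id, str(pos), m.alleleA, m.alleleB]
        for ind in individuals:
            p = ind.posteriors.get(m.id)
            trip = p.as_tuple() if p is not None else (0.0, 0.0, 0.0)
            cols += [f"{x:.6f}" for x in trip]
        rows.append(" ".join(cols))
    _write_text(gen_path_or_buf, "\n".join(rows) + "\n")


def _write_text(path_or_buf, text: str) -> None:
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_assignments(path_or_buf, source: str = "typed") -> list[HlaAssignment]:
    """Read an assignment TSV: individual_id, gene, allele1, allele2[, source].

    Allele order within a row is irrelevant; a duplicate (individual, gene)
    combination is an error.
    """
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str)
    required = ["individual_id", "gene", "allele1", "allele2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"assignment TSV missing columns: {missing}")
    out: list[HlaAssignment] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples():
        try:
            a1 = AlleleName.parse(row.allele1)
            a2 = AlleleName.parse(row.allele2)
        except Exception as exc:
            raise ValueError(
                f"assignment row for {row.individual_id}: {exc}"
            ) from exc
        gene = normalize_gene(row.gene)
        key = (row.individual_id, gene)
        if key in seen:
            raise ValueError(f"duplicate assignment for {key}")
        seen.add(key)
        row_source = getattr(row, "source", source)
        out.append(
            HlaAssignment(
                individual_id=row.individual_id, gene=gene,
                pair=make_pair(a1, a2), source=row_source,
            )
        )
    return out


def write_assignments(assignments: Sequence[HlaAssignment], path_or_buf) -> None:
    df = pd.DataFrame(
        {
            "individual_id": [a.individual_id for a in assignments],
            "gene": [a.gene for a in assignments],
            "allele1": [str(a.pair[0]) for a in assignments],
            "allele2": [str(a.pair[1]) for a in assignments],
            "source": [a.source for a in assignments],
        }
    )
    df.to_csv(path_or_buf, sep="\t", index=False)


def read_dosages(path_or_buf) -> list[HlaMarkerDosage]:
    """Read a dosage TSV: individual_id, allele, dosage."""
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str)
    required = ["individual_id", "allele", "dosage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV missing columns: {missing}")
    return [
        HlaMarkerDosage(
            individual_id=row.individual_id,
            allele=AlleleName.parse(row.allele),
            posterior_dosage=float(row.dosage),
        )
        for row in df.itertuples()
    ]


def call_from_dosage(
    dosages: Iterable[HlaMarkerDosage], threshold: float = 0.5
) -> tuple[list[AlleleName], bool]:
    """Call an individual's allele pair from per-allele posterior dosages.

    Only alleles with dosage strictly above ``threshold`` contribute: a
    dosage in (threshold, 1.5] counts one copy, above 1.5 two copies.  The
    individual is *called* only when exactly two copies result; anything
    else (0, 1, 3+ copies) is a not-called status, not an error.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    copies: list[AlleleName] = []
    for d in dosages:
        if d.posterior_dosage > 1.5:
            copies += [d.allele, d.allele]
        elif d.posterior_dosage > threshold:
            copies.append(d.allele)
    called = len(copies) == 2
    return sorted(copies), called
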