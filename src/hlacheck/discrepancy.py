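"""The HLA-check discrepancy score.

For one individual and one candidate diploid allele pair, each exonic SNP
marker contributes a per-marker discrepancy ``s``: the posterior probability
mass that is *inconsistent* with the genotype implied by the pair.  If the
pair implies a heterozygote and the posteriors are p(AA)=0.10, p(AB)=0.65,
p(BB)=0.25 then s = 1 - 0.65 = 0.35.  A marker at which a known base falls
outside the chip's two alleles makes the pair impossible there (s = 1); a
marker where either allele's base is unknown is excluded entirely.  The
pair's score is the plain sum

    D(pair) = sum over usable markers of s,

and the reported quantity for an attributed pair is

    delta = D(attributed) - min over all n*(n+1)/2 pairs of D,

so delta = 0 means no pair in the database fits the genotype better than
the attributed one.  Summing s (rather than combining log(1-s)) keeps single
badly-imputed markers from dominating the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .allele_db import (
    UNKNOWN,
    AlleleDefinition,
    AlleleName,
    AllelePair,
    AlleleTable,
    SnpMarker,
    format_pair,
    make_pair,
)
from .genotype_io import GenotypePosterior, IndividualGenotypes

#: Two scores within this of each other count as tied for the minimum.
TIE_TOL = 1e-9

#: Alleles with known bases at fewer than this fraction of markers are
#: excluded from the exhaustive best-pair search by default.
DEFAULT_MIN_COVERAGE = 0.5


class ExpectedGenotype(Enum):
    """Genotype a candidate allele pair implies at one biallelic marker."""

    HOM_A = 0
    HET = 1
    HOM_B = 2
    UNDEFINED = 3   # either allele's base unknown at the marker
    IMPOSSIBLE = 4  # a known base outside {alleleA, alleleB}


@dataclass(frozen=True)
class PairScore:
    """Summed discrepancy of one pair over the markers it could be scored on."""

    pair: AllelePair
    D: float
    n_used: int

    @property
    def defined(self) -> bool:
        return self.n_used > 0


@dataclass(frozen=True)
class CheckResult:
    """Outcome of checking one attributed pair for one individual."""

    individual_id: str
    gene: str
    attributed: AllelePair
    D_attributed: float
    D_min: float
    delta: float
    best_pairs: frozenset[AllelePair]
    n_markers_used: int
    status: str = "ok"  # ok | allele_not_in_db | no_usable_markers


def expected_genotype(
    pair: AllelePair, marker: SnpMarker, table: AlleleTable
) -> ExpectedGenotype:
    """Genotype class the pair implies at ``marker`` (chip-strand)."""
    b1 = table.allele(pair[0]).bases.get(marker.id, UNKNOWN)
    b2 = table.allele(pair[1]).bases.get(marker.id, UNKNOWN)
    return _combine_bases(b1, b2, marker)


def _combine_bases(b1: str, b2: str, marker: SnpMarker) -> ExpectedGenotype:
    if b1 == UNKNOWN or b2 == UNKNOWN:
        return ExpectedGenotype.UNDEFINED
    ok = (marker.alleleA, marker.alleleB)
    if b1 not in ok or b2 not in ok:
        return ExpectedGenotype.IMPOSSIBLE
    n_b = (b1 == marker.alleleB) + (b2 == marker.alleleB)
    return (ExpectedGenotype.HOM_A, ExpectedGenotype.HET, ExpectedGenotype.HOM_B)[n_b]


def marker_discrepancy(post: GenotypePosterior, expected: ExpectedGenotype) -> float:
    """Per-marker discrepancy s in [0, 1].

    s = 1 - p(expected genotype); 1 for an impossible pair; an UNDEFINED
    marker contributes 0 (callers exclude it from the usable-marker count).
    """
    if expected is ExpectedGenotype.UNDEFINED:
        return 0.0
    if expected is ExpectedGenotype.IMPOSSIBLE:
        return 1.0
    p = post.as_tuple()[expected.value]
    return min(1.0, max(0.0, 1.0 - p))


def pair_discrepancy(
    ind: IndividualGenotypes, pair: AllelePair, table: AlleleTable
) -> PairScore:
    """Sum the per-marker discrepancies of ``pair`` over the individual's markers.

    Markers the individual lacks, and markers where the pair's genotype is
    UNDEFINED, contribute nothing and are not counted in ``n_used``.  With
    zero usable markers D is NaN (an explicit undefined status, never a
    silent 0).
    """
    pair = make_pair(*pair)
    D = 0.0
    n_used = 0
    for marker in table.markers:
        post = ind.posteriors.get(marker.id)
        if post is None:
            continue
        exp = expected_genotype(pair, marker, table)
        if exp is ExpectedGenotype.UNDEFINED:
            continue
        D += marker_discrepancy(post, exp)
        n_used += 1
    return PairScore(pair=pair, D=D if n_used else math.nan, n_used=n_used)


# ---------------------------------------------------------------------------
# Vectorized exhaustive search
# ---------------------------------------------------------------------------

_CODE_A, _CODE_B, _CODE_OFF, _CODE_UNK = 0, 1, 2, 3


def _base_codes(table: AlleleTable, alleles: Sequence[AlleleDefinition]) -> np.ndarray:
    """(n_alleles, n_markers) int codes: 0=alleleA, 1=alleleB, 2=off-panel, 3=unknown."""
    codes = np.empty((len(alleles), len(table.markers)), dtype=np.int8)
    for i, a in enumerate(alleles):
        for j, m in enumerate(table.markers):
            b = a.bases.get(m.id, UNKNOWN)
            if b == UNKNOWN:
                codes[i, j] = _CODE_UNK
            elif b == m.alleleA:
                codes[i, j] = _CODE_A
            elif b == m.alleleB:
                codes[i, j] = _CODE_B
            else:
                codes[i, j] = _CODE_OFF
    return codes


class PairSearch:
    """Precomputed exhaustive scorer over all diploid pairs of one table.

    Enumerates every unordered pair, homozygous included — n*(n+1)/2
    candidates — and scores each against an individual's posteriors in one
    vectorized pass.  Semantics are identical to calling
    :func:`pair_discrepancy` pair by pair (asserted against a naive
    enumeration in the test suite).  Alleles below ``min_coverage`` known-base
    fraction are excluded from the search (they would win ties spuriously by
    being scored over fewer markers); the attributed pair itself is always
    scorable via :func:`pair_discrepancy` regardless.
    """

    def __init__(self, table: AlleleTable, min_coverage: float = DEFAULT_MIN_COVERAGE):
        if not table.alleles:
            raise ValueError("empty allele table")
        self.table = table
        self.alleles = [
            a for a in table.alleles if a.coverage(table.markers) >= min_coverage
        ]
        if not self.alleles:
            raise ValueError(
                f"no allele of {table.gene} reaches coverage {min_coverage}"
            )
        self._codes = _base_codes(table, self.alleles)
        n = len(self.alleles)
        self._ii, self._jj = np.triu_indices(n)
        self._marker_ids = [m.id for m in table.markers]

    @property
    def n_pairs(self) -> int:
        return len(self._ii)

    def score_all(self, ind: IndividualGenotypes) -> tuple[np.ndarray, np.ndarray]:
        """(D, n_used) arrays over all enumerated pairs for one individual."""
        m = len(self._marker_ids)
        P = np.zeros((m, 3))
        present = np.zeros(m, dtype=bool)
        for j, mid in enumerate(self._marker_ids):
            post = ind.posteriors.get(mid)
            if post is not None:
                P[j] = post.as_tuple()
                present[j] = True

        ci = self._codes[self._ii]  # (n_pairs, m)
        cj = self._codes[self._jj]
        undef = (ci == _CODE_UNK) | (cj == _CODE_UNK)
        imposs = ~undef & ((ci == _CODE_OFF) | (cj == _CODE_OFF))
        geno = np.clip(ci, 0, 1) + np.clip(cj, 0, 1)  # 0/1/2 where not undef/imposs

        s = np.clip(1.0 - P[np.arange(m)[None, :], geno], 0.0, 1.0)
        s[imposs] = 1.0
        usable = present[None, :] & ~undef
        D = np.where(usable, s, 0.0).sum(axis=1)
        n_used = usable.sum(axis=1)
        return D, n_used

    def best_pairs(self, ind: IndividualGenotypes) -> tuple[float, set[AllelePair]]:
        """Exact minimum D and all pairs attaining it within TIE_TOL."""
        D, n_used = self.score_all(ind)
        valid = n_used > 0
        if not valid.any():
            raise ValueError(
                f"individual {ind.individual_id}: no usable markers for any pair"
            )
        D = np.where(valid, D, np.inf)
        d_min = float(D.min())
        ties = np.flatnonzero(D <= d_min + TIE_TOL)
        pairs = {
            make_pair(self.alleles[self._ii[k]].name, self.alleles[self._jj[k]].name)
            for k in ties
        }
        return d_min, pairs


def best_pairs(
    ind: IndividualGenotypes,
    table: AlleleTable,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> tuple[float, set[AllelePair]]:
    """Exhaustively search all diploid pairs for the minimum discrepancy."""
    return PairSearch(table, min_coverage=min_coverage).best_pairs(ind)


def check_assignment(
    ind: IndividualGenotypes,
    attributed: AllelePair,
    table: AlleleTable,
    search: PairSearch | None = None,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> CheckResult:
    """Score an attributed pair against the best pair in the database.

    An attributed allele absent from the database yields an explicit
    ``allele_not_in_db`` result (itself a form of implausibility), not an
    exception; so does an individual with no usable markers.
    """
    attributed = make_pair(*attributed)
    if search is None:
        search = PairSearch(table, min_coverage=min_coverage)
    missing = [a for a in attributed if a not in table]
    if missing:
        return CheckResult(
            individual_id=ind.individual_id, gene=table.gene, attributed=attributed,
            D_attributed=math.nan, D_min=math.nan, delta=math.nan,
            best_pairs=frozenset(), n_markers_used=0, status="allele_not_in_db",
        )
    score = pair_discrepancy(ind, attributed, table)
    if not score.defined:
        return CheckResult(
            individual_id=ind.individual_id, gene=table.gene, attributed=attributed,
            D_attributed=math.nan, D_min=math.nan, delta=math.nan,
            best_pairs=frozenset(), n_markers_used=0, status="no_usable_markers",
        )
    d_min, best = search.best_pairs(ind)
    # the attributed pair is itself a candidate: the minimum can never sit above it
    if score.D < d_min - TIE_TOL:
        d_min, best = score.D, {attributed}
    elif score.D <= d_min + TIE_TOL:
        best = set(best) | {attributed}
    delta = 0.0 if attributed in best else max(0.0, score.D - d_min)
    return CheckResult(
        individual_id=ind.individual_id, gene=table.gene, attributed=attributed,
        D_attributed=score.D, D_min=d_min, delta=delta,
        best_pairs=frozenset(best), n_markers_used=score.n_used, status="ok",
    )


def check_cohort(
    individuals: Sequence[IndividualGenotypes],
    assignments: Iterable,
    table: AlleleTable,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[CheckResult]:
    """Check every individual's attributed pair; one PairSearch shared."""
    search = PairSearch(table, min_coverage=min_coverage)
    by_id = {ind.individual_id: ind for ind in individuals}
    results = []
    for a in assignments:
        ind = by_id.get(a.individual_id)
        if ind is None:
            raise KeyError(f"no genotypes for individual {a.individual_id}")
        results.append(check_assignment(ind, a.pair, table, search=search))
    return results


def results_frame(results: Sequence[CheckResult]) -> pd.DataFrame:
    """Per-individual results as a DataFrame (also the TSV writer's layout)."""
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in results],
            "gene": [r.gene for r in results],
            "attributed_pair": [format_pair(r.attributed) for r in results],
            "D_attributed": [r.D_attributed for r in results],
            "D_min": [r.D_min for r in results],
            "delta": [r.delta for r in results],
            "best_pairs": [
                ";".join(sorted(format_pair(p) for p in r.best_pairs))
                for r in results
            ],
            "n_markers_used": [r.n_markers_used for r in results],
            "status": [r.status for r in results],
        }
    )


def write_results(results: Sequence[CheckResult], path_or_buf) -> None:
    results_frame(results).to_csv(path_or_buf, sep="\t", index=False, float_format="%.6g")
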