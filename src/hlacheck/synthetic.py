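"""Synthetic allele tables and cohorts with known ground truth.

The real reference and test panels behind HLA imputation studies are
access-restricted, so every downstream contract here is exercised on
generated data instead: an allele table of biallelic markers with a
controllable fraction of unknown bases, and a Hardy-Weinberg cohort whose
genotype posteriors concentrate on the genotype implied by each individual's
true pair, with a controllable noise level and a controllable fraction of
deliberately corrupted recorded assignments.

Defaults are a deliberately chosen study condition, not knobs to tune per
test: 10 alleles x 20 markers, 300 individuals, no unknown bases, noise
e = 0.1, 5% corrupted assignments at a minimum distance of 3 markers, and a
geometrically decaying allele-frequency spectrum (common HLA alleles really
do dominate their gene's frequency mass).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .allele_db import (
    UNKNOWN,
    AlleleDefinition,
    AlleleName,
    AllelePair,
    AlleleTable,
    SnpMarker,
    make_pair,
    write_marker_map,
    write_projected_table,
)
from .discrepancy import ExpectedGenotype, expected_genotype
from .genotype_io import (
    GenotypePosterior,
    HlaAssignment,
    IndividualGenotypes,
    write_assignments,
    write_gen,
)

_NUCS = np.array(list("ACGT"))

#: Ratio of the geometric allele-frequency spectrum used when no explicit
#: frequencies are given.
FREQ_DECAY = 0.7


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic gene + cohort."""

    gene: str = "HLA-A"
    n_alleles: int = 10
    n_markers: int = 20
    unknown_rate: float = 0.0
    n_individuals: int = 300
    allele_freqs: tuple[float, ...] | None = None
    noise: float = 0.1
    corrupt_frac: float = 0.05
    corrupt_min_distance: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alleles < 2 or self.n_markers < 1:
            raise ValueError("need n_alleles >= 2 and n_markers >= 1")
        for name in ("unknown_rate", "noise", "corrupt_frac"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.allele_freqs is not None:
            freqs = tuple(float(f) for f in self.allele_freqs)
            if len(freqs) != self.n_alleles:
                raise ValueError("allele_freqs length must equal n_alleles")
            if abs(sum(freqs) - 1.0) > 1e-9 or min(freqs) < 0:
                raise ValueError("allele_freqs must be a simplex")
            object.__setattr__(self, "allele_freqs", freqs)

    def freqs(self) -> np.ndarray:
        if self.allele_freqs is not None:
            return np.asarray(self.allele_freqs)
        f = FREQ_DECAY ** np.arange(self.n_alleles)
        return f / f.sum()


@dataclass(frozen=True)
class SyntheticCohort:
    """Everything a downstream pipeline needs, plus the ground truth."""

    table: AlleleTable
    truth: tuple[HlaAssignment, ...]
    recorded: tuple[HlaAssignment, ...]
    individuals: tuple[IndividualGenotypes, ...]
    corrupted_ids: frozenset[str]


def _allele_names(cfg: SimulationConfig) -> list[AlleleName]:
    return [
        AlleleName(gene=cfg.gene, fields=(f"{i + 1:02d}", "01"))
        for i in range(cfg.n_alleles)
    ]


def gen_allele_table(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> AlleleTable:
    """Random biallelic allele table, every allele pair distinguishable.

    Each marker gets two distinct nucleotides; each allele carries one of
    them, replaced by UNKNOWN with probability ``unknown_rate``.  Tables are
    rejection-sampled until every pair of alleles differs at >= 1 marker
    where both bases are known (bounded retries, then an explicit error).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    names = _allele_names(cfg)
    for _ in range(200):
        markers = []
        for j in range(cfg.n_markers):
            a, b = rng.choice(4, size=2, replace=False)
            markers.append(
                SnpMarker(
                    id=f"rs{j + 1:05d}", gene=cfg.gene, cdna_pos=j + 1,
                    strand="+", alleleA=str(_NUCS[a]), alleleB=str(_NUCS[b]),
                )
            )
        which = rng.integers(0, 2, size=(cfg.n_alleles, cfg.n_markers))
        unknown = rng.random((cfg.n_alleles, cfg.n_markers)) < cfg.unknown_rate
        base = np.where(
            which == 0,
            np.array([m.alleleA for m in markers]),
            np.array([m.alleleB for m in markers]),
        )
        known_differs = (which[:, None, :] != which[None, :, :]) & ~(
            unknown[:, None, :] | unknown[None, :, :]
        )
        distinct = known_differs.any(axis=2)
        iu = np.triu_indices(cfg.n_alleles, k=1)
        if not distinct[iu].all():
            continue
        alleles = tuple(
            AlleleDefinition(
                name=names[i],
                bases={
                    m.id: (UNKNOWN if unknown[i, j] else base[i, j])
                    for j, m in enumerate(markers)
                },
            )
            for i in range(cfg.n_alleles)
        )
        return AlleleTable(gene=cfg.gene, markers=tuple(markers), alleles=alleles)
    raise RuntimeError(
        f"could not build a table with all {cfg.n_alleles} alleles pairwise "
        f"distinguishable over {cfg.n_markers} markers"
    )


def pair_distance(p: AllelePair, q: AllelePair, table: AlleleTable) -> int:
    """Markers at which two pairs imply different (both defined) genotypes."""
    d = 0
    for m in table.markers:
        gp = expected_genotype(p, m, table)
        gq = expected_genotype(q, m, table)
        if ExpectedGenotype.UNDEFINED in (gp, gq):
            continue
        if gp is not gq:
            d += 1
    return d


def gen_population(
    table: AlleleTable,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticCohort:
    """Hardy-Weinberg cohort with posteriors implied by the true pairs.

    True pairs are two independent draws from the allele frequencies.  At
    each marker the posterior puts mass ``1 - noise`` on the genotype the
    true pair implies and ``noise/2`` on each of the other two genotypes; a
    marker where the true pair's genotype is UNDEFINED in the (masked) table
    is omitted for that individual.  A ``corrupt_frac`` Bernoulli subset of
    individuals gets its recorded assignment replaced by a uniform draw from
    the pairs at >= ``corrupt_min_distance`` markers from the truth.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    freqs = cfg.freqs()
    names = [a.name for a in table.alleles]
    if len(freqs) != len(names):
        raise ValueError("config allele count does not match table")

    all_pairs = [make_pair(a, b) for a, b in
                 itertools.combinations_with_replacement(names, 2)]

    truth: list[HlaAssignment] = []
    recorded: list[HlaAssignment] = []
    individuals: list[IndividualGenotypes] = []
    corrupted: set[str] = set()
    e = cfg.noise
    for i in range(cfg.n_individuals):
        iid = f"ind{i + 1:04d}"
        a1, a2 = rng.choice(len(names), size=2, p=freqs)
        pair = make_pair(names[a1], names[a2])
        truth.append(HlaAssignment(individual_id=iid, gene=cfg.gene, pair=pair))

        posteriors: dict[str, GenotypePosterior] = {}
        for m in table.markers:
            g = expected_genotype(pair, m, table)
            if g is ExpectedGenotype.UNDEFINED:
                continue
            probs = [e / 2.0, e / 2.0, e / 2.0]
            probs[g.value] = 1.0 - e
            posteriors[m.id] = GenotypePosterior(*probs)
        individuals.append(IndividualGenotypes(individual_id=iid, posteriors=posteriors))

        rec_pair = pair
        if rng.random() < cfg.corrupt_frac:
            candidates = [
                q for q in all_pairs
                if q != pair and pair_distance(pair, q, table) >= cfg.corrupt_min_distance
            ]
            if candidates:
                rec_pair = candidates[rng.integers(len(candidates))]
                corrupted.add(iid)
        recorded.append(
            HlaAssignment(
                individual_id=iid, gene=cfg.gene, pair=rec_pair,
                source="typed" if rec_pair == pair else "imputed",
            )
        )
    return SyntheticCohort(
        table=table, truth=tuple(truth), recorded=tuple(recorded),
        individuals=tuple(individuals), corrupted_ids=frozenset(corrupted),
    )


def simulate(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate table + cohort from one config (deterministic in cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    table = gen_allele_table(cfg, rng)
    return gen_population(table, cfg, rng)


def write_fixture(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort in the exact dialects the other modules read.

    Produces alleles.tsv (projected table), markers.tsv, cohort.gen,
    cohort.sample, assignments.tsv (recorded), truth.tsv and
    corrupted_ids.txt under ``out_dir``; returns the path of each.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alleles": out / "alleles.tsv",
        "markers": out / "markers.tsv",
        "gen": out / "cohort.gen",
        "sample": out / "cohort.sample",
        "assignments": out / "assignments.tsv",
        "truth": out / "truth.tsv",
        "corrupted": out / "corrupted_ids.txt",
    }
    write_projected_table(cohort.table, paths["alleles"])
    write_marker_map(cohort.table.markers, paths["markers"])
    write_gen(cohort.individuals, cohort.table.markers, paths["gen"], paths["sample"])
    write_assignments(cohort.recorded, paths["assignments"])
    write_assignments(cohort.truth, paths["truth"])
    paths["corrupted"].write_text(
        "".join(f"{iid}\n" for iid in sorted(cohort.corrupted_ids))
    )
    return paths
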