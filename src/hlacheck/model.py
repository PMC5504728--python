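"""Scikit-learn estimator wrapping the check + calibrate + flag workflow.

The calibrate-then-flag procedure is outlier-detection shaped, so it is
exposed as an estimator: ``fit`` calibrates the ΔD cutoff on a cohort,
``predict`` labels samples +1 (plausible) / -1 (flagged), and
``score_samples`` returns -ΔD so that, per scikit-learn convention, lower
scores mean more anomalous.  A *sample* is one ``(IndividualGenotypes,
allele pair)`` tuple — one individual together with the pair attributed to
them.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_is_fitted

from .allele_db import AllelePair, AlleleTable
from .calibration_eval import calibrate_cutoff
from .discrepancy import DEFAULT_MIN_COVERAGE, CheckResult, PairSearch, check_assignment
from .genotype_io import HlaAssignment, IndividualGenotypes

Sample = tuple[IndividualGenotypes, AllelePair]


class HlaCheck(OutlierMixin, BaseEstimator):
    """Flag implausible HLA assignments by genotype-posterior discrepancy.

    Parameters
    ----------
    table:
        The gene's :class:`~hlacheck.allele_db.AlleleTable` (every known
        allele projected onto the marker panel).
    cutoff:
        ``"auto"`` to calibrate mu + 2*sigma on the fitted cohort's ΔD
        distribution, or an explicit numeric cutoff.
    method:
        ΔD sample the auto cutoff is fitted to: ``"cohort"`` (the attributed
        assignments themselves) or ``"shuffled"`` (assignments permuted
        between individuals, pooled over ``n_shuffles`` permutations).
    round_cutoff:
        Round the calibrated cutoff to the nearest integer.
    min_coverage:
        Alleles with a smaller fraction of known bases are excluded from the
        exhaustive best-pair search.
    random_state:
        Seed for the shuffled-null permutations.

    Attributes
    ----------
    mu_, sigma_ : float
        Normal fit of the calibration ΔD sample.
    cutoff_ : float
        The flagging threshold actually in force after ``fit``.
    null_deltas_ : ndarray
        The ΔD sample the cutoff was fitted to (empty for a numeric cutoff).
    offset_ : float
        ``-cutoff_``; ``decision_function = score_samples - offset_`` is
        negative exactly for flagged samples.

    Examples
    --------
    >>> from hlacheck.synthetic import SimulationConfig, simulate
    >>> cohort = simulate(SimulationConfig(seed=7))
    >>> X = [(ind, a.pair) for ind, a in zip(cohort.individuals, cohort.recorded)]
    >>> est = HlaCheck(table=cohort.table).fit(X)
    >>> (est.predict(X) == -1).sum() > 0  # the corrupted assignments
    True
    """

    def __init__(
        self,
        table: AlleleTable | None = None,
        cutoff: float | str = "auto",
        method: str = "cohort",
        n_shuffles: int = 10,
        round_cutoff: bool = False,
        min_coverage: float = DEFAULT_MIN_COVERAGE,
        random_state: int | None = None,
    ):
        self.table = table
        self.cutoff = cutoff
        self.method = method
        self.n_shuffles = n_shuffles
        self.round_cutoff = round_cutoff
        self.min_coverage = min_coverage
        self.random_state = random_state

    def _validate(self, X: Sequence[Sample]) -> list[Sample]:
        if self.table is None:
            raise ValueError("HlaCheck requires an allele table")
        samples = list(X)
        for s in samples:
            if len(s) != 2 or not isinstance(s[0], IndividualGenotypes):
                raise TypeError(
                    "each sample must be an (IndividualGenotypes, allele pair) tuple"
                )
        return samples

    def fit(self, X: Sequence[Sample], y=None) -> "HlaCheck":
        """Calibrate (or adopt) the ΔD cutoff on a cohort of samples."""
        samples = self._validate(X)
        if self.cutoff == "auto":
            individuals = [ind for ind, _ in samples]
            assignments = [
                HlaAssignment(
                    individual_id=ind.individual_id,
                    gene=self.table.gene, pair=pair,
                )
                for ind, pair in samples
            ]
            cal = calibrate_cutoff(
                individuals, assignments, self.table,
                n_shuffles=self.n_shuffles,
                seed=0 if self.random_state is None else self.random_state,
                rounding="integer" if self.round_cutoff else "none",
                method=self.method,
                min_coverage=self.min_coverage,
            )
            self.mu_, self.sigma_ = cal.mu, cal.sigma
            self.cutoff_ = cal.cutoff
            self.null_deltas_ = np.asarray(cal.null_deltas)
        else:
            cutoff = float(self.cutoff)
            if not np.isfinite(cutoff):
                raise ValueError("explicit cutoff must be finite")
            self.mu_ = self.sigma_ = float("nan")
            self.cutoff_ = cutoff
            self.null_deltas_ = np.empty(0)
        self.offset_ = -self.cutoff_
        self._search = PairSearch(self.table, min_coverage=self.min_coverage)
        return self

    def check(self, X: Sequence[Sample]) -> list[CheckResult]:
        """Full per-sample results (D, D_min, ΔD, best pairs, status)."""
        check_is_fitted(self, "cutoff_")
        samples = self._validate(X)
        return [
            check_assignment(ind, pair, self.table, search=self._search)
            for ind, pair in samples
        ]

    def score_samples(self, X: Sequence[Sample]) -> np.ndarray:
        """-ΔD per sample (NaN where the assignment could not be scored)."""
        return np.array([-r.delta for r in self.check(X)])

    def decision_function(self, X: Sequence[Sample]) -> np.ndarray:
        """Positive for plausible samples, negative past the cutoff."""
        return self.score_samples(X) - self.offset_

    def predict(self, X: Sequence[Sample]) -> np.ndarray:
        """+1 for kept samples, -1 for flagged (ΔD > cutoff or unscorable)."""
        results = self.check(X)
        return np.array(
            [1 if r.status == "ok" and r.delta <= self.cutoff_ else -1 for r in results]
        )

    def fit_predict(self, X: Sequence[Sample], y=None) -> np.ndarray:
        return self.fit(X).predict(X)
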