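"""Random-gene-set resampling null, p-total, and the chi-squared follow-up.

The question: is the number of cohort samples carrying a mutation in at
least one member of a query gene set (e.g. the 14-gene translesion-synthesis
group) larger than expected for an arbitrary gene set of the same size in
the same cohort?

The null model draws many random sets of the same size from the cohort's
mutated-gene universe and records each set's mutated-sample count. The
``p-total`` statistic is the fraction of random sets whose count reaches
(>=) the query set's observed count — an empirical upper-tail resampling
p-value. Because the random sets are drawn from the same cohort, the null
automatically carries the cohort's burden heterogeneity (hypermutators
inflate every set's union count, not just the query's).

A secondary test compares the observed count against the rounded null
average in a 2x2 contingency table with a Pearson chi-squared test
(df=1, no continuity correction).
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .maf_io import ClassificationFilter, ParseSummary, merge_caller_mafs, read_maf
from .mutation_matrix import (
    GeneSet,
    MutationMatrix,
    build_matrix,
    gene_mutation_frequency,
    geneset_mutated_sample_count,
)

__all__ = [
    "NullDistribution",
    "ChiSqResult",
    "EnrichmentReport",
    "resample_null",
    "exhaustive_null",
    "p_total",
    "chi_squared_vs_random",
    "run_cancer_type_analysis",
    "derive_cohort_seed",
]

EXHAUSTIVE_CAP = 500_000  # max number of enumerated gene sets
_CHUNK_CELLS = 20_000_000  # memory guard for vectorized sampling


@dataclass
class NullDistribution:
    """Mutated-sample counts of ``n_iterations`` random same-size gene sets."""

    counts: np.ndarray
    n_iterations: int
    set_size: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.n_iterations:
            raise ValueError("counts length must equal n_iterations")

    @property
    def average(self) -> float:
        """Mean count over the random sets (Table-style 'random average')."""
        return float(self.counts.mean())


@dataclass
class ChiSqResult:
    """Pearson chi-squared on a 2x2 table, df=1, no continuity correction."""

    statistic: float
    df: int
    p_value: float
    table: np.ndarray
    degenerate: bool = False


@dataclass
class EnrichmentReport:
    """One cohort's full burden-enrichment result (one Table-1A-style row)."""

    cancer_type: str
    n_samples: int
    observed_count: int
    null: NullDistribution
    p_total: float
    chisq: ChiSqResult
    per_gene_frequencies: Dict[str, float]
    gene_set_name: str = ""
    provenance: Dict = field(default_factory=dict)

    @property
    def random_average(self) -> float:
        return self.null.average

    def to_dict(self) -> Dict:
        return {
            "cancer_type": self.cancer_type,
            "gene_set": self.gene_set_name,
            "n_samples": self.n_samples,
            "observed_count": self.observed_count,
            "random_average": self.random_average,
            "p_total": self.p_total,
            "chisq_statistic": self.chisq.statistic,
            "chisq_p": self.chisq.p_value,
            "chisq_degenerate": self.chisq.degenerate,
            "per_gene_frequencies": dict(sorted(self.per_gene_frequencies.items())),
            "null": {
                "n_iterations": self.null.n_iterations,
                "set_size": self.null.set_size,
                "seed": self.null.seed,
                "average": self.null.average,
            },
            "provenance": self.provenance,
        }


def _eligible_gene_indices(
    matrix: MutationMatrix, exclude: Optional[GeneSet]
) -> np.ndarray:
    if exclude is None:
        return np.arange(matrix.n_genes)
    excluded = exclude.members
    return np.array(
        [i for i, g in enumerate(matrix.genes) if g not in excluded], dtype=np.int64
    )


def resample_null(
    matrix: MutationMatrix,
    set_size: int,
    n_iterations: int,
    seed: Union[int, np.random.SeedSequence, None],
    exclude: Optional[GeneSet] = None,
) -> NullDistribution:
    """Draw random same-size gene sets and record each union count.

    Each iteration draws ``set_size`` distinct genes uniformly without
    replacement from the matrix gene universe (minus ``exclude`` if given);
    sets are drawn independently across iterations, so the same set may
    recur. Identical seed implies identical counts.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    eligible = _eligible_gene_indices(matrix, exclude)
    m = len(eligible)
    if set_size > m:
        raise ValueError(
            f"set_size {set_size} exceeds eligible gene universe of size {m}"
        )
    rng = np.random.default_rng(seed)
    incidence = matrix.incidence[eligible]
    counts = np.empty(n_iterations, dtype=np.int64)
    # Vectorized sampling: rank a uniform matrix per row, take the first
    # set_size columns — equivalent to without-replacement draws.
    chunk = max(1, min(n_iterations, _CHUNK_CELLS // max(m, 1)))
    done = 0
    while done < n_iterations:
        size = min(chunk, n_iterations - done)
        keys = rng.random((size, m))
        sel = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        # union over chosen genes for each iteration
        hit = incidence[sel]  # (size, set_size, n_samples)
        counts[done : done + size] = hit.any(axis=1).sum(axis=1)
        done += size
    stored_seed = seed if isinstance(seed, (int, np.integer)) else None
    return NullDistribution(
        counts=counts,
        n_iterations=n_iterations,
        set_size=set_size,
        seed=int(stored_seed) if stored_seed is not None else None,
    )


def exhaustive_null(
    matrix: MutationMatrix,
    set_size: int,
    exclude: Optional[GeneSet] = None,
    cap: int = EXHAUSTIVE_CAP,
) -> NullDistribution:
    """Enumerate every possible gene set of ``set_size`` exactly once.

    Exact reference distribution; feasible only when C(universe, set_size)
    is below ``cap``. Serves as the oracle for :func:`resample_null`.
    """
    eligible = _eligible_gene_indices(matrix, exclude)
    m = len(eligible)
    if set_size > m:
        raise ValueError(
            f"set_size {set_size} exceeds eligible gene universe of size {m}"
        )
    n_sets = math.comb(m, set_size)
    if n_sets > cap:
        raise ValueError(
            f"C({m}, {set_size}) = {n_sets} exceeds the combinatorial cap {cap}"
        )
    incidence = matrix.incidence[eligible]
    counts = np.fromiter(
        (
            int(incidence[list(combo)].any(axis=0).sum())
            for combo in itertools.combinations(range(m), set_size)
        ),
        dtype=np.int64,
        count=n_sets,
    )
    return NullDistribution(
        counts=counts, n_iterations=n_sets, set_size=set_size, seed=None
    )


def p_total(null: NullDistribution, observed_count: int) -> float:
    """Fraction of the null counts that reach the observed count (>= rule).

    An empirical upper-tail p-value: the probability that a random same-size
    gene set yields at least as many mutated samples as the query set.
    """
    if len(null.counts) == 0:
        raise ValueError("empty null distribution")
    return float((null.counts >= observed_count).mean())


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def chi_squared_vs_random(
    observed_count: int, n_samples: int, random_average: float
) -> ChiSqResult:
    """Chi-squared comparison of observed vs. rounded-average random counts.

    The null average is first rounded (half-up) to an integer r, then the
    2x2 table [[observed, n-observed], [r, n-r]] is tested with the Pearson
    chi-squared statistic at df=1, WITHOUT continuity correction. A table
    with a zero margin is reported as p=1 with a degeneracy flag.
    """
    if not 0 <= observed_count <= n_samples:
        raise ValueError("observed_count must be in [0, n_samples]")
    if not 0 <= random_average <= n_samples:
        raise ValueError("random_average must be in [0, n_samples]")
    r = _round_half_up(random_average)
    table = np.array(
        [[observed_count, n_samples - observed_count], [r, n_samples - r]],
        dtype=np.int64,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ChiSqResult(
            statistic=0.0, df=1, p_value=1.0, table=table, degenerate=True
        )
    statistic, p_value, _, _ = stats.chi2_contingency(table, correction=False)
    return ChiSqResult(
        statistic=float(statistic), df=1, p_value=float(p_value), table=table
    )


def derive_cohort_seed(seed: int, cancer_type: str) -> int:
    """Stable per-cohort seed from (master seed, cohort label).

    A fresh generator per cancer type keeps cohorts independent and the
    whole analysis order-insensitive.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(cancer_type.encode("utf-8"))])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def run_cancer_type_analysis(
    maf_paths: Sequence,
    gene_set: GeneSet,
    *,
    cancer_type: str = "cohort",
    seed: int = 0,
    set_size: Optional[int] = None,
    n_iterations: int = 1000,
    classification_filter: Optional[ClassificationFilter] = None,
    exclude_query_set: bool = False,
    patient_level: bool = False,
    roster: Optional[Sequence[str]] = None,
) -> EnrichmentReport:
    """End-to-end analysis of one cohort: read, filter, merge, test.

    Pipeline: read each caller's MAF with the classification filter, merge
    to the deduplicated union, build the incidence matrix, count samples
    mutated in the query set, draw the random-set null, compute p-total and
    the chi-squared follow-up, and collect per-gene frequencies for every
    query-set member. Fully reproducible from (inputs, seed).

    Parameters
    ----------
    maf_paths
        One MAF path per caller pipeline.
    set_size
        Random-set size; defaults to the query set's size.
    exclude_query_set
        Remove query genes from the sampling universe (off by default: the
        random sets are drawn from the full mutated-gene universe).
    patient_level
        Truncate TCGA barcodes to the 12-character patient prefix before
        counting, so denominators count patients rather than aliquots.
    """
    from .maf_io import truncate_to_patient  # local import to avoid cycle noise

    if classification_filter is None:
        classification_filter = ClassificationFilter.default()
    summaries: List[ParseSummary] = []
    record_sets = []
    for path in maf_paths:
        summary = ParseSummary(path=str(path))
        record_sets.append(
            read_maf(path, classification_filter, summary=summary)
        )
        summaries.append(summary)
    merged = merge_caller_mafs(record_sets)
    if patient_level:
        merged = truncate_to_patient(merged)
        merged = merge_caller_mafs([merged])  # re-dedup at patient level
        if roster is not None:
            roster = sorted({s[:12] for s in roster})
    matrix = build_matrix(merged, roster=roster)

    if set_size is None:
        set_size = len(gene_set)
    observed = geneset_mutated_sample_count(matrix, gene_set)
    cohort_seed = derive_cohort_seed(seed, cancer_type)
    null = resample_null(
        matrix,
        set_size=set_size,
        n_iterations=n_iterations,
        seed=cohort_seed,
        exclude=gene_set if exclude_query_set else None,
    )
    ptot = p_total(null, observed)
    chisq = chi_squared_vs_random(observed, matrix.n_samples, null.average)
    frequencies = {
        g: gene_mutation_frequency(matrix, g) for g in sorted(gene_set.members)
    }
    dropped = {}
    for s in summaries:
        for token, count in s.dropped_classifications.items():
            dropped[token] = dropped.get(token, 0) + count
    provenance = {
        "seed": int(seed),
        "cohort_seed": cohort_seed,
        "set_size": int(set_size),
        "n_iterations": int(n_iterations),
        "exclude_query_set": bool(exclude_query_set),
        "patient_level": bool(patient_level),
        "maf_paths": [str(p) for p in maf_paths],
        "n_records_merged": len(merged),
        "dropped_classifications": dropped,
    }
    return EnrichmentReport(
        cancer_type=cancer_type,
        n_samples=matrix.n_samples,
        observed_count=observed,
        null=null,
        p_total=ptot,
        chisq=chisq,
        per_gene_frequencies=frequencies,
        gene_set_name=gene_set.name,
        provenance=provenance,
    )
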