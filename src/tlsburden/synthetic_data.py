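"""Synthetic somatic-mutation cohorts with known ground truth.

Generates multi-sample cohorts with the statistical structure the burden
analysis has to cope with in real pan-cancer data:

* per-sample mutation burden drawn from a heavy-tailed (log-normal)
  distribution, with a discrete hypermutator subpopulation on top —
  mimicking the POLE/MSI tail of endometrial cohorts, which inflates every
  gene set's union count;
* per-gene relative mutability from a mean-1 gamma distribution;
* independent Bernoulli gene x sample mutation indicators;
* an optional planted enrichment factor on a designated gene set, giving a
  known ground truth for power studies.

Cohorts are emitted as valid MAF so the whole pipeline — parsing,
filtering, merging, matrix building, resampling — is exercised end to end
with no external download.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from .maf_io import DEFAULT_VARIANT_CLASSIFICATIONS, MafRecord
from .mutation_matrix import GeneSet, build_matrix
from .burden_enrichment import p_total, resample_null

__all__ = ["CohortSimParams", "SimTruth", "simulate_cohort", "calibration_experiment"]

_CLASSIFICATION_CHOICES = tuple(sorted(DEFAULT_VARIANT_CLASSIFICATIONS))


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of one simulated cohort.

    Defaults describe a mid-sized solid-tumor cohort: 200 samples, a
    500-gene universe, a baseline per-gene per-sample mutation probability
    of 1%, substantial log-normal burden heterogeneity (sigma = 1), a 5%
    hypermutator subpopulation carrying 10x the burden, and unit-mean gamma
    gene-mutability weights with shape 1 (exponential spread).
    """

    n_samples: int = 200
    n_genes: int = 500
    base_rate: float = 0.01
    burden_dispersion: float = 1.0
    hypermutator_fraction: float = 0.05
    hypermutator_multiplier: float = 10.0
    gene_mutability_shape: float = 1.0
    enriched_set: Optional[GeneSet] = None
    enrichment_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be >= 1")
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.burden_dispersion < 0:
            raise ValueError("burden_dispersion must be >= 0")
        if not 0.0 <= self.hypermutator_fraction <= 1.0:
            raise ValueError("hypermutator_fraction must be in [0, 1]")
        if self.hypermutator_multiplier < 1.0:
            raise ValueError("hypermutator_multiplier must be >= 1")
        if self.gene_mutability_shape <= 0:
            raise ValueError("gene_mutability_shape must be > 0")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        if self.enriched_set is not None and len(self.enriched_set) > self.n_genes:
            raise ValueError("enriched set larger than gene universe")


@dataclass
class SimTruth:
    """Ground truth behind one simulated cohort."""

    genes: List[str]
    samples: List[str]
    cell_probabilities: np.ndarray  # (n_genes, n_samples)
    sample_multipliers: np.ndarray  # (n_samples,)
    hypermutator_flags: np.ndarray  # (n_samples,) bool
    gene_weights: np.ndarray  # (n_genes,)
    enriched_set: Optional[GeneSet]
    enrichment_factor: float
    incidence: np.ndarray  # realized (n_genes, n_samples) bool


def _gene_names(params: CohortSimParams) -> List[str]:
    # Planted genes occupy the first slots so they are always in the universe.
    names: List[str] = []
    if params.enriched_set is not None:
        names.extend(sorted(params.enriched_set.members))
    names.extend(
        f"G{i:05d}" for i in range(params.n_genes - len(names))
    )
    return names


def _sample_names(params: CohortSimParams) -> List[str]:
    # TCGA-style barcodes: 12-char patient prefix + aliquot suffix.
    return [f"TCGA-SY-{i:04d}-01A" for i in range(params.n_samples)]


def simulate_cohort(
    params: CohortSimParams,
) -> Tuple[List[MafRecord], SimTruth]:
    """Simulate one cohort; returns (MAF records, ground truth).

    Model: sample multiplier lambda_s ~ LogNormal(0, burden_dispersion),
    multiplied by ``hypermutator_multiplier`` for a
    Bernoulli(hypermutator_fraction) subset; gene weight
    w_g ~ Gamma(shape, scale=1/shape) (mean 1); cell (g, s) mutated with
    probability min(1, base_rate * lambda_s * w_g * enrichment), where the
    enrichment factor applies only to planted genes. Each mutated cell
    emits exactly one record with a classification drawn uniformly from the
    allowed list and a locus synthesized deterministically from
    (gene index, sample index), so dedup keys are unique by construction.
    Fully determined by ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    genes = _gene_names(params)
    samples = _sample_names(params)

    if params.burden_dispersion > 0:
        lam = rng.lognormal(mean=0.0, sigma=params.burden_dispersion, size=params.n_samples)
    else:
        lam = np.ones(params.n_samples)
    hyper = rng.random(params.n_samples) < params.hypermutator_fraction
    lam = lam * np.where(hyper, params.hypermutator_multiplier, 1.0)

    shape = params.gene_mutability_shape
    w = rng.gamma(shape=shape, scale=1.0 / shape, size=params.n_genes)

    enrich = np.ones(params.n_genes)
    if params.enriched_set is not None:
        members = params.enriched_set.members
        enrich = np.array(
            [params.enrichment_factor if g in members else 1.0 for g in genes]
        )

    probs = np.clip(
        params.base_rate * np.outer(w * enrich, lam), 0.0, 1.0
    )  # (n_genes, n_samples)
    incidence = rng.random(probs.shape) < probs

    records: List[MafRecord] = []
    gene_idx, sample_idx = np.nonzero(incidence)
    classifications = rng.choice(_CLASSIFICATION_CHOICES, size=len(gene_idx))
    for g, s, cls in zip(gene_idx, sample_idx, classifications):
        start = int(g) * 1_000_000 + int(s) + 1
        records.append(
            MafRecord(
                gene_symbol=genes[g],
                chromosome=str(int(g) % 22 + 1),
                start_position=start,
                end_position=start,
                reference_allele="A",
                tumor_allele="G",
                variant_classification=str(cls),
                sample_barcode=samples[s],
                caller="simulated",
            )
        )
    truth = SimTruth(
        genes=genes,
        samples=samples,
        cell_probabilities=probs,
        sample_multipliers=lam,
        hypermutator_flags=hyper,
        gene_weights=w,
        enriched_set=params.enriched_set,
        enrichment_factor=params.enrichment_factor,
        incidence=incidence,
    )
    return records, truth


def calibration_experiment(
    params: CohortSimParams,
    n_replicates: int,
    set_size: int,
    alpha: float,
    n_iterations: int = 1000,
) -> float:
    """Empirical rejection rate of p-total over replicate cohorts.

    For each replicate: simulate a fresh cohort (derived seed), run the
    full analysis path (records -> matrix -> observed count -> resampling
    null -> p-total), and test the query set at level ``alpha``.

    The query set is ``params.enriched_set`` when one is planted (power
    mode). Without a planted set (type-I mode, enrichment factor 1) the
    query set is itself drawn uniformly from the cohort's gene universe —
    the same mechanism that generates the random sets — so p-total should
    be approximately uniform and the rejection rate close to ``alpha``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    root = np.random.SeedSequence(params.seed)
    rejections = 0
    for child in root.spawn(n_replicates):
        sim_seed, query_seed, null_seed = (
            int(s) % (2**31) for s in child.generate_state(3, dtype=np.uint64)
        )
        rep_params = replace(params, seed=sim_seed)
        records, _ = simulate_cohort(rep_params)
        matrix = build_matrix(records)
        if params.enriched_set is not None:
            query = params.enriched_set
        else:
            qrng = np.random.default_rng(query_seed)
            picked = qrng.choice(matrix.n_genes, size=set_size, replace=False)
            query = GeneSet(
                name="random-query", members=frozenset(matrix.genes[i] for i in picked)
            )
        observed = int(matrix.set_mask(query).sum())
        null = resample_null(
            matrix, set_size=set_size, n_iterations=n_iterations, seed=null_seed
        )
        if p_total(null, observed) <= alpha:
            rejections += 1
    return rejections / n_replicates
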