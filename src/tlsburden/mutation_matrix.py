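"""Gene × sample boolean incidence matrix and mutation-frequency summaries.

The burden analysis reduces a merged, filtered MAF to a boolean incidence
structure: cell (g, s) is true iff sample s carries at least one retained
mutation in gene g. Per-gene mutation frequency is the number of mutated
samples divided by the total number of samples; the gene-set statistic is
the number of samples mutated in at least one member of the set (a union
count, hence sensitive to hypermutator samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "MutationMatrix",
    "build_matrix",
    "gene_mutation_frequency",
    "geneset_mutated_sample_count",
    "format_percent",
    "UndefinedCohortError",
]


class UndefinedCohortError(ValueError):
    """Raised when a frequency is requested from a 0-sample cohort."""


def _norm_gene(symbol: str) -> str:
    # HUGO symbols are uppercase; user gene-set files vary.
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (matched case-insensitively via uppercasing).

    Members need not all occur in a given matrix; absent members simply
    contribute nothing to the union count.
    """

    name: str
    members: frozenset

    def __post_init__(self) -> None:
        normalized = frozenset(_norm_gene(g) for g in self.members)
        if not normalized:
            raise ValueError("gene set must be non-empty")
        object.__setattr__(self, "members", normalized)

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_file(cls, path: Union[str, Path], name: Optional[str] = None) -> "GeneSet":
        """Plain-text gene list: one HUGO symbol per line, '#' comments allowed."""
        path = Path(path)
        members = set()
        for line in path.read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                members.add(line)
        return cls(name=name or path.stem, members=frozenset(members))


class MutationMatrix:
    """Boolean gene × sample incidence built from filtered, merged records.

    The gene universe is every symbol with at least one retained record
    (MAFs list only mutated genes); the sample list is either the distinct
    observed barcodes or a declared roster, which may include all-false
    columns (samples sequenced but carrying no retained mutation).
    """

    def __init__(
        self,
        genes: Sequence[str],
        samples: Sequence[str],
        incidence: np.ndarray,
    ):
        genes = [_norm_gene(g) for g in genes]
        samples = list(samples)
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene symbols in matrix")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers in matrix")
        incidence = np.asarray(incidence, dtype=bool)
        if incidence.shape != (len(genes), len(samples)):
            raise ValueError(
                f"incidence shape {incidence.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        self.genes = genes
        self.samples = samples
        self.incidence = incidence
        self._gene_index = {g: i for i, g in enumerate(genes)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_row(self, gene: str) -> Optional[np.ndarray]:
        idx = self._gene_index.get(_norm_gene(gene))
        return None if idx is None else self.incidence[idx]

    def set_mask(self, gene_set: GeneSet) -> np.ndarray:
        """Boolean per-sample mask: sample mutated in >=1 member gene."""
        rows = [self._gene_index[g] for g in gene_set.members if g in self._gene_index]
        if not rows:
            return np.zeros(self.n_samples, dtype=bool)
        return self.incidence[rows].any(axis=0)

    # --- TSV export/import for debugging and fixtures -------------------
    def to_tsv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame(
            self.incidence.astype(int), index=self.genes, columns=self.samples
        )
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "MutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genes=[str(g) for g in df.index],
            samples=[str(s) for s in df.columns],
            incidence=df.to_numpy(dtype=bool),
        )


def build_matrix(records, roster: Optional[Sequence[str]] = None) -> MutationMatrix:
    """Collapse records into a :class:`MutationMatrix`.

    Parameters
    ----------
    records
        Filtered, merged :class:`~tlsburden.maf_io.MafRecord` sequence.
    roster
        Optional declared cohort sample list. When given, the matrix columns
        are exactly the roster (all-false columns allowed) and a record
        naming a sample outside it is an error. Without a roster, samples
        are the distinct observed barcodes in first-seen order.
    """
    gene_order: dict = {}
    sample_order: dict = {}
    pairs = []
    for r in records:
        g = _norm_gene(r.gene_symbol)
        s = r.sample_barcode
        gene_order.setdefault(g, len(gene_order))
        if roster is None:
            sample_order.setdefault(s, len(sample_order))
        pairs.append((g, s))

    if roster is not None:
        samples = list(roster)
        sample_index = {s: i for i, s in enumerate(samples)}
        for _, s in pairs:
            if s not in sample_index:
                raise ValueError(f"record sample {s!r} not in declared roster")
    else:
        samples = list(sample_order)
        sample_index = sample_order

    genes = list(gene_order)
    incidence = np.zeros((len(genes), len(samples)), dtype=bool)
    for g, s in pairs:
        incidence[gene_order[g], sample_index[s]] = True
    return MutationMatrix(genes=genes, samples=samples, incidence=incidence)


def gene_mutation_frequency(matrix: MutationMatrix, gene: str) -> float:
    """Fraction of cohort samples carrying a retained mutation in ``gene``.

    The number of mutated samples divided by the total number of samples;
    a gene absent from the matrix has frequency 0.
    """
    if matrix.n_samples == 0:
        raise UndefinedCohortError("mutation frequency undefined for a 0-sample cohort")
    row = matrix.gene_row(gene)
    if row is None:
        return 0.0
    return int(row.sum()) / matrix.n_samples


def geneset_mutated_sample_count(matrix: MutationMatrix, gene_set: GeneSet) -> int:
    """Number of samples mutated in at least one member of ``gene_set``."""
    return int(matrix.set_mask(gene_set).sum())


def format_percent(fraction: float) -> str:
    """Whole-percent formatting, round-half-up (196/530 -> '37%')."""
    return f"{math.floor(fraction * 100 + 0.5):d}%"
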