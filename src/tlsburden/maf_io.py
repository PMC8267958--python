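"""Reading, filtering, merging and writing MAF somatic-variant files.

MAF (Mutation Annotation Format) is the tab-separated exchange format used by
TCGA: one row per variant call per tumor sample, '#'-prefixed pragma lines
before a header row. TCGA distributes one MAF per variant-calling pipeline
(muse, varscan2, somaticsniper, mutect2); downstream burden analysis works on
the deduplicated union of all callers' calls, restricted to an explicit list
of variant-classification tokens.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

__all__ = [
    "DEFAULT_VARIANT_CLASSIFICATIONS",
    "REQUIRED_COLUMNS",
    "MafRecord",
    "ClassificationFilter",
    "ParseSummary",
    "MafFormatError",
    "MafRowError",
    "normalize_classification",
    "read_maf",
    "merge_caller_mafs",
    "write_maf",
]

# The 25 variant-classification tokens retained in the burden analysis.
# Coding, UTR/flank, silent, intronic and non-coding-RNA classes are all kept
# ("all mutations included"); tokens absent from this list (e.g. "Unknown")
# are dropped at parse time.
DEFAULT_VARIANT_CLASSIFICATIONS = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "Targeted_Region",
        "Silent",
        "Intron",
        "RNA",
        "IGR",
        "Splice_Region",
        "5'Flank",
        "lincRNA",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
        "Start_Codon_Ins",
        "Start_Codon_SNP",
        "Stop_Codon_Del",
    }
)

REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
)

# Typographic quote glyphs seen in published classification lists, mapped to
# the ASCII apostrophe used by actual MAF files (3'UTR, 5'Flank, ...).
_QUOTE_NORMALIZATION = str.maketrans({"’": "'", "‘": "'", "′": "'"})


def normalize_classification(token: str) -> str:
    """Trim whitespace and normalize typographic apostrophes to ASCII."""
    return token.strip().translate(_QUOTE_NORMALIZATION)


class MafFormatError(ValueError):
    """File-level format problem (e.g. a required column is missing)."""


class MafRowError(ValueError):
    """Row-level problem, carrying the 1-based line number in the file."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class MafRecord:
    """One somatic variant call.

    Positions are 1-based inclusive. ``caller`` tags the pipeline the call
    came from and is ignored by deduplication. ``extra`` preserves any
    unrecognized MAF columns from the source file; it never participates in
    equality or deduplication.
    """

    gene_symbol: str
    chromosome: str
    start_position: int
    end_position: int
    reference_allele: str
    tumor_allele: str
    variant_classification: str
    sample_barcode: str
    caller: Optional[str] = None
    extra: Tuple[Tuple[str, str], ...] = field(default=(), compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if not self.sample_barcode:
            raise ValueError("sample_barcode must be non-empty")
        if self.start_position < 1:
            raise ValueError(f"start_position must be >= 1, got {self.start_position}")
        if self.end_position < self.start_position:
            raise ValueError(
                f"end_position {self.end_position} < start_position {self.start_position}"
            )

    @property
    def dedup_key(self) -> Tuple[str, str, int, int, str, str]:
        """Identity of the mutation event: the same call made by two callers
        shares this key. Caller-specific columns and classification do not
        enter the key."""
        return (
            self.sample_barcode,
            self.chromosome,
            self.start_position,
            self.end_position,
            self.reference_allele,
            self.tumor_allele,
        )


@dataclass(frozen=True)
class ClassificationFilter:
    """Set of variant-classification tokens retained by :func:`read_maf`.

    Tokens are compared case-sensitively after whitespace trimming and
    apostrophe normalization.
    """

    allowed: frozenset = DEFAULT_VARIANT_CLASSIFICATIONS

    def __post_init__(self) -> None:
        normalized = frozenset(normalize_classification(t) for t in self.allowed)
        if not normalized:
            raise ValueError("classification filter must be non-empty")
        object.__setattr__(self, "allowed", normalized)

    @classmethod
    def default(cls) -> "ClassificationFilter":
        return cls()

    @classmethod
    def all_inclusive(cls) -> "ClassificationFilter":
        """Filter that retains every classification token."""
        return _AllInclusiveFilter()

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ClassificationFilter":
        """One token per line; '#' comment lines and blank lines ignored."""
        tokens = set()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                tokens.add(line)
        return cls(allowed=frozenset(tokens))

    def allows(self, token: str) -> bool:
        return normalize_classification(token) in self.allowed


class _AllInclusiveFilter(ClassificationFilter):
    def allows(self, token: str) -> bool:  # noqa: D102 - trivial override
        return True


@dataclass
class ParseSummary:
    """Bookkeeping from one :func:`read_maf` call."""

    path: str
    n_data_rows: int = 0
    n_retained: int = 0
    dropped_classifications: Counter = field(default_factory=Counter)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped_classifications.values())


def read_maf(
    path: Union[str, Path],
    classification_filter: Optional[ClassificationFilter] = None,
    caller: Optional[str] = None,
    summary: Optional[ParseSummary] = None,
):
    """Parse a MAF file, keeping rows whose classification passes the filter.

    Parameters
    ----------
    path
        Tab-separated file with '#' pragma lines and a header row naming at
        least the columns in :data:`REQUIRED_COLUMNS`.
    classification_filter
        Defaults to the built-in 25-token list. Rows with disallowed
        classifications are dropped silently; their per-token counts are
        recorded in ``summary`` when one is passed.
    caller
        Optional pipeline tag attached to every record (used for provenance
        through merging). If the file has a ``Caller`` column, that column
        wins row by row.
    summary
        A :class:`ParseSummary` to fill in place.

    Returns
    -------
    list of MafRecord, in file order.
    """
    if classification_filter is None:
        classification_filter = ClassificationFilter.default()
    path = Path(path)
    if summary is None:
        summary = ParseSummary(path=str(path))
    else:
        summary.path = str(path)

    records = []
    header = None
    col_idx = {}
    caller_col = None
    with path.open("r", encoding="utf-8") as fh:
        for line_number, raw in enumerate(fh, start=1):
            if raw.startswith("#"):
                continue
            line = raw.rstrip("\r\n")
            if header is None:
                if not line:
                    continue
                header = line.split("\t")
                col_idx = {name: i for i, name in enumerate(header)}
                missing = [c for c in REQUIRED_COLUMNS if c not in col_idx]
                if missing:
                    raise MafFormatError(
                        f"{path}: missing required MAF column(s): {', '.join(missing)}"
                    )
                caller_col = col_idx.get("Caller")
                continue
            if not line:
                continue
            fields_ = line.split("\t")
            if len(fields_) < len(header):
                fields_ = fields_ + [""] * (len(header) - len(fields_))
            summary.n_data_rows += 1
            classification = normalize_classification(
                fields_[col_idx["Variant_Classification"]]
            )
            if not classification_filter.allows(classification):
                summary.dropped_classifications[classification] += 1
                continue
            try:
                start = int(fields_[col_idx["Start_Position"]])
                end = int(fields_[col_idx["End_Position"]])
            except ValueError as exc:
                raise MafRowError(line_number, f"unparseable position: {exc}") from None
            extra = tuple(
                (name, fields_[i])
                for name, i in col_idx.items()
                if name not in REQUIRED_COLUMNS and name != "Caller"
            )
            row_caller = fields_[caller_col] if caller_col is not None else ""
            try:
                record = MafRecord(
                    gene_symbol=fields_[col_idx["Hugo_Symbol"]].strip(),
                    chromosome=fields_[col_idx["Chromosome"]].strip(),
                    start_position=start,
                    end_position=end,
                    reference_allele=fields_[col_idx["Reference_Allele"]],
                    tumor_allele=fields_[col_idx["Tumor_Seq_Allele2"]],
                    variant_classification=classification,
                    sample_barcode=fields_[col_idx["Tumor_Sample_Barcode"]].strip(),
                    caller=row_caller or caller,
                    extra=extra,
                )
            except ValueError as exc:
                raise MafRowError(line_number, str(exc)) from None
            records.append(record)
            summary.n_retained += 1
    if header is None:
        raise MafFormatError(f"{path}: no header row found")
    return records


def merge_caller_mafs(
    record_sets: Iterable[Sequence[MafRecord]],
) -> "list[MafRecord]":
    """Deduplicated union of per-caller record lists.

    Two records are the same mutation event iff they agree on
    (sample, chromosome, start, end, ref allele, tumor allele); the retained
    record keeps the first caller tag seen. Output is sorted by
    (sample, chromosome, start, end, ref, alt) so the merge is deterministic
    and insensitive to input order at the set level.
    """
    seen = {}
    for record_set in record_sets:
        for record in record_set:
            seen.setdefault(record.dedup_key, record)
    return [seen[key] for key in sorted(seen)]


def write_maf(records: Sequence[MafRecord], path: Union[str, Path]) -> None:
    """Write records as a minimal standard MAF readable by :func:`read_maf`.

    Only the canonical columns (plus ``Caller`` when any record carries a
    tag) are written; ``extra`` columns from heterogeneous sources are not.
    """
    path = Path(path)
    with_caller = any(r.caller for r in records)
    columns = list(REQUIRED_COLUMNS) + (["Caller"] if with_caller else [])
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#version 2.4\n")
        fh.write("\t".join(columns) + "\n")
        for r in records:
            row = [
                r.gene_symbol,
                r.chromosome,
                str(r.start_position),
                str(r.end_position),
                r.reference_allele,
                r.tumor_allele,
                r.variant_classification,
                r.sample_barcode,
            ]
            if with_caller:
                row.append(r.caller or "")
            fh.write("\t".join(row) + "\n")


def truncate_to_patient(records: Sequence[MafRecord], width: int = 12):
    """Collapse TCGA tumor-sample barcodes to the patient prefix.

    TCGA barcodes are hierarchical (``TCGA-XX-YYYY-...``); the first 12
    characters identify the patient. Used when the cohort denominator should
    count patients rather than aliquots.
    """
    return [replace(r, sample_barcode=r.sample_barcode[:width]) for r in records]
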