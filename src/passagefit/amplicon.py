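"""Amplicon read processing: FASTQ to per-sample genotype counts.

Mirrors the classic fastx-tools chain used for pooled competition assays:
drop reads shorter than 100 nt, demultiplex on exact begin-of-line inline
barcodes (no mismatches, no offsets), extract the 5-nt window at read
positions 59-63 (1-based, barcode included) containing the diagnostic
SNP, and classify each window by exact match against the two allele
5-mers. Base qualities are parsed but never filtered on.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigurationError, InvalidInputError, UndefinedFrequencyError

__all__ = [
    "BarcodeSpec",
    "AlleleSpec",
    "ProcessingLog",
    "filter_short_reads",
    "demultiplex_exact_bol",
    "trim_window",
    "count_alleles",
    "compute_frequency",
    "count_reads",
    "read_sample_sheet",
    "load_alleles",
]

_VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class BarcodeSpec:
    """Inline barcode expected at the exact start of a sample's reads."""

    sample_id: str
    barcode: str

    def __post_init__(self):
        if not self.barcode or set(self.barcode) - _VALID_BASES:
            raise InvalidInputError(
                f"barcode for {self.sample_id!r} must be non-empty A/C/G/T"
            )


@dataclass(frozen=True)
class AlleleSpec:
    """Diagnostic 5-mer for one genotype at the SNP window."""

    genotype: str            # "WT" or "TF_NULL"
    kmer: str

    def __post_init__(self):
        if self.genotype not in ("WT", "TF_NULL"):
            raise InvalidInputError("genotype must be WT or TF_NULL")
        if len(self.kmer) != 5 or set(self.kmer) - _VALID_BASES:
            raise InvalidInputError("allele k-mer must be a 5-nt A/C/G/T string")


@dataclass
class ProcessingLog:
    """Read-accounting for one input file; conserves every input read."""

    reads_in: int = 0
    short_filtered: int = 0
    unmatched: int = 0
    trim_discarded: int = 0
    assigned: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> bool:
        return (
            self.reads_in
            == self.short_filtered + self.unmatched + self.trim_discarded + self.assigned
        )


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_fastq(path: str | Path):
    """Yield (title, seq, qual) records; sequences uppercased."""
    with _open_maybe_gz(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title, seq.upper(), qual


def filter_short_reads(reads, min_len: int = 100, log: ProcessingLog | None = None):
    """Drop reads shorter than ``min_len`` nucleotides (boundary kept)."""
    for rec in reads:
        if log is not None:
            log.reads_in += 1
        if len(rec[1]) >= min_len:
            yield rec
        elif log is not None:
            log.short_filtered += 1


def _validate_barcodes(barcodes: list[BarcodeSpec]) -> None:
    seen = {}
    for spec in barcodes:
        if spec.barcode in seen:
            raise ConfigurationError(
                f"duplicate barcode {spec.barcode} ({seen[spec.barcode]}, {spec.sample_id})"
            )
        seen[spec.barcode] = spec.sample_id
    codes = sorted(seen)
    for a, b in zip(codes, codes[1:]):
        if b.startswith(a):
            raise ConfigurationError(
                f"ambiguous barcodes: {a} is a prefix of {b}"
            )


def demultiplex_exact_bol(reads, barcodes: list[BarcodeSpec], log: ProcessingLog | None = None):
    """Split reads by exact begin-of-line barcode match.

    Returns ``(by_sample, unmatched)`` where ``by_sample`` maps sample_id
    to its records. A read matches iff its first ``len(barcode)`` bases
    equal a barcode exactly; barcodes are not trimmed from the read (the
    downstream window coordinates include them).
    """
    _validate_barcodes(barcodes)
    lookup = {spec.barcode: spec.sample_id for spec in barcodes}
    lengths = sorted({len(spec.barcode) for spec in barcodes})
    by_sample: dict[str, list] = {spec.sample_id: [] for spec in barcodes}
    unmatched = []
    for rec in reads:
        seq = rec[1]
        for L in lengths:
            sample = lookup.get(seq[:L])
            if sample is not None:
                by_sample[sample].append(rec)
                break
        else:
            unmatched.append(rec)
            if log is not None:
                log.unmatched += 1
    return by_sample, unmatched


def trim_window(read: str, first: int = 59, last: int = 63) -> str | None:
    """Bases ``first..last`` of a read, 1-based inclusive.

    Returns ``None`` for reads too short to contain the window; callers
    count those in their drop statistic rather than failing.
    """
    if first < 1 or last < first:
        raise InvalidInputError("need 1 <= first <= last")
    if len(read) < last:
        return None
    return read[first - 1 : last]


def count_alleles(kmers, alleles: list[AlleleSpec]) -> tuple[int, int, int]:
    """Classify 5-mers by exact match: (count_wt, count_tf0, count_other)."""
    by_genotype = {a.genotype: a.kmer for a in alleles}
    if len(by_genotype) != len(alleles):
        raise ConfigurationError("exactly one allele spec per genotype")
    if len(set(by_genotype.values())) != len(by_genotype):
        raise ConfigurationError("allele k-mers must be distinct")
    wt = by_genotype.get("WT")
    tf0 = by_genotype.get("TF_NULL")
    n_wt = n_tf0 = n_other = 0
    for k in kmers:
        if k == wt:
            n_wt += 1
        elif k == tf0:
            n_tf0 += 1
        else:
            n_other += 1
    return n_wt, n_tf0, n_other


def compute_frequency(count_tf0: int, count_wt: int) -> float:
    """Focal-genotype frequency ``tf0 / (tf0 + wt)``; unassigned reads excluded."""
    total = count_tf0 + count_wt
    if total <= 0:
        raise UndefinedFrequencyError("no informative reads for this sample")
    return count_tf0 / total


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Load a TSV/CSV sample sheet mapping barcodes to sample metadata."""
    sep = "," if str(path).endswith(".csv") else "\t"
    sheet = pd.read_csv(path, sep=sep, dtype={"barcode": str, "sample_id": str})
    required = {"sample_id", "barcode"}
    missing = required - set(sheet.columns)
    if missing:
        raise ConfigurationError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def load_alleles(path: str | Path) -> list[AlleleSpec]:
    """Load allele 5-mers from a YAML mapping {WT: ..., TF_NULL: ...}."""
    data = yaml.safe_load(Path(path).read_text())
    return [AlleleSpec(genotype=g, kmer=str(k).upper()) for g, k in data.items()]


def count_reads(
    fastq: str | Path,
    sample_sheet: pd.DataFrame,
    alleles: list[AlleleSpec],
    min_len: int = 100,
    window: tuple[int, int] = (59, 63),
) -> tuple[pd.DataFrame, ProcessingLog]:
    """Full chain: filter, demultiplex, trim, count.

    Returns the genotype count table (one row per sample-sheet row, with
    the sheet's metadata columns carried through) and the read-accounting
    log for the input file.
    """
    log = ProcessingLog()
    barcodes = [
        BarcodeSpec(sample_id=row.sample_id, barcode=row.barcode)
        for row in sample_sheet.itertuples(index=False)
    ]
    kept = filter_short_reads(parse_fastq(fastq), min_len=min_len, log=log)
    by_sample, _ = demultiplex_exact_bol(kept, barcodes, log=log)

    rows = []
    first, last = window
    for row in sample_sheet.itertuples(index=False):
        kmers = []
        for rec in by_sample[row.sample_id]:
            k = trim_window(rec[1], first, last)
            if k is None:
                log.trim_discarded += 1
            else:
                kmers.append(k)
                log.assigned += 1
        n_wt, n_tf0, n_other = count_alleles(kmers, alleles)
        log.per_sample[row.sample_id] = len(kmers)
        out = row._asdict()
        out.pop("barcode", None)
        out.update({"count_wt": n_wt, "count_tf0": n_tf0, "count_other": n_other})
        rows.append(out)
    return pd.DataFrame(rows), log
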