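"""Synthetic serial-transfer competition experiments.

Generates data with exactly the statistical structure the inference model
assumes — a deterministic frequency recursion per passage, optional
binomial bottleneck drift at each dilution, and (beta-)binomial read
sampling at sequenced timepoints — plus raw amplicon FASTQ with inline
sample barcodes and a diagnostic SNP, so the whole downstream pipeline can
be exercised without any external data.
"""

from __future__ import annotations

import gzip
import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CovariateSetting, SimulationDesign, TrueParameters
from .errors import InvalidInputError
from .model import effective_fitness, propagate_frequency

__all__ = [
    "simulate_trajectory",
    "simulate_read_counts",
    "simulate_experiment",
    "SimulatedDataset",
    "emit_fastq",
    "make_barcodes",
    "default_read_template",
    "DEFAULT_WT_KMER",
    "DEFAULT_TF_NULL_KMER",
]

# The diagnostic SNP distinguishing the genotypes sits at the center of the
# 5-nt window the counting pipeline extracts (read positions 59-63). The
# genomic context of the real SNP is configuration, not a constant; these
# are the fixture defaults (C>A change at the window center).
DEFAULT_WT_KMER = "TTCGA"
DEFAULT_TF_NULL_KMER = "TTAGA"

COUNT_COLUMNS = [
    "sample_id",
    "condition",
    "replicate",
    "timepoint",
    "cum_generations",
    "mat",
    "cocl2",
    "glucose_pct",
    "is_tf_null",
    "count_tf0",
    "count_wt",
]


def simulate_trajectory(
    params: TrueParameters,
    design: SimulationDesign,
    condition: CovariateSetting,
    rng: np.random.Generator,
    variant: str = "as_printed",
) -> np.ndarray:
    """Hidden focal-genotype frequency at each sampling timepoint.

    The frequency is propagated passage by passage at the condition's
    effective fitness, with a binomial bottleneck of ``bottleneck_cells``
    cells applied at every dilution when finite.
    """
    w_eff = effective_fitness(params.w_base, params.betas(), condition)
    per_passage = design.passage_generations
    sampled = set(design.sampling_timepoints)
    p = params.p0
    out = []
    if 0 in sampled:
        out.append(p)
    for i, dg in enumerate(per_passage, start=1):
        p = propagate_frequency(p, w_eff, dg, variant=variant)
        if math.isfinite(design.bottleneck_cells):
            n = int(design.bottleneck_cells)
            p = rng.binomial(n, p) / n
        if i in sampled:
            out.append(p)
        if i >= design.sampling_timepoints[-1]:
            break
    return np.asarray(out)


def simulate_read_counts(
    frequency: float,
    depth: int,
    overdispersion: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Sample ``(count_tf0, count_wt)`` reads at a hidden frequency.

    Pure binomial sampling when ``overdispersion`` is 0; otherwise
    beta-binomial with concentration ``1 / overdispersion`` (larger
    overdispersion = noisier counts). Counts always sum to ``depth``.
    """
    if not 0.0 <= frequency <= 1.0:
        raise InvalidInputError("frequency must lie in [0, 1]")
    if depth <= 0:
        raise InvalidInputError("depth must be positive")
    if overdispersion < 0:
        raise InvalidInputError("overdispersion must be >= 0")
    if overdispersion == 0 or frequency in (0.0, 1.0):
        k = int(rng.binomial(depth, frequency))
    else:
        kappa = 1.0 / overdispersion
        p = rng.beta(frequency * kappa, (1.0 - frequency) * kappa)
        k = int(rng.binomial(depth, p))
    return k, depth - k


@dataclass
class SimulatedDataset:
    """Observable count table plus the hidden truth that generated it."""

    table: pd.DataFrame          # COUNT_COLUMNS + true_freq
    params: TrueParameters
    design: SimulationDesign

    @property
    def counts(self) -> pd.DataFrame:
        """The observable table only (what a real experiment would yield)."""
        return self.table[COUNT_COLUMNS].copy()

    def write_counts(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    def write_truth(self, path: str | Path) -> None:
        truth = {
            "w_base": self.params.w_base,
            "beta_mat": self.params.beta_mat,
            "beta_cocl2": self.params.beta_cocl2,
            "beta_glucose": self.params.beta_glucose,
            "beta_tf_null": self.params.beta_tf_null,
            "p0": self.params.p0,
            "seed": self.design.seed,
        }
        Path(path).write_text(json.dumps(truth, indent=2) + "\n")


def simulate_experiment(
    design: SimulationDesign,
    params: TrueParameters,
    overdispersion: float = 0.0,
    variant: str = "as_printed",
) -> SimulatedDataset:
    """Run the full generative model for every condition and replicate."""
    rng = np.random.default_rng(design.seed)
    cum_gen = design.cumulative_generations
    rows = []
    for ci, condition in enumerate(design.conditions):
        for rep in range(1, design.n_replicates + 1):
            freqs = simulate_trajectory(params, design, condition, rng, variant)
            for ti, (tp, g, f) in enumerate(
                zip(design.sampling_timepoints, cum_gen, freqs)
            ):
                tf0, wt = simulate_read_counts(
                    f, design.read_depth, overdispersion, rng
                )
                rows.append(
                    {
                        "sample_id": f"c{ci}_r{rep}_t{ti}",
                        "condition": ci,
                        "replicate": rep,
                        "timepoint": ti,
                        "cum_generations": g,
                        "mat": condition.mat,
                        "cocl2": condition.cocl2,
                        "glucose_pct": condition.glucose_pct,
                        "is_tf_null": condition.is_tf_null,
                        "count_tf0": tf0,
                        "count_wt": wt,
                        "true_freq": f,
                    }
                )
    return SimulatedDataset(pd.DataFrame(rows), params, design)


def make_barcodes(n: int, length: int = 6) -> list[str]:
    """Deterministic list of ``n`` distinct same-length barcodes.

    Equal lengths guarantee no barcode is a prefix of another, which the
    exact begin-of-line demultiplexer rejects as ambiguous.
    """
    if n > 4**length:
        raise InvalidInputError(f"cannot make {n} distinct barcodes of length {length}")
    out = []
    for combo in itertools.product("ACGT", repeat=length):
        out.append("".join(combo))
        if len(out) == n:
            break
    return out


def default_read_template(length: int = 94, seed: int = 7) -> str:
    """Deterministic pseudo-genomic insert placed after each barcode."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def emit_fastq(
    dataset: SimulatedDataset,
    barcodes: dict[str, str],
    alleles: dict[str, str] | None = None,
    read_template: str | None = None,
    path: str | Path = "reads.fastq",
    snp_first: int = 59,
    snp_last: int = 63,
) -> dict[str, int]:
    """Write the dataset's counts as a pooled amplicon FASTQ file.

    Each record is ``barcode + read_template`` with the genotype's 5-mer
    substituted at read positions ``snp_first..snp_last`` (1-based,
    barcode included), and a constant quality string (Phred 40); the
    counting pipeline never uses quality. Gzip output when ``path`` ends
    in ``.gz``. Returns records written per sample.
    """
    if alleles is None:
        alleles = {"WT": DEFAULT_WT_KMER, "TF_NULL": DEFAULT_TF_NULL_KMER}
    if read_template is None:
        read_template = default_read_template()
    if len(alleles["WT"]) != snp_last - snp_first + 1:
        raise InvalidInputError("allele k-mer length must match the SNP window")

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    written: dict[str, int] = {}
    with opener(path, "wt") as fh:
        for row in dataset.table.itertuples(index=False):
            sample = row.sample_id
            barcode = barcodes[sample]
            read_len = len(barcode) + len(read_template)
            if read_len < snp_last:
                raise InvalidInputError(
                    f"template too short: read length {read_len} < {snp_last}"
                )
            base = barcode + read_template
            serial = 0
            for genotype, count in (("TF_NULL", row.count_tf0), ("WT", row.count_wt)):
                kmer = alleles[genotype]
                read = base[: snp_first - 1] + kmer + base[snp_last:]
                qual = "I" * len(read)
                for _ in range(int(count)):
                    fh.write(f"@{sample}:{genotype}:{serial}\n{read}\n+\n{qual}\n")
                    serial += 1
            written[sample] = serial
    return written
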