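"""Transposon copy number from read depth over a diagnostic region.

A TE family's haploid copy number can be estimated from short reads as
the mean per-base depth over a family-diagnostic consensus region (the
divergent gag interval, positions 56-1000 after the 5' LTR) divided by
the mean depth across a panel of single-copy genes. This module is a
deliberately transparent depth-ratio estimator: reads are placed on
targets by k-mer seeding plus an edit-distance check, depth ratios give
the estimate, and full-length copies on assemblies are counted by local
alignment for calibration.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement
from scipy import stats

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "ConsensusRegion",
    "SingleCopyPanel",
    "CopyNumberEstimate",
    "assign_reads",
    "estimate_copy_number",
    "count_assembly_copies",
    "calibrate",
    "correlate_phenotype",
]

CANONICAL_REGION_LENGTH = 945  # gag positions 56..1000 inclusive
_VALID = set("ACGT")


@dataclass(frozen=True)
class ConsensusRegion:
    """Family-diagnostic consensus sequence (e.g. the divergent gag region)."""

    family: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if set(seq) - _VALID:
            raise InvalidInputError(f"{self.family}: sequence must be A/C/G/T only")
        object.__setattr__(self, "sequence", seq)

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class SingleCopyPanel:
    """Normalization panel of single-copy genes."""

    genes: tuple[tuple[str, str], ...]   # (label, sequence)

    def __post_init__(self):
        genes = tuple((g, s.upper()) for g, s in self.genes)
        if len(genes) < 5:
            raise ConfigurationError("panel needs at least 5 single-copy genes")
        labels = [g for g, _ in genes]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate gene labels in panel")
        object.__setattr__(self, "genes", genes)

    def check_disjoint(self, regions: list[ConsensusRegion], k: int = 31) -> None:
        """Reject a panel sharing any k-mer with a consensus region."""
        te_kmers = set()
        for r in regions:
            s = r.sequence
            te_kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
            rc = reverse_complement(s)
            te_kmers.update(rc[i : i + k] for i in range(len(rc) - k + 1))
        for label, seq in self.genes:
            for i in range(len(seq) - k + 1):
                if seq[i : i + k] in te_kmers:
                    raise ConfigurationError(
                        f"panel gene {label} shares a {k}-mer with a consensus region"
                    )


@dataclass
class CopyNumberEstimate:
    family: str
    copies: float
    te_depth: float
    panel_depth: float
    assembly_count: int | None = None


# ---------------------------------------------------------------------------
# Read assignment
# ---------------------------------------------------------------------------

def _read_seqs(source) -> list[tuple[str, str]]:
    """Accept a path (FASTA/FASTQ, optionally gz) or an iterable of (name, seq)."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        name = path.name[:-3] if path.name.endswith(".gz") else path.name
        fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
        opener = gzip.open if path.name.endswith(".gz") else open
        with opener(path, "rt") as fh:
            return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]
    return [(n, s.upper()) for n, s in source]


def _kmer_index(targets: list[tuple[str, str]], k: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for ti, (_, seq) in enumerate(targets):
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], set()).add(ti)
    return index


@dataclass
class AssignmentResult:
    coverage: dict[str, np.ndarray]
    assigned: int = 0
    unassigned: int = 0
    ties: int = 0
    per_target: dict[str, int] = field(default_factory=dict)


def assign_reads(
    reads,
    targets: list[tuple[str, str]],
    k: int = 21,
    max_mismatch_per_100: float = 3.0,
) -> AssignmentResult:
    """Place reads on targets and accumulate per-base coverage.

    Each read (both strands tried) is assigned to the single target
    sharing the most seed k-mers, then verified by an edit-distance check
    (<= ``max_mismatch_per_100`` per 100 read bases, infix alignment).
    Ties between targets and failed verifications leave the read
    unassigned; tie reads are dropped rather than split to avoid double
    counting.
    """
    seqs = _read_seqs(reads)
    names = [n for n, _ in targets]
    if len(set(s for _, s in targets)) != len(targets):
        raise ConfigurationError("duplicate target sequences")
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate target names")
    index = _kmer_index(targets, k)
    result = AssignmentResult(
        coverage={n: np.zeros(len(s)) for n, s in targets},
        per_target={n: 0 for n in names},
    )
    for _, read in seqs:
        if len(read) < k:
            result.unassigned += 1
            continue
        # best seed support per (target, strand); read maps on one strand
        scores: dict[int, tuple[int, str]] = {}
        for oriented in (read, reverse_complement(read)):
            hits = np.zeros(len(targets), dtype=int)
            for i in range(len(oriented) - k + 1):
                for ti in index.get(oriented[i : i + k], ()):
                    hits[ti] += 1
            for ti in np.flatnonzero(hits):
                h = int(hits[ti])
                if ti not in scores or h > scores[ti][0]:
                    scores[int(ti)] = (h, oriented)
        if not scores:
            result.unassigned += 1
            continue
        top = max(h for h, _ in scores.values())
        top_targets = [ti for ti, (h, _) in scores.items() if h == top]
        if len(top_targets) > 1:
            result.unassigned += 1
            result.ties += 1
            continue
        ti = top_targets[0]
        oriented = scores[ti][1]
        tname, tseq = targets[ti]
        max_dist = int(np.ceil(max_mismatch_per_100 * len(oriented) / 100.0))
        aln = edlib.align(oriented, tseq, mode="HW", task="locations", k=max_dist)
        if aln["editDistance"] < 0:
            result.unassigned += 1
            continue
        start, end = aln["locations"][0]
        result.coverage[tname][start : end + 1] += 1
        result.assigned += 1
        result.per_target[tname] += 1
    return result


def estimate_copy_number(
    coverage: dict[str, np.ndarray],
    families: list[str],
    panel_genes: list[str],
) -> list[CopyNumberEstimate]:
    """Depth-ratio copy number: family mean depth over pooled panel depth."""
    panel_cov = [coverage[g] for g in panel_genes]
    panel_depth = float(np.concatenate(panel_cov).mean())
    if panel_depth <= 0:
        raise InvalidInputError("panel mean depth is zero; cannot normalize")
    out = []
    for fam in families:
        te_depth = float(coverage[fam].mean())
        out.append(
            CopyNumberEstimate(
                family=fam,
                copies=te_depth / panel_depth,
                te_depth=te_depth,
                panel_depth=panel_depth,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Assembly copy counting
# ---------------------------------------------------------------------------

def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _candidate_hits(contig: str, region: str, k: int = 21):
    """Approximate start positions of region copies via seed diagonals."""
    index: dict[str, list[int]] = {}
    for i in range(len(region) - k + 1):
        index.setdefault(region[i : i + k], []).append(i)
    diags: list[int] = []
    for j in range(len(contig) - k + 1):
        for i in index.get(contig[j : j + k], ()):
            diags.append(j - i)
    if not diags:
        return []
    diags.sort()
    # cluster diagonals closer than half the region length
    clusters = [[diags[0]]]
    tol = max(len(region) // 2, 50)
    for d in diags[1:]:
        if d - clusters[-1][-1] <= tol:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    return [int(np.median(c)) for c in clusters]


def _evaluate_candidate(contig: str, start: int, region: str, aligner: PairwiseAligner):
    """Local-align the region to a padded window; return (interval, len_frac, identity)."""
    L = len(region)
    pad = max(L // 4, 100)
    lo = max(start - pad, 0)
    hi = min(start + L + pad, len(contig))
    window = contig[lo:hi]
    if not window:
        return None
    alns = aligner.align(window, region)
    if len(alns) == 0:
        return None
    aln = alns[0]
    t_blocks, q_blocks = aln.aligned
    if len(q_blocks) == 0:
        return None
    q_span = sum(b - a for a, b in q_blocks)
    matches = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        tseg = window[ts:te]
        qseg = region[qs:qe]
        matches += sum(a == b for a, b in zip(tseg, qseg))
    aligned_cols = sum(te - ts for ts, te in t_blocks)
    identity = matches / aligned_cols if aligned_cols else 0.0
    interval = (lo + int(t_blocks[0][0]), lo + int(t_blocks[-1][1]))
    return interval, q_span / L, identity


def count_assembly_copies(
    assembly,
    region: ConsensusRegion,
    min_len_frac: float = 0.9,
    min_identity: float = 0.9,
    k: int = 21,
) -> int:
    """Count full-length copies of a consensus region in an assembly.

    A locus counts when its best local alignment covers at least
    ``min_len_frac`` of the region at ``min_identity`` identity over the
    aligned columns, on either strand. Overlapping or nearby hits
    (< 100 bp apart) merge into one locus only while their union stays
    <= 1.5x the region length, so tandem arrays still count per copy.
    """
    contigs = _read_seqs(assembly)
    aligner = _local_aligner()
    L = len(region)
    hits = []  # (contig_idx, strand, interval)
    for ci, (_, contig) in enumerate(contigs):
        for strand, seq in (("+", contig), ("-", reverse_complement(contig))):
            for start in _candidate_hits(seq, region.sequence, k=k):
                ev = _evaluate_candidate(seq, start, region.sequence, aligner)
                if ev is None:
                    continue
                (a, b), len_frac, identity = ev
                if len_frac >= min_len_frac and identity >= min_identity:
                    if strand == "-":   # map back to forward coordinates
                        a, b = len(seq) - b, len(seq) - a
                    hits.append((ci, a, b))
    # merge per contig (strand-agnostic: a locus is a locus)
    count = 0
    for ci in {h[0] for h in hits}:
        intervals = sorted((a, b) for c, a, b in hits if c == ci)
        merged: list[list[int]] = []
        for a, b in intervals:
            if merged and a - merged[-1][1] < 100:
                union = (min(merged[-1][0], a), max(merged[-1][1], b))
                if union[1] - union[0] <= 1.5 * L:
                    merged[-1] = list(union)
                    continue
            merged.append([a, b])
        count += len(merged)
    return count


# ---------------------------------------------------------------------------
# Calibration and phenotype correlation
# ---------------------------------------------------------------------------

def calibrate(estimates, assembly_counts) -> tuple[float, float, float]:
    """Least-squares line and Pearson r of depth estimates vs true counts."""
    x = np.asarray(assembly_counts, float)
    y = np.asarray(estimates, float)
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("calibration needs >= 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError("zero variance: correlation undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def correlate_phenotype(
    copy_totals,
    phenotype,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rank correlation with a permutation null.

    Returns ``(rho, p)`` where p is the two-sided permutation p-value
    (fraction of shuffles with |rho| at least as extreme, +1 corrected).
    """
    x = np.asarray(copy_totals, float)
    y = np.asarray(phenotype, float)
    if x.size != y.size or x.size < 4:
        raise InvalidInputError("phenotype correlation needs >= 4 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError("constant vector: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    extreme = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ry)
        r = float(np.corrcoef(rx, perm)[0, 1])
        if abs(r) >= abs(rho) - 1e-12:
            extreme += 1
    p = (extreme + 1) / (n_permutations + 1)
    return rho, p


def estimates_to_frame(estimates: list[CopyNumberEstimate], strain: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain": strain,
            "family": e.family,
            "copies": e.copies,
            "te_depth": e.te_depth,
            "panel_depth": e.panel_depth,
        }
        for e in estimates
    )
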