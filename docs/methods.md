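# Methods

## The competition model

Two genotypes grow together through serial dilution cycles. Writing
`p_t` for the focal genotype's frequency at the `t`-th sequenced
timepoint and `Δg_t` for the generations since the previous one, the
model propagates

    p_t = p_{t-1} · w_eff^Δg_t        (variant "as_printed")

where `w_eff = w + Σ β_k · x_k` is the per-generation relative fitness
under the replicate's covariates: `mat` (0 = h+, 1 = h−), `cocl2`
(0/1 for 250 µM CoCl2), glucose coded as percent above 2 g/100 mL, and
`is_tf_null` for designs that compare a transposon-free strain against a
point-mutant control carrying the same background mutation.

The multiplicative recursion is a first-order description: it ignores
the renormalization against the competitor and can leave [0, 1] when
selection per interval is strong. The exact haploid-selection update

    p_t = p_{t-1}·w^Δg / (p_{t-1}·w^Δg + (1 − p_{t-1}))     ("normalized")

is provided as a variant and is used wherever tests stress extreme
parameters. The two differ by exactly
`p²·w^Δg·(w^Δg − 1) / (p·w^Δg + 1 − p)`, i.e. ≈ `p²·(w^Δg − 1)`; in the
near-neutral regime of these assays (|w − 1| ≈ 0.002, Δg ≈ 20 per
sampled interval, p ≈ 0.4–0.5) that is ~1e-2 at most per whole
trajectory step and ~1e-3 per generation-scale step, so the choice of
variant is well below the posterior width at the depths studied but not
numerically negligible; the default is the plain product with a hard
validity check that raises and names the normalized variant on overflow.

## Likelihood, priors, sampling

The observation model is `count_tf0 ~ Binomial(count_tf0 + count_wt, p_t)`
— the simplest model consistent with counting pooled amplicon reads. A
beta-binomial option (`likelihood: beta_binomial`) adds a free
overdispersion parameter `φ` with concentration `1/φ`, for data noisier
than binomial (PCR jackpots, uneven pooling).

Priors (all overridable via `PriorSpec`):

| parameter | prior | rationale |
|---|---|---|
| `w` | Normal(1, 0.05), truncated to (0, ∞) | weakly informative; competition fitness differences are a few per mille |
| each `β` | Normal(0, 0.01) | condition effects are an order smaller than `w − 1` |
| `p0` (per replicate) | Beta(2, 2) | cultures mixed near 1:1; mild pull to 0.5 |
| `φ` (if used) | Half-Normal(0.02) | shrinks toward binomial |

`p0` is estimated per replicate because the generation-0 sample is
sequenced like any other; a `fixed_p0` option exists for simulation
work. Sampling uses an affine-invariant ensemble MCMC (emcee) with
differential-evolution moves, which mix far better than stretch moves on
this narrow, correlated, ~15-dimensional posterior. Walkers start in a
tight ball around the posterior mode (Nelder-Mead then Powell refinement
of the log-posterior). Defaults: 64 walkers, 1,000 warmup steps, 2,000
kept steps (128,000 draws). Walkers are treated as chains for split
R-hat and effective sample size; the integrated autocorrelation time is
~50 steps, so R-hat ≈ 1 + 50/steps — runs shorter than ~5,000 steps
attach a (non-fatal) R-hat warning while medians and HPDIs are already
stable. A run fails hard only on non-finite densities or acceptance
collapse.

HPDI: the narrowest contiguous window over the sorted draws containing
`ceil(prob·n)` of them, leftmost on ties; default mass 0.89. The
neutrality rule declares a parameter consistent with its null (1 for
`w`, 0 for `β`) when the null lies inside the closed interval — boundary
inclusive, the conservative reading.

## What the simulator emulates

`simulate_experiment` draws data from exactly the model above plus two
realism terms the inference deliberately ignores:

- **Bottleneck drift** — at every dilution the frequency is resampled
  binomially with `bottleneck_cells` cells (default 5×10^6, ≈ 0.025 OD
  in 5 mL; `inf` disables drift). This lets tests measure when ignoring
  drift biases inference: at 10^5 reads per sample the cumulative drift
  noise (~1e-3 in final frequency) is comparable to counting noise, and
  the measured 89% HPDI coverage stays within its binomial band.
- **Overdispersed counting** — optional beta-binomial read sampling.

Passage schedules mirror the two experimental regimes: "exponential"
(twice-daily transfers, overnight 0.025→3.0 OD ≈ 6.91 doublings and
daytime 0.1→0.714 OD ≈ 2.84 doublings, 14 days, 136.4 generations,
8 sequenced timepoints) and "saturation" (48-hour transfers reaching
OD 10, ≈ 8.64 doublings per passage, 14 days, ~60 generations).
Generation bookkeeping treats OD as proportional to cell number;
real cultures deviate from this near saturation, which is one reason
passing tests on simulated data do not certify the saturation regime's
absolute generation counts. Amplicon depth per sample defaults to 10^5
reads (the real depths are not published; the value is configurable and
every statistical contract is depth-aware). The FASTQ emitter writes
`barcode + template` reads with the genotype's 5-mer at read positions
59–63 and constant quality `I` (Phred 40) — the counting chain never
reads quality.

What the simulator does **not** model: sequencing errors inside the
diagnostic window (real data would shift a small fraction of reads into
`count_other`, which the frequency excludes by construction), PCR
amplification bias between alleles, barcode cross-talk, mating or
sexual reproduction (the assays mix same-mating-type strains), and
frequency-dependent or epistatic fitness.

## Amplicon counting

The chain reproduces the classic fastx-tools pipeline semantics:
reads shorter than 100 nt are dropped; demultiplexing requires an exact
begin-of-line barcode match (no mismatches, no offsets; barcode sets
where one code prefixes another are rejected as ambiguous at load);
the 5-nt window at positions 59–63 (1-based, barcode included) is
extracted, with too-short reads counted in a drop statistic; windows are
classified by exact match against the two allele 5-mers, everything else
(including Ns) landing in `count_other`. The frequency is
`count_tf0 / (count_tf0 + count_wt)`. Collapsing identical sequences
before counting is an internal detail of the original tooling with no
effect on exact-match counts, so the implementation counts windows
directly. Every input read is conserved across
filtered/unmatched/discarded/assigned, and the pipeline is
order-independent.

The two allele 5-mers are configuration, not constants — the genomic
context of the diagnostic SNP is not part of the package — with fixture
defaults `WT = TTCGA`, `TF_NULL = TTAGA` differing at the window center.

## Copy-number estimation

A transparent depth-ratio method (deliberately simpler than published
TE-quantification pipelines, and validated against constructed fixtures
rather than any external tool): reads are assigned to the single target
(TE family consensus region, canonically the 945-bp divergent gag
interval, or a ≥5-gene single-copy panel) sharing the most 21-mer seeds
on either strand, verified by an edit-distance check (≤3 per 100 bases,
infix alignment); ties between targets are dropped rather than split, to
avoid double counting. Copy number = mean per-base depth over the family
region ÷ pooled mean depth over the panel. Reads overlapping target
boundaries fail verification, depressing edge coverage equally for TE
and panel targets, so the ratio stays unbiased; fixtures with 0–10
inserted copies at 30× coverage recover estimates within 10% (absolute
< 0.1 at zero copies).

Full-length copies on assemblies are counted by seeding candidate loci
from shared 21-mers (clustered by diagonal), then local alignment
(affine gaps: match 2, mismatch −3, open −5, extend −2) of the consensus
region against a padded window; a locus counts at ≥90% region coverage
and ≥90% identity (both configurable). Nearby hits (<100 bp apart) merge
only while their union stays ≤1.5× the region length, so tandem arrays
count per copy. Counting is invariant to contig order and
reverse-complementation.

Calibration is an ordinary least-squares line plus Pearson r of estimate
vs assembly count; phenotype association uses Spearman ρ with a seeded
permutation p-value (default 10,000 shuffles, two-sided,
add-one-corrected).

## Workflows and reproducibility

`run_workflow` executes `simulate_fit`, `count_fit`, or `copynum` from a
single YAML config with a versioned schema (unknown keys are errors).
One global seed expands into per-stage seeds by hashing the stage name,
so inserting a stage never shifts another stage's random stream. Every
run writes a manifest with the config snapshot, per-stage seeds and
status, and SHA-256 checksums of all inputs and outputs;
`validate_manifest` re-checksums them. Re-running a config with the same
seed reproduces byte-identical numeric outputs (the MCMC uses a seeded
`RandomState`, the simulator a seeded `Generator`).

## Problem sizes used in the shipped checks

The recovery check runs the full design (12 cultures × 8 timepoints,
depth 10^5) once; repeated-coverage checks use 50 reduced-scale repeats
(4 cultures, 5 timepoints spanning the same ~136 generations, depth
10^4, shortened chains), chosen so the whole suite stays interactive
while the coverage estimate's binomial error (~±0.03 at n = 150 pooled
parameter checks) remains small against its acceptance band. Copy-number
fixtures use a ~50-kb synthetic genome at 30× with 100-nt reads.

## Known limitations

- The recursion treats generations as a continuous exponent; OD-based
  generation counts inherit OD measurement error, which is not modelled.
- Ignoring bottleneck drift in the likelihood slightly narrows posteriors
  when drift noise rivals counting noise (very high depth or small
  bottlenecks); the simulator exposes both knobs so users can check their
  own regime.
- R-hat computed across ensemble walkers is an optimistic-variance
  diagnostic compared to independent chains; the ESS floor and the
  mode-centered initialization compensate in practice, and all headline
  checks are median/HPDI-based.
- The copy-number estimator assumes the consensus region is diagnostic
  (no cross-family mosaic reads beyond what seed-tie dropping removes)
  and roughly uniform coverage; GC-skewed libraries would need a
  panel matched in composition.
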