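# Methods

This note records the models implemented in `paleoprof`, the parameters
that matter, what the synthetic data does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Damage model

A double-stranded fragment is assumed to carry independent single-stranded
overhangs at both ends with length distributed Geometric(λ) on {0, 1, 2, …},
so position *i* (1-based from a terminus) is single-stranded with
probability (1−λ)^i. A cytosine deaminates — read as C→T — with probability
δ_d when single-stranded and δ_s when double-stranded; deamination on the
complementary strand appears as G→A measured from the read's 3′ end
(double-stranded library convention, reads written 5′→3′). The marginal
terminal rate is

    r_i = δ_s + (δ_d − δ_s)(1 − λ)^i.

Only C→T and G→A substitutions are ever introduced; indel damage is out of
scope (depurination-driven fragmentation enters only through the length
model). Defaults (λ=0.3, δ_d=0.4, δ_s=0.01) are typical of well-preserved
archaeological material: a ~28% terminal C→T rate decaying to ~1% in the
interior.

**Profile estimation** counts, per terminal position over the first k=15
bases (interior positions carry no signal and serve as the baseline for
presence calls), reference-C opportunities and C→T hits from the 5′ end and
reference-G/G→A from the 3′ end. Reads shorter than 2k contribute each
position to one terminus only (5′ half to the 5′ profile, ceil(L/2)
boundary). Zero-opportunity positions are NaN, never 0.

**Parameter fitting** minimizes squared deviation of r_i from the observed
5′ C→T rates (optionally pooled with 3′ G→A), with parameters box-bounded
to [0,1]. The model is linear in (δ_s, δ_d−δ_s) at fixed λ, so the fit is
initialized by a 25-point grid over λ with a linear solve at each node,
then refined with bounded least squares at tight (1e-15) tolerances — the
noiseless inverse reproduces generating parameters to ~1e-6. A flat-zero
profile returns δ_d=δ_s=0 with λ flagged unidentifiable. No claim is made
of numerical agreement with external damage-fitting tools; only the
parameterization is shared.

**Presence calls** require the terminal rate to reach `min_terminal_rate`
(default 0.05, chosen to separate damaged ancient samples from undamaged
modern contamination; configurable) *and* its one-sided 95% Clopper–Pearson
lower bound to exceed the mean rate at interior positions 11..k. Fewer than
100 opportunities at position 1 gives an `indeterminate` verdict, distinct
from `negative`.

**Paired comparisons** use the Wilcoxon signed-rank test with zero
differences dropped and mid-ranks on ties. The exact null distribution is
computed by shift convolution over doubled ranks for n ≤ 25 pairs; above
that, a tie-corrected normal approximation with a 0.5 continuity
correction. Note the exact two-sided p is a lattice whose spacing reaches
~0.03 at n=12, so the approximation tracks it to ~0.007 on average but can
deviate by up to ~0.014 on individual samples — an intrinsic property of
any continuous approximation, not an implementation artifact.

## Fragment-length analyses

Medians use the mean-of-middle-two convention (displacements are therefore
resolved to 0.5 bp). The host-vs-bulk comparison is offered against the
whole sample (default in the pipeline report) and against the non-host
complement; Cohen's d uses the pooled-SD (n_a+n_b−2) denominator. The
400-read per-(sample, taxon) normalization samples without replacement;
groups under the target are excluded and tallied rather than resampled with
replacement, keeping variance honest. Group comparisons pool lengths by a
metadata key (Gram status, S-layer, GC class) and test with Mann-Whitney U
(two groups; exact when tie-free and n_x·n_y ≤ 400, else tie-corrected
normal approximation) or Kruskal-Wallis (more).

## GC-vs-length shift detection

Reads at or above the 30 bp QC floor are binned by length (1 bp bins; bins
under 50 reads are ineligible). The baseline is the longest 25% of eligible
bins — long fragments survive regardless of GC, so their bin means estimate
the unbiased level and its between-bin scatter. Each eligible bin's mean GC
is standardized against that baseline (z, ddof=1); the onset is the largest
length L such that *every* eligible bin at length ≤ L is shifted by
z ≥ 1, provided the run spans at least 3 consecutive bins (persistence
guards the otherwise ill-posed "begins to shift" against single-bin noise).
A perfectly flat curve yields z=0 everywhere; a zero baseline SD with
non-flat bins raises an error advising a larger baseline. The reference
population for the z-score is the largest open interpretive choice in this
analysis; baseline quantile, threshold, persistence and bin width are all
configurable. Under the null (no survival bias) the false-onset rate at
defaults is ~2% per sample (measured over 100 simulations).

## Survival models

The melting-temperature proxy is Marmur–Doty-style:
Tm = 64.9 + 41·(gc_count − 16.4)/length (°C), monotone in GC at fixed
length and in length at fixed GC fraction. Four modes:

- `none` — every fragment survives;
- `hard_threshold` — pure length cutoff (survive iff length ≥ midpoint bp);
- `logistic_tm` — logistic(steepness·(Tm − midpoint °C));
- `length_gated_tm` — fragments ≥ the cutoff length always survive; shorter
  fragments survive with the logistic-Tm probability against the melting
  point of a cutoff-length fragment at a calibration GC.

The gated mode exists because the two simpler GC-aware candidates fail to
produce a *sharp* GC-shift onset: a pure length cutoff removes all short
fragments (no GC signal at all), while a fixed-Tm logistic threshold also
thins the low-GC tail well above the nominal cutoff, smearing the detected
onset ~15 bp upward. Gating confines GC selection to sub-cutoff lengths, so
the detected onset lands within 1–2 bp of the cutoff.

## Authentication

The mismatch allowance is max(1, floor(L/50)): "one mismatch per 50 bases"
is ambiguous below 100 bp, and the floor of one lets a 75 bp read carry a
single mismatch. Deamination-consistent mismatches (reference C read T in
the 5′ half, reference G read A in the 3′ half) are excluded from the
budget by default, since counting damage against the allowance would bias
the filter against exactly the authentic ancient reads it is meant to keep;
the discount is half-read-scoped rather than terminal-window-scoped so
interior double-stranded deamination is also forgiven. The damage criterion
is evaluated once on the pooled profile of reads surviving criteria 1–2 — a
sample-level verdict, because per-read damage evidence is a single base at
best. Note the strict filter's pass fraction at a fixed per-base error rate
is *not* globally monotone in read length: the allowance is a step function,
so between steps (e.g. 50→99 bp at one allowed mismatch) longer reads
accumulate more errors against the same budget. Monotonicity holds across
allowance boundaries (50/100/200/300 bp), which is how the sequencing-
strategy effect (short-read data losing disproportionately more reads)
manifests.

## Synthetic data: what it does and does not emulate

The generator emulates: multi-taxon composition with host, oral and
environmental genomes (i.i.d. random sequences at specified GC); lognormal
fragment lengths (median 70 bp default, log-SD 0.35, clipped to
[20, 250] bp — the length-distribution family is a stand-in, as real
taphonomic length distributions are not settled); strand-symmetric fragment
drawing with reverse-complement before damage; geometric-overhang
deamination; melting-temperature survival thinning; an undamaged
modern-contaminant fraction; and optional uniform sequencing error (off by
default — analyses treat merged reads as damage+biology only). Qualities
are constant Phred 40 unless an error model is enabled.

It does not emulate: real genome composition (repeats, skew, local GC
structure), paired-end reads and adapter artifacts, PCR duplicates, indel
damage, taxonomic misassignment, or reference bias. A green test therefore
establishes estimator correctness under the stated model, not robustness to
those real-data effects.

The demonstration world: three individuals × (calculus-like, dentin-like)
plus a contaminant-only blank; calculus-like samples are 90% oral taxa /
5% host / 5% environmental, dentin-like 85% environmental / 10% host / 5%
oral, with the environmental fraction spread over four taxa because
postmortem contamination is taxonomically diffuse — this is what makes
dentin-like alpha diversity higher, as observed in real material. Host
fragments are drawn with the median displaced −15 bp relative to microbial
fragments (both materials; real dentin shows no consistent displacement, a
simplification here). Damage parameters: calculus (λ=0.30, δ_d=0.40),
dentin (λ=0.25, δ_d=0.48), δ_s=0.01 — dentin's terminal rate higher, as
reported for real pairs. Default scale: 20 000 reads per sample, 60 kb
genomes, runtime well under a minute per stage on one CPU.

## Reproducibility

Every stochastic stage derives its seed from the global seed by stable
(BLAKE2) hashing of the stage name, so stages rerun independently yet
reproducibly and outputs are byte-identical for a given config+seed. All
output tables carry a `# seed=… config=…` provenance line with a hash of
the full configuration. Coordinates are 0-based half-open everywhere
internally; SAM positions are converted on I/O.
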