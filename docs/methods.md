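# Methods

`polarhythm` analyses short expression time series of the kind collected in
high-latitude field campaigns: a 24 h cycle sampled every 4 h (seven
timepoints, the first and last clock hour coinciding one day apart), with a
few independent replicate pools of animals per timepoint, at one or more
stations. It asks which transcripts oscillate with a daily (20 or 24 h) or
ultradian (12 or 16 h) period, when they peak relative to the solar and
tidal cycles, and how the rhythm architecture differs between stations.

## The detection statistic

For a candidate period *P*, sampling times are folded onto the cycle
(*t* mod *P*, 1-minute rounding), giving *m* ordered cycle positions. On the
default design the folds are *m* = 6 groups of sizes (6,3,3,3,3,3) at 24 h,
(6,6,3,3,3) at 20 h, (6,6,6,3) at 16 h and (9,6,6) at 12 h — the 0 h and
24 h samples merge at the 24 h fold.

A rhythmic transcript should rise to a peak and fall again somewhere along
the cycle, so the alternative is an *umbrella ordering*. Each choice of peak
position and rise length *r* ∈ {1, …, m−1} defines one cyclic ordering —
*m*(*m*−1) patterns in total. A pattern is scored with a
Jonckheere–Terpstra-type statistic

    U = Σ over ordered group pairs (i below j) of
        #{x ∈ g_i, y ∈ g_j : x < y} + ½·#{ties},

the pairs being all pairs within the rising limb (ascending) and all pairs
within the falling limb (descending), the peak group belonging to both.
This is the same family of peak-shaped rank alternatives used by
nonparametric circadian detectors such as RAIN; the way patterns are
combined (below) is this package's own, deliberately simple choice. Ranks
only: any strictly increasing transform of a row leaves all p-values
unchanged, so the test is insensitive to the expression scale and to
monotone normalizations.

### The null distribution

The per-pattern p-value is the exact right tail P[U* ≥ U] under random
assignment of the pooled values to groups of the observed sizes:

* pooled N ≤ 12 — full enumeration of all multinomial(N; sizes) group
  assignments, valid for any tie structure;
* N > 12, no tied values — the exact null distribution of U over random
  group-label sequences, built by dynamic programming over rank placements:
  items are placed in increasing order and placing an item into group *h*
  adds one concordant pair per already-placed item in any group "below" *h*
  in the pattern. This is an iterated convolution; it is data-independent,
  cached per (fold, pattern), and agrees with enumeration to 1e−12 where
  both apply (tested). Exact tails matter: on 21 samples a perfectly ordered
  row reaches p ≈ 10⁻⁹–10⁻¹³, whereas a normal approximation saturates near
  10⁻⁶ and would cap the adjusted significance attainable by strong rhythms;
* N > 12 with ties — a tie-corrected normal approximation with continuity
  correction. Its mean and variance are computed exactly for arbitrary tie
  structures by index-overlap algebra (the expectation of products of
  pattern indicators over pairs of item pairs, crossed with the matching
  sums of tie-aware comparison scores); both moments are verified against
  enumerated distributions in the tests. Constant rows degenerate to p = 1.

### Combination, multiplicity, assignment

Per period, the *m*(*m*−1) pattern p-values are combined by Bonferroni:
`raw_p = min(1, m(m−1) · min_p)`, ties between patterns broken toward the
lowest peak index then the shortest rise. Bonferroni over so correlated a
family is conservative — measured type-I rates at the 0.05 level are
0.02–0.03 on iid data — and this costs real power relative to
dependence-aware corrections; it is kept for its simplicity and exactness
as an upper bound.

Benjamini–Hochberg is applied jointly over the full transcript × period
p-value vector (no period is favoured), each transcript is assigned the
period with the smallest adjusted p (ties toward the longer period), and
the assigned period classifies it as daily (20/24 h) or ultradian (12/16 h).

### Known power limitations

Two structural ceilings are worth knowing before interpreting counts:

* A 12 h rhythm folds to only three cycle positions whose two flanks have
  equal means (cos ±120° coincide). The best attainable p is therefore
  bounded by the probability that the peak group holds the top ranks —
  6/C(21,9) ≈ 2·10⁻⁵ when the peak falls on the double-size position and
  6/C(21,6) ≈ 1.1·10⁻⁴ otherwise — *independent of amplitude*. At a joint
  BH cutoff of 0.001 this means many genuinely rhythmic 12 h transcripts
  cannot reach significance unless the discovery list is very large.
  Detectors that test the unfolded periodic pattern across all seven
  timepoint groups do not share this ceiling; the folded test trades that
  power for a simpler, exactly solvable null.
* With amplitude 2 and 10 % lognormal noise, about 80–90 % of planted 24 h
  rhythms are recovered at adjusted p < 0.001 in a 1 000-transcript
  universe; the loss is the Bonferroni factor compounding with BH.

## Phase, amplitude, coincidence

The per-transcript profile is the median of replicate values at each cycle
position of the assigned period. Phase is the position of the profile
maximum (ties toward the earliest position), reported both in cycle hours
and as the local clock hour of the matching sampled timepoint; with 3–7
points per cycle an ordinal argmax is more honest than a cosinor fit for
non-sinusoidal waveforms. A constant profile has no phase ("phase
undefined").

Amplitude is A = (max − min)/min of the profile after an optional
pseudocount — A = 0.5 means the peak exceeds the trough by half the trough
level — binned into 0–0.5, 0.5–1.5, 1.5–5 and >5. The default pseudocount
is 0 and a profile whose minimum is not positive is a hard error, forcing
an explicit choice for zero-containing rows. Both statistics are invariant
under per-transcript median normalization (the heatmap normalization);
amplitude is a ratio and phase depends only on ranks.

A transcript's coincidence label is the kind of the nearest environmental
event (solar min/max, high/low tide) within ±2 h of its peak clock hour —
half the sampling interval, configurable — with ties resolved toward tide
events for ultradian and solar events for daily transcripts; `none`
otherwise. Distances are taken on the 24 h clock, adequate for the
single-cycle window the design covers.

## Environmental cycles

Solar elevation uses the standard low-precision solar-position formulas
(Fourier-series declination and equation of time, then the hour-angle
altitude formula), accurate to a few tenths of a degree for 2000–2030 —
sufficient for diel shape and above/below-horizon status; refraction is not
modelled. Midnight sun is declared when a ≤10-minute scan of the civil day
never drops to the horizon. Lower-culmination altitude follows the
closed-form φ + δ − 90°, which the implementation reproduces to ±0.5°.

The tide is a pure harmonic superposition h(t) = z₀ + Σ Aᵢ·cos(2πt/Tᵢ − φᵢ)
over user-supplied constituents; the default single M2 constituent
(T = 12.4206 h) reproduces a semidiurnal cycle with high tides ~12.4 h
apart. No gauge data are modelled — constituent amplitudes and phases are
user parameters, not reproduced values. Extrema of any sampled series are
sign changes of the first difference; plateaus report their midpoint;
series endpoints are never events.

## Synthetic data

The generator plants cosine waveforms
x(t) = b·(1 + (A/2)·(1 + cos 2π(t−φ)/P)) — chosen so the noiseless
(max−min)/min equals exactly the amplitude statistic A — under
multiplicative lognormal noise (`x·exp(N(0, σ))`), with a negative-binomial
count mode for count realism. Defaults: baseline 10, amplitude 2
(a mid-range "high amplitude" in the field's binning), σ = 0.1 (a 10 %
coefficient of variation, plausible for pooled-animal RNA-seq replicates),
phases uniform over the sampled cycle positions, or von-Mises-clustered
around a configured clock hour to emulate phase clustering at environmental
events. A single master seed drives counter-derived per-transcript
substreams, so any subset regenerates reproducibly.

The two-station scenario plants the cross-station taxonomy directly:
transcripts rhythmic exclusively at station A or B, at both with the same
period range, at both with a range switch (both directions), plus
arrhythmic background — station A daily-dominated, station B
ultradian-enriched, at a desk scale of 2 000 transcripts (the field-scale
universe of tens of thousands is a config change).

What the generator does *not* emulate: read-level sampling, library-size
composition effects, transcript-length biases, correlated noise between
transcripts, non-sinusoidal waveforms. Passing tests therefore demonstrate
the statistical machinery on idealized rhythms, not performance on any real
library.

## Comparison and enrichment

Stations are detected and BH-adjusted independently (a transcript's status
at a cutoff is daily/ultradian/none), then statuses cross into seven
categories partitioning the universe; "same" means same period *range*, so
a 24 h ↔ 20 h pair is `both_same_daily`. Per-cutoff summary tables count
each transcript once at its assigned period; counts at 0.001 ⊆ 0.01 ⊆ 0.05
and daily + ultradian = all, structurally.

Enrichment is a one-sided hypergeometric tail per flat term (no
ontology-graph propagation; curated gene→term pairs are supplied by the
user), BH across terms, universe = the transcripts actually tested. Terms
with fewer than 5 in-universe genes are dropped by default.

## Problem sizes and numerical choices

Test-suite simulations use 10²–10³ transcripts, chosen as the smallest
universes at which joint-BH behaviour and category recovery are
informative. The exact-null DP costs a few seconds once per design and is
cached thereafter. Enumeration is the exact path up to N = 12 pooled
samples (~35 000 assignments at worst). p-values are clipped to (0, 1];
floats are written with 12 significant digits so files round-trip
losslessly. All randomness flows from explicit integer seeds; fixed seeds
and fixed inputs give byte-identical outputs.
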