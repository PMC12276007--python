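# Methods

This note documents the models implemented by `pugfold`, the assumptions
behind them, the choices made where the design was genuinely open, and what
the synthetic-data generators do and do not emulate.

## Repeat chains and coordinates

A pUG chain is a run of alternating G/U nucleotides; runs may begin with
either base (G-start or U-start phase) and are counted in repeat units of
2 nt at 0.5 granularity, so a 25-nt U-start run is 12.5 repeats. Nucleotide
coordinates are 1-based inclusive. Fold placement works at repeat level: a
fold occupies 12 consecutive full repeats (12 guanosines, 24 nt). Phase is
reported but placements are not enumerated separately per phase — every
count in the placement model is repeat-denominated, which is the resolution
at which the experimental read-outs (CD fractions, gel fragment lengths)
distinguish configurations.

`find_pug_runs` returns maximal alternating runs; maximality means a run
cannot be extended in either direction, and every GU/UG dinucleotide in a
sequence belongs to exactly one run (property-tested). `parse_pug` accepts
only a single uninterrupted run; T→U conversion and lowercase input are
handled silently for FASTA-dialect tolerance.

## Placement combinatorics

On an integer chain of n repeats the legal starts are 1..n−11. A
configuration is any non-empty set of non-overlapping placements; it is
*maximal* when every free gap (5′ flank, inter-fold gaps, 3′ flank) is
shorter than 12 repeats. Enumeration is a depth-first recursion in
lexicographic start order, so output order is deterministic. Adjacency
means exactly zero intervening repeats.

The "all possible folds" measure is the **uniform distribution over maximal
configurations**. For n = 29 this gives 27 configurations — 6 maximal
singles (starts 7–12; any other single leaves room for a second fold) plus
21 doubles, of which the 6 with consecutive placements are adjacent — hence
6/27 ≈ 22% adjacent doubles. The enumeration is verified against an
independent brute-force subset oracle for every n ≤ 40. A half-repeat tail
is floored: it cannot host any part of a fold.

The **sequential kinetic simulator** is a different measure and is kept
separate by design: folds nucleate one at a time, each start drawn
uniformly from the currently legal set, until no start remains (so every
outcome is maximal). Its exact outcome distribution is computed by
exhaustive recursion over choice orders with rational arithmetic; for
n = 29 the mean fold count is 30/18 ≈ 1.67 and the adjacent-double
probability is (2/18)·(1 + 1/2 + … + 1/6) ≈ 27.2%. The Monte-Carlo
simulator is tested against this closed form. The 22% combinatorial figure
never uses the sequential model.

`predict_t1_fragments` encodes complete RNase T1 digestion: the enzyme
cleaves 3′ of single-stranded guanosines, so maximal blocks of adjacent
folds survive as one protected core. Terminal chemistry follows the
digestion geometry — a block starting at repeat 1 keeps the transcript 5′
chemistry (triphosphate for a transcript, hydroxyl for a dephosphorylated
RNA), internal blocks start with the 5′-OH left by T1; a block reaching the
chain 3′ end keeps 3′-OH, all others end in 2′,3′-cyclic phosphate. Only
the protected core is modeled; partial digestion and residual overhangs are
not.

## CD quantification

Molar CD absorption is Δε = θ/(32980·C·L·N) with θ in millidegrees, C in M,
L in cm, N the nucleotide count. Fraction folded is the signed ratio of
sample to (GU)₁₂ reference Δε at 245, 281 and 304 nm, times 0.95 — the
folded fraction of (GU)₁₂ itself (its 3′-terminal U is unstructured). Peaks
are read at the nearest grid wavelength for grids up to 2 nm; coarser grids
fall back to linear interpolation (measured scans use 1 nm steps). The
kinetics monitoring set {243, 264, 284, 304} nm is exported separately;
both sets are configurable.

Fold-count arithmetic uses 24 nt per fold with no 0.95 inside the formula:
the 0.95 enters only through the measurement normalization. This
reproduces both anchors — a self-referenced (GU)₁₂ reads 95% folded, and
two folds on 58 nt read 48/58 ≈ 83% — without double-counting the terminal
U. For (GU)₁₈ the one-fold model value is 24/36 ≈ 67%; the package reports
measured and model values side by side and asserts no equality between
them, since terminal-U handling on intermediate lengths is ambiguous at
this resolution.

## Kinetic fits

All fitters use `scipy.optimize.least_squares` with analytic Jacobians,
ftol = xtol = gtol = 1e-12 and at most 10⁴ evaluations; R² is reported for
every fit. On noiseless synthetic data every fitter recovers its
generating parameters to < 1e-6 relative error (tested over parameter
sweeps).

* **Single-exponential folding** S(t) = S∞ + (S₀−S∞)e^(−kt). Initial k
  from a log-linear regression; a trace whose excursion is within 5× the
  point noise (median absolute successive difference estimator) returns an
  explicit no-transition result rather than a rate.
* **Mono HDX** I(t) = [I(0)−I(∞)]e^(−k_ex·t) + I(∞), with I(∞) constrained
  to 0 by default (no imino signal remains after months in D₂O; the
  constraint is releasable). A fitted rate with k·t_max < 1e-3 is flagged
  as a boundary (no appreciable decay over the sampled window).
* **Biexponential HDX** I(t) = I₀[f·e^(−k_fast·t) + (1−f)·e^(−k_slow·t)]
  with bounds 0 ≤ f ≤ 1 and positive rates; k_fast > k_slow enforced by
  relabeling after the fit. Initialization: slow rate from a log-linear
  fit of the late third, fast rate from the early third after stripping
  the extrapolated slow component, f at 0.5 — robust across the ~100×
  rate separations of interest. If the fitted rates collapse
  (k_fast/k_slow < 3) or f leaves (0.02, 0.98), the series is effectively
  monophasic: the mono fit is returned with a degenerate flag. I₀ is left
  free and reported as fitted (measured normalizations can exceed 1 when a
  fast phase is incompletely captured by the first point).
* **Split-fit consistency** fits sub-integrations (e.g. the imino region
  split in half) and the global series and reports the maximum relative
  discrepancy in k_ex, flagging above a configurable threshold (default
  20%).
* **Boltzmann melt** y(T) = A₂ + (A₁−A₂)/(1+e^((T−Tm)/dT)); either
  monotone direction is accepted, baselines and width are free (they are
  not published quantities), and a flat curve raises an explicit
  no-transition error. Tm far outside the measured ramp is rejected.

Time units follow the measurements — folding in minutes, HDX in hours,
melts in °C — with explicit conversion helpers (t½ = ln2/k exactly).

## Segmental register exchange

The fold's four 3-repeat segments open by two routes: global unfolding at
k_unfold (all segments exchange) and, for the two terminal segments only,
register exchange with flanking single-stranded repeats at k_flip per
segment. Assumptions:

* **EX1 limit** — every opening event exchanges the segment's imino
  protons, so the observed fast rate is k_flip + k_unfold. No intrinsic
  chemical exchange rate is modeled.
* **Irreversible labeling** — in excess D₂O deuteration is one-way;
  re-protection does not restore signal.
* **Terminal segments only** — the fast amplitude is
  exchangeable/4 = 1/2 whenever at least one flanking repeat exists on
  either side (through the stochastic fold-position ensemble both
  terminal segments participate), and 0 for the minimal 12-repeat fold.
  This makes the fast amplitude independent of chain length, matching the
  flat ~50% ratios observed from 13 to 18 repeats.

The ensemble survival is S(t) = a·e^(−(k_flip+k_unfold)t) +
(1−a)·e^(−k_unfold·t). The stochastic simulator samples exponential
waiting times per segment and molecule and agrees with the closed form
within 3 Monte-Carlo standard errors at 10⁴ molecules (tested). A 50%
signal change in all molecules and a 100% change in half of the molecules
produce identical ensemble curves; the simulator implements the former and
the distinction is unobservable in this model.

## Synthetic data

Generators draw all randomness from one seeded NumPy Generator per call;
identical arguments give byte-identical output.

* **CD spectra**: four Gaussian bands at 245(−), 260(+), 281(+), 304(−) nm
  with σ = 6 nm on a 210–340 nm, 1-nm grid. Band amplitudes are package
  constants with the correct sign pattern; absolute scale is arbitrary
  because every analysis is a ratio against the (GU)₁₂ basis. A sample at
  folded fraction φ is the basis scaled by φ/0.95, converted to raw θ with
  the supplied C, L, N (defaults 20 µM, 1 mm, chain length).
* **Folding traces**: 180 points over 330 min by default.
* **HDX series**: first point at 0.3 h (first spectrum within ~20 min of
  D₂O addition), quarter-hour sampling to 72 h, then daily to 3 weeks.
* **Melts**: 20 → 81.5 °C in 1.5 °C steps (42 points); a Tm outside the
  ramp warns.
* **Noise** is additive i.i.d. Gaussian, default σ = 2% of the dynamic
  range — chosen as a realistic instrument noise floor that keeps
  recovered parameters within their reported uncertainties.
* **Digest tables** aggregate predicted T1 fragments over an ensemble;
  stain-weighted intensity is count × fragment length in nt, emulating an
  intercalating stain. The double-fragment intensity share of a sequential
  (GU)₂₉ ensemble is tested against the closed-form value from the exact
  placement recursion.

What the generators do **not** emulate: spectral band-shape changes with
ionic conditions, baseline drift, correlated noise, incomplete or
over-digestion, gel mobility, and NMR line shapes. Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
noise model, not robustness to instrument systematics.

## Problem sizes

Test and acceptance runs use sizes chosen for tight statistical tolerances
at interactive runtimes: brute-force oracle checks to 40 repeats,
sequential ensembles of 2–4 × 10⁴ molecules, stochastic HDX ensembles of
10⁴ molecules, and 50–60 seeded replicates for recovery statistics. All
scale linearly if larger runs are wanted.

## Known limitations

* Placement enumeration is exponential in chain length; it is intended for
  oligonucleotide-scale chains (≲ 60 repeats), not genomic surveys (the
  scanner itself is linear and handles arbitrary FASTA input).
* Expanded-loop placements (AA-insertion constructs) are characterized
  only through their melting behavior; they are not enumerated as fold
  positions.
* EX1 is assumed, not fit; if intrinsic exchange were rate-limiting (EX2),
  the fast-phase rate would no longer equal the opening rate.
* µs–ms dynamics (NMR line broadening) and intermolecular quadruplexes are
  outside the model.
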