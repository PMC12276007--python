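# pugfold

Quantitative analysis of long poly(UG) RNA folding.

Poly(UG) ("pUG") dinucleotide repeats are among the most common simple
sequence repeats in eukaryotic transcriptomes. Chains of 12 or more GU
repeats can adopt the **pUG fold**, a left-handed RNA G-quadruplex that
incorporates 12 repeats (24 nt) in four 3-repeat segments around three
G-quartets and one U-quartet. Longer chains can hold several folds at once,
and the question of where folds sit, how fast they form, and how they
breathe is quantitative: `pugfold` implements the models needed to answer
it from circular-dichroism (CD), nuclease-protection and
hydrogen/deuterium-exchange (HDX) NMR measurements.

## What the package computes

**Fold-placement combinatorics** (`pugfold.placement`). On a chain of *n*
repeats a fold may start at repeat positions 1..*n*−11. The package
enumerates every set of non-overlapping placements, restricts to *maximal*
configurations (no further fold fits), and classifies adjacent double folds
(zero intervening repeats). For a 29-repeat chain this gives 27 maximal
configurations, 6 of which contain adjacent doubles — 22%. A separate
sequential kinetic simulator places folds one at a time at uniformly random
legal positions (the two measures are deliberately distinct). RNase
T1-resistant fragments are predicted from any configuration, with 5′
(PPP/HO) and 3′ (OH / 2′,3′-cyclic phosphate) termini tracked.

**CD quantification** (`pugfold.cd`). Raw ellipticity θ (mdeg) is converted
to molar CD absorption

    Δε = θ / (32980 · C · L · N)

(C molar strand concentration, L path length in cm, N nucleotides). The
fraction of a chain engaged in pUG folds is the signed peak ratio against
the minimal (GU)₁₂ fold at 245, 281 and 304 nm, scaled by 0.95 — the folded
fraction of (GU)₁₂ itself, whose 3′-terminal U is unstructured:

    fraction folded = (Δε_RNA / Δε_(GU)12) × 0.95

Fold-count arithmetic converts fractions to fold numbers: each fold engages
24 nt, so 73% folded on a 58-nt chain means ~1.76 folds on average.

**Kinetics and thermodynamics** (`pugfold.kinetics`). Nonlinear
least-squares fits (analytic Jacobians) of single-exponential folding
traces, mono- and biexponential HDX decays I(t) = I₀[f·e^(−k_fast·t) +
(1−f)·e^(−k_slow·t)] with the floor constrained to zero, and Boltzmann
sigmoid melts y(T) = A₂ + (A₁−A₂)/(1+e^((T−Tm)/dT)). Rate/half-life
conversions (t½ = ln2/k) across s/min/h/day are explicit.

**Segmental register exchange** (`pugfold.register_exchange`). A
four-segment fold model in which the two terminal segments can swap
register with flanking single-stranded repeats at rate k_flip while the
whole fold unfolds globally at rate k_unfold. In the EX1 limit the imino
survival is

    S(t) = a·e^(−(k_flip+k_unfold)·t) + (1−a)·e^(−k_unfold·t),  a = 2/4

whenever at least one flanking repeat exists — predicting the ~50%
fast-phase amplitude independent of chain length. Both the closed form and
a per-molecule stochastic simulation are provided and agree within
Monte-Carlo error.

**Synthetic data** (`pugfold.synth`). Seeded, bit-reproducible generators
for CD spectra (four Gaussian bands: −245, +260, +281, −304 nm), folding
traces, HDX series on the experimental sampling schedule, melt curves on
the 20→81.5 °C ramp, and RNase digest tables, so every analysis stage is
testable without instrument data.

## Worked example

```python
>>> import pugfold as pf
>>> stats = pf.adjacency_stats(pf.enumerate_configurations(29, maximal_only=True))
>>> stats.n_configs, stats.n_adjacent_double, round(100 * stats.fraction_adjacent, 1)
(27, 6, 22.2)

>>> from pugfold import synth
>>> spec = synth.generate_cd_spectrum(n_nt=58, n_folds=2, noise_sd=0.0)
>>> frac = pf.fraction_folded(pf.molar_cd(spec), synth.gu12_reference())
>>> round(frac.mean_fraction, 3)
0.828
>>> round(pf.mean_folds_from_fraction(0.73, n_nt=58), 2)
1.76

>>> series = synth.generate_hdx_series("biexp", i0=1.14, k_fast=1.34,
...     k_slow=0.008, fast_fraction=0.502, noise_sd=0.02, seed=1)
>>> fit = pf.fit_hdx_biexponential(series)
>>> round(fit.fast_ratio_percent, 1), round(fit.t_half_slow, 1)
(50.8, 85.2)
```

The first block says a 29-repeat chain has 27 ways to be maximally folded,
6 of them compact adjacent doubles (22.2% — the stochastic-placement
prediction for the double-fold fragments seen in RNase T1 digests). The
second shows a two-fold 58-nt chain reads out as 83% folded and a measured
73% implies ~1.76 folds. The third recovers the generating biexponential
HDX parameters from noisy data: a ~50% fast phase and a multi-day slow
half-life.

The same operations are available from the shell:

```
pugfold enumerate --repeats 29
pugfold synth hdx --model biexp --i0 1.14 --k-fast 1.34 --k-slow 0.008 \
    --fast-fraction 0.502 --noise-sd 0.02 --seed 1 --out hdx.csv
pugfold fit-hdx hdx.csv --model biexp
```

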