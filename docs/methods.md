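# Methods

This note documents the models behind each analysis stage, the parameters
that matter, the design choices that were genuinely open, and what the
synthetic-data generators do and do not emulate.

## Isotope pool dilution

The pool-dilution estimator assumes gross production `p` and consumption
`c` of the NO₂⁻+NO₃⁻ pool are constant over the sampling interval, that
produced nitrogen enters at natural ¹⁵N abundance, and that consumption does
not fractionate isotopes. Under those assumptions the pool `C` and its
atom%-excess `APE` follow `dC/dt = p − c` and `dAPE/dt = −p·APE/C`; note the
dilution rate is the *production* term — consumption removes ¹⁵N and ¹⁴N in
proportion and cannot change the enrichment, which is also why the
consumption-only forward simulation holds APE constant.

Numerical choices:

- Time is carried internally in days (all reported rates are per day);
  hours are accepted at I/O boundaries and converted.
- The formula has a removable singularity at `Cₜ = C₀`; we switch to the
  limiting form `p = C₀/Δt · ln(APE₀/APEₜ)` when
  `|Cₜ − C₀| < 1e−9·max(C₀, Cₜ)`.
- Small negative estimates (within 5% of the estimate scale) are clamped to
  zero and flagged `clamped_negative`; larger negatives keep their value and
  flag `model_violation`, so measurement noise and assumption failure remain
  distinguishable. Enrichment that *rises* over the interval contradicts
  the model outright; the estimator returns NaN with `enrichment_increased`
  rather than a number.
- The ¹⁵N label added at t = 0 is counted as part of the pool (`c0`
  includes the label mass), the usual pool-dilution convention.
- The planned label addition ("1–10% of the nitrate pool") is interpreted
  as a fraction of the post-addition pool; `fraction_basis="pre"` switches
  to the unamended-pool reading.
- Net-flux windows (default 6–18 h) may be satisfied by linear
  interpolation from samples within ±1 h of each endpoint; beyond that the
  computation refuses (`window_uncovered`) rather than extrapolate.

## Carbon fixation and N:C coupling

Tissue enrichment is converted via `at% = 100·R/(1+R)`,
`R = R_VPDB·(1 + δ/1000)` with the Craig VPDB ratio 0.0112372 (configurable;
natural ¹⁵N abundance is likewise fixed at 0.3663 atom%). The fixation rate
treats the DIC atom% excess as constant at its post-mixing value. In an
intermittently opened container some added ¹³C-bicarbonate is lost, which
biases the inferred rate downward and hence the N:C slope upward; the
`label_retention ∈ (0, 1]` scalar lets users down-weight the DIC excess to
explore that bias, but no automatic correction is attempted. Background DIC
is taken as 1975 μM at δ¹³C = 0‰ (surface-seawater DIC is near 0‰) unless
supplied.

The N:C coupling is deliberately fit with nitrification as the response and
fixation as the predictor, so the slope *is* the N:C ratio; the reciprocal
slope is exposed for the C:N reading. Whether tissue carbon is on a dry- or
wet-weight basis is recorded by the caller, not converted — the conversion
factor is sample-specific and must be supplied explicitly.

## Ammonia speciation

The NH₃ fraction uses Henderson–Hasselbalch with a stoichiometric seawater
ammonium pKa* linear in temperature and salinity,
`pKa* = 10.0423 − 0.0315536·T + 0.003071·S`. pH defaults to 8.05 but is the
single most sensitive input (the fraction roughly doubles per +0.3 pH), so
the CLI requires it explicitly. Full carbonate-system speciation, pH-scale
conversions and activity corrections are out of scope.

## qPCR, FISH and cell-specific rates

Standard curves are ordinary least squares of Cq on log₁₀(copies μl⁻¹)
over ≥3 dilution levels; efficiency `10^(−1/slope) − 1` is flagged outside
[0.9, 1.1]. Duplicate wells are averaged on the Cq scale before inversion.
Per-gram normalization assumes the whole elution represents the extracted
tissue mass (copies μl⁻¹ of extract × elution volume ÷ tissue mass); no
extraction-yield correction is applied. Cell-specific rates default to one
16S rRNA gene copy per cell — the single-operon case typical of
ammonia-oxidizing archaea — with `copies_per_cell` configurable.

## Comparative genomics

AAI: per direction, the best hit per query by bitscore (ties broken by
identity, then lexicographically smallest subject id, for determinism);
hits must cover ≥70% of the query length *in each direction*; reciprocal
pairs are retained and identities averaged weighted by the A→B query
length. Because "gene length" weighting is ambiguous (query, subject or
alignment length), the reverse-weighted and unweighted means and their
symmetrized average are reported alongside the headline value. Alignment
itself is external: hit tables enter as 14-column BLAST tabular
(outfmt 6 + qlen + slen).

Fragment ANI: non-overlapping fixed windows (default 1020 bp, 0-based
half-open coordinates, terminal remainders discarded), reciprocal best
fragment mappings at ≥70% identity; ANI is their mean identity and the
aligned fraction is retained-fragment length over the smaller genome.

Assembly GC excludes IUPAC ambiguity codes from numerator and denominator;
N50 is the standard cumulative-half definition.

Gene-family algebra operates on integer presence/count matrices
(families × genomes): exclusive sharing requires ≥1 copy in every focal
genome and 0 in all others; core/unique/other fractions are computed over
the focal genome's gene counts and sum to one. Family construction
(ortholog inference) is out of scope.

## Proteomics

NSAF is computed per sample and normalized to sum to one at machine
precision; group shares are summed per sample and then arithmetically
averaged across samples (proteins absent from a sample contribute zero
there). The identification filter requires ≥2 exclusively unique peptides;
decoys are removed after FDR estimation. FDR follows the concatenated
target-decoy convention 2D/(T+D), with D/T available as `convention="simple"`.

## Synthetic-data generators

Each generator is seeded (one root seed, spawned substreams) and returns the
hidden truth it used. The incubation model integrates the three-pool ODE
with fixed-step RK4 (step ≤ 0.01 d) and is cross-checked against the closed
form `APE(t) = APE₀·(C(t)/C₀)^(−p/(p−c))`. Defaults mirror the experimental
design: 1.5 L containers, ~5.1 g clones, a ~10 μM nitrate pool labelled at
10% of the post-addition pool, 0 h/20 h pool-dilution sampling and
6 h/18 h net-flux sampling, ambient NH₄⁺ of 0.29 μM, and NO₂⁻ accumulating
2.8× faster than NO₃⁻. The proteome generator draws multinomial spectral
counts with protein weights proportional to bin share × length, which makes
within-bin SpC/L flat and bin NSAF shares recover the inputs in expectation.
Toy genome pairs are substitution-only (no indels or rearrangements), so
fragments stay co-linear and per-site identity is exact.

What the generators do **not** emulate — and therefore what passing tests do
not demonstrate about real data: time-varying rates (diel or
substrate-driven), isotope fractionation, NH₄⁺-limitation feedback on
nitrification, label loss from open containers, qPCR inhibition or
extraction-yield variation, shared-peptide ambiguity in protein inference,
and alignment artefacts (the hit tables are idealized). The pipeline's
per-treatment truth recovery shows estimator correctness under the stated
model, not field accuracy.

## Pipeline

The orchestration treats the container-day as the unit of analysis (clones
move to fresh containers daily, so days are not strictly paired within a
clone). The synthetic design is 3 treatments × 3 replicates, gross rates on
days 1/3/5, net fluxes on days 1/3/5/7, end-point tissue ¹³C and qPCR on
day 7; sizes were chosen to keep a full run under a second while leaving
Monte-Carlo error well inside the recovery tolerances. Treatment-day
averaging scope is configuration, not an automated statistical-equivalence
gate; hypothesis testing is left to stock statistical routines downstream.

## Known limitations

- The pool-dilution estimator resolves the combined NO₂⁻+NO₃⁻ pool only;
  separate nitrite/nitrate compartment models (and ¹⁵NH₄⁺ pool dilution)
  are out of scope.
- Weighted gross-rate aggregation schemes are not implemented; the
  weighting definition is not standardized and must be applied by the user.
- The acceptance/validation stack runs on synthetic inputs; checks against
  deposited genome and proteome archives require network access and are not
  part of the test suite.
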