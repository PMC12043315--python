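# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions.

## Lipid-contact statistics (`lipidstab.contacts`)

**Model.** A lipid–residue interaction is reduced to a binary bound state
per trajectory frame. Distance series are binarized with the dual-cutoff
convention: the state becomes bound when the minimum distance drops to
*r*<sub>on</sub> and stays bound until it exceeds *r*<sub>off</sub>. The
hysteresis suppresses boundary flicker, which would otherwise fragment one
physical binding event into many short ones. Defaults *r*<sub>on</sub> =
0.475 nm, *r*<sub>off</sub> = 0.8 nm follow common coarse-grained practice;
both are configurable, and *r*<sub>on</sub> = *r*<sub>off</sub> reduces to a
single threshold.

**Estimators.** Occupancy is the bound-frame fraction. Residence events are
maximal bound runs; events touching either trace end are flagged censored
(their true duration is only bounded below). The default residence
estimator is the arithmetic mean of *uncensored* durations — censored
events are excluded from the mean (avoiding downward truncation bias) but
still counted in occupancy. An alternative estimator fits
S(t) = exp(−k t) to the normalized event-survival curve by least squares
and reports 1/k̂; it uses all events, censored included, since a censored
duration still contributes correctly to the early part of the survival
curve while the fit is dominated by the exponential tail. The survival fit
is flagged under-determined (NaN) with fewer than two distinct durations.

Site-level statistics treat a site as bound when *any* member residue is
bound (union series). Pooling across replicate trajectories uses
frame-weighted occupancy and concatenates events without merging across
replicate boundaries; mixed frame spacings are rejected.

**Frame discretization.** Event boundaries are frame-sampled, never
interpolated. For the two-state chain with per-frame transition
probabilities p = 1 − exp(−k dt), the mean bound run is 1/p_off frames, so
the estimator converges to dt/(1 − exp(−k_off dt)) rather than exactly
1/k_off; the two agree to first order in k_off·dt, and tests account for
the distinction. Likewise the frame-discretized chain equilibrates at
p_on/(p_on+p_off), within O(k·dt) of the continuous k_on/(k_on+k_off).

## Binding-site span screen (`lipidstab.sites`)

The span of a site is the maximum sequence distance between its basic
residues. The basic set is {Arg, Lys}; histidine is excluded because CDL
interaction fingerprints are built on R/K. Spans below 10 positions are
classed single-helix, above 30 multi-helix, in between ambiguous; a span of
exactly 30 is reported as a separate tie count rather than silently binned,
since a strict less-than/greater-than split leaves it unspecified. Sites
with fewer than two basic residues have no span (class undefined). Residue
positions are taken verbatim from the annotation — no renumbering.

The histogram uses fixed log10 bins of width 0.1 anchored at 0, so bins are
comparable across datasets; zero/undefined spans are excluded with a
reported count. The screen does not parse structures: "multi-helix" is a
sequence-distance proxy, and interfacial sites of homo-oligomers (bridging
single residues on different subunits) are out of scope — hence the
optional monomer-only filter.

The canonical table schema is long-format CSV with columns `protein_id,
oligomeric_state, site_id, residue_position, residue_name`; external site
databases are adapted by renaming columns to this schema.

## Mass model (`lipidstab.masses`)

Formula and sequence masses delegate to pyteomics (IUPAC average atomic
weights or principal-isotope monoisotopic masses). The default lipid adduct
is the tetrapalmitoyl (16:0) cardiolipin free acid, C73H142O17P2, average
mass 1353.85 Da — 1.4 kDa at one reporting decimal (half-up rounding). Salt
forms can be substituted by passing a different adduct mass. Charging is by
proton adduction (positive mode), m_H+ = 1.007276 Da.

Peak assignment matches each observed centroid to the nearest theoretical
m/z within a ppm tolerance, keeps one assignment per peak resolved by the
smaller error, and flags assignments with more than one in-tolerance
candidate as ambiguous. The default 50 ppm suits adduct-series assignment
on ~100 kDa complexes: it is far below the adduct spacing m_CDL/z (~80 m/z
at 17+). For unfolded-monomer quantification at m/z ≈ 2000–2800 the
pipeline default widens to 2000 ppm, because broad monomer peaks carry
centroid jitter on the m/z (not ppm) scale while the species are separated
by tens of m/z units; both tolerances are configurable.

## Native-MS quantification (`lipidstab.nms`)

**Peak detection.** Local maxima above min_snr × noise, where noise is
1.4826 × the median absolute deviation of the median-filter-detrended
signal (robust against the peaks themselves; the filter width, default 101
samples, should exceed the widest peak). A peak's window extends from the
apex to the first local minimum or the noise floor; centroid is the
intensity-weighted mean, area the trapezoid integral. On noiseless
synthetic data the floor falls back to a tiny fraction of the maximum so
true maxima are still detected.

**Quantification.** The default intensity measure is peak area (robust to
width variation from detergent adducts); height is available for parity
with viewer-based quantification. Charge-state policy: all assigned charge
states, or the top-k most intense per species (default k = 3, the usual
"main charge states" convention). Every readout is invariant to uniform
intensity scaling.

**Stabilization assay.** Per replicate spectrum, the ratio
I_test/(I_test + I_ref) of summed monomer intensities; ratios are computed
per replicate first and only then compared across lipid conditions,
matching the replicate structure of the experiment (four spectra per
condition). The comparison is a two-sided two-sample t-test, Student's
pooled-variance by default (the conventional "two-tailed t-test" of
small-n reporting), Welch optional. Sign convention: delta =
mean(with) − mean(without) > 0 means the reference species is stabilized
more. The degenerate all-constant case returns p = 1 for equal means by
convention. The same statistical core serves the pull-work comparison.

## Pull-work analysis (`lipidstab.pull`)

Work is the trapezoid integral of force over the pull coordinate from the
trace's initial coordinate to a stop displacement (default 1.1 nm, the
separation at which non-covalent inter-helix contacts are lost). The stop
point is linearly interpolated; traces ending short of it are rejected —
no extrapolation. "1.1 nm" is interpreted as *displacement* from the
initial coordinate; an absolute-coordinate mode is provided because either
reading is defensible. Negative forces contribute negatively. Time-stamped
force series are converted via coordinate = initial + rate·time (default
rate 0.1125 nm/ns). The xvg reader skips `#`/`@` lines and rejects ragged
rows with a line number.

## Synthetic generators (`lipidstab.synthetic`)

All generators take an integer seed; replicate and condition streams are
derived by seeding a fresh numpy Generator with (seed, condition,
replicate), making replicates independent yet individually reproducible,
and fixed seeds bit-identical.

- **Two-state kinetics:** per-frame transition probabilities
  1 − exp(−k dt), simulated by alternating geometric dwells (exact and
  fast). The chain starts unbound, emulating a lipid approaching from
  bulk; the equilibration transient is negligible at the default 1e5
  frames. Defaults k_on = 0.05/ns, k_off = 0.02/ns at dt = 1 ns give ~71%
  occupancy and 50 ns mean residence — the regime of a specific,
  structural lipid site resolved at coarse-grained frame spacing.
- **Two-site kinetics:** three states (unbound, site 1, site 2) with
  competing-risk discretization: exit probability 1 − exp(−k_tot dt) split
  in proportion to the outgoing rates, which reduces to the two-state rule
  for a single exit. At most one site is bound per frame, emulating one
  lipid exchanging between overlapping sites.
- **Spectra:** Gaussian peaks (native envelopes of 100 kDa complexes are
  not isotope-resolved) whose areas carry the signal; adduct counts
  binomial(n_max, p_bind) — independent binding slots; additive Gaussian
  intensity noise clipped at zero, scaled to the tallest peak. Defaults
  (σ = 1.5–2 m/z, 1% noise) reflect well-resolved native spectra; the real
  instruments' noise characteristics are not published, so these are free
  choices.
- **Site tables:** spans from a two-component log-normal mixture (medians
  5 and 70 positions, log-sd 0.35/0.25), chosen to reproduce the observed
  bimodality with the multi-helix mode near known multi-helix exemplars
  (~75 positions) and negligible mass at the 30-position boundary. Class
  counts are allocated by stratification (round(n × fraction_multi)), so
  the default 255-site table contains exactly 75 single-helix and 180
  multi-helix sites; each record places two basic residues exactly its
  drawn span apart.
- **Force traces:** harmonic ramp F = k·d (k = 1000 kJ/mol/nm²) to the
  rupture displacement (1.1 nm), then exponential decay; a sample is
  placed exactly at the rupture kink so the sampled piecewise-linear trace
  integrates to the closed form ½k d² without discretization error. A
  bound lipid adds a constant force bonus/d_rupture before rupture,
  contributing exactly `lipid_work_bonus` of extra work. Per-sample
  Gaussian force noise (default 25 kJ/mol/nm, ~2% of peak force).
- **Competition experiment:** spectra containing tetramer and monomer
  peaks of both variants; monomer intensity proportional to the species'
  dissociated fraction for the condition, tetramer to its complement.
  Each (replicate, condition, species) intensity gets an independent
  log-normal factor (sd 0.05, typical run-to-run native-MS variation).
  Defaults: both variants 30% dissociated without lipid, lipid halving the
  reference's dissociation, four replicates per condition, masses ~100 kDa
  tetramers / ~25 kDa monomers separated by 200–800 Da. Species whose
  peaks collide within 3σ trigger a warning in the ground truth. Lipid
  adduct peaks on tetramers are *not* modelled: the assay readout uses
  monomer intensities only.

**What the generators do not emulate:** detergent/lipid clusters and
chemical background, charge-state redistribution upon activation,
peak-shape asymmetry, baseline drift, correlated (1/f) noise, real
dwell-time distributions with multiple bound substates, and rupture-point
variability between pulls. Passing recovery tests therefore demonstrates
estimator correctness under the stated noise models, not robustness to
every instrumental artefact.

## Problem sizes in the test suite

Recovery tests use 1e5–2e5 frames for kinetics (3-standard-error bands
computed with the chain's autocorrelation inflation factor
(1+ρ)/(1−ρ), ρ the per-frame correlation), 200 re-seeded competition
experiments for sign recovery, 1000 null experiments for the type-I error
band [0.03, 0.07] (the binomial 99% interval around 0.05), and 20
replicate pulls for the work comparison — sizes at which the statistical
tolerances are meaningful while the whole suite runs in a couple of
minutes.

## Known limitations

- The survival-exponential residence estimator assumes a single
  exponential; multi-exponential dwell distributions (multiple bound
  substates) will bias it toward the dominant component.
- Peak windows are delimited by local minima, so heavily overlapping peaks
  (closer than ~2σ) partition their shared valley rather than being
  deconvolved; species must be chosen resolvable, as in the real assay.
- The span screen is a sequence proxy: long loops can exceed 30 positions
  on a single structural element, and the screen cannot see inter-subunit
  sites.
- MD-derived occupancies/residence times and instrument p-values from real
  studies depend on unreleased trajectories and raw spectra; the package
  validates its estimators by parameter recovery on synthetic ground
  truth instead.
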