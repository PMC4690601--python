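# Methods

## Problem setting

A solid-state nanopore in a thin SiN membrane separates two electrolyte
chambers; a voltage bias drives a steady open-pore ion current I₀, and each
DNA molecule passing (or colliding with) the pore produces a transient
current reduction ΔI lasting a dwell time t_d. Two quantities summarise an
event: the fractional blockade ΔI/I₀ and t_d. Osmylation — covalent addition
of an osmium-bipyridine complex to pyrimidines — enlarges the molecule, so
the blockade grows with the fraction of labeled bases. The package's job is
the quantitative chain from sequences and labeling protocols to blockade
populations and molecular sizing.

## Sequence accounting

Protocols are described by per-base reaction probabilities
(`t_efficiency`, `c_efficiency`). The deterministic mode labels every
targeted base — Protocol A all T's, Protocol B all T's and C's — which is
the convention under which the built-in oligo panel's osbipy counts are
reported, and is the default. (The reaction is not perfectly efficient in
reality — roughly 90% per T under Protocol A conditions — so a stochastic
mode draws an independent Bernoulli per targeted base from a seeded
generator; it exists for simulation realism, not for reproducing the panel.)
Positions are 1-based in every report.

Duplex accounting treats each A:T base pair as contributing exactly one
osmylatable T across the two strands: the expected labeled fraction of a
duplex is (AT-pair fraction) × (per-T efficiency), linear in the efficiency.
For the built-in 202-bp amplicon (AT fraction 0.5495) at 50% T-efficiency
this gives 27.5% strand osmylation, ≈55 labeled base pairs.

The CE absorbance ratio R(312/272) is treated purely as a linear calibration
target (unmodified DNA does not absorb at 312 nm). Ordinary least squares on
the panel's eight (fraction, R) pairs gives slope 2.132, intercept 0.015,
residual sd 0.041 — the intercept is statistically indistinguishable from
the measured unreacted-oligo ratio of 0.03 at one residual sd. No reaction
kinetics or electropherogram modeling is attempted.

## Conductance model

Open pore: `G_open = σ [4L/(πd²) + 1/d]⁻¹` — a cylinder of diameter d and
effective thickness L in series with the access resistance of the two pore
mouths (the 1/d term). With d, L in nm and σ in S/m, G is in nS. Blocked
pore: the coaxial molecule of diameter d_mol leaves an annular cross-section,
modeled by substituting d_b with `d_b² = d² − d_mol²` in *both* terms.
σ cancels in ΔI/I₀ = 1 − G_blocked/G_open, which is strictly increasing in
d_mol, zero at d_mol = 0, and approaches 1 as d_mol → d.

Sizing inverts this map by `scipy.optimize.brentq` on the bracket
[0, d(1−10⁻⁹)] with xtol 10⁻¹² nm; round-trips hold to well under 10⁻⁶ nm.
For the 4.4 nm / 10 nm pore the measured duplex blockades 0.44 and 0.22
invert to effective diameters 3.05 nm and 2.18 nm. A no-access-resistance
variant (`model="simple"`, pure cylinder, for which ΔI/I₀ = d_mol²/d²
exactly) is kept as a comparison switch; the access-resistance model is the
default because a 10-nm-thick pore is far from the thick-pore limit.

Electrolyte conductivity is a user input. The simulator presets use 3.0 S/m
for the 0.4 M KCl + 4.8 M urea ssDNA buffer (0.4 M KCl alone is ~4.6 S/m at
room temperature; 4.8 M urea raises viscosity by roughly half, depressing
ionic mobility accordingly) and 4.6 S/m for the urea-free dsDNA buffer.
These affect only the simulated baseline current scale, never ΔI/I₀.

## Trace simulator

The generator emulates the statistical structure of the recorded data, not
its physics. Event starts are a Poisson process thinned to forbid overlap
(rejections are counted; >50% rejection is flagged). Each event draws a
population by weight, a blockade from a truncated normal, and a dwell from a
per-population log-normal (10^N(μ, s) seconds, floored at 2 samples), and is
rendered as a rectangular pulse of depth ΔI = blockade × I₀. Gaussian white
noise is added, then an optional low-pass filter is applied to the whole
trace. All draws come from one `numpy` Generator seeded by the config, so
output is bit-reproducible.

Defaults are desk-scale: 500 kHz sampling, 50 kHz cutoff, ≤30 s of trace,
event rate 40/s — enough for the ~1000-event statistics the analyses need
while keeping a full three-sample series under a minute. The high-bandwidth
acquisition profile (4.16 MHz sampled, 250 kHz filtered) is reachable by
overriding two fields. Dwell parameters (log₁₀ mean −3.7, sd 0.25, i.e.
most-probable dwell ~0.2 ms spanning about a decade) were fixed once to
resemble published ssDNA dwell histograms at these pore sizes. The collision
population carries weight 0.3 in the presets, with the 80-mer series
sharing a collision peak at ΔI/I₀ = 0.44 and per-sample translocation peaks
(0.57, 0.63, 0.74) taken from the panel.

What the simulator deliberately omits — and what passing tests therefore do
not demonstrate about real recordings: intra-event structure (folded or
multi-level translocations), 1/f and dielectric noise, voltage- and
concentration-dependent capture rates, baseline drift, and any physical
link between osmylation chemistry and blockade depth beyond the configured
population means.

The filter is a 2nd-order magnitude-normalized Bessel biquad applied
forward-backward (`sosfiltfilt`): zero phase, 4-pole magnitude, DC gain 1.
The design cutoff is pre-corrected (solved numerically per sampling-rate/
cutoff pair) so the *combined* response is −3 dB exactly at the nominal
cutoff; the implemented 10–90% step rise time is 0.40/cutoff.

## Event detection

Baseline: iterative sigma-clipping (median ± 3×(1.4826·MAD), to mask
convergence, max 50 iterations) over the whole trace; returns the clipped
mean and the robust sd, floored at machine epsilon for noiseless input.
This tolerates events occupying up to roughly a third of the samples.

Detection: an event opens when the current drops below
I₀ − k·noise_sd (default k = 5, standard practice at these signal-to-noise
ratios) and closes when it recrosses I₀ − noise_sd ("baseline-return", the
default; a "threshold-crossing" rule is available). Events shorter than
`min_duration` (default 4 µs) or longer than `max_duration` (default 0.1 s)
are discarded and counted. Depth is the baseline minus the *mean* in-event
current — consistent with reporting one ΔI/I₀ per event for histogramming —
with 0.5/cutoff seconds trimmed from each end of the average on filtered
traces when the event is at least three trims long (shorter events keep all
samples and are flagged `edge_trimmed=False`), which removes the
filter-rise-time bias on the plateau estimate. Indices are half-open
[start, end), 0-based internally; user-facing output is in seconds.

Note one algebraic point: adding a constant to a trace shifts I₀ but not ΔI,
so ΔI/I₀ is *not* translation-invariant — the invariants the detector
guarantees are that translation preserves event bounds, t_d and ΔI, and that
positive scaling preserves ΔI/I₀ and t_d.

## Blockade statistics

Mixtures are fitted by expectation-maximization on the raw per-event values
(statistically more efficient than least-squares on a binned histogram; a
`method="binned"` Gaussian-curve fit to the histogram is provided for
comparison with peak values read off histograms). The 2-component fit runs
20 restarts — one deterministic quartile initialization plus 19 seeded
random quantile-pair initializations — keeping the best log-likelihood; the
log-likelihood is asserted non-decreasing at every EM iteration, and
components collapsing to sd < 10⁻⁴ are pruned with a warning. Model choice
(`n_components="auto"`) uses BIC with a 2-point margin required to prefer
two components, mirroring how per-sample histograms are sometimes single-
and sometimes double-peaked. At least 50 events are required for any fit.

Labels: with two components the lower mean is "collision" (molecules that
strike the pore without translocating) and the higher is "translocation"; a
single component is a translocation peak; exactly equal means are broken by
weight (heavier = translocation) — arbitrary but fixed.
`most_probable_blockade` returns the component means, collision first,
matching the two-value reporting convention of the study table. Dwell
histograms use uniform log₁₀ bins (default 5/decade) spanning the data
range. The blockade-vs-osmylation-fraction trend is a plain OLS line —
descriptive only, no physical model implied.

## Pipeline and reproducibility

`run_pipeline` chains simulate → detect → fit → most-probable peaks per
sample, then the trend across samples, and emits a schema-versioned JSON
report plus per-sample event TSVs. Every stochastic stage derives its seed
as SHA-256(global seed | stage | sample id) mod 2³¹, so stages are decoupled
and a report is byte-identical across runs with the same seed. All text
formats carry 9 significant digits and round-trip byte-identically.

## Known limitations

- The conductance model ignores electro-osmotic flow, surface charge and
  urea-dependent conductivity; "effective thickness" must come from sizing
  the pore, not from the membrane's physical thickness.
- Rectangular-pulse events mean detector dwell estimates are optimistic
  relative to real, filter-rounded events of marginal depth.
- EM mean recovery to ±0.01 is demonstrated at ~1000 events with population
  separations like 0.44/0.57 and sds ≤0.04; strongly overlapping or
  heavy-tailed populations (real unreacted ssDNA shows folding tails) will
  do worse, and the collision-peak estimate is the first casualty.
- The R calibration is linear by construction; it extrapolates poorly
  beyond the fitted fraction range [0, 0.5125].
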