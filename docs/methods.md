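# Methods

`neurosw` implements a resting-state EEG source-connectivity analysis:
band-wise lagged linear connectivity between cortical regions of
interest (ROIs), weighted small-world graph indices with cross-band
normalization, and a Group x Band repeated-measures comparison. Because
no real recordings ship with the package, a synthetic two-cohort
generator with a controllable coupling topology provides the study
conditions under which every claim in the test suite is checked.

## Pipeline model

**Inputs.** Per-subject multichannel time series at the ROI level — by
default 84 channels, one per Brodmann area and hemisphere (42 areas x 2,
left hemisphere first) — sampled at 256 Hz. The pipeline deliberately
starts *after* source reconstruction: inverse solutions are an
independent, well-served problem and their operator choices would
dominate everything downstream.

**Preprocessing.** A linear-phase windowed-sinc (Kaiser) band-pass FIR,
0.2–47 Hz by default, applied forward-backward so the net phase is
exactly zero. Zero-phase filtering matters here: any band-dependent
group delay would masquerade as lag and contaminate the lagged
connectivity measure. The design contract (verified against the
measured frequency response in the tests) is ≥40 dB at half the
high-pass edge and at the low-pass edge + 5 Hz, with ≤1 dB passband
ripple between 1 and 45 Hz; the single-pass design targets 50 dB so the
contract holds with margin, and the two-pass application doubles the
stopband depth. The series is then cut into non-overlapping 2 s epochs.

Artifact handling is a deterministic robust-amplitude rule: per channel,
the peak absolute amplitude of each epoch is converted to a robust z
score (median/MAD across epochs, MAD scaled by 1.4826), and an epoch
exceeding z = 5 on any channel is dropped. Expert-guided ICA cleaning of
real EEG is intentionally out of scope — it is irreproducible without
the operator — and the synthetic data carry no stereotyped artifacts.
Note that the peak of ~500 samples is Gumbel-distributed, so even clean
Gaussian data loses a few percent of epochs to this rule when the union
is taken over 84 channels; the generator therefore simulates 6 minutes
per subject so that at least 5 minutes survive screening (the screening
raises an error naming the subject otherwise).

**Connectivity.** The cross-spectrum S(f) is estimated by averaging
Hann-tapered DFT outer products over epochs (0.5 Hz resolution at the
defaults). For each channel pair the lagged linear connectivity at
frequency f is the lagged squared coherence

    rho2_lag(f) = Im(S_xy)^2 / (S_xx S_yy − Re(S_xy)^2),

the fraction of linear dependence attributable to a non-zero phase lag.
Instantaneous (volume-conduction-like) mixing contributes only to
Re(S_xy) and cancels by construction; the tests verify that full-rank
instantaneous mixing of independent sources stays at the epoch-shuffled
surrogate chance floor while genuinely delayed coupling does not. Band
values are unweighted means of per-bin values over half-open intervals
[lo, hi) of the canonical seven bands (delta 2–4, theta 4–8, alpha1
8–10.5, alpha2 10.5–13, beta1 13–20, beta2 20–30, gamma 30–45 Hz), so a
bin on a shared edge is counted once. The bounded measure is the default
edge weight; the monotone transform −ln(1 − rho2_lag) ("lagged_F") is
available as an option, and per-bin values are clipped to
[0, 1 − 1e-12] before the log. Bins with a non-positive denominator
(numerically degenerate) are skipped with a warning.

**Graph indices.** The weighted clustering coefficient is the Onnela
geometric-mean form with weights rescaled by the matrix maximum; it
reduces to the binary clustering coefficient on 0/1 weights. The
weighted characteristic path length uses shortest paths with edge
length 1/w (all-pairs Floyd–Warshall, vectorized; verified in the tests
against a pure-Python relaxation loop and scipy's Dijkstra). Zero
weights are treated as absent edges and an error is raised if they
disconnect the graph — on real pipeline output this cannot happen, since
estimated lagged coherence is strictly positive. No threshold or
sparsification is applied: the full positive weighted graph is used.

Within each subject, clustering and path length are divided by their
mean over the seven bands; the small-world index is SW = C_norm/L_norm.
The normalization makes the band profile a within-subject contrast
(mean of each normalized metric is exactly 1 per subject, asserted to
1e-12 on every run), which is what licenses treating Band as a repeated
measure. The per-subject (rather than group-pooled) band mean is used;
with equal group sizes the two interpretations give the same
group-difference directions.

**Statistics.** A split-plot ANOVA with Group (between subjects) and
Band (7 levels, within subjects): Group is tested against
subjects-within-group, Band and Group x Band against the
Band x subject residual — degrees of freedom (1, 24) and (6, 144) at
13+13 subjects. The sum-of-squares decomposition is verified exactly
(1e-9, relative) on every call. Within-subject p-values carry a
Greenhouse–Geisser correction with epsilon estimated from the pooled
within-group band covariance (floored at 1/6 for singular covariance).
Normality is screened per Group x Band cell with the Lilliefors form of
the Kolmogorov–Smirnov test (parameters estimated from the cell; the
plain KS null would be anti-conservative); cells with fewer than 4
observations cannot be screened and raise an error, zero-variance cells
are flagged, not crashed.

The per-band group comparison is Duncan's multiple range test, written
as the general stepwise procedure (protection level
alpha_p = 1 − (1−alpha)^(p−1), studentized-range critical values,
harmonic-mean cell size) although two groups reduce it to a protected
LSD. **Error stratum:** the default is a per-band independent-samples
pooled variance (df 24 at the study size), not the interaction residual
(df 144). The reason is a property of the cross-band normalization: it
constrains each subject's band profile, inducing negative correlation
between a subject's band values, so the interaction residual MS
*overstates* the variance of a per-band between-group contrast and the
resulting test is conservative (measured null rejection ≈ 0.03 per band
versus ≈ 0.05 for the per-band stratum, which is exactly calibrated —
the two-mean Duncan decision coincides with a pooled t test, verified
in the suite). The interaction stratum remains available as
`error_stratum="interaction"`.

## The synthetic generator

Each subject is a sum over bands of band-limited Gaussian sources (white
noise spectrally masked to [lo, hi), unit variance) plus broadband white
noise (sd 1.0). In a band carrying a planted topology, sources are mixed
along the edges of a Watts–Strogatz-style graph: `lattice` is the exact
ring lattice, `random` a full rewiring, `smallworld` a partial rewiring
(edge count n·k/2 is conserved in all cases). The mixed signal of node i
adds `coupling_strength` times the delayed source of each in-neighbour.

Two design points matter:

* **Edges are randomly oriented.** If an undirected edge coupled both
  directions with the same delay, the two cross terms c·P·e^{−iωL} and
  c·P·e^{+iωL} would sum to a purely real cross-spectrum and the planted
  edge would be invisible to the lagged measure. Each edge therefore
  carries influence one way, with the direction drawn per edge.
* **The delay is a quarter period of the band center** in the planted
  study configurations (e.g. 11 samples for theta at 256 Hz), putting
  the within-band phase near pi/2, where the lagged measure is most
  sensitive; a fixed delay that happens to sit near phase 0 or pi would
  null the planted dependence.

Seeding is splittable (`SeedSequence(cohort_seed, spawn_key=(subject,
band))`): output is bit-reproducible and adding subjects never perturbs
earlier ones.

**Planted contrast.** The default study configuration gives the PD-like
cohort an ordered (ring-lattice) theta coupling and a random alpha2
coupling, and the control-like cohort the reverse; the other five bands
carry an identical small-world (p = 0.2) baseline in both cohorts.
Generator parameters were fixed once at degree 4 and coupling strength
0.6 — enough structure for the ordered-vs-random contrast to be
recovered reliably at 13 subjects per group (standardized per-band SW
difference ≈ 1.5–2 at the reduced replicate size), while keeping edge
weights within an order of magnitude of the estimation floor, which is
the regime that fixes the direction of the effect (next paragraph).

**Why ordered topology lowers SW here.** On binary graphs a ring
lattice has *higher* classic small-world ratio than a random graph (its
clustering advantage, ≈ 7x at n = 84, k = 8, beats its path-length
penalty, ≈ 2.5x). The pipeline reverses this: estimated lagged
coherence is strictly positive everywhere, so every node has 83
"neighbours" and the weighted clustering sum is dominated by
floor-level triangles — the lattice/random clustering contrast is
diluted to a few percent — while shortest paths ride the strong edges
and keep the full path-length contrast. Net, the lattice band shows a
distinctly *higher* normalized path length, hence lower SW: ordered
topology → lower SW, random topology → higher SW, which is the
qualitative contrast the statistics are asked to recover. This
mechanism depends on the noise floor (number of epochs) and coupling
strength being in a moderate regime; it is a property of the artifact,
not a quantitative claim about brains.

**What the generator does not emulate.** No scalp electrodes, no
forward/inverse modeling, no 1/f background spectrum, no ocular or
muscle artifacts, no nonstationarity. Passing tests therefore show that
the estimators and decision procedure behave correctly under controlled
lagged linear dependence — not that real PD and control EEG will
separate this way. Absolute SW values and effect magnitudes are
artifact-internal and not comparable to published group tables.

## Problem sizes and numerical choices

* Full-scale runs (acceptance script): 13+13 subjects, 84 ROIs, 360 s at
  256 Hz (≈ 180 2-s epochs before screening).
* Replicate experiments use a reduced size chosen to keep Monte-Carlo
  studies cheap while preserving the topology contrast: 40 ROIs, 64 s at
  128 Hz (32 epochs) for the planted contrast; 8 ROIs, 24 s of uncoupled
  noise for the null size study (1000 replicates).
* Log clipping for lagged_F: 1e-12. SS decomposition tolerance: 1e-9
  relative. Normalization conservation: 1e-12. GG epsilon floor:
  1/(k−1).
* The studentized-range quantile is cached per (alpha, span, df); for
  two means its survival function uses the exact identity
  P(Q > q) = 2 P(t_df > q/sqrt(2)).
* Degenerate inputs: all-zero weight matrices, zero-variance cells and
  zero error mean squares raise or warn explicitly rather than
  propagating NaNs silently.

## Known limitations

* The generator's group contrast is planted at the topology level;
  amplitude (power) differences between groups, a prominent feature of
  real clinical EEG, are not modeled.
* The rejection rule screens amplitude only; it cannot stand in for ICA
  on real recordings with structured artifacts.
* Unequal group sizes are supported by the ANOVA with
  proportional-subclass formulas (exact for one between-factor
  designs); heavily unbalanced multi-factor extensions are out of
  scope.
* With very strong coupling or very many epochs the clustering-dilution
  regime breaks down and the SW direction of the planted contrast can
  attenuate; the defaults sit well inside the validated regime.
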