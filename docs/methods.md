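# Methods

## The annulus model

An arterial cross-section is modeled as a thick-walled circular annulus
described by two measured lengths, external diameter ED and lumen diameter
ID, with 0 < ID < ED. All other quantities are algebraic derivatives:
WTh = (ED − ID)/2, WLR = WTh/ID (reported ×100), MCSA = π(ED² − ID²)/4,
LCSA = π·ID²/4, EP = π·ED, IP = π·ID. Whether ED and ID are measured to the
internal or external elastic lamina is a staining/segmentation question the
package does not arbitrate: both are treated as opaque calibrated lengths in
μm, and no unit conversion happens inside the core.

Some legacy reports compute MCSA as π(ED²/2 − ID²/2), which is exactly twice
the annulus area; `printed_form=True` reproduces that convention. Only
absolute values change — every direction-of-change result is identical.

Sections are accepted when the long/short axis ratio is strictly below 1.50
(near-circular cut, diameter error < 3%) and ED lies in the closed window
[10, 50] μm, the caliber band that dominates peripheral-resistance
regulation and still tapers linearly.

## Interval statistics and complex profiles

Whole-range means of ED/ID/WTh/WLR are reported with SD/SEM/CV but carry
little information: the caliber distribution is strongly skewed (small
vessels dominate) and per-dimension distributions fail normality testing.
The package instead bins vessels into 5 μm ED intervals — bins are
half-open [low, low + 5) anchored at 10 μm, the last bin closed at 50 so
the window is honored as printed; bins thinner than `min_per_bin` (default
3) are omitted and reported, since near-empty bins distort regressions.
Normality is assessed per sample with a Lilliefors-corrected KS test,
D'Agostino–Pearson K², and Shapiro–Wilk; a sample is flagged non-normal when
any of the three rejects at α = 0.05. Note the union of three 5% tests
rejects truly normal data ~15% of the time — the flag is a screening
device, not a calibrated test.

The complex profile arranges vessels (or interval means) by ascending ED
against rank or accumulated frequency. Profiles retain the
caliber-frequency structure that regressions discard: two beds with
identical tapering lines but different caliber laws have identical fits and
different profiles. This frequency information is also what lets states be
matched across groups (below).

## Tapering regressions

ID = a·ED + b and WTh = c·ED + d are fitted to the interval means, each bin
one unweighted point — matching the mean-per-interval convention. A
`weight_by_n` option reweights bins by vessel count; it is off by default
and the equivalence/inequivalence with per-vessel fitting is covered by a
test. Outlying bins (vessel subpopulations branching at different
hydrodynamic points) are removed by a ROUT procedure before the final OLS
pass: a Tukey-biweight robust line, residuals externally studentized — the
point under test is excluded from its own robust scale estimate (the
68.27th |residual| percentile with the variance-consistent √(m/(m−2))
de-bias), since at 8 bins a single large outlier otherwise masks itself —
then a Benjamini–Hochberg step-up at Q (default 1%, the method's
conventional setting). This configuration detects a 10-SD planted bin in
98/100 seeded runs at the cost of flagging something in ~7% of clean beds;
Q → 0 removes nothing. Outlier removal defaults to the per-bin level; the
same routine can be applied per-vessel before binning.

Slope/intercept comparison between two lines is the classic two-line ANCOVA
F-test (separate-slopes vs common-slope model; intercepts tested only under
a common slope), symmetric in its arguments. The exponential alternative
A·exp(k·ED) is compared by corrected AIC: both models have two
coefficients, so the extra-sum-of-squares F-test has zero numerator degrees
of freedom; the linear model is recommended unless the exponential's Akaike
weight exceeds 0.95. Within 10–50 μm linear generation is preferred
100/100 and exponential generation (k = 0.06 μm⁻¹) detected 100/100 in the
package's own selection harness.

## Hemodynamic indices

Under Poiseuille flow with constant viscosity and segment length, relative
resistance is RR(ED) = 1/(π·(ID(ED)/2)⁴) in μm⁻⁴, evaluated along the
fitted taper. TRR is the fine-grid mean of RR over ED ∈ [10, 20] μm (the
aggregation is a package choice; a point value is recoverable by narrowing
the window). Terminal capacity comes in two conventions:

* frequency-weighted: TC = Σᵢ (π·IDᵢ²/4)·fᵢ over bins, with IDᵢ the
  regression-predicted bin ID and fᵢ the bin frequency. This is an
  area-weighted "capacity" in arbitrary units and is sensitive to sampling
  frequencies by construction;
* truncated-cone: TC = πh(ID_lc² + ID_lc·ID_sc + ID_sc²)/3 and
  TMV = πh(ED_lc² + ED_lc·ED_sc + ED_sc²)/3 − TC, with the caliber limits
  (defaults 10 and 50 μm, h = 40 μm) evaluated on the fit. The formulas are
  evaluated with *diameters*, as conventionally printed — 4× the geometric
  volume of revolution; `radius_convention=True` divides by 4. All intended
  uses are comparative, so the constant factor is harmless; reports state
  which convention produced a number.

On a bed whose frequency vector matches uniform caliber sampling, the
frequency-weighted TC times h equals the radius-convention cone TC (within
binning error); with skewed frequencies they deliberately diverge — the
reason the cone form is preferred for group comparisons. Equal relative
wall growth produces organ-dependent TRR/TC changes because the initial
organ-specific dimensions enter the fourth-power law.

## The 19-variant catalogue

A remodeling event (EDn, IDn) → (EDhr, IDhr) has a direction signature: the
5-tuple of up/same/down over (ED, ID, WTh, MCSA, WLR). Exhaustive search
over annulus pairs (dense grids on [1, 100] μm plus explicitly constructed
equality families for WTh-, MCSA- and WLR-preserving transitions, "same"
judged at relative tolerance 1e-9) shows exactly 20 non-trivial signatures
are realizable: 9 with ED up, 2 with ED same, 9 with ED down. The canonical
catalogue numbers 19 of them; the remaining pattern
(↑, ↑, ↓, MCSA ↑, ↓) is reported as feasible-but-uncatalogued rather than
forced into a number. Three triples (#6–8, #11–13, #15–17) share ED/ID/WTh
directions and differ only in the gradient of change, expressed through the
WLR or MCSA coordinate.

Variants #3 and #4 share (↑, ↑, ↓, ·, ↓) and differ in the MCSA coordinate.
The literature is not internally consistent about which number carries
"MCSA reduced"; the default here assigns #4 = MCSA down (so a
distended-thinned bed with reduced media classifies as 4) and #3 = MCSA
preserved, with `swap_3_4=True` flipping the pair everywhere (catalogue,
classifier, surfaces).

Classification of a complete feasible signature is exact dictionary lookup;
the all-same signature returns the null class 0; partial signatures
(gradient coordinate unknown) return the compatible set; infeasible tuples
raise. The legacy indices are implemented for critique only:
RI = (IDn − ID₍MCSA-preserving₎)/(IDn − IDhr),
hypertrophy = (IDn − ID₍ED-preserving₎)/(IDn − IDhr), GI = ΔMCSA/MCSAn.
When the remodeled state truly is MCSA-preserving, RI = 1 exactly; when it
is ED-preserving, hypertrophy = 1 — and in every other case the indices
conflate many variants, which the non-identifiability report quantifies
(WLR rises in 9 catalogue variants, falls in 8, and is unchanged in 2; an
often-quoted narrative count of 3 unchanged variants disagrees with the
19-entry catalogue, so the report prints both). Perimeter and area ratios
add nothing: EP/IP and MCSA/LCSA are monotone in WLR, so their directions
coincide with it.

## Detecting a signature from two fitted beds

Group means hide the tapering structure, so the detector works on the two
fitted lines. Control and remodeled states are matched by
accumulated-frequency (quantile) correspondence: a monotone remodeling map
preserves vessel ranks, so the q-th quantile caliber of the control bed
corresponds to the q-th quantile caliber of the remodeled bed regardless of
how either bed was re-binned. (Taper fits retain their per-bin vessel
counts for this purpose; span-relative matching is the fallback and is
measurably biased by partial bins at the range ends.) ID and WTh are
evaluated on the two lines at matched calibers; MCSA and WLR derive from
those states. A dimension is called changed when its relative change
exceeds δ (default 5%) — with δ = 0 any noise produces a direction and
"same" can never be returned, hence the nonzero default — or, under the
statistical rule, when a z-test on the fits' coefficient covariances
rejects at α = 0.05 (ID and WTh only; ED and the derived dimensions keep
the threshold, as the fits carry no sampling model for them). True changes
near δ are at the detection boundary by construction: a variant whose ED
shrank by 5.2% will sometimes read "ED same". The round-trip tests
therefore use deviations chosen so every changed dimension clears δ.

## 3D congruence classification

Each variant generates a one-parameter family of transformed lines from the
control taper. The deviation parameter t ∈ [0, 1] scales "up" dimensions by
1 + 3·g·t (+300% at full deviation) and "down" dimensions by 1 − 0.99·g·t
(−99%), per-dimension gradients g fixed per variant; dimensions constrained
to "same" are enforced exactly through the annulus identities (e.g. the
MCSA-preserving families solve ID from ED² − const). Sampled over a t-grid
and the control ED grid, the family is the variant's transformation surface
in (ED, ID, WTh) space. Any sampled state that leaves the valid annulus
cone or violates the variant's signature is clipped out (several families
— lumen widening at fixed ED, the MCSA-preserving/increasing contractions —
are structurally truncated well before t = 1); a family mostly clipped for
a given control line triggers a warning.

The source geometry never defines how a variant morphs a whole line, so the
parameterization is a package design. Three of its choices matter:

* **Slice correspondence, not region membership.** Every one-parameter
  family swept from the whole control line covers a wide 2D region in the
  annulus plane, and these regions engulf other variants' lines — distance
  to the surface as a point set identifies nothing. Congruence is therefore
  the minimum over t of the maximum over the remodeled line's samples of
  the distance to the single t-slice member line (point-to-polyline-segment
  distance, so slice discretization does not inflate the metric): the
  remodeled line must coincide with ONE transformed line along its whole
  length.
* **The caliber span is evidence.** The criterion is symmetric: every
  member-line sample must also be near the remodeled line, and the
  remodeled line is sampled out to its occupied bin edges. A variant must
  map the control caliber span onto the observed remodeled span; a family
  whose member line predicts vessels the bed does not contain (or cannot
  reach the bed's smallest/largest calibers) is penalized. In subrange
  analyses (below) the reverse term only sees the analyzed window.
* **Noise-aware band.** Distances are standardized by
  √(SE_pred(x)²·1.25 + floor²) — the remodeled fit's coefficient-based
  prediction SE, inflated 1.25× because an ID error moves the WTh
  coordinate by half as much in the opposite direction, floored at 1% of
  the mean control ID — and a variant is congruent when its standardized
  max distance is ≤ z (default 3). A fixed micrometre tolerance
  (`tolerance=`, e.g. the 2%-of-mean-ID convention) is available and
  switches to a plain max-distance criterion; the standardized band is the
  default because a fixed band either rejects the true variant under
  realistic bin-mean noise or admits neighbors without it. Member lines
  with t < 0.05 are excluded for non-null variants — a line that close to
  control is the null (no remodeling) family's claim, which is always
  evaluated separately.

Gradient defaults for the subtype triples were chosen by separation
analysis of the families' (slope, intercept) slice paths over typical
control lines (ED/ID between ~1.7 and 2.3), subject to each family's sign
constraints: #8/#11 use an ID/ED gradient ratio of (1 + min ED/ID)/2, #15
sits 80% of the way toward its upper feasibility bound (min ED/ID)², and
#17 pairs a firm caliber contraction (g_ED = 0.25) with mild media growth
(g_MCSA = 0.12) because lumen headroom caps the product of the two rates.
Under these defaults, forward simulation of every variant at moderate
deviation followed by congruence testing recovers the generator uniquely in
all 19 noise-free cases (worst runner-up margin ≈ 10× the congruence band)
and in ≥ 95 of 100 replicates with 0.5 μm Gaussian noise on the bin-mean
IDs. Ties, when they occur, are reported as a set ranked by score — never
silently broken. Segmental analyses (e.g. distal ED 10–20 μm vs proximal
30–50 μm behaving differently) run the same test on a caliber subrange.

The 2D companion table transforms the control line by each variant at fixed
t and records the displacement direction of every derived dimension (ED,
ID, WTh, EP, IP, MCSA, LCSA, total area, WLR, EP/IP, MCSA/LCSA) against
caliber. Since each axis admits only three directions, no single 2D
dimension separates 19 variants — the quantitative argument for the 3D
test.

## Synthetic beds

`synthio` emulates the measurement process, not vascular biology:

* **caliber law**: truncated exponential on [10, 50] μm with decay rate
  0.049 μm⁻¹, placing ~45% of vessels in ED 10–20 μm (qualitatively
  matching published accumulated-frequency profiles; no numeric frequency
  tables exist to calibrate against);
* **taper**: ID = 0.45·ED + 1.0 μm by default (a mid-range organ line),
  per-vessel Gaussian ID noise SD 0.5 μm, WTh from the annulus identity;
* **quantization**: ED rounded to 2 μm (the eyepiece-micrometer step at
  40×), ID to 1 μm; a 2 μm step never moves a record across more than one
  5 μm bin boundary;
* **outliers**: 5% of vessels displaced ±6 noise-SDs in ID, emulating
  segments branching at different hydrodynamic points;
* records violating 0 < ID < ED after rounding are resampled, and the same
  spec + seed always reproduces the same bed byte-for-byte.

`apply_variant` applies a variant's transformation record by record — the
identical parameterization the congruence surfaces use — and
`simulate_remodeled_intervals` forward-models the bin means a remodeled bed
would yield (bin supports transformed along with the vessels), optionally
with Gaussian bin-mean noise. Round-trip harnesses use deviation
t = min(0.3, 0.6·t_max) per variant, since several families leave the valid
annulus cone before t = 0.3.

What passing these tests shows — and does not. The generator produces
ideal-annulus, single-population beds whose remodeling follows the
package's own transformation families exactly; recovery there validates the
internal consistency of the pipeline (binning → fitting → classification),
not that real tissue follows one-parameter uniform-scaling families, and
not robustness to segmentation error, oblique sectioning beyond the axis
filter, fixation shrinkage, or mixed remodeling along one tree.

## Numerical choices and limitations

* Problem sizes: synthetic beds of 300–800 vessels (about 3–8× the 80–100
  measurement protocol, for tighter harness statistics), 9 bins over
  10–50 μm, congruence grids of 41 ED × 121 t samples with local t
  refinement; recovery and calibration rates use 100 seeded replicates.
* Congruence resolution: states within ~0.1 μm of a family boundary (e.g. a
  lumen 99.5% collapsed vs the −99% limit) are below the noise-aware band's
  floor and can only be separated in absolute-tolerance mode.
* The ANCOVA comparison and the taper fits assume independent bin means
  with equal variance; the caliber-skewed design makes bin variances
  unequal, so CI coverage of the unweighted fit runs ~2–5 points below
  nominal. ROUT removal trades a further small calibration loss for
  robustness and is off in the parameter-recovery harness.
* RR/TRR assume constant viscosity and segment length, no network
  composition (series/parallel), and no flow or pressure prediction.
* The catalogue classifies direction geometry only; it carries no cellular
  mechanism (hypertrophy vs hyperplasia vs fibrosis), and a bed remodeling
  non-uniformly along its tree will match different variants on different
  caliber segments rather than one number.
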