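# Methods

## The mass-balance model

The package treats the intact polar (IP) ether lipid pool of a seawater
sample as a budget over candidate archaeal producers:

    IP_total  =  Σ_g  cells_g · q_g

with `cells_g` the cell density of group *g* (cells/L) and `q_g` its
per-cell ether lipid quota (ng/cell). All downstream quantities are
rearrangements of this identity:

* **Quota estimation.** Where the amplicon survey detects only
  Thermoplasmatota (MGII/III), attributing the whole pool to them gives the
  per-sample apparent quota `q = IP_total / cells_MGII/III`. Quotas are
  estimated per sample and summarized as range plus arithmetic mean across
  samples (a per-sample ratio, not a pooled regression), because the
  sample-to-sample spread is itself informative.
* **Expected pools and attribution.** For samples where both groups occur,
  expected pools use the published Thaumarchaeota quota
  (1.27 × 10⁻⁶ ng/cell) and the surface-derived MGII/III mean quota; the
  attribution fraction of group *g* is its expected pool over the summed
  expected pools. Groups below 1% relative abundance are excluded from the
  expected pools by default (`BudgetParameters.min_group_fraction`) — their
  contribution is below every other uncertainty in the budget.
* **Inference and detectability.** Dividing a measured pool by a
  hypothesized producer's quota yields the cell density that producer would
  need. Converting it to a relative abundance against the ddPCR total and
  comparing with the per-sample detection limit (one read,
  `100/read_depth` %) yields a verdict: `detectable` means absence from the
  sequencing data is evidence against that producer, not a sensitivity
  limit. All comparison boundaries in the package are inclusive (≥), so
  ties behave deterministically.
* **Membrane fraction.** Quotas are also expressed against the theoretical
  whole-membrane lipid content of a 500-nm archaeal cell
  (1.4 × 10⁻⁶ ng/cell), bounding how much of the producer's membrane the
  measured compounds could represent.

Samples in which no compound passed quantification are "control-like": they
are reported but excluded from quota summaries.

## Lipid quantification

Single-point internal-standard quantification,
`conc = (A/A_IS) · RF · m_IS / V` (ng/L; areas in arbitrary units, `m_IS`
in ng, `V` in L). The formula places the response factor so that RF > 1
means the analyte responds more weakly than the C46 standard. Exactly two
response factors are applied: 1.5 for all tetraethers (calibrated on
crenarchaeol) and 4.0 for archeol. The C46 response is taken per record
(per sample/fraction), not averaged across a run.

Reporting rules, chosen to preserve information rather than hide it:

* SN < 5 ⇒ the peak contributes zero but carries a distinct `failed_sn`
  flag (distinct from `below_loq`, so a user can revisit near-threshold
  peaks).
* Computed concentration < LOQ (0.00060 ng/L) ⇒ the value is reported as-is
  with a `below_loq` flag, not zeroed.
* Multiple adducts for one compound ⇒ the maximum-area adduct is used
  (deterministic and conservative; summation is not assumed).
* IP = total − core per compound may be negative (fraction-specific matrix
  effects); negatives are kept per compound and clamped to zero only when
  summing `ip_total`, which therefore is order-invariant and never negative.

Head-group-specific GDGT forms (MH/DH/PH/HPH) have no authentic standards;
they are reported as within-class relative peak-area distributions only.
TEX86 = (GDGT-2 + GDGT-3 + cren′) / (GDGT-1 + GDGT-2 + GDGT-3 + cren′); a
zero denominator raises `UndefinedResultError` rather than returning 0.

## Community quantification

Absolute abundances are the ddPCR total multiplied by per-group read
fractions; the total is conserved exactly across groups. Copies convert to
cells at one SSU rRNA copy per cell (configurable), appropriate for marine
planktonic Thaumarchaeota and Thermoplasmatota. Shannon diversity uses the
natural logarithm; rarefaction subsamples without replacement via exact
multivariate hypergeometric draws with an explicit seed.

## Statistics

Bray-Curtis, NMDS and the Mantel test are implemented in the package rather
than delegated, and cross-checked in the tests against scipy, scikit-learn
and scikit-bio:

* **Bray-Curtis** `Σ|x−y| / Σ(x+y)`; not scale-invariant, so community rows
  are converted to relative abundances before distance computation. The
  lipid-side feature vector concatenates the relative total-lipid
  composition with the per-head-group-class relative distributions.
* **NMDS** minimizes Kruskal stress-1
  `sqrt(Σ(d − d̂)² / Σ d²)`, `d` the configuration distances and `d̂` the
  isotonic (pool-adjacent-violators) regression of `d` on the input
  dissimilarities. Ties use the primary (weak) approach: tied
  dissimilarities are pre-sorted by configuration distance so they do not
  force pooling. Optimization is the iterated Guttman transform, best of 20
  random restarts (seeded), `max_iter` 300, `tol` 1e-6 on the stress
  decrease. A monotone safeguard rejects any update that would increase
  stress and stops there, so the recorded stress history is non-increasing
  by construction; the final stress always equals a direct evaluation of
  the stress formula on the returned coordinates. Degenerate all-equal
  dissimilarities yield a warning and `converged_ = False`.
* **Mantel** correlates the strictly-upper triangles and permutes the rows
  and columns of the second matrix jointly; the one-tailed (positive
  association) p-value uses the +1 correction, so with 999 permutations the
  smallest attainable p is 0.001. Permutations are vectorized; a constant
  matrix raises `UndefinedResultError`.

## Synthetic data generator

The generator emulates a stratified oligotrophic euphotic zone sampled at 9
depths (5–200 m, DCM at 120 m; two stations by default, 18 samples):

* **Community.** Above the DCM: MGII 72%, MGIII 26%, trace minor groups,
  Thaumarchaeota a structural zero. Within/below: Thaumarchaeota 40%,
  MGII 36%, MGIII 22%, Halobacterota 0.8% (kept under the 1% exclusion
  threshold on purpose). Per-sample compositions get Dirichlet jitter
  (concentration 200); AASV counts are multinomial at read depths uniform
  in 1,695–40,915; ddPCR totals are uniform in 2.11–6.02 × 10⁶ copies/L
  above the DCM and 4.0 × 10⁶–1.22 × 10⁷ below.
* **Lipids.** True IP pools are cells × quota (Thaumarchaeota
  1.27 × 10⁻⁶, MGII/III 1.21 × 10⁻⁹ ng/cell) spread over compounds by
  per-taxon signatures (crenarchaeol-dominated for Thaumarchaeota,
  GDGT-0-dominated for Thermoplasmatota, archeol a minor component of
  both). The hydrolyzed-fraction total is IP / ip_fraction with
  core-lipid-dominated surface pools (30% IP above the DCM, 60% within/
  below); this reproduces the ~100–1000× lipid contrast across the DCM.
* **Noise.** Peak areas invert the quantification formula and receive
  multiplicative lognormal noise (σ = 0.20, a typical LC-MS analytical
  spread); the non-hydrolyzed fraction receives an extra matrix-effect
  σ = 0.30, drawn independently, which makes the core-dominated above-DCM
  subtractions go negative in roughly a fifth of compound measurements —
  the behaviour the clamp rule exists for. The SIM noise floor is set so a
  5 × 10⁻⁵ ng/L peak has SN exactly 5: below the LOQ, so near-LOQ peaks can
  pass the SN filter and be flagged `below_loq` instead of vanishing.
* **Determinism.** Identical config + seed gives byte-identical tables.

What the generator does *not* emulate: chromatographic artifacts,
compound-dependent response drift, chimeras or taxonomy misassignment,
lipid export/packaging dynamics, or depth-continuous gradients (clusters
are homogeneous apart from the sampled noise). Recovery tests on this
generator therefore validate the inference arithmetic and its robustness to
multiplicative noise and count subsampling — not the analytical chemistry.

Note that even with both lipid noise terms at zero, the amplicon channel
keeps its multinomial read noise: quotas recovered against *sequenced*
abundances match truth to ~1% at typical read depths, while recovery
against the generator's true cell densities is exact to floating precision.

## Problem sizes

The default dataset (18 samples) drives the structural and pipeline tests.
Quota-recovery uses 200 samples (≈110 above-DCM); the Mantel null
calibration uses 1,000 replicate 10-sample tests at 999 permutations each.
These sizes give comfortably stable medians and rejection rates while
keeping the whole suite around ten seconds.

## Known limitations

* The quantification formula beyond "relative to the internal standard"
  (RF placement, per-record C46 response, max-area adduct rule) is a
  defensible convention, not a measured calibration; alternatives rescale
  concentrations by a constant factor and cancel in every ratio the budget
  reports.
* Attribution assumes the quota map is complete: an unmodelled producer
  inflates the quotas of the modelled ones.
* The copies→cells conversion ignores rRNA copy-number variation beyond the
  single configurable factor.
* NMDS finds a local optimum; restarts mitigate but do not guarantee the
  global one (the stress-consistency check holds regardless).
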