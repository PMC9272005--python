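# Methods

`glyi` curates a durum-wheat glyoxalase I (GLYI, lactoylglutathione lyase,
EC 4.4.1.5) gene family from an annotated catalog and models the enzyme's
biochemistry: hemithioacetal equilibrium, Michaelis–Menten and competitive
inhibition kinetics, 2^-ΔΔCt expression quantification, and the
methylglyoxal/glutathione assay arithmetic. This note records the models,
the defaults, and the design decisions taken where the problem left room.

## Family catalog

The catalog is a genes → transcripts → proteins tree serialized as a flat
TSV (one row per splice variant). Coordinates are 1-based inclusive
throughout. Two structural invariants are enforced at load time: CDS
length is a positive multiple of 3, and the protein length equals
CDS/3 − 1 (the stop codon encodes no residue). The shipped family table
carries 27 genes and 60 splice variants; summary statistics (multi-splice
genes are those with strictly more than one transcript; the CDS mean is
reported exact and rounded to the nearest integer) are recomputed from the
rows, never stored.

Molecular weight uses average (not monoisotopic) residue masses plus one
water; the residue table is an argument so alternative mass sets can be
swapped in. The isoelectric point solves the Henderson–Hasselbalch net
charge for zero by bisection on pH ∈ [0, 14] to 1e-4; the default pKa set
is the EMBOSS-style one (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1,
H 6.5, K 10.8, R 12.5, Y 10.1). The MW/pI columns of the shipped table
were produced upstream by a commercial package whose mass/pKa tables are
unpublished, so the calculators are validated against their own closed
forms and an independent library route, not against those columns.

## Curation pipeline

1. **Domain filter.** A candidate is dropped when it has no PF00903
   (lactoylglutathione-lyase) domain annotation or when its longest domain
   is shorter than `min_domain_len` = 100 aa. The observed family splits
   cleanly — rejected fragments span 76–97 aa, kept domains start at
   119 aa — so 100 sits in the gap; it is configurable.
2. **Reference anchoring.** The N-terminal qualifying domain is aligned
   globally (Needleman–Wunsch with affine gaps, Gotoh recursion) against
   each reference profile. Scoring is BLOSUM62 with gap cost
   `open + extend·L` (open 10, extend 0.5), and traceback ties are broken
   deterministically: diagonal, then gap-in-candidate, then
   gap-in-reference. The alignment yields a reference→candidate position
   map used to read off the candidate residue under each conserved site.
3. **Site check.** Seven sites are tested for exact residue identity (no
   conservative-substitution credit, matching the binary Present/Absent
   bookkeeping of the source table): four metal-coordination residues
   (human-type Q34/E100/H127/E173; bacterial-type H5/E56/H74/E122), two
   GSH-binding residues (R38/N104 homologs) and the dimer-interface
   glycine (G106 homolog; the other interface residues are not positionally
   conserved and are not tested). The first metal site accepts Q or H — it
   is the cofactor discriminator. The profile with the most matching metal
   sites (ties: total matches, then alignment score) decides.
4. **Metal call.** H at the discriminator → Ni²⁺-dependent; Q plus domain
   length ≥ `zn_len_threshold` = 140 aa → Zn²⁺-dependent. The Zn-specific
   insertion region is not sequence-specified, so domain length stands in
   for it; a Q-type domain below 140 aa is left uncalled (and therefore
   inactive), while an H-type domain above 140 aa only draws an advisory
   note. A variant is *active* iff metal, GSH and dimer checks all pass;
   inactive variants carry no metal call.
5. **Architecture and localization.** Qualifying-domain count groups
   variants as one- or two-domain (only the N-terminal domain is
   site-checked; the C-terminal copy of two-domain plant GLYIs is
   degenerate). Localization consensus merges labels from external
   predictors (vocabulary Cyt/C/M/−, multi-label cells split on "/"):
   a variant supports a compartment listed by any tool, and is counted as
   *organellar* when it supports chloroplast or mitochondrion **and** no
   tool places it in the cytoplasm. The cytoplasm-exclusion clause is what
   reproduces the published per-gene organellar counts (7/3/2/2 for the
   four named genes; 17 organellar variants over five genes in total);
   a plain "any tool lists C or M" rule would overcount tool-discordant
   variants.

### Reference profiles

The packaged rule file is YAML: per profile a domain sequence, the seven
site positions with expected residues, and the metal type; plus thresholds
and scoring. The true human/E. coli reference sequences are not
redistributed; the shipped `reference_profiles.synthetic.yaml` carries
**synthetic** surrogate domains — fixed-seed random backbones with the
diagnostic residues planted at the documented positions (180 aa Zn-type,
130 aa Ni-type, so the length rule discriminates correctly). Every
positional rule behaves exactly as with the real references; no claim is
made about sequence-level agreement with them. Users with the real domain
sub-sequences can supply their own rule file.

## Hemithioacetal equilibrium

MG + GSH ⇌ HA with Kdiss = [GSH_free][MG_free]/[HA] (default 3.0 mM; all
concentrations mM). The forward solve takes the smaller root of
x² − (MG_t + GSH_t + Kdiss)x + MG_t·GSH_t = 0 in the cancellation-free
form 2·MG_t·GSH_t/(b + √(b² − 4·MG_t·GSH_t)) — stable when Kdiss dwarfs
the totals — and derives free species by mass balance so the balances hold
exactly. The larger root always violates HA ≤ min(totals) and is asserted
away, not assumed. The inverse design (target HA at fixed free GSH) is
closed-form and round-trips through the forward solve to 1e-9 relative
over h ∈ [1e-3, 10] × g ∈ [0.01, 10] mM. Formation kinetics are not
modelled; the 30-min pre-incubation is treated as equilibrated.

## Enzyme kinetics

Absorbance slopes convert to specific activity via Beer–Lambert:
|slope|/(ε·path)·volume/protein, with ε = 2.86 mM⁻¹cm⁻¹ for S-LG at
240 nm (0.4 mL standard assay) and ε = 13.6 mM⁻¹cm⁻¹ for TNB at 412 nm in
the glutathione recycling assay. The slope magnitude is used; the reaction
direction (absorbance increase on HA → S-LG) is a documentation matter,
not a sign flip in the arithmetic.

The primary estimator is untransformed nonlinear least squares of
v = Vmax·S/(Km + S) (and of the competitive model
v = Vmax·S/(Km(1 + I/Ki) + S)), started from a Hanes linearization.
The four classical linearizations are provided as diagnostics only —
on exact data all four agree with the NLS values to 1e-9, and this
cross-method agreement is the property the tests pin down; no pooled
averaging across plots is applied by default because the pooling weights
used upstream are unspecified.

Dixon analysis fits 1/v versus I per substrate series; for a competitive
inhibitor the lines meet at I = −Ki. Ki is taken from the least-squares
common intersection (the point (x\*, y\*) minimizing Σ_S (a_S + b_S x − y)²,
a closed-form 2×2 solve), with a global competitive-model fit always
reported alongside; on exact data the two agree to 1e-6, under noise they
are mutually consistent Monte-Carlo estimators. Parallel lines (the
non-competitive pattern) have no finite intersection and raise a
diagnostic error. Km is mM internally and µM in display.

Metal activation is an ordinary least-squares line of percent activation
versus dose over the assayed 0.125–1.5 mM Zn²⁺ range; the intercept is
reported as fitted, never forced through zero, and predictions outside the
dose range warn.

## Expression quantification

2^-ΔΔCt with multiple reference genes (default CDC and RLI): technical
replicates are averaged first; ΔCt = Ct_target − mean(Ct_references)
per sample (the arithmetic mean of Cts equals the geometric mean of linear
quantities); ΔΔCt subtracts the mean calibrator ΔCt per gene within each
stratum of the non-calibrator grouping columns, so the calibrator group's
mean log-fold is exactly zero by construction. Amplification efficiency is
fixed at 2.0 (plain 2^-ΔΔCt); an efficiency-corrected base is available
but off by default. Because both calibration schemes used upstream occur
(tissue-wise control calibration; shoot-vs-root calibration), the
calibrator is an explicit {column: value} argument rather than a
hard-coded condition. Biological replicates (n = 3 in the emulated
design) carry the dispersion.

Group comparison: fixed-effects one- or two-factor ANOVA (statsmodels
OLS), pairwise decisions by Duncan's multiple range test built from
scipy's studentized-range quantiles with per-range protection level
α_p = 1 − (1−α)^(p−1), harmonic-mean group size for unbalanced designs,
and the standard step-down rule that a range nested in a non-significant
wider range is never significant. Letters summarize homogeneous subsets;
two groups reduce to an LSD-style comparison whose decision coincides
with the pooled-variance t-test at the same α. All-constant input is a
degenerate-variance error rather than a spurious "all different".

## Assay quantification

MG: unweighted OLS calibration with intercept (zero is not forced) over
the 0.5–30 µM standards; inverse prediction, dilution factor, extract
volume and fresh weight give µmol g⁻¹ FW. Predictions outside the
standard range are flagged as extrapolations; negative inverse predictions
clip to zero with a warning. Glutathione: GSH = total − GSSG in the
assay's own bookkeeping (the alternative 2-GSH-equivalents stoichiometry
is a documented ambiguity, left to the caller's calibration standards);
the GSH/GSSG ratio is undefined at zero GSSG. VPD interference is a
protocol note (VPD-treated GSSG standards), not a computation. Pearson
correlation comes from scipy (t-transform p, n − 2 df); the published
MG–activity correlation coefficient is not reproducible because the
per-sample data are unprinted, so the tests exercise the capability on
synthetic correlated series only.

## Synthetic data

Generators are pure functions of their seed (one `numpy` Generator per
call; the seed is recorded in every truth table).

* **Protein families** embed a reference domain in uniform-random flanking
  sequence (flanks 5–40 aa, recorded spans). Defaults mirror the curated
  family: 54 candidates, 28 active (23 Ni / 5 Zn), 17 of the active
  two-domain (the C-terminal copy carries a knocked-out metal residue, as
  in plant two-domain GLYIs). Inactive records get 1–7 planted site
  mutations (to alanine, which no site expects) or a 60–99 aa truncated
  domain that the length filter must catch. Counts are exact by
  construction, assignments shuffled by the seed.
* **Kinetics** evaluates the (competitive) rate law on the study's designs
  — the 12-point 0.025–1 mM HA series and the 4×5 Dixon grid
  (HA 0.1/0.25/0.5/1 mM × free GSH 0.2/1/5/10/15 mM) — around the
  mitochondrial ground truth (Vmax 0.519 µmol min⁻¹ mg⁻¹, Km 0.092 mM,
  Ki 6.5 mM), adding N(0, σ·Vmax) noise truncated at zero.
* **Ct tables** emulate the expression design (9 genes × 3 conditions ×
  2 tissues × 3 biological × 3 technical replicates): baselines uniform in
  18–30 cycles per gene × tissue, a planted log2 effect lowers the target
  Ct by that many cycles, a per-sample shift (SD 0.3 cycles) emulates
  plate/loading offsets that ΔCt must cancel, technical noise N(0, 0.1)
  cycles by default.

What the generators do **not** emulate: amplification-efficiency
differences between genes, primer-dimer/melt artefacts, heteroscedastic
rate noise, alignment-ambiguous domain boundaries, or real sequence
homology between family members (flanks are i.i.d. uniform). Passing
tests therefore demonstrate correctness of the arithmetic and the
decision rules under the stated noise models, not robustness to those
real-data pathologies.

## Problem sizes and numerical choices

The Monte-Carlo calibration uses 200 replicates of the 36-point
(12 S × 3 replicates) design at 2% noise — enough for the 3-SE
unbiasedness check to be meaningful while the full suite stays fast.
The brute-force alignment oracle enumerates every gapped alignment for
pairs up to length 6 over a 4-letter alphabet; the property test samples
that space (seeded/derandomized) rather than enumerating all ~30M ordered
pairs. Bisection tolerance for pI is 1e-4 pH units; equilibrium
invariants are enforced to 1e-9 relative; curve fits report scipy
covariance-based standard errors.

## Known limitations

* Agreement with the upstream MW/pI columns is plausibility-level only
  (≈110 Da/residue), since the upstream mass/pKa tables are unpublished.
* The reference profiles are synthetic surrogates; runs against real
  candidate proteins require a user rule file with the true domain
  sub-sequences.
* The Zn/Ni call uses domain length as a proxy for the Zn-specific
  region; borderline-length Q-type domains are conservatively uncalled.
* Duncan letters are computed on cell means with a pooled MSE; random
  effects and repeated measures are out of scope.
* `classify run` on bare FASTA treats the whole sequence as the domain;
  with annotated domain spans (the library route) alignment quality is
  higher.
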