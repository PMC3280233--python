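# Methods

This note documents the models behind each pipeline stage, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the known limitations. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Backbone hydrogen bonds and wrapping (structure module)

**Bond detection.** Protein structures rarely include hydrogen positions,
so backbone hydrogen bonds are detected with a heavy-atom geometric
criterion: donor backbone N of residue *i*, acceptor carbonyl O of residue
*j*, N–O distance ≤ 3.5 Å, in-chain separation |i−j| ≥ 2, and carbonyl-side
angle C(j)=O(j)···N(i) ≥ 120°. Each donor N reports at most one bond (the
shortest N–O distance wins), and proline contributes no donor — its
backbone nitrogen carries no amide hydrogen. The 120° angular cutoff is the
conventional lower bound for carbonyl-accepting hydrogen bonds; a more
permissive 90° admits a spurious i→i−3 contact at the N-terminus of an
ideal α-helix (N–O 3.21 Å, angle 111°) that no hydrogen-aware criterion
would accept. All cutoffs are keyword-configurable; inter-chain bonds are
off by default (the analysis targets free subunits) behind a flag.

**Wrapping ζ.** For each bond, ζ counts nonpolar side-chain carbons inside
the union of two spheres of radius 6 Å (≈ three water layers) centred at
the two α-carbons; a group in the lens-shaped intersection counts once. A
"nonpolar group" is a side-chain carbon with no covalent bond to N, O or S
in the standard residue topology — aliphatic and aromatic CHₙ carbons
count; Ser/Thr/Cys Cβ, carboxylate, amide and guanidinium carbons, and
ring carbons flanking ring nitrogens do not. The per-residue lookup table
ships in `structure.NONPOLAR_SIDECHAIN_CARBONS`. Side chains of residues
with incomplete backbones still wrap neighbouring bonds; such residues are
only excluded as donors/acceptors.

**Dehydrons and ν.** A bond is a dehydron iff ζ ≤ 19 (configurable); in
soluble-protein surveys this threshold sits roughly one standard deviation
below the population mean wrapping. Per gene, ν = Σdehydrons / ΣBHBs with
counts pooled by summation across all product structures before dividing —
a ratio of pooled counts, not a mean of per-structure ratios, so larger
structures weigh more, which is what a quotient "over all gene products"
means. ν is undefined (an error, never 0) when a gene has no detected BHB.

## Disorder-based inference (disorder module)

For genes without solved structures, ν is inferred from per-residue
disorder scores f_d ∈ [0,1] produced by an external predictor (consumed as
input; no predictor is bundled). Residues with 0.35 ≤ f_d < 0.95 (lower
bound inclusive, upper exclusive) are dehydron-prone — the order–disorder
twilight zone corresponding to marginal wrapping. Genes containing a run of
≥ 30 consecutive residues with f_d ≥ 0.95 are excluded entirely: without
sustainable structure there is nothing to wrap. The 30-residue window is a
conventional long-disorder length; it is a free parameter here because no
canonical value exists for this filter.

ν_seq is the band fraction among ordered residues (f_d < 0.95). This
aggregation from residue flags to a per-gene ratio is an explicit stand-in
(the simplest monotone surrogate consistent with the twilight-zone
picture), is labelled as `nu_seq` in all outputs, and is never
cross-asserted against the structural ν — the two need not agree
numerically.

## Synonymous divergence (divergence module)

Paralog pairs are aligned at the protein level (global alignment, match +1,
mismatch 0, gap −1) and back-threaded onto codons; gap columns are excluded.
Ks is estimated by Nei–Gojobori (1986) counting: per codon position, the
synonymous site fraction is the share of the three single-nucleotide
changes that are synonymous (changes creating stops are counted in the
denominator, never as synonymous); codons differing at k positions are
resolved by averaging over the k! substitution pathways, dropping pathways
that cross a stop codon (all pathways are used in the rare case that every
one does). With p_s = synonymous differences / synonymous sites,

    Ks = −(3/4)·ln(1 − (4/3)·p_s),

undefined at p_s ≥ 3/4: saturation raises an error rather than returning a
number. Family Ks is the arithmetic mean over its pairs' finite values
(saturated pairs dropped first); families at Ks ≥ 2 fail the saturation
filter and are excluded downstream. The mean (rather than median or
maximum) is recorded in output metadata as the aggregation rule. A
maximum-likelihood codon model would be more accurate at high divergence,
but the analysis uses Ks only as a monotone divergence-time proxy, for
which counting methods suffice; transition/transversion and codon-frequency
corrections are deliberately out of scope.

**Known bias at high divergence.** Under a synonymous-only substitution
process, two-fold degenerate positions are 2-state: their pairwise
difference probability saturates at 1/2 per position, i.e. 3/2 per NG86
site — above the 3/4 ceiling the Jukes–Cantor correction assumes. The
correction therefore over-inflates at large distances: analytically ≈ +16%
at a true divergence of 1.0 (and the suite measures ≈ +18% there), while
recovery at 0.1 and 0.5 is within a few percent. This is a property of
NG86+JC itself — an independent reference implementation returns identical
per-pair values — and is the reason the estimator-recovery check fails its
10% band at the highest planted divergence.

## Expression diversification and segregation (expression module)

η is the exact Pearson product-moment coefficient of two expression vectors
over ≥ 3 shared observed conditions. Values are used as provided (the bare
formula), with an optional log2(x+1) transform behind a flag. Pairs with a
zero-variance vector are *excluded*, not set to η = 0 — an undefined
correlation must not masquerade as orthogonality. ⟨η⟩ is the unweighted
mean over all unordered member pairs with defined η, and S = (1 − ⟨η⟩)/2
maps [−1, 1] onto [1, 0]. Missing values are handled per pair over the
intersection of observed conditions; pairs sharing fewer than 3 are
excluded.

## Family analysis (analysis module)

Records join per-gene ν (family ⟨ν⟩ = mean over members), family ⟨η⟩/S,
family Ks and WGD labels (a family is WGD-flagged when any member pair
appears in the label list). Families failing any upstream filter are
dropped with a per-family reason code, and drop counts are logged.

The statistical surface:

- **Regression** of y = Ks·⟨ν⟩ on a degree-1 or degree-2 polynomial in ⟨η⟩
  (ordinary least squares; the response is the literal product, no other
  normalisation is fitted). Both degrees are always reported — the linear
  fit is the headline for low-selection-efficiency cohorts, the quadratic
  accommodates the sharper response expected under efficient selection —
  with coefficients in ascending powers, R², and the F-test p-value of the
  overall fit (the F-test is the labelled choice; no other test is
  implied).
- **Binned segregation**: mean S/Ks in ten fixed-width ⟨ν⟩ bins, half-open
  [lo, hi) with the final bin closed at 1.0; empty bins are missing, never
  zero. Zero-Ks families are excluded upstream (S/Ks undefined).
- **WGD flatness**: within the WGD subset (≥ 10 records required), the OLS
  slope of S/Ks on ⟨ν⟩, with a two-sided permutation p-value from 10,000
  seeded shuffles of ⟨ν⟩ across records:
  p = (1 + #{|slope_perm| ≥ |slope_obs|}) / (n_perm + 1). Permutation was
  chosen over a parametric slope test to avoid distributional assumptions
  on S/Ks; the statistic is vectorised, so the default 10,000 draws cost
  milliseconds at cohort sizes.

## Synthetic data (simulate module)

The generators produce every input format the pipeline consumes, with the
planted truth recorded in `truth.json`. All are deterministic given their
seed, and a cohort's randomness derives from the single spec seed.

- **Helix fixtures**: ideal α-helix backbone (φ = −57°, ψ = −47°, standard
  bond geometry) of Gly, Ala or Leu with idealised side chains
  (χ₁ ≈ −60°, χ₂ ≈ 175° for Leu); an optional per-atom Gaussian jitter
  (default 0) yields families of perturbed fixtures for oracle-equivalence
  testing. These probe the geometry code; they are not realistic folds, so
  absolute ζ values are not representative of globular proteins.
- **Expression families**: member vectors drawn from a multivariate normal
  with exchangeable correlation ρ = target η (valid for ρ > −1/(m−1)),
  mean 8, SD 2 in arbitrary expression units, globally shifted to
  non-negativity (a global shift leaves every Pearson coefficient
  unchanged). Real tissue panels are heavy-tailed and heteroskedastic;
  passing tests show correct behaviour of the correlation machinery, not
  robustness to microarray noise models.
- **Codon pairs**: a random sense-codon ancestor; each lineage accumulates
  a Poisson number of synonymous-only substitutions with mean
  true_Ks/2 × (ancestral synonymous sites), each event replacing a codon
  (picked proportionally to its count of synonymous single-nucleotide
  neighbours) by one such neighbour uniformly. Stops can never arise.
  Synonymous-only evolution keeps the true divergence exactly controlled at
  the cost of the two-fold-site saturation mismatch described above.
- **Cohorts**: per family, a target η is drawn from `eta_range`, the
  expression matrix generated, and the *realised* ⟨η⟩ recomputed with the
  same operation the pipeline uses; SSD families then receive
  ⟨ν⟩ = (a + b·⟨η⟩ + ε)/Ks with ε ~ N(0, noise_sd), so at noise 0 the
  downstream fit returns (a, b) with R² = 1 exactly. WGD families draw ⟨ν⟩
  uniformly on [0.05, 0.95], independent of everything else. A relation
  that forces ⟨ν⟩ outside [0, 1] raises an error — no silent clipping; with
  noise, a family's ε is redrawn (at most 100 times) before erroring, a
  truncation that is negligible under the default ranges (≥ 4σ of margin).

Default cohort conditions: 500 families × 3 members over a 20-condition
panel (between the handful of phases of a yeast time course and a
73-tissue human atlas), η targets in (−0.3, 0.8), relation
(a, b) = (0.55, −0.35) — the negative slope encodes "more dosage-sensitive
families segregate more" — noise SD 0.05, Ks ~ U(1.2, 1.9) (inside the
saturation filter), WGD fraction 0.2. Under this relation the SSD subgroup
carries an S/Ks-vs-⟨ν⟩ trend of exactly −1/(2b) per family (≈ +1.43),
attenuated in the fitted slope by the planted noise, while the WGD subgroup
is flat — the contrast the control test quantifies.

## Verification sizes

The statistical suites run at: 100 jittered helices (oracle equality on
every bond); 1000 random affine-invariance cases; 200 replicates × 300
codons per planted divergence; 100 cohorts × 500 families for CI coverage
of the planted slope; 200 all-WGD cohorts for permutation-p uniformity
(Kolmogorov–Smirnov) plus 100 mixed cohorts for the flat-WGD /
recovered-SSD contrast; 200 simulated null cohorts for the type-I error of
the permutation test. These sizes give comfortable binomial/KS resolution
for the asserted bounds while keeping the default test run fast.

## Limitations

- No mmCIF input, hydrogen placement, side-chain reconstruction, DSSP-style
  energetics, or nucleic-acid chains; altloc handling keeps the
  highest-occupancy conformer only.
- ν_seq depends on an external disorder predictor's calibration; the band
  fraction is a surrogate, not a validated regression onto structural ν.
- NG86+JC underlies all Ks values: adequate as a monotone time proxy below
  saturation, upward-biased near it (see above), and blind to
  transition/transversion and codon-usage effects.
- Real-data effects the cohorts do not emulate: probe-to-gene mapping
  noise, cross-platform batch effects, codon-usage bias, indels, gene
  conversion between paralogs, and intra-family obligatory complexes
  (which would force co-expression).
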