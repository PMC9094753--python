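# Methods

This note documents the models, conventions and parameter choices behind
each stage of the package, what the synthetic-data generators do and do
not emulate, and the known limitations.

## Sequence conventions and qtRNA construction

Codons and mRNA are handled in the DNA alphabet (ACGT), tRNA sequences
in the RNA alphabet (ACGU); the only conversion is T↔U at the
codon/anticodon boundary, so `codon_to_anticodon` is reverse complement
plus transcription and is an exact involution with `anticodon_to_codon`
over all 256 quadruplets.

All indices are 0-based with half-open windows. tRNA position labels
(32–38) are *annotations carried by the scaffold*, supplied with the
input (FASTA + TSV sidecar); the package never infers cloverleaf
structure. A qtRNA is built by replacing the three-base anticodon
(positions 34–36) with the four-base anticodon (34, 35, 35.5, 36), a net
+1 length change; the qtRNA's 37/38 indices are therefore recomputed at
+1 relative to the scaffold. Point-insertion codons follow the XYZZ /
XYYZ patterns (duplicate the third or second base of the original
triplet codon). Where the extra base is "inserted" mechanistically is
not modeled — only the resulting anticodon matters for every downstream
computation, so anticodon replacement is the implemented end state.

Names render as `qtRNA-<ThreeLetterAA>-<CODON>`, with the initiator
methionine as `fMet`. The default registry holds 21 scaffolds (20
canonical isoacceptor classes + fMet) with the canonical first-listed
E. coli anticodon per class; the sequence bodies are deterministic
synthetic stand-ins (`make_toy_scaffold`), which is sufficient because
every operation acts only on the annotated anticodon loop. Degenerate
enumeration supports fully random (N) positions only; the loop-side
library randomizes positions 32/37/38 of a *qtRNA* (a base codon must be
given), while the NNNN library randomizes the anticodon of the scaffold
directly.

## Readthrough efficiency and growth defect

Luminescence is compared at a common culture density to compensate for
differential growth: the *first* upward crossing of OD600 = 0.5,
linearly interpolated in time (first-crossing because the monotone
growth phase is the intended regime). Percent efficiency is
100·(QuadLum_induced − QuadLum_uninduced)/(TriLum − QuadLum_uninduced);
values may legitimately be negative when toxicity depresses the induced
signal. Efficiencies are computed per replicate and then averaged
(preserving replicate-level variance); the triplet-control normalizer
TriLum is the mean over control replicates, treated as a single
normalizer. Because every replicate shares that normalizer, the
replicate SD understates plate-to-plate spread — noticeable in the
worked example. Replicates whose cultures never reach the OD threshold
are excluded and flagged rather than raising.

Growth defect is the ratio OD_induced(t*)/OD_uninduced(t*) at the time
t* when the induced culture first reaches OD 0.5; if it never does, t*
falls back to the final time point and the result is flagged. The
fractional density difference 1 − ratio is also exported alongside.
Inputs are assumed blank-corrected. Reporter position (residue 1 for
fMet reporters vs 357 otherwise) is metadata only and never branched on.

A qtRNA row of a crosstalk matrix is called orthogonal when its
on-target mean efficiency exceeds every off-target entry by a
configurable factor (default 3×).

## Selection enrichment

Reads are matched by exact string search for the constant flanks
(default 10 nt) bounding the randomized window; the window must have the
exact expected length and ACGT randomized bases, otherwise the read is
discarded and counted as such (losses stay visible; no alignment or
error correction — reasonable for short constant flanks at Illumina
error rates). Reverse-complement matching is attempted when the forward
strand fails (on by default).

Per-member enrichment is log10 of the Laplace-smoothed frequency ratio,
((c_post+ψ)/(N_post+ψK)) / ((c_pre+ψ)/(N_pre+ψK)) with ψ = 1 and K
members — finite for zero counts at typical depths and exactly
antisymmetric under phase swap. Log base 10 throughout (titers and
enrichment plots are decade-scaled). Library classification uses
documented, configurable thresholds: SINGLE_DOMINANT when the top
member is ≥ 1.0 log10 enriched *and* leads the runner-up by ≥ 1.0
log10; NO_PRESSURE when no member moves ≥ 0.5 log10; otherwise
POSITIONAL_PREFERENCE when some randomized position carries one base in
≥ 75 % of post-selection reads. Because "enriched far above all other
variants" can be read as the member's own enrichment or its gap to the
runner-up, both are reported. Titer ranking passes selections whose
post/pre ratio strictly exceeds 10.

## Charging quantification

Trypsin specificity is cleavage C-terminal to K or R except before P;
the 0-missed-cleavage peptides concatenate back to the protein, and
missed-cleavage variants are merged runs of adjacent peptides. The
"straddling" peptide for a site is the peptide *containing* that
residue; when a variant introduces K or R at the site, the site becomes
the C-terminus of the N-terminal cleavage product, which is then the
straddling peptide. Such boundary changes set `digest_altering`: AUC
comparisons across different peptides mix different ionization
efficiencies, which is not corrected (a documented limitation of the
AUC approach itself).

Masses are monoisotopic residue sums plus one water (18.010565 Da),
delegated to pyteomics' residue table; fixed modifications are accepted
as per-residue offsets (off by default). Features below the
limit of detection (default 10⁴ AU, an instrument floor) are censored;
remaining areas are normalized to fractions over the detected set.
Mass-only features are assigned at 10 ppm tolerance, with variants
indistinguishable at that tolerance reported as one ambiguity group
(Leu/Ile always; Gln/Lys resolve below ~3.6 kDa). Charging is
SELECTIVE_COGNATE when the cognate fraction is ≥ 0.75,
SELECTIVE_NONCOGNATE when another single variant reaches 0.75,
PROMISCUOUS when two variants each exceed 0.2, else UNDETERMINED; the
0.75/0.2 cutoffs are package choices (the underlying categories have no
canonical numeric definition) and are configurable.

## Synthetic-data generators

One master seed fans out to per-generator substreams through
`numpy.random.SeedSequence.spawn`, so all outputs are bit-reproducible
and stages can be tested independently.

* **Plates.** OD(t) = K/(1 + ((K−od0)/od0)e^(−rt)) on a 10-min grid over
  8 h; defaults od0 = 0.01 (≈1:500 dilution of an overnight culture),
  r = 0.9 h⁻¹, K = 1.2 — typical rich-medium E. coli kinetics. Induction
  toxicity scales the induced-well rate by (1 − toxicity). Luminescence
  is background + amplitude · efficiency · OD with multiplicative
  log-normal noise of a given CV (unit mean); efficiency is the
  configured fraction for induced quad wells, 0 uninduced, 1 for the
  triplet control. This luminescence model is a testing instrument, not
  a biological claim: it omits reporter maturation lag, substrate
  depletion and autoluminescence drift, so passing recovery tests
  demonstrates correctness of the analysis arithmetic, not robustness to
  those real-data effects.
* **Selection reads.** Pre-selection reads are multinomial-uniform over
  the library; post-selection reads are multinomial with given weights;
  each read is flank5 + member window + flank3, exactly `depth` reads
  per phase. Default random weights are Dirichlet with concentration
  α = 0.5: phage selections are winner-take-most, and a sparse,
  heavy-tailed weight vector (members spread over several decades)
  emulates that regime. An optional per-base substitution rate exercises
  the discard accounting. Phage population dynamics across passages are
  not simulated.
* **Chromatograms.** AUC_v = occupancy_v · total · log-normal(CV);
  features below the LOD are still emitted, since censoring is the
  quantifier's job.
* **Toy scaffolds.** A fixed 76-nt tRNA-shaped template with the
  anticodon spliced at the canonical offset (position 34 at index 33)
  and consistent 32/37/38 annotations; deterministic in its arguments.

## Verification problem sizes

The recovery suites run at sizes chosen to give stable statistics while
staying quick on a laptop: 100 plates (25 per true efficiency in
{0.5, 2, 10, 50} %) at CV 5 % with 8 replicates, recovering the truth
with mean absolute error well under 1 percentage point; enrichment
recovery at the sequencing-depth floor of 10× library size (640 reads
per phase on the 64-member library), where a *single* campaign's
Spearman correlation between true log-weights and estimated enrichment
is noisy (mean ≈ 0.92, SD ≈ 0.02 across seeds — dominated by the
Monte-Carlo noise of a 640-read draw, not by estimator error), so the
recovery statistic is the mean Spearman over 20 independent campaigns;
digest reassembly over 1000 random proteins up to length 1000; occupancy
round trip on a 4-variant truth vector at CV 5 % with an L1 budget of
0.05. Deeper sequencing would make single-campaign recovery tight, but
the floor depth is the interesting regime to verify.

## Known limitations

* No structure prediction, promoter design or primer thermodynamics;
  scaffolds must ship correct anticodon annotations.
* Read matching is exact; heavily error-laden reads inflate the discard
  count rather than being rescued.
* Occupancy compares areas of (possibly different) peptides without
  ionization-efficiency correction; `digest_altering` flags where this
  matters. Spectrum-level identification (MS2 scoring) is out of scope —
  the package consumes feature tables.
* The growth/luminescence simulator is deliberately simple; see above
  for what passing its closed loops does and does not show.
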