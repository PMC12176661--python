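# Methods

## Scoring model

The pipeline scores a two-arm pooled knockout screen: one initial library
sample and endpoint samples for a vehicle arm and a drug arm, all grown from
the same infected, selected population. It assumes single-copy sgRNA
integration, that the non-targeting controls are fitness-neutral, and that
the supplied core-essential reference genes are fully depleting in every arm.
These two reference classes anchor the score scale: after filtering
(initial count ≥ 100 per sgRNA, ≥ 6 distinct sgRNAs per gene), pseudocount
normalization `a = (c+1)/Σ(c+1)`, per-arm sgRNA log2 fold-changes and
per-gene means, raw gene scores are mapped affinely so that the median
sgRNA-level lfc of non-targeting controls is 0 and that of
core-essential-gene sgRNAs is −1. The per-gene difference of scaled scores
between arms is z-standardized over all scored genes; large negative z marks
drug-selective dependencies, large positive z sensitizing knockouts.

Numerical and procedural choices, in the order they bite:

- **Normalization denominator includes the pseudocount**, so each sample's
  abundances form a proper probability vector (sum exactly 1). At realistic
  depths the alternative denominator `Σc` differs by a factor
  `1 + n/Σc ≈ 1.002`, which cancels in fold-changes.
- **Anchors are medians of sgRNA-level lfcs** (not of gene scores), then
  applied to gene-level scores. The median of an even-length set is the
  midpoint of the two central values (numpy's convention). Because the
  scaling is a monotone affine map, the scaled sgRNA-level medians of the two
  reference classes are exactly 0 and −1 by construction — this is the
  pipeline's internal control, and `compute_anchors` refuses to proceed when
  fewer than 10 sgRNAs (configurable) survive in either class or when the
  non-targeting median does not exceed the core-essential median.
- **The z-score uses the plain sample mean and sample standard deviation
  (ddof = 1) over all scored genes**, including essential-in-both genes. A
  robust median/MAD variant is available behind `robust_z=True` for screens
  with heavy-tailed differences, but is not the default.
- **Non-targeting controls are exempt from the ≥ 6 sgRNAs-per-gene filter**
  (they have no gene) but are subject to the initial-count filter.
- **Replicate endpoint samples** in an arm are each scored against the shared
  initial sample and averaged at sgRNA level before gene aggregation. The
  motivating screens have single endpoint samples; this is an extension.
- **Ties in rank outputs** are broken lexicographically by gene id, making
  every output table deterministic.
- **Hit cut-offs** `z_cut = 2` and `essential_cut = −0.5` are package
  defaults for categorization, not published constants; the published
  analyses report top-N lists, so top-N export (`top_n`, default 30) is also
  provided. Essential-in-both takes precedence over the z cuts so that genes
  pinned near −1 in both arms are not mislabelled selective on a small
  difference.

Annotated sgRNAs missing from a count table are treated as count 0 (and thus
removed by the initial filter) with a logged warning; a gene column that
disagrees with the annotation is a hard error.

## Simulator

The generator emulates the screen design: an initial post-selection library,
two arms grown for `generations` population doublings (default 8, matching a
~two-week screen; the `highdose` preset uses 10 for the longer high-dose
design together with stronger drug-arm effects), sequenced at `depth`
expected reads per sgRNA (default 500).

Generative model, per screen realization:

- initial composition `p0` is log-normal across sgRNAs (σ = 0.5, a typical
  cloning-bias skew), normalized;
- each targeting sgRNA has an efficacy `e ~ Beta(9, 2)` (mean 0.82, mode
  0.89), modelling mixed-efficacy guides; `efficacy_beta=None` forces `e = 1`;
- each gene carries a planted fitness effect per arm, in growth-rate units
  where −1 abolishes growth of a fully edited clone: core-essential genes
  −1 in both arms, drug-selective genes `selective_fitness` (default −0.4)
  in the drug arm only, sensitizing genes +0.3 in the drug arm only, the
  rest 0;
- on top of the planted value every gene receives an independent per-arm
  Gaussian jitter with sd `gene_arm_noise_sd = 0.06` (~0.5 doublings of
  drift over the screen). This models biological variability between the
  separately cultured arms — media batches, density history, clonal
  composition — and is what gives the selective-z null its spread: with
  sequencing noise alone the null would be a sharply heteroscedastic mixture
  dominated by the low-count core-essential guides, which no z-score could
  calibrate;
- cells double `g·(1 + e·f)` times, so the expected endpoint composition is
  `p ∝ p0 · 2^{g·e·f}` after dropping the common `2^g` factor;
- reads are drawn multinomially (`depth × n_sgRNA` total per sample);
  `overdispersion > 0` multiplies the composition by per-sgRNA Gamma noise
  first, giving negative-binomial-like counts for stress tests.

`expected_lfc` evaluates the renormalized log2 abundance ratio of this model
without count sampling and serves as the closed-form oracle in tests.

What the simulator does *not* model: stochastic drift between passages
(screens at ≥ 1000× coverage make it second order), cell-cycle and clonal
interference, guide off-target effects, PCR jackpotting beyond the optional
overdispersion, and any real metabolic pathway structure. Passing recovery
tests therefore show the pipeline recovers planted effects under this noise
model, not that any particular real screen's hit list is correct.

Default library shape (300 genes × 8 sgRNAs, 200 non-targeting controls,
40 core-essential reference genes) mirrors a metabolism-focused library at
desk scale; the `small` preset (24 genes × 6 sgRNAs + 30 controls) exists
for fixtures and completes in well under a second.

## Recovery and calibration

`recovery_metrics` reports the AUROC of `−z` for planted selective vs
neutral genes (via scikit-learn), recall of planted selective genes among
the top-N most negative z, and the sign accuracy of planted sensitizing
genes. At the default recovery settings the benchmark script reports
AUROC 1.0 and recall 0.95 (seed 7). The null-calibration script, 20
simulated screens with no planted selective effects, observes |z| ≥ 2 in
4.9% of genes against the 4.55% normal-tail expectation; core-essential
reference genes remain slightly over-represented in the tails because their
endpoint counts are small, which is a real feature of anchored screens, not
an artifact.

## Assay statistics

- **Composite RNA-ISH score**: `Σ level·percentage` over expression levels
  0–4; bins must sum to 100; range 0–400. Per-cell level assignment
  (microscopy) is out of scope — the operation consumes binned percentages.
- **Autophagic-flux index**: each well's RFP/GFP ratio divided by the mean
  ratio of the vehicle wells, so vehicle wells average to exactly 1. The
  reporter's GFP moiety is degraded by autophagy, the cleaved RFP fragment is
  not, so the index rises with flux.
- **Bliss excess**: `observed − (yA + yB − yA·yB)` per combination cell from
  the single-agent rows/columns of an inhibition-fraction dose matrix.
  Observed inhibitions are clamped into [0, 1] before the computation
  (viability noise can exceed baseline) and clamping is logged; both the
  mean and the peak excess are reported because published summaries differ
  on which they quote.
- **Phosphoinositide percentages**: per-peak background subtraction clamped
  at zero (negative net counts are physically meaningless, logged), then each
  of the six glycero-inositol peaks as a percentage of their summed net
  counts; percentages sum to 100.

## Known limitations

- No per-gene statistics beyond the z-score: no RRA/MLE-style p-values, FDR,
  Bayesian essentiality models, or copy-number correction.
- The core-essential reference list is a user (or simulator) input; the
  package does not ship one.
- The "initial" sample is whatever the design block designates; the pipeline
  does not distinguish post-selection from arm-seeding timepoints.
- The anchoring denominator is a single scalar per arm; screens whose
  essential-depletion window differs strongly between arms are comparable
  only through that rescaling.
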