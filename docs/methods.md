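# Methods

## The denoising problem

Single-cell immune profiling couples paired TCR αβ sequencing with
DNA-barcoded peptide-MHC (pMHC) multimer staining. Each droplet (GEM) should
contain one T cell plus the multimers it bound, with UMI counts acting as a
proxy for binding strength. In practice GEM-to-GEM leakage and capture of
ambient multimers from suspension make most raw GEMs multi-pMHC, so the raw
data cannot be read off as TCR-pMHC pairs. The package denoises such data by
studying GEMs in clonotype *ensembles*: deviations that are random at the
single-GEM level average out across a clonally expanded population, while the
true cognate pMHC shows a systematically higher UMI distribution.

## Procedure

1. **Clonotype redefinition.** GEMs are regrouped by the amino-acid 6-tuple
   (Vα, Jα, CDR3α, Vβ, Jβ, CDR3β) rather than nucleotide identity; somatic
   pedigree is irrelevant to receptor biochemistry, and the coarser grouping
   yields larger clonotypes and more statistical power. GEMs with multiple
   chains of one type keep the chain with the highest UMI (ties break on
   lexicographic (V, J, CDR3) so results are input-order invariant; unselected
   chains are preserved). A single-chain GEM whose half-key matches exactly
   one established clonotype receives the missing chain (flagged, UMI
   recorded as 0); ambiguous half-keys are never imputed.

2. **Expected-binder annotation.** For every clonotype with ≥ `min_gems`
   (default 10) members, the pMHC with the highest mean UMI across member
   GEMs is the candidate target. It is declared the *expected binder* iff a
   one-sided rank-sum test of its UMI vector against every competing pMHC
   gives p < α (default 0.05); a clonotype with a single detected pMHC is
   annotated directly. UMI vectors span all member GEMs with absences counted
   as zero (`zero_fill=True`). This default matters: with detected-only
   vectors, a competitor seen in exactly one GEM bounds the attainable exact
   one-sided p-value at 1/(n₁+1) ≥ 0.09 for clonotypes near the size floor,
   so such clonotypes could never be annotated no matter how clean the
   signal; zero-filled vectors reflect that a pMHC *absent* from a GEM is
   evidence against it. The detected-only behaviour remains available via
   `zero_fill=False`.

3. **UMI threshold search.** Three cutoffs are grid-searched to maximize
   accuracy (fraction of GEMs in annotated clonotypes whose top capture
   equals the expected binder, computed over GEMs retained at the candidate
   point): the minimum top-capture UMI (grid 1–20), the minimum top/second
   UMI ratio for pMHC multiplets (1.0–3.0 in steps of 0.1), and the minimum
   UMI per selected TCR chain (0–5). The search is exhaustive; ties resolve
   to the point retaining more GEMs, then to the lexicographically smallest
   thresholds. The winning thresholds are then applied to the *entire*
   table, and every surviving GEM is assigned its top-UMI pMHC.

4. **Specificity filters.** Independently composable, applied in the
   canonical order: HLA match (the assigned pMHC's restricting allele must be
   in the donor's haplotype — thymic restriction), paired chains (exactly one
   α and one β), specificity singlets (a clonotype-pMHC pair supported by one
   GEM is discarded), and the platform's `is_cell` call. The *recommended
   minimum* is thresholds + HLA match.

## Statistical and numerical choices

- **Rank-sum test.** For pooled sample sizes n₁+n₂ ≤ 12 the p-value is exact:
  the Mann-Whitney U of the observed labelling is compared against the full
  enumeration of label assignments (valid under ties, which are pervasive in
  small integer counts). Larger samples use the tie-corrected normal
  approximation with continuity correction (`scipy.stats.mannwhitneyu`).
  scipy's own resampling path is not used because it rejects single-element
  samples, which occur routinely for sparsely detected competitors. No
  multiple-testing correction is applied: α is a per-comparison gate, and
  requiring *every* competitor to fall below it is already conservative.
- **Ratio boundary.** "1.2 times greater" is read inclusively (≥ 1.2×), and
  the comparison `top/second ≥ r` is evaluated as `top·q ≥ p·second` with
  r = p/q exact (decimal grid values become exact rationals), so boundary
  cases like 6/5 vs 1.2 are never decided by floating-point rounding.
- **Conservative ties.** A GEM whose top capture is tied is removed by the
  threshold filter (its assignment is ambiguous) and counts as a miss in the
  accuracy metric, so ties can never inflate the optimized objective.
- **Allele matching** happens at two-field resolution after canonicalization
  to `LOCUS*NN:NN`; input dialects (`A0201`, `HLA-A*02:01`, …) are unified on
  read.

## Benchmark metrics

- **Retention**: GEMs surviving a filter state over the raw GEM count, %.
- **Accuracy**: fraction of GEMs (in clonotypes with an expected binder)
  whose top capture equals the expected binder, %.
- **Binding concordance**: per clonotype-pMHC pair, the fraction of the
  clonotype's GEMs assigned to that pMHC. The dataset average is GEM-weighted
  (each GEM contributes its own pair's concordance), which lets large
  unanimous clonotypes dominate, as they should in a clean dataset; an
  unweighted per-pair mean is available behind a flag. GEMs below 50%
  concordance are classified as outliers into: clonotype lacking an expected
  binder; cross-reactivity-consistent (dominant pMHC = expected binder,
  expected binder present in the GEM at lower UMI); dispersed-multiplet
  artifact (all of the clonotype's ≥ 3 targets below the cutoff and the GEM
  carries multiplets); other — with an HLA-divergence sub-flag.
- **Similarity AUC**: CDR3 similarity uses a k-mer substitution kernel,
  κ(a,b) = exp(β·BLOSUM62(a,b)) with β = 0.11387 and k-mer lengths {1,2,3}
  (the standard defaults of this kernel family; both configurable),
  cosine-normalized so self-similarity is 1. TCR-level similarity is the sum
  of the α and β chain similarities, in [0, 2]. Clonotypes sharing an
  assigned specificity form a plateau; each clonotype contributes its maximal
  similarity to other plateau members (intra) and to an equally sized seeded
  random sample from other plateaus (inter, self-comparison excluded,
  singleton plateaus skipped). The AUC of intra vs inter scores (midrank,
  i.e. tie-corrected Mann-Whitney) is reported ×100. It measures data
  consistency — TCRs binding the same pMHC should look alike — not
  predictive performance.

## The simulator

`simulate_dataset` draws a four-donor screen with known ground truth:

- Donor haplotypes: two alleles per locus (HLA-A, -B, -C) from a 24-allele
  catalogue. Each clonotype's cognate pMHC is restricted to an allele its
  donor carries (thymic-selection emulation); ambient noise features are
  drawn panel-wide and may violate the haplotype, which is what gives the
  HLA filter its traction.
- Clonotype sizes: zipf(a=2.0) truncated at 80 — a heavy tail in which ~6% of
  clonotypes reach the size-10 annotation floor, mirroring the sparsity of
  large clones in real repertoires.
- UMI counts: negative binomial, signal mean 15 (shape 5) for the cognate,
  noise mean 2 (shape 2) for ambient captures, Poisson(3) ambient features
  per GEM; zero draws emit nothing. TCR chains mean 4 (shape 2, floored at 1).
- Corruptions: 10% chain dropout, 5% spurious extra chains, 5% non-cell
  barcodes.
- CDR3s: a per-specificity 5-residue motif embedded at a random offset in an
  otherwise random 10–18-residue sequence framed by C…F, separately for α and
  β, so intra-specificity similarity exceeds inter-specificity similarity by
  construction with tunable effect size.

These defaults are the reference conditions used across the test suite. For
the "filters improve the raw data" check, a deliberately harsher regime
(noise mean 6, ambient rate 5, 200 clonotypes) is used so the raw table sits
in the noisy regime real screens occupy (raw accuracy around 60–80%) rather
than at a ceiling where improvement would be unmeasurable.

What the simulator does **not** model: VDJ recombination statistics and gene
usage bias, UMI dependence on avidity or TCR expression, donor-specific
background structure exploitable by control-based normalization, doublets of
two real cells, or cross-reactive TCRs with two genuine targets. Passing
tests therefore demonstrate the correctness and self-consistency of the
machinery under the stated noise model, not performance on any particular
real screen.

## Problem sizes

The test suite and acceptance script run on simulated screens of 50–500
clonotypes (roughly 150–1,700 GEMs), chosen so every stage — including the
2,520-point threshold grid and the kernel AUC — completes in seconds while
leaving dozens of clonotypes above the annotation floor. The pipeline itself
is routinely run on tables of ~200k GEMs; nothing in it is quadratic in GEM
count except the per-plateau similarity step, which scales with plateau
sizes, not the table.

## Known limitations

- Whether the upstream curation of real data should drop failing chains or
  whole GEMs when one chain of a pair is invalid is ambiguous; chains are
  dropped individually here (a GEM dies only when no chain survives), which
  preserves the most information. Reproducing exact published GEM counts on
  the public four-donor dataset may require the stricter reading.
- The kernel parameters behind published similarity-AUC values are not
  standardized across studies; the defaults here are the family's published
  defaults, so cross-study AUC comparisons are approximate.
- Negative-control features are carried through and exposed but no
  control-based background subtraction is performed.
- The "repeated chain multiplets across GEMs" edge case is treated as an
  ordinary multiplet.
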