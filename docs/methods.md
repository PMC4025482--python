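# Methods

## Heptad and zipper model

A heptad is a seven-residue window phased a-first, (a b c d e f g), with the
hydrophobic coiled-coil core at *a* and *d* (d = a + 3). The g-first phase
(g a b c d e f), which keeps the inter-helix g–e′ electrostatic pairing
contiguous, is treated purely as a display convention; storing one internal
phase avoids off-by-one placement of *d*. All 7-residue windows of a peptide
are assessed (so overlapping heptads in different registers are all
reported), and a window passes when:

- class(*a*) = hydrophobic and class(*d*) = hydrophobic under the four-class
  residue table (below), and
- no proline occupies any of the seven positions (default; configurable), and
- under the stricter `leucine_d` rule, the *d* residue is leucine.

Proline is excluded even though the class table groups it hydrophobic:
proline breaks α-helices, and without the exclusion the wild-type query
would yield a spurious second heptad (`ACYPQMN`, proline at *e*) that no
helix could realize. Both the hydrophobic-a/d and leucine-at-d rules are
provided because either is defensible for motif calling; the default is the
more permissive hydrophobic rule, which on the packaged queries gives the
same in-register calls as the stricter rule.

The residue table assigns basic = {K,R,H}, acidic = {D,E}, hydrophobic =
{G,A,V,L,I,M,P,F,W}, polar = {S,T,N,Q,Y,C}. It is a config-overridable
total partition so users can substitute e.g. a Kyte–Doolittle-style scheme.

Zipper calling groups passing windows by register (start mod 7) and takes
maximal runs with spacing exactly 7; a run of ≥ 2 heptads is called a
zipper, reflecting evidence that two-heptad zippers can function as
oligomerization domains. Charged residues at e/g are annotated (for g–e′
pairing) but never required, since short zippers can oligomerize without
them. On the Ser→Leu variant query the scan also reports one off-register
single heptad (`LYQFVNS` at position 5) created by the same leucine; it
cannot extend to a run and does not affect the zipper call. The placement
of the two in-register heptads (a at positions 2 and 9) is inferred from
the 7-residue spacing of the two *d*-position leucines rather than from an
explicitly printed window list, and should be read with that caveat.

`mutate_d_positions` rebuilds the d-substituted peptide series (LL, SL, LS,
SS naming by concatenated *d* residues) used to probe which leucines a
zipper needs; applying "SL" to the variant run reproduces the wild-type
sequence exactly.

## Helical wheel and faces

The wheel uses the ideal α-helix rotation of 100.0°/residue (3.6
residues/turn): residue *i* sits at ((i − 1) × 100) mod 360 degrees, the
first residue at 12 o'clock, advancing clockwise viewed from the
N-terminus. One documented orientation is chosen because wheel figures vary
and the convention is not otherwise constrained. Heptad letters are
assigned only over complete heptads starting at the supplied register, so a
trailing partial heptad contributes no face statistics. The face summary
reports the hydrophobic fraction of a/d, the polar fraction of b/c/f, and
charged residues at e/g. Hydrophobic-moment calculations (Eisenberg μH) are
deliberately out of scope.

## Logo statistics

For an ungapped alignment, per-position information content is
`info = log2(20) − H`, H the Shannon entropy of the empirical residue
frequencies (0·log 0 = 0). The background is uniform over the 20 residues
and no pseudocounts are added, so the closed forms hold exactly: a
perfectly conserved position carries log2(20) ≈ 4.322 bits and a uniform
position 0 bits — which is what the tests assert. The approximate
small-sample correction e(n) = (20 − 1)/(2·ln 2·n), floored at zero, is
available by flag but off by default so that the analytic values remain
exact. Consensus is the per-position modal residue; ties break
alphabetically and are reported alongside.

## Homology-based secondary structure

Queries are matched gaplessly (alignments with insertions or deletions are
out of contract) against windows of known per-residue structure restricted
to four labels {H, E, C, T}; finer DSSP classes must be pre-collapsed.
Acceptance requires: length ≥ 6, or exactly 5 with perfect identity; at
most two substitutions; every substitution scoring ≥ 0 under BLOSUM62; and
strictly positive scores when exactly two substitutions are present. The
"≥ 0" condition is evaluated per substitution, not as an alignment-sum
threshold — the two-substitution clause legislates the individual scores,
which fixes the per-position reading. The cap at two substitutions is the
conservative interpretation (rules are stated only for 0, 1 and 2) and is
configurable. BLOSUM62 itself comes from Biopython's published matrix,
wrapped in a validated symmetric lookup.

`search` enumerates every (query substring, window offset) pair — no seed
heuristics, no maximality filter — which for ≤ 25-residue queries is cheap
and makes the brute-force oracle comparison exact. Among accepted matches
with an identical matched database peptide, one representative is kept per
protein family (family identity is taken as input metadata; no family
inference is attempted). Sub-alignments of a longer accepted alignment are
themselves reported when they satisfy the rules; recovery of a planted
window is therefore judged by which *sources* have accepted matches, with
the full-length alignment ranked first.

Consensus prediction is a per-residue strict majority over the labels of
all covering accepted matches, `ambiguous` on ties and `unsupported` at
zero coverage. All overlapping accepted matches vote with equal weight —
the simplest defensible aggregation; no length weighting is applied.
Chou–Fasman/GOR-style propensity predictors, 3D structure handling, and
E-value statistics are non-goals.

## Allelic-interaction statistics

With only printed means and SEMs available (raw per-individual counts are
not published), interaction detection uses summary statistics throughout
rather than re-running ANOVA on raw data:

- additive null: expected mean = mean_a + mean_b, expected SEM =
  √(sem_a² + sem_b²); a null allele is modelled as a zero-activity record,
  making the expectation the other hemizygote alone;
- departure: z = (observed − expected)/√(sem_e² + sem_o²), called
  inhibitory below −z_crit, synergistic above +z_crit, additive otherwise
  (z_crit = 1.96, the two-sided 5% convention, configurable);
- two-group comparison: t = (m₁ − m₂)/√(sem₁² + sem₂²), with a
  Welch–Satterthwaite df and two-sided p only when group sizes are known.
  With equal n and equal SEMs this equals the pooled-variance Student t,
  which is verified against scipy on constructed samples. Group sizes for
  the published comparisons are unknown, so df/p matching is explicitly not
  a validation surface — only the t value itself.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

- **Peptides**: planted heptads draw their a/d residues from the
  hydrophobic class minus proline and every other position from the polar
  class. With a polar background, no window outside the planted run can
  have hydrophobic residues at both *a* and *d* (the only hydrophobic
  positions sit 3 or 7 apart), so a scan recovers exactly the planted
  starts — making truth comparison sharp rather than statistical.
- **Structure databases**: planted windows copy query substrings verbatim
  or with 1–2 substitutions of strictly positive score (so the matcher must
  accept them); decoys are composition-preserving shuffles of query
  substrings, rejection-sampled until they admit no accepted alignment,
  which keeps the amino-acid background realistic without homology.
- **Phenotype counts**: per-fly counts are round(max(0, Normal(μ, σ))); the
  trans-heterozygote mean is μ_a + μ_b + δ, so δ < 0 plants an inhibitory
  interaction. Truncated-rounded Gaussian noise is the default because the
  published SEMs are small relative to the means and σ should remain a free
  parameter; Poisson counts are available by flag. Defaults mirror the
  sex-comb magnitudes: μ_a = 6.2, μ_b = 2.5, δ = −1.7, σ = 0.7, n = 50
  flies, giving SEMs ≈ 0.1 like the published table. At these magnitudes
  the planted effect is ≈ 10 combined standard errors, so the ≥ 95%
  inhibitory-recovery rate is expected to be met with a wide margin, and
  with δ = 0 the additive call rate is the nominal ≈ 95% of a two-sided 5%
  test (asserted at ≥ 90%).
- **Heptad alignments**: each position equals the consensus with
  probability 1 − noise_rate, else a uniformly random other residue. The
  default (n = 130, noise 0.3) emulates an alignment of 130 bZIP heptads
  whose modal sequence is the consensus `LEALRQE` (a-first phase of
  E_g L_a E_b A_c L_d R_e Q_f). Note the 130-window fixture is synthetic:
  the real source alignment is not published, so the recoverable claim is
  only that the modal consensus matches.

All generators are deterministic under a seed and return a truth block
recording their parameters.

## What the synthetic conditions do and do not show

Passing planted-truth tests shows the detectors implement their rules
exactly and that, at published-table magnitudes, the summary-statistic
machinery recovers planted effects. It does not show that real structure
databases contain only near-neutral homologs (real windows carry remote
homology and compositional bias the shuffled decoys lack), nor that real
bristle counts are Gaussian, nor anything about in-vivo oligomerization —
those claims rest on bench experiments outside a computational package.

## Problem sizes and numerics

The validation suites use 200 random (query, database) instances for the
matcher-vs-oracle comparison, 25 synthetic databases for planted-window
recovery, and 500 replicates per calibration rate; the full test suite and
the acceptance script each complete in a few seconds on one CPU. Wheel
angles and entropies are closed-form; the only tolerance-bearing
comparisons are float round-trips at ~1e−9 or tighter. Ties in consensus
extraction break alphabetically and are reported; zero SEMs are legal in
records (constant counts) but rejected by `summary_t`, which directs the
user to exact-count comparison.

## Known limitations

- Heptad calling is rule-based, not probabilistic: no COILS/Paircoil-style
  log-odds scoring, and no dimer-vs-trimer state prediction.
- The structure database is a local TSV of pre-extracted windows; no live
  structure-repository query, so results cannot drift with database
  versions but also cannot discover new homologs.
- The four-label secondary-structure alphabet discards finer distinctions.
- Interaction calls treat printed SEMs as exact and independent; without
  raw data, distributional checks (normality, equal variance) are not
  possible.
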