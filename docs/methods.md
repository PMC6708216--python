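# Methods

## Model

Target–decoy FDR estimation rests on the premise that an unmatchable
spectrum is equally likely to land on either side of a combined
target+decoy database. With a decoy the same size as the target, decoy
counts estimate target false positives one-for-one. With a *small* decoy
(a fraction 1/N of the target), an incorrect match lands on the decoy side
with odds `u : 1`, where `u` is the ratio of peptide candidates each side
offers. The corrected estimate at a score cutoff is therefore

```
FDR_small = (#Decoy / #Target) / u
```

`u` is operationalised as the **unique-peptide ratio** (UPRatio): the number
of distinct decoy peptides divided by the number of distinct target peptides
under the digestion parameters of the search. Two assumptions make this
work: target and decoy databases share (almost) no peptides, and the
decoy/target false-positive ratio is constant — in particular constant
across candidate ranks, which is what the entrapment validation measures.

### The UPRatio reading

The ratio is defined via cumulative unique-peptide counts `Tmass`/`Dmass`
evaluated at each database's largest peptide mass, which reduces to the
total unique-peptide counts over the digest-constrained mass range. Counting
(rather than summing masses) is the reading consistent with "ratio of decoy
to target unique peptides"; a summed-mass variant is available behind
`compute_up_ratio(..., statistic="mass")` as a diagnostic only.

Peptides occurring in both databases would be credited to the target by any
search engine, so the default overlap policy removes them from the decoy set
before the ratio (`drop-from-decoy`; `keep` and `drop-from-both` are
available and reported).

## Digestion

Trypsin: cleave after K/R, by default not before proline (the default of
common search engines; configurable because conventions differ). Defaults:
≤ 2 missed cleavages, fully tryptic termini (semi-tryptic supported),
length 6–45, fixed carbamidomethyl on cysteine (+57.021464 Da). Monoisotopic
residue masses come from pyteomics; a peptide's neutral mass is the residue
sum plus water (18.0105647 Da). I and L are distinct for uniqueness (string
identity). N-terminal methionine is not clipped by default; a toggle exposes
the alternative. Peptides containing ambiguity letters (B/J/O/U/X/Z) have no
defined mass and are excluded, with a counter.

## Decoy construction

Four per-protein transformations: reversal, pseudo-reversal (each tryptic
segment's body reversed, its terminal K/R fixed), uniform shuffle, and
pseudo-shuffle (per-segment shuffle, K/R fixed). Segment boundaries follow
the digestion module's cleavage rule, so decoy construction and digestion
stay mutually consistent. A protein C-terminal segment not ending in K/R has
no fixed terminus and is permuted whole.

Small decoys sample the target *before* transforming — distributionally
identical to transforming first, and cheaper. In `entries` mode the sample
is exactly `floor(fraction × entries)` records; in `residues` mode records
are taken from a random permutation while they fit the residue budget, so
the achieved ratio is reported and can fall slightly below the request. One
integer seed drives sampling and shuffling; a fixed seed reproduces the
decoy FASTA byte-for-byte, supporting the store-and-reuse workflow for
audits.

**Caveat (proline rule).** Pseudo-reversal preserves the mass multiset of
internal fully-tryptic peptides exactly under plain K/R cleavage. With
proline suppression active, reversing a segment body can move a P next to
the fixed K/R and create or destroy a cleavage site, so the invariant is
only approximate; the property test uses plain K/R cleavage.

## FDR curves

Rank-1 PSMs are sorted by score (orientation declared; e-value-style
lower-is-better supported). At each distinct score cutoff,
`fdr_tds = n_decoy / n_target` (0 with no decoys; 1 with no targets),
`fdr_small = fdr_tds / correction` capped at 1. A PSM is a decoy only when
*all* its mapped proteins carry the decoy prefix — a shared peptide counts
as target, consistent with the overlap policy (configurable). Q-values are
the running minimum of the FDR from the loosest cutoff inward, making
"PSMs at 1% FDR" well defined; ties at the cutoff are accepted together.
Corrections above 1 (decoy larger than target) are allowed for symmetry.

## Entrapment validation

Shifting every precursor's *neutral* mass by +10 Da (m/z moves by
10/charge; a charge-less MGF record is treated as singly charged and
counted) makes every subsequent identification a known false positive, so
the decoy/target ratio of identifications measures the false-positive ratio
directly, rank by rank. The report gives per-rank ratios, a max/min flatness
diagnostic, the coefficient of variation across ranks, and the pooled ratio
(sum of decoys over sum of targets across ranks 1–5), which is the
recommended FPRatio estimate — more counts, same expectation when the ratio
is rank-flat. MGF is the supported format (text, lossless round-trip);
fragment peaks pass through untouched.

## Mass-window scan

The union mass range is tiled with log-spaced windows of relative width
2 × tolerance (default 10 ppm), one window modelling the candidate interval
of one precursor. The through-origin least-squares slope of decoy versus
target counts over non-empty windows (`Σxy / Σx²`; a zero-target window must
expect zero decoys) estimates the global UPRatio. The slope is only a stable
estimator when occupied windows hold many peptides: with sparse windows the
target count is a noisy regressor and the errors-in-variables bias shrinks
the slope by roughly `λ/(1+λ)` for mean occupancy `λ`. The window-slope
check therefore uses a 10,000-protein database (~8.6 × 10⁵ unique peptides,
mean occupancy ≈ 18), where the slope agrees with the UPRatio to a few
percent.

## Synthetic study conditions

The generator draws protein lengths from a normal distribution
(mean 350, sd 120, truncated at 20 residues — typical of a eukaryotic
proteome) with i.i.d. residues at average proteome composition. It emulates
database *scale* and composition, not homology: synthetic proteins share
almost no peptides, so UPRatio ≈ DBRatio here, whereas redundant real
proteomes (isoform-rich databases) push UPRatio well above DBRatio. Passing
tests therefore validate the estimator arithmetic and its calibration, not
the empirical value of UPRatio on any real proteome.

Simulated searches: each spectrum's rank-1 match is correct with probability
`1 − pi0` (default pi0 = 0.5); incorrect matches at any rank are decoys with
probability `u/(1+u)`, encoding the core premise directly (`decoy_odds`
overrides `u` to model violations). Ranks 2–5 are always incorrect. Correct
scores are Normal(4, 1); incorrect scores Gumbel(0, 0.4). An
extreme-value-style null with a *sharper* tail than the correct-score
distribution is needed for a fixed-FDR cutoff to be meaningful (with equal
tails the likelihood ratio is constant and the true FDR plateaus); these
defaults identify ~90% of identifiable spectra at 1% FDR, the separation
regime of high-resolution searches. Spectrum-level correctness and scores
come from a random stream keyed only by the seed, decoy assignment and
peptide identity from a second stream — so the same spectra searched against
two decoy databases share their correct matches, which is what makes
TDS-versus-small-decoy acceptance overlap measurable in silico.

Problem sizes used by the shipped checks: 2,000-protein databases
(10,000 for the window slope), 20,000 all-incorrect spectra for the
per-rank ratios, and twenty seeds × 100,000 spectra for the calibration and
overlap studies.

## Known limitations

- No peptide- or protein-level FDR; PSM-level only, rank-1 only for
  estimation (ranks 2–5 serve the entrapment diagnostics).
- No variable modifications; fixed modifications only.
- The simulator models match outcomes, not spectra: no peak-level effects,
  no engine-specific score shapes, no spectrum quality correlation between
  ranks.
- Decoy competition is modelled as an independent draw per search, so the
  small systematic advantage TDS enjoys from displacing incorrect targets
  appears here too (the observed ~1% acceptance difference), but
  engine-specific competition details are out of scope.
- MGF is the only spectrum format for shifting; binary formats are excluded
  to keep round-trips lossless.
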