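# Methods

## Scientific background

Shotgun proteomics can reveal internal backbone cleavage of proteins through
*semi-enzymatic* peptides: identifications with one terminus that neither the
digestion protease nor the annotated protein termini explain.  When such a
**neo-C-terminus** additionally carries a −0.984016 Da mass shift — the
elemental signature of a C-terminal primary amide (-CONH2 replacing -COOH,
net +N +H −O) — it marks an α-amidating cleavage event.  Two mechanisms
produce these C-terminally amidated protein fragments (CTAPs): enzymatic
processing by peptidyl-glycine α-amidating monooxygenase (PAM), which removes
a C-terminal glycine and leaves the upstream residue amidated, and
non-enzymatic hydroxyl-radical attack on the backbone, which can cleave
essentially any bond.  CTAPs are degradation substrates of the SCF–FBXO31
ubiquitin ligase, which recognizes the terminal amide itself; the
disease-associated FBXO31 D334N variant instead recognizes unmodified C
termini matching a [Lys/Arg]-X-Φ-COOH motif.

ctapkit implements the downstream computational analyses of this biology on
peptide-spectrum-match (PSM) tables: it does not perform spectral searching
(FragPipe/MSFragger-style engines are upstream) and does not estimate FDR.

## The site-calling procedure

1. **Annotation** (`ctap_caller.annotate_psms`).  Each PSM is validated
   against the FASTA (peptide must equal the protein substring at its
   claimed 1-based inclusive coordinates), filtered on its confidence score,
   and classified: the N terminus is `ANNOTATED_N` (start = 1),
   `MET_CLIPPED_N` (start = 2 with initiator Met), `ENZYMATIC` (protease
   bond), or `NEO`; the C terminus is `ANNOTATED_C`, `ENZYMATIC`, or `NEO`.
   The C-terminal mass delta is assigned to a shift-ladder bin; bin k = −1
   (centered on the exact amidation delta) sets the amidation flag.
2. **Site calling** (`call_sites`).  Amidated PSMs whose C terminus is NEO
   are grouped by (protein, end position); each group becomes one CTAP site
   with aggregated evidence (PSM count, distinct peptides, samples, maximum
   probability).  Amidation at enzymatic or annotated C termini is excluded
   by definition: it cannot be distinguished from chemical artifacts of
   sample handling.
3. **Controls.**  `category_stats` cross-tabulates C-terminus class against
   amidation in both conditional directions (the association that justifies
   the neo requirement), and `shift_noise_control` counts neo-terminus PSMs
   per ladder bin: the k = −1 signal bin versus decoy bins at other
   multiples of 0.984 Da, summarized as the signal/mean-decoy ratio.

### Parameters that matter

| parameter | default | rationale |
|---|---|---|
| amidation delta | −0.984016 Da | exact elemental value of +N+H−O |
| ladder | k·0.984 Da, k ∈ ±{1,2,3} | decoy multiples bracketing the signal |
| bin tolerance | 0.005 Da | engines report deltas to ~1e-4 Da; < step/2 so bins never overlap |
| `min_probability` | 0.9 | a deliberately strict PSM-confidence filter; published analyses of this kind print a far more permissive 0.01, which we read as a likely typo for 0.99 — the threshold is exposed and the default documented as this package's choice |
| missed cleavages | 1 | standard semi-enzymatic search setting |
| peptide length | 7–50 | standard search-engine window |

Peptides whose sequence occurs more than once in the database are flagged
ambiguous and excluded from site calling by default (site coordinates must
be unambiguous); `exclude_ambiguous=False` restores them.

## Protease model

Built-in rules: trypsin (cut after K/R, blocked before P; `stricttrypsin`
drops the proline block), Glu-C (after D/E, no proline block), ArgC (after
R, blocked before P), trypsin-N (before K/R), chymotrypsin (after F/W/Y/L,
blocked before P).  Bond index i means the bond between residues i and i+1,
so a peptide's C-terminal bond index equals its end coordinate.  Met
clipping credits only start = 2; deeper ragged N-termini stay NEO.  Missed
cleavages count internal protease bonds of the span, so a semi-enzymatic
peptide that reads through an internal site carries that site in its
missed-cleavage count (the standard search-engine convention).

## The fragmentation simulator

`fragmentation_sim` generates ground-truthed PSM tables that emulate
semi-enzymatic searches of fragmented samples.  Per backbone bond, cleavage
occurs with probability `p_cleave × residue_bias[upstream residue]`
(`pam_mode` restricts eligibility to bonds upstream of Gly, the PAM
mechanism; the `oxidative` bias preset raises Cys ×3 and Lys ×2).  Each
event emits an amidated N-terminal fragment and an unmodified complementary
fragment, independently per bond from the intact template — no recursive
re-fragmentation, so truth sites stay independent.  The complementary
fragment's damaged N terminus is emitted chemically unmodified; its
neo-N-terminus provides realistic semi-enzymatic background.  Species are
digested in silico; peptides are detected with probability `d` and produce
1 + Poisson(λ) PSMs with Beta(8,1) confidence scores, reported in
parent-protein coordinates.  Noise: with probability ε an unmodified PSM
gains the amidation delta; with probability δ any PSM's delta is replaced
by a random decoy ladder shift.

**Detectability-aware ground truth.**  A cleavage landing exactly on a
protease bond is *intrinsically* invisible to the caller — the amidated
peptide's C terminus classifies ENZYMATIC and is rejected by definition.
With `detectable_only` (default on), sampled bonds must not coincide with a
protease site, and their zero-missed-cleavage evidence peptide must fall in
the 7–50 length window and map uniquely in the database.  Ground truth thus
means "sites whose evidence is observable in principle", which is the
quantity a recovery benchmark should condition on; disable the flag to
sample raw chemistry instead.

Default study conditions: 200 uniform-composition random proteins of length
100–400, `p_cleave` 0.01, ε = δ = 0.01, d = 0.8, λ = 5.  λ reflects the
multi-PSM-per-peptide redundancy of deep, fractionated DDA runs (≈6 PSMs
per detected peptide); with the strict 0.9 score filter it yields a
per-site detection probability of ≈0.94.  The clean-recovery check
(ε = δ = 0, d = 1) is run with the score filter at 0 so that recovery is a
property of the pipeline logic, not of the simulated score distribution;
the noisy check uses the default caller settings.

What the simulator does *not* model: spectra, retention time, charge-state
and intensity realism, calibrated FDR, shared peptides from homologous
proteins, and the α-keto-acid mass shift on the complementary fragment's N
terminus.  Passing recovery tests therefore demonstrates correctness of the
classification/calling logic under the stated noise model, not performance
on real tissue data.

## Flanking and C-terminal motif statistics

`flanking_enrichment` counts residues at positions −w..+w around each site
(−1 = the amidated residue, +1 = first residue after the cleaved bond;
window 5 by default) against the residue composition of the analyzed
database — not an external proteome, so database composition biases cancel.
Enrichment is log2((f_obs + α′)/(f_bg + α′)) with α′ = α/(n + 20α), the
pseudocount expressed as a frequency (α = 1).  Adding the same α′ to both
sides keeps every cell finite, makes identical distributions come out
exactly zero, and leaves the matrix invariant under duplicating the
background.  `cterm_position_enrichment` applies the same scheme anchored
at the C terminus of two sequence sets.

`motif_match` implements [Lys/Arg]-X-Φ-COOH: basic ∈ {K, R} at −3 and
hydrophobic Φ at −1.  Φ defaults to {A, F, I, L, M, V, W, Y}: Ala is
included because Tyr→Ala retains degradation in the mutational series, Thr
excluded because Tyr→Thr abolishes it.  Both sets are configurable since
the exact hydrophobicity boundary is an empirical question.

## Library-screen quantification

The isokinetic library randomizes the three C-terminal positions over the
19 natural amino acids without Cys (19³ = 6,859 members; 18³ = 5,832
classes after Ile/Leu collapsing, the default MS-indistinguishability
relation, which is exposed rather than fixed).  Quantification follows the
pooled-IP convention literally: reporter intensities are summed per peptide
across detections, then every per-peptide channel sum is divided by the
*total input-channel* sum over the library — one scale factor per run — so
relative input intensities sum to 1 and enrichment = rel_ip/rel_input.
Binders are peptides with defined enrichment ≥ 1.0 (the threshold is
exposed; counts are only meaningful alongside it), and the amide/acid fold
enrichment is a ratio of median defined enrichments — medians because true
binders give the amide distribution a heavy right tail.

## Binding-curve fits

After baseline subtraction, each amide/acid pair is scaled by the pair
maximum to percent units, so the stronger binder saturates at exactly 100.
Fits minimize squared residuals over K_D alone with F_max fixed at 100 and
no nonspecific term (a free-F_max variant exists for un-normalized data):
hyperbolic F = 100·L/(K_D + L), or the ligand-depletion quadratic
F = 100·θ with P·θ² − (K_D + L + P)·θ + L = 0, evaluated in the
cancellation-free form θ = 2L/(K_D + L + P + √((K_D+L+P)² − 4LP)).  The
optimizer evaluates an 80-point log-spaced K_D grid spanning
[min positive conc/100, max conc×100] and refines the best bracket by
bounded scalar minimization; non-convergence is flagged, not raised.  The
depletion model is never the default — it exists for K_D values approaching
the probe concentration, and any fitted K_D below 5× the probe
concentration carries a tight-binding warning (reported, not censored).
The default titration design in tests and the acceptance script is a
two-fold dilution series 4.9–5000 nM plus zero, matching a 0–5 µM
titration of the receptor against a low-nanomolar probe.

## Problem sizes

The test suite and acceptance script use desk-scale inputs chosen as this
package's study conditions: 200 proteins of length ≤ 60 for the exhaustive
digestion oracle (all five protease rules, full + semi), 200 proteins of
length 100–400 for recovery simulations (≈250 truth sites, ≈10⁵ PSMs per
run; five seeds for the noisy condition), 800 titration fits (4 K_D values
× 200 replicates at σ = 2 percent units).

## Known limitations

- Site calling trusts upstream FDR control; no decoy-database modeling.
- Protein inference is out of scope: multi-mapping peptides are dropped,
  not apportioned.
- The ladder assumes well-calibrated precursor masses; systematic mass
  error larger than the 0.005 Da tolerance would silently empty all bins.
- `enumerate_semi` is O(L²) per protein and intended for search-space
  inspection at desk scale, not proteome-wide enumeration.
- Published site counts from tissue re-analyses are not reproducible here
  by design: they depend on raw spectra and a specific search-engine
  version, which this package deliberately treats as upstream.
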