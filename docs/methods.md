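# Methods

## The model

A protein sequence is treated as text over a 20-letter alphabet; an
*l*-residue word expresses a unit of local structure.  Homologous sequences
are paraphrases: when a homolog aligned at high identity (≥ 30% by default)
shows a gapless *l*-mer opposite a target word, that fragment is recorded as
a *synonym* of the word, keyed by target position (synonyms are
context-sensitive: the same string at two positions is two table entries).
The frequency F of a synonym counts its aligned occurrences across the
homolog set; with self-seeding (default on) every target word is also its
own synonym with F = 1, so identical targets score even without homologs.

Two target words sharing a synonym string are synonymous by transitivity.
Each shared synonym contributes the mean of its two frequencies,
(F_S + F_T)/2, to all residue pairs on the word diagonal; a residue pair's
raw score sums these contributions (exact half-integer arithmetic, no
rounding before normalization).

**Rank normalization.**  Alignable pairs (raw > 0) are sorted by raw score
(ties broken by (i, j) coordinates — the published rule is silent on ties)
and split into N = min(N_max, #alignable) contiguous groups of equal size,
remainder to the top groups so the maximum emitted score is exactly N; group
g scores N − g + 1.  N_max defaults to 500.  Normalization is per sequence
pair (one library per pair); rank-based, so invariant under monotone
transforms of the raw scores.

**Alignment.**  Library DP is global Needleman–Wunsch with affine gaps
costing open + extend·k for a gap of length k; library-based DP uses zero
gap costs (positional support is already encoded in the scores — standard
consistency-library practice), the BLOSUM62 baseline uses open 11 /
extend 1 in half-bit units.  Traceback prefers diagonal, then up, then left,
and closes gaps eagerly, making every alignment deterministic.  For MSAs the
per-pair libraries are consistency-extended — ext(x_i, y_j) = lib(x_i, y_j)
+ Σ_z Σ_k min(lib(x_i, z_k), lib(z_k, y_j)) over third sequences z — then
merged progressively along a UPGMA tree built on distances
1 − score/(min(m, n)·N), scoring profile columns by the mean extended score
over member residue pairs (gap members contribute 0).  This internal
progressive engine is a documented stand-in for running genuine T-Coffee on
the exported library; the library writer (`TC_LIB_FORMAT_01`) exists
precisely so that T-Coffee can be used instead.

**Profile baselines.**  BASIC is the bilinear form of two PSSM log-odds rows
through BLOSUM62, D(i,j) = Σ_kl A(i,k) M(k,l) B(j,l); B-DHIP is the
symmetric cross dot-product of log-odds with estimated probabilities,
D(i,j) = ½(A(i)·B̃(j) + Ã(i)·B(j)).  The published formula images being
unavailable, these implement the verbatim textual descriptions and the
original methods' standard forms; any scaling constants would not survive
rank normalization anyway.  Integer-truncated PSSM percentage rows are
renormalized to sum to 1; all-zero rows fall back to background frequencies
and are flagged.

**Evaluation.**  Q-score = 100·|pairs(test) ∩ pairs(ref)|/|pairs(ref)|,
pooled over sequence pairs for MSAs, on entire sequences (no core-block
masking).  Sequence identity = identical aligned pairs / aligned pairs.
RMSD superposes the pooled N/CA/C/O atoms of aligned residue pairs with
complete backbones on both sides (SVD Kabsch, reflection-corrected);
residues with missing backbone atoms are kept but skipped rather than given
fabricated coordinates.  The iRMSD is a simplified APDB-style statistic:
root mean of (d_A − d_B)² over aligned-pair quadruples whose CA–CA distance
in A is below a 10 Å neighborhood radius; it is superposition-free and is
not claimed to match any external implementation bit-for-bit.
Fold-identification uses TM-score ≥ 0.5 as the proven-positive label and
predicts similarity by identity > threshold (strict).  The outlier selector
maximizes identity/100 − TM-score (identity rescaled to [0, 1] so the two
terms are commensurable; a raw-difference mode exists), ties broken
lexicographically.  Structure↔sequence mapping is positional, with
mismatched lengths an error rather than a guess.

## The family simulator

The generator emulates a twilight-zone alignment problem with known truth:

* **Ancestor**: residues i.i.d. from BLOSUM62 background frequencies,
  length 200 by default.
* **Site rates**: Gamma(shape 0.4, mean 1) multipliers, constant over
  geometric blocks of mean length 8 — conserved motifs and variable loops
  at secondary-structure-element scale, shared by every branch of the
  family.  Homogeneous-rate sequences contain none of the conserved words
  the method is premised on, so rate structure is essential, not cosmetic.
* **Targets**: each descends from the ancestor along an independent branch;
  per-site substitution probability is 1 − exp(−μ·r_i) with replacements
  drawn from BLOSUM62 conditional exchange probabilities, and μ calibrated
  by root finding on the drawn rates so the expected target–target identity
  matches the request (15% by default).
* **Homologs**: relatives, not derivatives.  Each homolog branches off its
  target's lineage at a random checkpoint compatible with the requested
  homolog identity (60% by default) and evolves on its own for the
  remaining path budget, so realized identity tracks the request (±10
  points) while deeper-branching homologs independently witness ancestral
  states.  A homolog derived by further mutating the target itself would be
  a Markov refinement carrying zero extra information about the other
  family.
* **Indels**: start probability per site = rate multiplier × a budget of
  0.02 per full branch, geometric lengths (mean 2); indels concentrate in
  variable regions.  True residue correspondences are composed exactly
  through every branch.

What the simulator does **not** emulate: PSI-BLAST-scale homolog sets
(hundreds of members, identities spread over 30–90%, and — crucially —
membership overlap between the searches of two remote homologs, which in
real data lets the same database sequence donate the same words to both
targets' tables).  Under the simulated conditions every homolog sits within
±10 points of 60% identity to its own target, so cross-family word sharing
can arise only at superfamily-conserved blocks, whose total extent is capped
by the 15% identity budget (roughly a tenth of the sequence).  Passing the
desk-scale studies therefore shows the machinery is correct and the
robustness property is real; it does not, and cannot, reproduce the
benchmark-scale accuracy advantage of the word scheme over substitution
matrices, and the pairwise-recovery study honestly reports the baseline
ahead under these conditions.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| word length l | 7 | word size for synonym extraction; 7 suits PSI-BLAST-scale homolog sets.  Desk-scale studies use 4: expected chance l-mer collisions per residue pair scale like (1/20)^l × table occupancy, making 3 noise-dominated and ≥ 5 signal-free at 15% pair identity |
| min homolog identity | 30% | "similar enough" threshold limiting polysemy; boundary inclusive |
| N_max | 500 | rank-normalization group count |
| gap open/extend | 0/0 (library), 11/1 (BLOSUM62) | see above |
| iRMSD radius | 10 Å | CA neighborhood for intra-molecular distance pairs |
| simulator | 200 aa, 2 targets, 20 homologs @60%, pair identity 15%, indel 0.02, Γ(0.4) blocks of mean 8 | the study conditions |

Desk-scale study sizes (25 seeds, 200-residue ancestors, 4-member families
with 2 injected outliers) were chosen so each study completes in about a
minute on one CPU while keeping the paired sign test meaningful.

## Numerical and degenerate-input choices

Raw scores accumulate as exact rationals before conversion; normalization of
an empty matrix is the empty matrix (N = 0).  Profile scorers may emit
negative cells; only cells > 0 are "alignable".  DP tie-breaking and
traceback order are fixed (diagonal, up, left; close gaps first).  Rigid
superposition uses SVD with a determinant correction so reflections are
never applied; single-point sets superpose exactly.  PDB reading keeps the
first altloc, skips HETATM, and records missing backbone atoms as absent.
Gap characters `-` and `.` are both accepted on input, `-` is written on
output.  All internal coordinates are 0-based half-open; only the T-Coffee
library format is 1-based, converted at its reader/writer.

## Known limitations

* The internal progressive merger is a simplified stand-in for T-Coffee
  (no sequence weighting, no heuristic library filtering, no iterative
  refinement); export the library for paper-grade MSAs.
* The iRMSD is a simplified statistic, not a re-implementation of the
  APDB code path.
* One-hop word transitivity with small, target-bound homolog sets is
  information-limited in the twilight zone (see above); the simulator's
  studies quantify this honestly rather than masking it.
* mmCIF structures and NMR multi-model handling beyond the first model are
  out of scope.
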