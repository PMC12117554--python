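# Methods

## Problem setting

Structure-based zinc-site predictors are assessed against reference sites
extracted from holo structures, while the *inputs* are apo structures or
computed models whose side chains may have relaxed away from the
metal-bound geometry. `znbench` implements the bookkeeping and statistics
for that assessment; it does not run or reimplement any predictor.

## Reference-site model

A structure is a keyed collection of residues — identity is
`(chain, seq_num, insertion_code)` — plus lone metal ions routed out of the
residue list at parse time. Distance rules use non-hydrogen atoms only
(hydrogen is detected from the element field when parsing, else from the
atom name) and all cutoffs are **inclusive** (≤): 3.0 Å metal→ligand,
5.0 Å ligand-atom→shell, 3.8 Å for attributing a predicted metal
coordinate to residues. Altloc conformers collapse to the
highest-occupancy one, ties broken by altloc letter.

Apo↔holo site correspondence is *supplied* by the reference table (ligand
keys listed in the apo structure's own numbering, in a fixed equivalence
order); the package never recomputes equivalence by superposition. The
shell is informational: matching uses ligand sets exclusively, so whether
waters or hetero species appear in the shell has no effect on any metric.

Model-confidence filtering (`confidence_pass`) requires a fraction
(default 0.90, inclusive) of residues with pLDDT strictly above the
threshold. The pLDDT scale is auto-detected: values all ≤ 1.0 are read on
the 0–1 scale (threshold 0.7), otherwise 0–100 (threshold 70).

## Matching and statistics

- **TP rule**: a prediction matches an *n*-ligand site iff it names at
  least *n−1* of its ligands. For *n* = 1 this is vacuous; the rule is kept
  literal because real zinc sites in scope have *n* ∈ {3, 4}.
- A prediction matching several sites is assigned to the site with the
  largest ligand overlap, ties to the earlier site in input order, and is
  counted once.
- The best-ranked match per site is its primary TP; later matches are
  **redundant TPs (RTP)**. The non-redundant analysis drops RTP records
  before tallying (outputs shrink accordingly).
- **Precision** = 100 · (TP + RTP) / outputs. **R(top m)** uses unique TPs
  in the numerator and the capped denominator Σ N<sub>k sites</sub>·min(k, m)/k; for
  multi-site structures a hit on *any* site counts. **F1** is the harmonic
  mean. A CLES is identified when ≥ 50 % (inclusive) of its member sites
  are hit.
- Score thresholds are inclusive on the passing side; ranking ties keep
  input order (stable sort). Percentages are reported to one decimal with
  half-up rounding; regression comparisons against printed values use
  ±0.1 because published rounding is occasionally half-down.

## Consensus benchmark

Cross-tool agreement (`same_site`) mirrors the n−1 rule: two residue sets
agree when they share all but at most one residue of the smaller set.
Consensus sites are built greedily per structure (predictions visited in
predictor order then rank; one prediction supports at most one site) and
require support from ≥ 2 distinct tools.

Confusion matrices follow the *negative-output* convention: a tool whose
outputs for a structure all fail its threshold (or that produced nothing)
makes a negative call — TN if the structure has no consensus site, FN per
consensus site it misses. Passing predictions matching a consensus site
are TPs; passing predictions matching nothing are FPs, including on
positive structures — a wrong positive output costs precision, and the
missed site is *not* also an FN. Recall is TP over the total consensus-site
count. Consequently tp + fn can be smaller than the site total for tools
without thresholds (they are never "negative"). FN is counted per missed
*site* (not per structure); the alternative per-structure count is
indistinguishable on the published table and this choice is the stricter
one. Venn percentages round half-up to whole percent.

## Apo-variability analysis

Per CLES, each apo site contributes the n×n matrix of pairwise distances
between donor-proxy atoms (Asp Cγ, Cys Sγ, Glu Cδ, His Cε1); the N
matrices stack into an N×n×n tensor with elementwise mean and **population
SD** (ddof = 0; the N = 2 closed form — SD = δ/2 for a δ displacement —
documents the convention). A site is flagged as rearranged when at least
2 upper-triangle entries deviate from the mean by more than 2 SD,
**two-sided** (contracted sites count as much as expanded ones; the
spread is visualised in both directions). Zero-SD pairs are never deviant.

Flagged sites are grouped into subclusters by single-linkage clustering on
the Frobenius distance between their full distance matrices. The cut
threshold defaults to twice the median Frobenius distance among
*non-flagged* sites — i.e. groups separate when they differ clearly more
than the background noise; with fewer than two calm sites the flagged
pairwise median is used. The threshold is exposed as a parameter since
only the grouping concept, not an algorithm, is prescribed.

## Synthetic worlds

The generator states one fixed world per configuration and seed:

- **Geometry**: donor atoms 2.1 Å from the metal (typical Zn–S/N/O bond
  length), tetrahedral (4 ligands) or trigonal (3) directions; residues
  carry only the atoms downstream code reads (Cα, Cβ, donor proxy) —
  no rotamer library, because the evaluation never touches other atoms.
  Decoy residues sit ≥ 8 Å out on a deterministic golden-spiral shell, so
  decoy triads can never satisfy the n−1 rule by construction.
- **Apo noise**: isotropic Gaussian per-proxy displacement (default
  σ = 0.3 Å, the small thermal/rotamer jitter regime), optional discrete
  subcluster modes (planted 2–3 Å displacements emulate alternative
  crystallisation minima), optional rigid translation (distance matrices
  are invariant to it — tested).
- **Predictors**: per true site a detection draw (`p_detect`), optional
  one-ligand omission (`p_partial` — still a TP under n−1, asserted),
  duplication (`dup_rate`), Poisson decoy FPs (`fp_rate`), and a score
  draw in which a TP outranks any given FP with probability exactly
  `score_informativeness` (two-branch construction: 1+U vs U−1 against
  FP ∼ U(0,1)).
- **Randomness contract**: one root seed; `numpy` substreams keyed by
  structure index, so per-structure outputs are stable when the data set
  is resized (tested).

What a green synthetic test does **not** establish: realism of protein
backbones, predictor-specific failure modes (homology bias, crashes on
large inputs), crystallographic artefacts, or correlated errors across
tools — consensus error rates on real proteomes will differ.

## Analytic expectations used in parameter recovery

Expected recall = `p_detect` (partial omissions do not reduce it).
Expected precision ≈ p·(1+dup) / (p·(1+dup) + fp_rate) on single-site
structures with non-truncating top-m; standard errors use binomial
approximations on the pooled site/output counts, with a 3 SE default band
(`k_se`).

## Known limitations

- The n−1 rule is degenerate for hypothetical 1-ligand sites (kept
  literal; out of scope for CHED zinc sites).
- The published apo-benchmark recall columns back-calculate to
  inconsistent denominators across tools and are therefore *not*
  reproduced; only the precision columns (and all consensus-table metrics)
  are regression-tested from the printed counts.
- mmCIF input, symmetry-mate expansion and physiological-site
  classification are out of scope.
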