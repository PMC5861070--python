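# Methods

This note records the models, conventions and design choices behind
`domainevol`, in the order the pipeline applies them.

## Scope and data model

The unit of analysis is a pre-aligned protein family (optionally paired
with in-frame CDS), a metadata table assigning each sequence to a
species, clade and group, and a domain partition given in the ungapped
coordinates of one named reference sequence (1-based inclusive in all
user-facing I/O; 0-based half-open internally). The package refuses
unaligned input rather than aligning: alignment construction is a
separate, method-laden step that the analyses here should not silently
absorb. The partition names two primary domains, `pro` and `mature`
(non-overlapping), and optional sub-regions of the pro domain, `NLS`
and `HCPR` (the highly conserved N-terminal pro-domain region,
residues 1–40 in the IL-1α default `{"pro": [1,112], "mature":
[113,271], "HCPR": [1,40], "NLS": [70,85]}`).

Gap `-` and missing data (`X` for protein, `N` for nucleotide) are
distinct symbols, but both count as "gap or missing" wherever filtering
decisions are made.

## Filtering

Two rules, wired to different downstream stages:

- **Complete deletion** (before distances/trees): keep exactly the
  columns in which no sequence has a gap or missing symbol. When
  records carry a CDS, removing an aligned residue removes its codon,
  preserving the translation invariant.
- **Modal-gap deletion** (before conservation profiling): drop only the
  columns whose modal character is a gap. A tie between the pooled
  gap count and the best residue count **keeps** the column — the
  profiling stage wants the maximal set of usable sites, and exhaustive
  enumeration over 4-sequence columns confirms keep-on-tie never
  retains fewer columns than drop-on-tie.

Complete deletion's retained columns are always a subset of modal-gap
deletion's; both rules are idempotent; both report retained-column
provenance (1-based) as TSV.

Because modal-gap deletion can remove columns where the reference has a
residue, profiling a pre-filtered alignment would renumber reference
coordinates and silently shift every domain. `conservation_profile()`
therefore filters internally and keeps the *input* alignment's
reference numbering; `site_conservation()` remains available for
alignments whose coordinates are already final.

## Substitution model and distances

The amino-acid model is the Jones–Taylor–Thornton (1992) empirical
matrix: symmetric exchangeabilities `s_ij` and frequencies `π`, embedded
as packaged constants (conventional `ARNDCQEGHILKMFPSTWYV` ordering,
guarded by a sha256 checksum) and identical to the widely distributed
`jones.dat` values. The rate matrix is `Q_ij = s_ij·π_j` off-diagonal,
rows summing to zero, scaled to one expected substitution per site per
unit time, so distances and branch lengths are in amino-acid
replacements per site. Reversibility (`π_i Q_ij = π_j Q_ji`) lets
`P(t) = exp(Qt)` be computed once per call from the spectral
decomposition of the symmetrised matrix.

The pairwise distance is the maximum-likelihood time:
`argmax_t Σ_sites log(π_a P_ab(t))`, found by bounded derivative-free
scalar maximisation on `[1e-6, 10]` to absolute tolerance `1e-6`
(verified against a brute-force grid search of the same likelihood at
step `1e-4`). Identical sequences return the lower bound; an optimum
at the upper bound sets a per-pair *saturated* flag rather than
failing.

## Trees, bootstrap, likelihood

Topologies come from Saitou–Nei neighbor joining on the complete
pairwise JTT distance matrix; negative intermediate branch lengths are
clamped to zero with the deficit logged (standard practice). Full
maximum-likelihood topology search is deliberately out of scope: the
package provides `tree_loglik` (Felsenstein pruning with per-node
rescaling) to compare candidate topologies under the same model, which
covers the model mathematics deterministically at desk scale.

Bootstrap supports resample alignment columns with replacement;
replicate `r` draws from a generator seeded `seed + r`, so results are
reproducible and independent of execution order. A bipartition's
support is the integer percentage of replicate NJ trees containing it
(bipartitions canonicalised against a fixed reference taxon, making
them rooting-independent); branches below the collapse threshold
(default 50%) are collapsed to polytomies, discarding the collapsed
edge length as in consensus-tree practice.

## Conservation

Site conservation is the percentage of sequences carrying the modal
residue — deliberately identity-to-mode, not entropy or
similarity-class weighted, because that is the quantity the domain
summaries and heat-map table report. Gap symbols count in the
denominator but cannot be modal (guaranteed upstream by modal-gap
deletion). Residue ties break alphabetically, which is deterministic
and order-independent; the *percentage* is tie-invariant. Domain
summaries are unweighted arithmetic means of column percentages within
each interval, with column counts reported.

The modal consensus of a sequence subset excludes gaps from modality
(an all-gap column emits `-` and is logged). The group-vs-modal
contrast compares each focal sequence to the reference group's modal
sequence per domain, excluding columns where either symbol is a gap
from numerator and denominator alike. The reference sequence defaults
to a human sequence when one is identifiable from the id, else the
first record (logged).

## Nei–Gojobori dN/dS

Per sense codon, the potentially synonymous sites `s` are the summed
per-position fractions of the three single-nucleotide changes that
preserve the amino acid (`s + n = 3` exactly); mutations producing stop
codons count as nonsynonymous. Observed differences between two codons
are averaged with equal weight over the minimal mutational pathways
connecting them; pathways passing through a stop codon are excluded,
and if every pathway does, all pathways are used with stop-involving
steps counted nonsynonymous (logged). These are the dominant
conventions of Nei–Gojobori implementations (MEGA follows them);
Biopython's NG86 differs only in averaging stop-passing pathways in,
which the cross-check tests account for.

For a pair: `S` is the mean of the two sequences' summed site counts,
`N = 3·codons − S`, `pS = Sd/S`, `pN = Nd/N`, and distances use the
Jukes–Cantor correction `d = −(3/4)·ln(1 − (4/3)p)`, which is
undefined at `p ≥ 3/4` (reported as a saturation flag carrying the raw
proportion rather than a number). Codon columns containing a gap or
ambiguous base in either sequence are dropped pair-wise (complete
deletion in codon space). Both dN/dS and dS/dN are emitted, each with
an undefined flag when its denominator is zero; no interpretation is
hard-coded.

Group estimates default to the **pooled** estimator — raw counts
(S, N, Sd, Nd) summed over all unordered within-group pairs before
normalisation and correction — which is more stable than averaging
per-pair corrected distances when per-pair S is small; the
mean-of-pairs estimator remains selectable.

Under the simulator's own generating model the NG86+JC estimator is
consistent and, in practice, unbiased across divergences up to ~0.8
substitutions/codon; the tests therefore assert convergence of dN/dS
to the generating ω at low divergence rather than a bias trend, which
is not empirically observable there.

## NLS detection and scoring

Monopartite candidates are all 4-mers matching `K-(K/R)-X-(K/R)`;
bipartite candidates are two basic clusters (≥ 2 of K/R within a
3-residue window) separated by a 10–12 residue linker. The 0–10 score
is a transparent surrogate: one point per basic core residue, a
two-point penalty per tryptophan in the core, plus one point if an
additional K/R lies within two positions of the core, clamped to
[0, 10]. Scores below 2 classify as non-functional. The scheme is
*calibrated to the decisive contrast* — an intact KKRR core scores 4
(functional) and the single R→W replacement (KKWR) scores 1
(non-functional) — and makes no claim to reproduce the exact numerics
of position-specific activity matrices trained on importin-α binding
data; that is this module's central documented approximation. Within
matching monopartite cores, replacing any K/R by W strictly decreases
the score; for bipartite candidates the penalty is non-increasing only,
because clamping at zero can absorb it.

Classification over an alignment projects the partition's NLS interval
through the reference gap pattern onto columns, so per-taxon gaps
elsewhere cannot shift the scanned window.

## Net charge and isoelectric point

Henderson–Hasselbalch summation: positive groups (N-terminus, H, K, R)
contribute `1/(1+10^(pH−pKa))`, negative groups (C-terminus, D, E, C,
Y) contribute `−1/(1+10^(pKa−pH))`. The default pKa set is the flat
Bjellqvist set used by the standard proteomics pI tools (N-term 7.5,
C-term 3.55, D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0);
an EMBOSS set is selectable for sensitivity — pI values shift by
roughly 0.1–0.3 between conventions, which bounds how precisely any
single reported pI should be read. The charge curve is strictly
decreasing in pH, so the pI is the unique zero, found by bisection on
[0, 14] to |charge| < 1e-4 and printed to two decimals.

## Factorial contrasts

Per-species domain values enter an ordinary least squares model
`value ~ C(species) + C(protein)*C(domain)`. The species indicators
are a fixed-effect surrogate for by-subject random intercepts: in
balanced designs the within-subject contrast estimates are identical,
and the output is flagged "FE approximation" so no mixed-model claim
is implied. By-subject random slopes are out of scope and noted in the
output metadata. Term significance uses partial (type II) F tests; a
zero-residual (perfectly fitting) model defines all term p-values as 1
and contrast p-values as 1 (estimate 0) or 0 (estimate ≠ 0) rather
than NaN.

Least-square means are cell predictions averaged over observed species;
two contrast families are emitted and corrected separately — domain
differences within each protein, and protein differences within each
domain — because which family a figure's annotations belong to is a
reporting choice, not a modelling one. Holm–Šidák adjustment sorts
ascending, sets `adj_(i) = 1 − (1 − p_(i))^(m−i+1)`, enforces a running
maximum, and restores input order; the procedure's family-wise error
under a global null of independent comparisons is verified by Monte
Carlo (1000 replicates of Welch t-tests on standard-normal groups).

## Synthetic data

The simulator generates the statistical structure the analyses assume,
with the study conditions as defaults: 16 taxa, pro and mature domains
of 200 codons, ω = 0.1 (pro) and 0.6 (mature), tree depth 0.3
substitutions per codon site, a 4-taxon loss clade, gap-column rate
0.02 per column.

- **Tree**: a pure-birth (Yule) shape with the mean root-to-tip path
  scaled to the configured depth, or any user Newick.
- **Codon model**: Goldman–Yang-style 61-state model with uniform
  sense-codon equilibrium and transition/transversion ratio 1;
  single-nucleotide changes get rate 1 (synonymous) or ω
  (nonsynonymous), zero otherwise; stops are unreachable by
  construction. Uniform frequencies make Q symmetric, so one `eigh`
  per ω serves every branch; the configured ω *is* the dN/dS truth —
  the point of choosing the simplest adequate model.
- **NLS motif**: written in post hoc rather than simulated under
  selective constraint, to make the classification contrast
  deterministic. The window is Ser-Ser + core + Ser-Ser; the serine
  padding guarantees the flank-bonus rule cannot rescue a lost core.
  Core codons are `AAA AAA CGG AGA` (KKRR); the loss clade — which
  must be monophyletic, since the scenario is a single ancestral
  loss — carries `TGG` at the third codon (KKWR), a single C→T
  change. Gap columns are never injected into the motif window.
- **Gap columns**: each selected column is gapped in a strict majority
  of taxa, so modal-gap deletion provably removes it; surviving taxa
  are a random minority.

What the generator does *not* emulate: indels with evolutionary
structure (gaps are whole-column artefacts), rate heterogeneity among
sites or branches, codon usage bias, non-uniform amino-acid
frequencies at the codon level, and selection acting on the motif
itself. Passing truth-recovery tests therefore demonstrates the
pipeline's internal correctness and sensitivity under its own model
assumptions — not robustness to the full complexity of real alignments.

Everything is driven by one seed; identical configs produce
byte-identical output files (checksummed in the truth manifest).

## Problem sizes and numerical choices

The validation experiment simulates 100 families under the default
conditions and re-analyses each from scratch; the qualitative
structures (dN/dS ordering, conservation ordering, NLS partition) are
each recovered in ≥ 95% of seeds, and in practice in all of them.
Unit-scale checks use exhaustive enumeration where the space allows
(61 codons, 61×61 codon pairs, 3⁴ filter columns). Bootstrap examples
use 100 replicates on small alignments; production runs default to
1000. Distance optimisation tolerance is 1e-6 on `[1e-6, 10]`;
transition-matrix row sums hold to 1e-10; likelihood root-invariance
to 1e-8; pI bisection to 1e-4 on the charge.

## Known limitations

- Only the JTT matrix ships; the model interface accepts any
  reversible exchangeability/frequency pair, but no WAG/Dayhoff data
  is embedded.
- NJ + fixed-topology likelihood, not heuristic ML search; published
  tree topologies obtained with search heuristics may differ.
- The NLS score is a surrogate scale, reliable for the
  functional/non-functional classification it is calibrated to, not
  for comparing scores between unrelated signals.
- The factorial model is fixed-effects only; datasets needing random
  slopes or unbalanced-design shrinkage should use a dedicated
  mixed-model package on the exported long-format tables.
- pI ignores post-translational modifications; annotated modification
  sites are treated as annotation, not chemistry.
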