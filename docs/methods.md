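# Methods

## The problem

`te_evoscan` analyzes families of PIF/Harbinger-superfamily transposase
fragments cloned from a set of related host species — here modelled on a
grass tribe whose genera diverged roughly 13–25 My ago. Each input record is
a short conserved transposase-domain fragment (~360 bp of coding sequence,
usually interrupted by a 72–88 bp spliceosomal intron) carrying host
taxonomy in its header. The pipeline asks three questions: which copies are
still potentially functional, what selective regime shaped them, and do any
cross-genus pairs look too similar to be explained by vertical descent.

## QC and functional classification

Clone libraries contain PCR artifacts. Two rules are applied per sampled
individual: exact duplicate clones are collapsed (first by input order
kept), and any clone at Hamming distance exactly 1 from the per-individual
strict-majority consensus is removed as a likely polymerase error. Ties in
a consensus column yield `N`, a character that matches nothing; because the
removal rule requires *exactly* one mismatch, a group containing a tie
column removes nothing — deliberately the most conservative reading.
Identical sequences carried by *different* individuals are never collapsed:
they are precisely the horizontal-transfer signal screened for later.

The reading frame is located by translating all six frames and searching
for the conserved upstream anchor motif (default `GAMDGTH`, up to
`max_mismatches` substitutions); when no frame carries the motif the frame
with fewest internal stops wins, with ties resolved to the + strand and the
lowest offset. The intron is excised as the GT..AG-bounded segment of
plausible length (default 50–120 nt) whose removal restores a stop-free
in-frame coding sequence; among several such candidates, splicings whose
translation carries the downstream anchor (`ELFNPRH`) are preferred, and
residual ties are flagged `ambiguous_intron_placement` and resolved
leftmost. A sequence that is already in frame and stop-free is taken as
intron-less; a frame-preserving, stop-free intron is therefore undetectable
from a single sequence — a known limitation, since resolving it requires
the family-level alignment that an external aligner provides.

Classification: `frameshift` when the ungapped coding length is not a
multiple of 3 or (aligned input) an internal gap run has length not
divisible by 3; `premature_stop` when the in-frame translation contains a
stop before the final codon; otherwise `functional`. "Functional" is an
upper bound: missense inactivation is invisible at this fragment length.

## Divergence and selection statistics

Pairwise identity is match-fraction over aligned columns, with gap/N
columns excluded pairwise (or counted as mismatches under the `complete`
policy). Proportions are corrected to distances with the Jukes–Cantor
formula d = −(3/4)·ln(1 − (4/3)p), defined for p < 0.75; saturated pairs
raise an explicit error and are excluded from summaries.

Synonymous/nonsynonymous counting follows Nei–Gojobori with an optional
transition/transversion weighting. Potential sites: at each codon position
the three possible changes get weight R (transition) or 0.5 (each
transversion); changes creating stop codons are excluded from numerator and
denominator; the synonymous fraction per position is the weighted fraction
of synonymous changes, and s + n = 3 per codon by construction. With the
default R = 0.5 all changes are equally weighted and the scheme reduces
exactly to unmodified Nei–Gojobori; R is exposed (`--ts-tv-ratio`) because
published analyses sometimes use a "modified" variant without stating R.
Observed differences per codon pair are averaged with equal weight over all
minimal mutational pathways, excluding pathways that pass through a stop
codon; when *every* pathway is blocked the average is taken over all
pathways, which preserves the invariant Sd + Nd = observed nucleotide
differences. Codons containing gaps, N, or a stop in either sequence are
dropped pairwise. ω = dN/dS is undefined (never silently 0/0) when dS = 0,
and identical pairs are flagged rather than tested.

The codon Z-test uses Z = (dN − dS)/SE with SE estimated by bootstrap over
codon columns (default 1000 seeded replicates) and a standard-normal
reference; alternatives are two-sided (default), purifying (dN < dS) and
positive. Bootstrap was chosen over the analytic variance because it is
assumption-light and directly testable: under neutral simulation (ω = 1,
120 codons, 500 replicates) the measured type-I error at α = 0.05 is
~5–6%. Fewer than 10 comparable codons sets a low-power flag. In the
all-pairs selection summary, one member of every identical-sequence pair is
removed first (earlier record kept), and the summary reports the mean of
defined ω values and the fraction of testable pairs rejecting neutrality.

## Phylogenetics

Topology estimation is neighbor-joining on JC-corrected distances
(p-distance optional). NJ is implemented in-package because the contract
fixes determinism the usual library implementations do not: Q-criterion
ties break on the smallest index pair, and negative branch-length estimates
clamp to zero. On any additive matrix NJ provably recovers the generating
topology and branch lengths; this is property-tested against random trees
up to 12 leaves and cross-checked against an independent library
implementation. Full heuristic ML/MP tree search is deliberately out of
scope — the quantities consumed downstream are group membership and
support, not tree scores.

Support comes from a seeded column bootstrap: alignment columns are
resampled with replacement, each replicate is re-joined, and bipartition
frequencies (percent) attach to the point-estimate tree. Support is keyed
by canonical unrooted bipartition, so it survives rerooting unchanged.
Rooting is by midpoint of the longest leaf-to-leaf path (found by exact
brute-force accumulation from every leaf; ties on path endpoints break
lexicographically), which preserves all path lengths. Clades with support
strictly above the threshold (default 80%) are reported as maximal groups,
with nested supported clades noted under their maximal parent.

Fixed-tree likelihood evaluation implements Felsenstein pruning under GTR,
with rate variation as 4 equal-probability discrete-Gamma categories
(mean-of-bin rates via regularized incomplete gamma functions) and an
optional invariant-sites class (zero-rate mixture component; variable-class
rates rescaled by 1/(1 − I) so branch lengths keep their
substitutions-per-site meaning). The rate matrix is scaled to one expected
substitution per site at equilibrium. Partial likelihoods are rescaled per
node and accumulated in log space, and the mixture is combined with
log-sum-exp, so long trees do not underflow. Gaps and N are missing data.
The implementation matches exhaustive ancestral-state summation to 1e-9 in
log space and is invariant to rerooting.

## Horizontal-transfer screen

The screen is deliberately conservative: over tribe-scale divergence even
strong purifying selection cannot prevent synonymous changes from
accumulating, so a *fully identical* cross-genus coding pair is the
signature of recent transfer (or introgression). Identity is computed over
aligned coding sequences with gap/N columns excluded pairwise; same-genus
identical pairs are ignored. Near-identical cross-genus pairs (default
≥ 99%) are reported as a secondary tier, sorted by identity. Where both
members retain an intron, the two introns are globally aligned
(match +1, mismatch −1, gap −2) and the intron identity attached as
corroboration — a fast neutrally evolving intron should also be
near-identical if the transfer is recent. The report contextualizes each
candidate with the expected number of synonymous substitutions under
vertical descent, 2 × divergence-time × synonymous-clock × synonymous
sites (defaults: 13–25 My window, 1e-8 /site/year — order-of-magnitude
context only, never a test statistic); a pair is flagged HT-consistent when
even the minimum expectation is ≥ 1 yet the observed synonymous differences
are below a tenth of it. A member carrying a stop codon is annotated "not
under selective constraint", which strengthens the transfer interpretation
since selection cannot explain its conservation.

The screen cannot distinguish vector-mediated transfer from hybridization/
introgression; that requires flanking-sequence evidence and is out of
scope.

## The simulator

The generator produces data with exactly the structure the analysis
assumes, plus a complete truth log (events, per-record lineage and
functional status, transfer pairs).

Host tree: a Yule-style topology (a uniformly chosen lineage splits at each
event) with the root at `tribe_age` (default 25 My) and all other split
ages i.i.d. uniform on [13, 25] My — genera separated by deep divergence, as
in the radiation being modelled. This is a calibrated stand-in, not an
exactly conditioned birth-process draw.

Transposase family: `n_ancestral_lineages` (default 4) founders are
pre-diverged from a common random ancestor by a burn-in of 0.3 proposal
substitutions/site (pairwise), then descend through the host tree. Within
each inter-split epoch every copy independently experiences duplication
(0.03 /copy/My), loss (0.02) and pseudogenization (0.025) as exact Poisson
processes (Gillespie within the epoch), while sequences accumulate
substitutions at `clock_rate` = 0.003 accepted neutral substitutions
/site/My. Mutation proposals follow an HKY-like kernel (default κ = 1, i.e.
equal rates, matching the default R = 0.5 of the estimator); functional
copies reject stop-creating proposals and accept nonsynonymous proposals
with probability ω (default 0.2), pseudogenes accept everything. This
ω-thinning formulation was chosen over a full codon rate matrix for
transparency and speed; calibration tests confirm the realized NG estimate
centers on the nominal ω (≈1 under ω = 1; within ±0.1 under ω = 0.2).
Pseudogenization writes a literal lesion — a 1–2 nt frameshift deletion or
an in-frame premature stop, with equal probability — so downstream
classification recall is exactly testable. The intron evolves neutrally at
2× the clock with occasional small deletions; its GT/AG ends are conserved
and its length is kept ≥ 50 nt. Horizontal transfer copies a random extant
copy verbatim from one genus into another at the event time (no
transfer-associated mutation), matching the identity-based detection logic;
a `forced_ht_age` knob implants one transfer at a chosen age for
sensitivity studies. Indels are deletions only, tracked in a fixed master
coordinate system, so the emitted alignment is exact by construction.

Default rates were chosen once to mirror the study conditions: ~50%
of extant copies functional, within/between-lineage coding identity
bracketing roughly 75–100%, and a few dozen extant copies across 8 genera —
desk-scale problem sizes (120 codons, 80 nt intron) that keep the whole
suite fast while leaving every statistic well inside its asymptotic
regime.

What the simulator does **not** emulate: insertion-site context (TIRs,
TSDs), non-autonomous element dynamics, insertions, PCR/sequencing error
beyond what the QC filter models, rate heterogeneity among coding sites,
and biased codon usage. Passing recovery tests on simulated data therefore
demonstrates internal consistency of the estimators under the assumed
generative model, not robustness to every feature of real clone libraries.

## Published-data checks

Four checks in the acceptance suite reproduce numbers computed from the 240
deposited GenBank records (KT024997–KT025236): the 127/113
functional/nonfunctional split, mean pairwise dN/dS ≈ 0.203 over the 126
functional sequences (±0.03, absorbing unstated settings of the original
software), minimum identity ≈ 85.69% (reduced) / 72.5% (complete, most
divergent pair *Eremopyrum bonaepartis* × *Crithopsis delileana*), and
exactly two identical cross-genus pairs. These require a one-time download
(`scripts/fetch_accessions.py`, network + mafft) into `data/deposited/`;
without those files the four tests fail with an explanatory message rather
than silently passing or skipping. Everything else runs from code alone.

## Numerical choices and degenerate inputs

- 0-based, half-open coordinates everywhere.
- `N` counts as a mismatch under the `complete` identity policy, is skipped
  under pairwise deletion, and excludes its codon from NG counting.
- Identical pairs: ω undefined and Z-test refused, with typed errors.
- Empty FASTA, < 3 taxa for NJ, tree/alignment taxon mismatches, saturated
  distances and copy-number explosions (> 10,000) all raise early, typed
  errors.
- All stochastic components (bootstraps, simulator, Z-test resampling) are
  pure functions of their seed.
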