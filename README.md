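# te-evoscan

Evolutionary analysis of transposase-gene families cloned from related host
species — built around PIF/Harbinger-superfamily DNA transposons in grasses,
but generic over any short conserved transposase-domain fragment with host
taxonomy in the FASTA headers.

Transposable elements propagate vertically with their hosts, duplicate,
decay into pseudogenes, and occasionally jump between reproductively
isolated lineages. Given a clone library of transposase-domain fragments
(~360 bp coding, typically interrupted by a short spliceosomal intron),
this package answers:

1. **Which copies are potentially functional?** QC (within-individual
   deduplication, a 1-bp polymerase-error filter), reading-frame location by
   conserved anchor motifs (GAMDGTH / ELFNPRH flanking the DD of the DDE
   catalytic triad), GT..AG intron excision, and classification into
   functional / frameshift / premature-stop.
2. **What selection acts on them?** Pairwise Nei–Gojobori counting with
   Jukes–Cantor correction: for each pair, potential synonymous (S) and
   nonsynonymous (N) sites, observed differences averaged over minimal
   mutational pathways (stop-crossing pathways excluded), pS = Sd/S,
   pN = Nd/N, dS and dN via d = −(3/4)ln(1 − (4/3)p), and ω = dN/dS.
   Neutrality is tested per pair with a codon Z-test,
   Z = (dN − dS)/SE, SE by seeded bootstrap over codon columns; ω ≪ 1
   across pairs is the signature of purifying selection on an active
   transposase.
3. **Did any copy move horizontally?** Neighbor-joining trees on
   JC distances with bootstrap support and midpoint rooting, supported-clade
   extraction, and a conservative cross-genus identity screen: a fully
   identical coding pair spanning genera that diverged 13–25 My ago is
   incompatible with vertical descent, because selection cannot stop
   synonymous changes from accumulating. Near-identical pairs and intron
   identity provide corroborating tiers.

A forward codon simulator generates families with exactly this structure —
divergent ancestral lineages in an ultrametric host-genus tree, ω-thinned
substitution on functional copies, literal frameshift/stop lesions on
pseudogenization, a fast neutral intron, optional verbatim horizontal
transfers — together with a complete ground-truth log, so every stage of
the analysis is testable against known answers. Fixed-tree GTR+Γ(+I)
likelihood evaluation (Felsenstein pruning) is included for model-based
scoring of inferred topologies.

## Worked example

Simulate a family and run the full pipeline on its exact alignment:

```bash
te-evoscan simulate --seed 4 --out fix
cat > config.yaml <<EOF
input_fasta: fix/sim_coding_aligned.fasta
input_is_coding_alignment: true
intron_fasta: fix/sim_intron_aligned.fasta
out_dir: out
seed: 4
tree_bootstrap: 100
EOF
te-evoscan run --config config.yaml
```

The report (abridged, as printed):

```json
{
  "n_input": 47,
  "n_complete": 47,
  "n_reduced": 32,
  "n_nonfunctional": 15,
  "status_counts": {"functional": 32, "premature_stop": 11, "frameshift": 4},
  "identity_complete": {"min_pct": 75.49, "max_pct": 99.72},
  "identity_reduced": {"min_pct": 80.28, "max_pct": 99.72},
  "selection": {
    "n_pairs": 496,
    "mean_omega": 0.260,
    "frac_rejecting_neutrality": 0.919
  },
  "ht_n_identical": 0,
  "ht_n_near_identical": 0
}
```

Reading it: of 47 nonredundant copies, 32 have intact reading frames
(the reduced set) and 15 carry frameshifts or premature stops; coding
identity spans 75–100% (the deepest splits are the ancestral transposase
lineages, which predate the host genera); mean pairwise ω ≈ 0.26 with 92%
of pairs rejecting neutrality — purifying selection, as simulated
(true ω = 0.2) — and no cross-genus identical pairs, as expected with
transfers disabled. `out/` additionally holds midpoint-rooted newick trees
with bootstrap support, supported-clade tables, the per-pair selection
table, and a machine-readable `report.json`.

The standalone subcommands `qc`, `dnds`, `tree`, `htscan`, `simulate`
expose each stage separately; `--help` documents their flags.

## Layout

```
src/te_evoscan/
  records.py     core types (TransposaseRecord, CodonAlignment)
  seqio.py       FASTA/newick I/O, taxon-header parsing
  qc.py          dedup, 1-bp filter, frame location, intron excision, classification
  evometrics.py  identity, JC, Nei-Gojobori, codon Z-test, distance matrices
  phylo.py       NJ, bootstrap, midpoint rooting, GTR+Gamma(+I) pruning, clades
  htscreen.py    cross-genus identity screen + intron corroboration
  simulate.py    forward simulator with ground truth
  pipeline.py    config validation and orchestration
  cli.py         te-evoscan command group
docs/methods.md  model assumptions, defaults, numerical choices, limitations
```
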