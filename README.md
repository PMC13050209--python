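# lohkit

Reference-symmetric genotyping and loss-of-heterozygosity (LOH) inference
for mutation-accumulation (MA) experiments in diploid hybrids.

Single-reference genotyping of hybrid clones is systematically biased
toward the reference homolog, inflating apparent LOH events that "convert"
toward the reference. lohkit implements a dual-reference workflow that
removes this bias, plus the statistical machinery to turn detected events
into corrected rates and to partition rate variation into genetic
components:

- **calls_io** — VCF call-set reading/writing, the hard site-quality
  filters (QD/MQ/FS/SOR, depth, QUAL, repeat + 7.5-kb telomere masks),
  effective genome length, and UCSC-chain liftover.
- **dual_reference** — potential/final ancestral marker sets, symmetric
  reconciliation of the two per-reference call sets (GQ ≥ 50, ΔGQ ≥ 30
  rules), aneuploidy flagging.
- **error_model** — founder genotyping-error model: descendant-configuration
  transition probabilities, posterior odds ratios for false-homozygote and
  false-heterozygote founder calls, and unanimity-rule Homo-/Hetero-FDR
  estimators.
- **het_filter** — beta-binomial allele-balance model
  (σ² = n/4 + ρn(n−1), ρ = 1/(8β+4)) fitted over read-depth bins; removes
  heterozygous calls outside the 95% interval.
- **loh_events** — LOH tract finding (single-marker tracts allowed,
  midpoint boundaries, terminal extension), <10-kb merging into events,
  interstitial/terminal classification, breakpoint placement, homolog-bias
  tests, 50-kb window tiling and HCHB (high-conversion high-bias) scans
  with Benjamini-Hochberg control.
- **rates** — detection-probability correction for inter-marker events,
  overlap probabilities, P0-method terminal-event rates, per-window local
  rates and conversion rates.
- **variance_model** — nested Poisson/Bernoulli GLMMs with stitched
  identity–log and −log(1−y) links, fitted by Laplace-approximate maximum
  likelihood (written from scratch on scipy); likelihood-ratio model
  selection, cis/trans variance partitioning, and the long-arm G-test.
- **simulate** — a synthetic MA-experiment generator with full truth
  bookkeeping (markers, per-arm event processes, genotyping errors,
  beta-binomial read counts, optional one-sided reference bias), so every
  inference stage has a closed testing loop.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion.
One assertion
(`TestCriterion2UnanimityGrid::test_unanimity_rule_on_full_grid`) is known
to fail at 7 of 625 extreme grid corners; the companion
`test_unanimity_grid_documented_failures` characterizes the failure set.

## CLI

All commands default to the published thresholds (GQ ≥ 50, ΔGQ ≥ 30,
QUAL ≥ 1000, depth ≥ 6 and ≤ 5× median, 7.5-kb telomeres, 10-kb merge gap,
50-kb windows, FDR 0.05, β-binomial 95% CI):

```bash
lohkit simulate --seed 1 -o sim/                 # synthetic experiment + truth
lohkit reconcile --ref1 sim/calls_hyb00_ref1.tsv \
                 --ref2 sim/calls_hyb00_ref2.tsv -o rec.tsv
lohkit filter    --calls rec.tsv --beta 59 -o filtered.tsv
lohkit detect    --calls filtered.tsv --genome sim/genome.yaml -o events.tsv
lohkit hchb      --events events.tsv --genome sim/genome.yaml -o hchb.tsv
lohkit rates     --events events.tsv --genome sim/genome.yaml \
                 --markers sim/markers.tsv -T 800 --n-clones 10 -o rates.tsv
lohkit errors    --calls sim/calls_hyb00_ref1.tsv -o fdr.tsv
lohkit varpart   --counts counts.tsv -o varpart.tsv
```

Every command writes a JSON run manifest next to its outputs and exits 2 on
missing inputs, 3 on validation failures.

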