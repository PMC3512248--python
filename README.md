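# lgtrates

Detection, dating, and rate estimation of lateral gene transfer (LGT) events
for metabolic genes on a dated reference phylogeny.

The pipeline follows a confirm-then-count design:

1. **Ancestral state reconstruction** (`lgtrates.asr`) — binary-trait
   maximum likelihood under the one-rate Mk model on the time-scaled
   reference tree flags *candidate gain edges*: branches whose parent likely
   lacked a gene and whose child likely carried it.
2. **Congruence assessment** (`lgtrates.congruence`) — gene-tree clades
   subtended by a candidate gain are compared against the reference
   topology. A clade is a `supported_conflict` when a bipartition with
   support ≥ 70% (either bootstrap or posterior track) is incompatible with
   the induced reference subtree; an `alternative_rooting` when its unrooted
   topology matches the reference but its basal split differs; otherwise
   `congruent` (or `unresolved` for tiny/support-free clades).
3. **Event inference** (`lgtrates.events`) — confirmed (gene, clade) pairs
   become transfer events; events over identical recipient clades whose gene
   copies are genomically adjacent (operonic, gap ≤ 1 ORF by default) are
   collapsed into single events; duplication-ambiguity flags yield min/max
   counts; counts divide by the domain age (3.5 Gy) to give rates in events
   per billion years (rounded half-away-from-zero to one decimal).
4. **Dating** (`lgtrates.dating`) — penalized-likelihood rate smoothing
   converts substitution branch lengths into node ages under min/max age
   constraints, so each event gets a geologic age interval. A pre-dated tree
   bypasses this stage.

Supporting modules: `lgtrates.trees` (Newick/tabular I/O and the tree data
model), `lgtrates.simulate` (birth–death reference trees and gene histories
with implanted transfers/losses/linkage), `lgtrates.datasets` (a bundled
survey of archaeal metabolic gene clades, linkage and duplication flags plus
a small dated reference tree used by the tests and the acceptance report),
`lgtrates.pipeline` / `lgtrates.cli` (YAML-driven orchestration and
reporting).

## CLI

A single entry point with subcommands:

```bash
# write a synthetic input bundle (reference tree, presence matrix,
# gene trees, linkage table, truth file)
lgtrates simulate --n-taxa 32 --n-genes 3 --transfer-rate 0.05 --seed 1 --out-dir bundle/

# per-gene ancestral state reconstruction (per-node marginals as TSV)
lgtrates asr --tree bundle/reference.nwk --matrix bundle/presence.tsv --gene g1 --out asr.tsv

# penalized-likelihood dating under an age-constraint table
lgtrates date --tree tree.nwk --constraints constraints.tsv --clades clades.tsv --out ages.tsv

# assess gene-tree clades against the reference topology
lgtrates assess --gene-tree gene.nwk --ref-tree ref.nwk --clades clades.tsv --out verdicts.tsv

# full detection pipeline from a YAML config; emits events.tsv + summary.tsv
lgtrates detect --config bundle/config.yaml --out-dir out/

# re-summarise a previously written events table
lgtrates report --events out/events.tsv --config bundle/config.yaml --out summary.tsv
```

Exit codes: 0 success, 1 validation error, 2 runtime error.

A minimal `detect` config:

```yaml
reference_tree: reference.nwk     # dated (branch lengths in Gy) or dated upstream
presence_matrix: presence.tsv     # taxon x gene 0/1 matrix
linkage: linkage.tsv              # taxon, copy_a, copy_b, gap_orfs
gene_trees: {g1: gene_g1.nwk}
categories: {all genes: [g1]}
thresholds: {support: 70, present: 0.7, absent: 0.3, max_gap_orfs: 1}
domain_age: 3.5
```

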