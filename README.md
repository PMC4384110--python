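# sandwichfold

Rule-grammar recognition of seven-strand beta-sandwich protein sequences.

The classifier decides whether an amino-acid sequence can host the two-sheet
sandwich fold: it searches for a placement of seven 6-residue strand windows
joined by six loops (loop lengths 3–16, total 30–60) such that a set of
residue-count rules holds — counts of residue classes at core-facing
positions, surface-facing positions and whole strands, per strand, over the
interlock strands (2, 3, 5, 6), over the non-interlock strands (1, 4, 7) and
over all strands, plus loop-composition rules built on a "loop-favorable"
score. The decision is purely boolean: a sequence is accepted iff some
placement satisfies every rule.

The package also ships:

* **topology** — abstract supersecondary-structure analysis: partition of
  strands into *strandons* (maximal runs of consecutive, H-bonded strands),
  the two strand-arrangement constraints, and detection of the *interlock*
  (the cross-sheet pairing of strands i, i+1 with j, j+1 that characterizes
  the sandwich architecture).
* **synth** — generators for labeled benchmark data: positives guaranteed
  to satisfy the grammar with known strand coordinates, targeted negatives
  that provably cannot satisfy a chosen rule group, and random background
  sequences.
* **evaluation** — sensitivity/specificity scoring, the six rule-subset
  ablation presets, and a bound-fitting primitive that recovers empirical
  count intervals from annotated positives.

## CLI

```bash
# classify sequences (TSV report on stdout; witness strand starts are 1-based)
sandwichfold classify input.fasta
sandwichfold classify input.fasta --explain --format json --out report.json

# generate a labeled benchmark (FASTA + truth TSV)
sandwichfold simulate --n-pos 50 --n-neg 10 --n-random 50 --seed 1 --out-prefix bench

# score a labeled set / run the ablation presets
sandwichfold evaluate bench.fasta bench.truth.tsv
sandwichfold ablate bench.fasta bench.truth.tsv

# supersecondary-structure checks on a topology JSON file
sandwichfold topology check topo.json
sandwichfold topology interlock topo.json

# emit the default rule set (the override-file schema) as YAML
sandwichfold dump-rules
```

Topology JSON: `{"n_strands": 7, "sheets": [[1,2,5,4],[7,6,3]],
"hbond_pairs": [[1,2],[2,5],[5,4],[7,6],[6,3]]}`.

Rule overrides: a YAML/JSON document whose entries replace fields of the
default rule set; `sandwichfold dump-rules` prints the full schema with
provenance notes. Example:

```yaml
geometry:
  parity: even-in          # flip which strand positions face the core
loop_rules:
  favorability_coefficient: 0.5
rules:
  - id: t1r4
    all: [0, 3]            # loosen the Cys grand total
```

Exit codes: 0 success (accept/reject lives in the report), 1 usage error,
2 data/validation error.

## Library

```python
from sandwichfold import default_ruleset, search, explain

rs = default_ruleset()
decision = search(sequence, rs)
if decision.accepted:
    print(decision.witness.strand_starts_1based())
else:
    a, report = explain(sequence, rs).best_failing
    print(report.rule_ids())
```

`enumerate_satisfying(seq, rs)` lists *all* satisfying placements in
canonical order (length-guarded oracle mode); `search` returns the first
one and is verified against it property-wise in the test suite.

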