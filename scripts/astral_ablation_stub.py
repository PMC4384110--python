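#!/usr/bin/env python
"""OPTIONAL, UNTESTED stub: run the ablation presets on an external
structure-database sequence set.

The published evaluation used a non-redistributable sequence collection
with fold labels (tens of thousands of domain sequences at <95% identity).
Reproducing those absolute counts requires downloading that dataset and
mapping its fold labels to positive/negative yourself.  Once you have:

  * a FASTA file of domain sequences, and
  * a TSV with columns ``id`` and ``label`` (``positive`` for seven-strand
    two-sheet sandwich domains, ``negative`` otherwise),

run::

    python scripts/astral_ablation_stub.py domains.fasta labels.tsv > table.tsv

Long sequences make the search slower; consider filtering to domains of
roughly 70-250 residues first.  This stub is not exercised by the test
suite and ships for documentation only.
"""

import sys


def main() -> int:
    if len(sys.argv) != 3:
        print(__doc__, file=sys.stderr)
        return 1
    fasta, labels = sys.argv[1], sys.argv[2]

    from sandwichfold import default_ruleset
    from sandwichfold.evaluation import ablation_presets, run_ablation
    from sandwichfold.io import read_fasta, read_truth_table
    from sandwichfold.synth import AnnotatedSequence

    truth = read_truth_table(labels)
    records = [
        AnnotatedSequence(
            id=rec.id, sequence=rec.residues, label=truth[rec.id]["label"]
        )
        for rec in read_fasta(fasta)
        if rec.id in truth
    ]
    table = run_ablation(records, ablation_presets(default_ruleset()))
    sys.stdout.write(table.to_csv(sep="\t", index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
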