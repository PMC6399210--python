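"""Run the whole analysis end to end on the bundled synthetic world.

Simulates two retention classes of gene families, reconciles and splits
them into orthogroups, clusters and classifies copy-number profiles,
computes WGD retention rates and the tau class contrast, runs Ka/Ks on
simulated codon pairs, and writes one table per stage plus a JSON report.
"""

import json

from paleologs import run_pipeline

report = run_pipeline(
    {
        "seed": 1,
        "simulate": {"families_per_class": 15},
        "kaks": {"replicates": 5, "codons": 300},
    },
    out_dir="scratch/example_pipeline",
)

print(json.dumps(report.summary, indent=2, default=float))
print("\ntables written to:", report.out_dir)
for name, path in report.paths.items():
    print(f"  {name:18s} {path}")
print(
    "\n-> retention_rates approach the simulated per-class retention"
    " probabilities, and tau_contrast_p is the rank-sum p-value for the"
    " broad-vs-narrow tissue-specificity difference."
)
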