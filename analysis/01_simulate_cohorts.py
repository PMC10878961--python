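"""Generate the two synthetic cohorts every later step analyses.

Writes full fixture bundles (matrices, hashtag counts, gene lengths, planted
gene sets, truth manifests) under scratch/fixtures/ — they are bulky working
data — and a small design summary under results/.

The bulk cohort emulates a three-batch compendium of young and aged samples
with the immediate-early-response (IER) signature induced 2-fold in batch 1;
the single-cell cohort emulates the 4-condition hashing experiment
(ice / ice+TP / 37C / 37C+TP, 400 cells each) with 50 IER genes induced
~4-fold at 37C and blocked by triptolide.
"""

import sys
from pathlib import Path

import pandas as pd

from iersig import BulkSimConfig, ScSimConfig, write_fixture_bundle

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11


def main():
    fixtures = ROOT / "scratch" / "fixtures"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    bulk_cfg = BulkSimConfig(seed=SEED)
    sc_cfg = ScSimConfig(seed=SEED)
    bulk_files = write_fixture_bundle(fixtures / "bulk", bulk_cfg, force=True)
    sc_files = write_fixture_bundle(fixtures / "sc", sc_cfg, force=True)

    summary = pd.DataFrame([
        {"cohort": "bulk", "n_genes": bulk_cfg.n_genes,
         "n_samples": bulk_cfg.n_samples, "ier_genes": bulk_cfg.ier_gene_count,
         "ier_fold": bulk_cfg.ier_fold, "seed": SEED},
        {"cohort": "single_cell", "n_genes": sc_cfg.n_genes,
         "n_samples": sum(sc_cfg.n_cells.values()),
         "ier_genes": sc_cfg.ier_gene_count,
         "ier_fold": sc_cfg.stress_fold_median, "seed": SEED},
    ])
    summary.to_csv(results / "01_cohort_design.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nbulk fixture bundle: {bulk_files['matrix'].parent}")
    print(f"single-cell fixture bundle: {sc_files['counts'].parent}")


if __name__ == "__main__":
    main()
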