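"""Signature-fraction variability audit of the bulk cohort.

For the planted IER signature and, as controls, the planted aging set and a
random same-size set, computes the per-sample signature fraction and the
centile of its coefficient of variation against 10,000 random same-size gene
sets (seed 123).  A stress signature restricted to one batch shows a CV far
beyond random sets; an aging effect spread over half the samples in every
batch is milder; a random set sits in the bulk of the null.

Writes per-sample fractions and the audit summary under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from iersig import BulkSimConfig, GeneSet, simulate_bulk
from iersig.workflows import run_bulk_audit

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11


def main():
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    cfg = BulkSimConfig(seed=SEED)
    m, truth = simulate_bulk(cfg)
    rng = np.random.default_rng(SEED + 1)
    signatures = {
        "IERsig": GeneSet("IERsig", truth.ier_genes),
        "aging": GeneSet("aging", truth.aging_genes),
        "random78": GeneSet("random78", frozenset(
            rng.choice(m.gene_ids, size=78, replace=False))),
    }

    frac_rows, audit_rows = [], []
    for name, sig in signatures.items():
        frac, boot = run_bulk_audit(m, sig, B=10_000, seed=123)
        for s in m.sample_ids:
            frac_rows.append({
                "signature": name, "sample_id": s, "fraction": frac[s],
                "batch": m.sample_meta.loc[s, "batch"],
                "age_group": m.sample_meta.loc[s, "age_group"],
            })
        audit_rows.append({
            "signature": name, "set_size": boot.set_size,
            "signature_cv": boot.signature_cv,
            "null_cv_median": float(np.median(boot.null_cvs)),
            "percentile": boot.percentile, "B": boot.B, "seed": boot.seed,
        })

    pd.DataFrame(frac_rows).to_csv(results / "02_signature_fractions.tsv",
                                   sep="\t", index=False)
    audit = pd.DataFrame(audit_rows)
    audit.to_csv(results / "02_bootstrap_audit.tsv", sep="\t", index=False)
    print(audit.to_string(index=False))
    ier = audit.set_index("signature").loc["IERsig"]
    print(f"\nThe planted IER signature's fraction CV ({ier.signature_cv:.3f}) "
          f"sits at the {ier.percentile:.1f}th centile of the random-set null "
          f"— the variability footprint of a batch-restricted stress artifact.")


if __name__ == "__main__":
    main()
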