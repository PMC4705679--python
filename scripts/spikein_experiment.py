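#!/usr/bin/env python
"""Optional full-scale spike-in benchmark (requires external data).

Runs the complete test on the public SEQC spike-in count matrix (GEO series
GSE49712: groups A and B, five technical replicates each, 92 synthetic
spike-in controls at fold changes 0.5, 0.67, 1 and 4) and reports

  * ROC AUC of the statistic over the spike-in controls (DE vs non-DE), and
  * the number of false positives at FDR < 0.05 among the 23 fold-change-1
    controls.

The data are NOT bundled; download the series' supplementary count matrix
from GEO and supply a control truth table (control id, fold change — the
published spike-in mix ratios) with matching row identifiers:

  python scripts/spikein_experiment.py \\
      --counts GSE49712_HTSeq.txt --ercc-truth ercc_fold_changes.tsv \\
      [--b 1000] [--seed 0] [--out report.json]

The counts file must be delimited text, genes in rows, with a sample header
containing five group-A and five group-B columns (A* columns are assigned to
group 1, B* to group 2 unless --design is given).
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--counts", type=Path, required=True)
    parser.add_argument("--ercc-truth", type=Path, required=True,
                        help="two-column table: control gene id, fold change")
    parser.add_argument("--design", type=Path, default=None,
                        help="optional two-column design file; by default "
                             "samples starting with A/B form groups 1/2")
    parser.add_argument("--b", type=int, default=1000)
    parser.add_argument("--p-perms", type=int, default=None)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--fdr-cutoff", type=float, default=0.05)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args(argv)

    import rots

    counts = rots.read_counts(args.counts)
    if args.design is not None:
        design = rots.read_design(args.design)
    else:
        groups = []
        for s in counts.sample_ids:
            if s.upper().startswith("A"):
                groups.append(1)
            elif s.upper().startswith("B"):
                groups.append(2)
            else:
                sys.exit(f"cannot infer group of sample {s!r}; use --design")
        design = rots.GroupDesign(counts.sample_ids, np.array(groups))

    fit = rots.run_rots(
        counts, design, B=args.b, P=args.p_perms, seed=args.seed
    )

    truth = pd.read_csv(args.ercc_truth, sep=None, engine="python", header=None)
    fc_of = dict(zip(truth.iloc[:, 0].astype(str), truth.iloc[:, 1].astype(float)))
    stat_of = dict(zip(fit.gene_ids, fit.statistic))
    fdr_of = dict(zip(fit.gene_ids, fit.fdr))
    controls = [g for g in fc_of if g in stat_of]
    missing = sorted(set(fc_of) - set(controls))
    if missing:
        print(f"warning: {len(missing)} control(s) absent from results "
              f"(zero counts or id mismatch): {missing[:5]}...", file=sys.stderr)

    flags = np.array([fc_of[g] != 1.0 for g in controls])
    scores = np.array([stat_of[g] for g in controls])
    auc = rots.roc_auc(scores, flags)
    null_controls = [g for g in controls if fc_of[g] == 1.0]
    false_pos = sum(fdr_of[g] < args.fdr_cutoff for g in null_controls)

    report = {
        "auc_spikein_controls": round(float(auc), 6),
        "false_positives_fc1_controls": int(false_pos),
        "n_fc1_controls_evaluated": len(null_controls),
        "n_controls_evaluated": len(controls),
        "Z_opt": round(fit.Z_opt, 4),
        "R_opt": round(fit.R_opt, 4),
        "alpha": [fit.alpha.a1, fit.alpha.a2],
        "k_opt": fit.k_opt,
        "B": fit.B,
        "seed": fit.seed,
    }
    text = json.dumps(report, indent=2)
    print(text)
    if args.out is not None:
        args.out.write_text(text + "\n")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
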