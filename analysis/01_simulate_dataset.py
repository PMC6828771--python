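#!/usr/bin/env python
"""Generate the synthetic wound-response datasets with planted ground truth.

Writes a control time course (genes, RNA-seq counts in triplicate over
{0,1,3,6,12} h, duplicate ChIP coverage + peak calls for five histone marks
over {0,1,3,6} h, and the truth table) plus a matched
histone-acetyltransferase-inhibitor arm in which induction trajectories are
flattened and acetylation gains suppressed.
"""

import argparse
from pathlib import Path

from woundchrom.simulate import SyntheticConfig, write_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--n-genes", type=int, default=2000)
    args = ap.parse_args()

    cfg = SyntheticConfig(n_genes=args.n_genes, seed=args.seed)
    for name, inhibitor in (("dataset", False), ("dataset_mb3", True)):
        manifest = write_dataset(cfg, args.out / name, inhibitor=inhibitor)
        print(f"{name}: {len(manifest['files'])} files "
              f"({'inhibitor' if inhibitor else 'control'} arm, "
              f"seed {args.seed}, {args.n_genes} genes)")
    truth_classes = cfg.class_proportions
    print("planted class proportions:",
          ", ".join(f"{k}={v:g}" for k, v in truth_classes.items()))


if __name__ == "__main__":
    main()
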