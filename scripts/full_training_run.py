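#!/usr/bin/env python
"""Full-size training run on an externally curated kinetics dataset.

This script is for benchmarking against real measured turnover numbers,
which are not shipped with the repository.  Supply your own CSV with columns
``smiles, sequence, temperature_C, kcat_s`` (one row per measurement; pass
--fasta to resolve a ``sequence_id`` column instead).  It applies the
full curation pipeline (deduplication, pair-disjoint split, low/high
temperature oversampling), trains the full-width architecture, and reports
held-out metrics.

Usage:
    python scripts/full_training_run.py --data my_kinetics.csv \
        --epochs 60 --seed 0 --out results/full_model.npz

Expect hours of CPU time at full width on datasets of tens of thousands of
entries; start with --small to smoke-test your file.
"""

import argparse
import pathlib

import thermokcat as tk
from thermokcat.train import (TrainConfig, deduplicate, evaluate, oversample,
                              pair_disjoint_split, read_kinetics_csv,
                              train_model)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", required=True, help="kinetics CSV")
    ap.add_argument("--fasta", default=None,
                    help="FASTA file resolving a sequence_id column")
    ap.add_argument("--epochs", type=int, default=60)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--small", action="store_true",
                    help="compact architecture for smoke tests")
    ap.add_argument("--out", required=True, help="checkpoint path (.npz)")
    args = ap.parse_args()

    entries = deduplicate(read_kinetics_csv(args.data, fasta=args.fasta))
    print(f"{len(entries)} unique (compound, protein, T) measurements")
    train, val, test = pair_disjoint_split(entries, (0.8, 0.1, 0.1),
                                           seed=args.seed)
    train = oversample(train, seed=args.seed)
    print(f"train {len(train)} (after oversampling) / val {len(val)} / "
          f"test {len(test)}")

    mc = (tk.ModelConfig.small(seed=args.seed) if args.small
          else tk.ModelConfig(seed=args.seed))
    tc = TrainConfig(epochs=args.epochs, seed=args.seed)
    model, history = train_model(train, val, mc, tc, verbose=True)
    model.save(args.out)
    history.to_csv(pathlib.Path(args.out).with_suffix(".history.csv"),
                   index=False)

    preds = model.predict([(e.smiles, e.sequence, e.temperature_C)
                           for e in test])
    m = evaluate(preds, [e.log10_kcat for e in test])
    print(f"held-out (pair-disjoint): rmse={m.rmse:.4f} mae={m.mae:.4f} "
          f"r2={m.r2:.4f} (n={len(test)})")


if __name__ == "__main__":
    main()
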