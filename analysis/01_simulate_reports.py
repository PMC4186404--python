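#!/usr/bin/env python
"""Simulate an AERS-like spontaneous-report corpus with a planted atrophy signal.

Generates a corpus in which glibenclamide carries a planted muscle-atrophy
relative reporting rate of 12 (the disproportionality the published counts
imply), with 2% duplicate reports and a small positive-rechallenge
fraction, then writes it as a three-table $-delimited dump plus the
planted-truth ledger.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from atrophysignal.report_store import Dialect, write_reports
from atrophysignal.synthetic import ReportSimConfig, gen_reports


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n", type=int, default=100_000, help="number of reports")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/simulated_reports"))
    args = parser.parse_args()

    config = ReportSimConfig(
        n_reports=args.n,
        planted_signals=(("GLIBENCLAMIDE", "MUSCLE ATROPHY", 12.0),),
        duplicate_fraction=0.02,
        pos_rechallenge_fraction=0.001,
        seed=args.seed,
    )
    store, ledger = gen_reports(config)
    write_reports(store, args.out, Dialect.AERS_DOLLAR)
    (args.out / "ledger.json").write_text(
        json.dumps(
            {
                "config": dataclasses.asdict(config),
                "n_planted_duplicates": ledger.n_planted_duplicates,
                "n_pos_rechallenge": len(ledger.pos_rechallenge_ids),
            },
            indent=2,
        )
    )
    atrophy = sum(1 for rec in store if "MUSCLE ATROPHY" in rec.reactions)
    print(f"wrote {len(store)} reports to {args.out}")
    print(f"  planted duplicates: {ledger.n_planted_duplicates}")
    print(f"  muscle-atrophy reports overall: {atrophy} ({100 * atrophy / len(store):.3f}%)")


if __name__ == "__main__":
    main()
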