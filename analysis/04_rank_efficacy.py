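#!/usr/bin/env python
"""Rank the drugs' atrophic potency per muscle from the published fits.

Builds the potency ranking (ascending EC50) for each muscle from the
published protein-content fit parameters with their standard errors, with
'>' where the adjacent EC50s differ significantly (two-sided z-test,
alpha = 0.05) and '>=' otherwise.  The FDB string should come out as
repa.>=glib.>glimep.>tolb.>nate., matching the published order.
"""

import argparse
import json
import math
from pathlib import Path

from atrophysignal.dose_response import HillFit, rank_efficacy
from atrophysignal.reference import (
    DRUG_ABBREV,
    PROTEIN_CONTENT_PARAMS,
    as_hill_params,
    complete_rows,
)


def fits_for_muscle(muscle: str) -> dict[str, HillFit]:
    fits: dict[str, HillFit] = {}
    for (drug, m), row in PROTEIN_CONTENT_PARAMS.items():
        if m != muscle:
            continue
        if row["ec50"] is None:
            fits[drug] = HillFit(params=None, se={}, rss=math.nan, converged=False, n_points=60)
        else:
            fits[drug] = HillFit(
                params=as_hill_params(row),
                se={"ec50": row["ec50_se"], "emax": row["emax_se"]},
                rss=0.0, converged=True, n_points=60,
            )
    return fits


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/rankings"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    out = {}
    for muscle in ("FDB", "SOL", "EDL"):
        ranking = rank_efficacy(fits_for_muscle(muscle))
        string = ranking.format(DRUG_ABBREV)
        out[muscle] = {"order": list(ranking.order), "relations": list(ranking.relations),
                       "string": string, "warnings": list(ranking.warnings)}
        print(f"{muscle}: {string}")
    (args.out / "protein_content_rankings.json").write_text(
        json.dumps(out, indent=2, ensure_ascii=False)
    )


if __name__ == "__main__":
    main()
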