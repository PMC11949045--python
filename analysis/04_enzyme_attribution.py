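#!/usr/bin/env python
"""Which APOBEC3 enzyme? YTCA vs RTCA tetranucleotide attribution.

A3A deaminates cytosine preferentially in a YTCA context (Y = C or T)
while A3B prefers RTCA (R = A or G). This driver plants three mutational
processes on the shared reference — an all-YTCA A3A-like process, an
all-RTCA A3B-like process, and a context-uniform control — across 20
simulated tumors each, and checks that the background-normalized
YTCA:RTCA ratio recovers the generating enzyme.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from apobec_emt import (
    attribute_enzyme,
    count_tca_contexts,
    make_reference,
    sample_tca_variants,
)

RESULTS = Path("results")
SEED = 20250926


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    reference = make_reference(100_000, 0.45, 1, seed=SEED)
    rows = []
    for flavor, truth in (
        ("ytca", "A3A-like"),
        ("rtca", "A3B-like"),
        ("uniform_tca", "none"),
    ):
        for i in range(20):
            variants = sample_tca_variants(
                reference, 100, flavor, seed=int(rng.integers(2**31 - 1))
            )
            counts = count_tca_contexts(variants, reference)
            call = attribute_enzyme(counts)
            rows.append(
                {
                    "tumor": f"{flavor}_{i + 1:02d}",
                    "generator": flavor,
                    "truth_label": truth,
                    "ytca": counts.ytca,
                    "rtca": counts.rtca,
                    "ratio_normalized": call.ratio_normalized,
                    "called_label": call.label,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "attribution.tsv", sep="\t", index=False)

    for flavor in ("ytca", "rtca"):
        sub = table[table["generator"] == flavor]
        acc = (sub["called_label"] == sub["truth_label"]).mean()
        print(
            f"{flavor:12s}: {acc:5.0%} of 20 tumors called "
            f"{sub['truth_label'].iloc[0]}"
        )
    uniform = table[table["generator"] == "uniform_tca"]
    finite = uniform["ratio_normalized"].replace([np.inf, -np.inf], np.nan).dropna()
    print(
        f"uniform_tca : median normalized YTCA:RTCA ratio {finite.median():.2f} "
        f"(no enzyme preference planted; ratio centers on 1)"
    )
    print(f"wrote {RESULTS}/attribution.tsv")


if __name__ == "__main__":
    main()
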