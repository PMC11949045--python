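#!/usr/bin/env python
"""De novo signature extraction with KL-NMF.

Two extraction experiments:

1. The cohort catalog from 02_fit_signatures.py. APOBEC mutations are a
   few percent of the total burden there, so a rank-2 factorization is
   expected to capture background structure rather than the APOBEC
   process — a useful negative control showing that de novo extraction
   needs either deep APOBEC exposure or many high-burden samples.

2. A cell-line-style experiment: 30 samples whose APOBEC (SBS2+SBS13)
   activity spans 0-90% of a flat background, mimicking deaminase-induced
   lines where APOBEC signatures dominate. Here rank-2 extraction should
   cleanly separate an APOBEC-like spectrum from the background.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from apobec_emt import (
    build_catalog,
    cosine_similarity,
    io,
    make_reference,
    match_signatures,
    mixture_distribution,
    nmf_extract,
    sample_variants,
)
from apobec_emt.catalog import MutationCatalog

SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")
SEED = 20250926


def cohort_extraction() -> None:
    catalog = io.read_catalog(SCRATCH / "catalog.tsv")
    signatures = io.read_signatures(SCRATCH / "signatures.tsv")
    met = MutationCatalog(catalog.counts.filter(like="_M"))
    result = nmf_extract(met, rank=2, n_restarts=20, seed=SEED)
    matches = match_signatures(result.signatures, signatures)
    apobec_mix = mixture_distribution(signatures, {"SBS2": 0.5, "SBS13": 0.5})
    print(f"cohort catalog ({len(met.samples)} metastatic samples, rank 2):")
    for denovo, ref, cos, _ in matches:
        cos_apo = cosine_similarity(result.signatures[denovo], apobec_mix)
        print(
            f"  {denovo}: best reference {ref} (cosine {cos:.3f}); "
            f"cosine to the SBS2+13 composite {cos_apo:.3f}"
        )
    print(
        "  -> background components only: at ~3% cohort-wide APOBEC burden the"
        " process is below what rank-2 extraction can isolate\n"
    )


def cell_line_extraction() -> None:
    signatures = io.read_signatures(SCRATCH / "signatures.tsv")
    reference = make_reference(100_000, 0.45, 1, seed=SEED + 1)
    rng = np.random.default_rng(SEED + 2)
    variants = []
    truth_w = []
    for i in range(30):
        w = float(rng.uniform(0, 0.9))
        truth_w.append(w)
        mix = mixture_distribution(
            signatures, {"SBS2": w / 2, "SBS13": w / 2, "SBS5": 1 - w}
        )
        variants += sample_variants(
            reference, mix, 5000, seed=int(rng.integers(2**31 - 1)),
            sample_id=f"line{i:02d}",
        )
    catalog = build_catalog(variants, reference)
    result = nmf_extract(catalog, rank=2, n_restarts=20, seed=SEED + 3)
    io.write_signatures(result.signatures, RESULTS / "denovo_signatures.tsv")
    apobec_mix = mixture_distribution(signatures, {"SBS2": 0.5, "SBS13": 0.5})
    background = signatures["SBS5"]
    rows = []
    for name in result.signatures.names:
        rows.append(
            {
                "denovo": name,
                "cosine_to_apobec_composite": cosine_similarity(
                    result.signatures[name], apobec_mix
                ),
                "cosine_to_background": cosine_similarity(
                    result.signatures[name], background
                ),
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "denovo_matches.tsv", sep="\t", index=False)
    print("cell-line-style catalog (30 samples, APOBEC weight 0-0.9, rank 2):")
    for _, r in frame.iterrows():
        kind = (
            "APOBEC-like"
            if r.cosine_to_apobec_composite > r.cosine_to_background
            else "background"
        )
        print(
            f"  {r.denovo}: cosine {r.cosine_to_apobec_composite:.3f} to SBS2+13"
            f" composite, {r.cosine_to_background:.3f} to background -> {kind}"
        )
    # exposures should track the planted per-sample APOBEC weight
    apo_col = frame.sort_values("cosine_to_apobec_composite").iloc[-1]["denovo"]
    rel = result.exposures.div(result.exposures.sum(axis=1), axis=0)[apo_col]
    corr = np.corrcoef(truth_w, rel.to_numpy())[0, 1]
    print(f"  exposure vs planted APOBEC weight: Pearson r = {corr:.3f}")
    print(f"wrote {RESULTS}/denovo_signatures.tsv and {RESULTS}/denovo_matches.tsv")


def main() -> None:
    if not (SCRATCH / "catalog.tsv").exists():
        raise SystemExit("run analysis/02_fit_signatures.py first")
    cohort_extraction()
    cell_line_extraction()


if __name__ == "__main__":
    main()
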