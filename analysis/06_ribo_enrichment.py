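#!/usr/bin/env python
"""Codon-resolved enrichment calling on a synthetic two-chaperone cohort.

Simulates selective-ribosome-profiling count tables for 40 genes in which
an upstream window is bound by chaperone A (PFD-like) and a downstream
window by chaperone B (TRiC-like), runs coverage filtering, positional
Fisher tests with per-gene BH correction and >=5-codon run calling for each
chaperone, and summarizes onset order and codon overlap
(results/ribo_calls.tsv, results/ribo_comparison.json).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from chaperotrack import riboenrich
from chaperotrack.simulate import simulate_ribo_counts

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260927
N_GENES = 40
GENE_LEN = 400
DEPTH = 20.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    profiles = {"A": {}, "B": {}}
    call_rows = []
    rng = np.random.default_rng(SEED)
    for g in range(N_GENES):
        start_a = int(rng.integers(40, 120))
        start_b = int(rng.integers(220, 300))
        windows = {"A": [(start_a, start_a + 40, 8.0)],
                   "B": [(start_b, start_b + 40, 8.0)]}
        for chap in ("A", "B"):
            df, _ = simulate_ribo_counts(
                GENE_LEN, DEPTH, windows[chap],
                seed=int(np.random.SeedSequence([SEED, g, ord(chap)])
                         .generate_state(1)[0] % 2**31),
                gene_id=f"g{g:03d}")
            gene = riboenrich.CodonCounts(f"g{g:03d}",
                                          df["input_count"].to_numpy(),
                                          df["ip_count"].to_numpy())
            if not riboenrich.coverage_filter([gene]):
                continue
            prof = riboenrich.profile_gene(gene)
            calls = riboenrich.call_interactions(prof)
            profiles[chap][gene.gene] = prof
            for s, e in calls:
                call_rows.append((chap, gene.gene, s, e,
                                  float(prof.p_adj[s - 1:e].min()),
                                  round(float(np.nanmean(prof.odds_ratio[s - 1:e])), 2)))
    calls_df = pd.DataFrame(call_rows, columns=["chaperone", "gene",
                                                "start_codon", "end_codon",
                                                "min_p_adj", "mean_or"])
    calls_df.to_csv(OUT / "ribo_calls.tsv", sep="\t", index=False)
    comparison = riboenrich.compare_chaperones(profiles["A"], profiles["B"])
    comparison["per_gene_overlap"] = {
        k: round(v, 3) for k, v in comparison["per_gene_overlap"].items()}
    (OUT / "ribo_comparison.json").write_text(json.dumps(comparison, indent=2))
    print(f"{len(calls_df)} interaction calls across {N_GENES} genes")
    print(f"A-before-B onset fraction: {comparison['onset_a_first_fraction']:.2f} "
          f"(shared genes: {len(comparison['shared_genes'])})")
    print(f"pooled codon overlap: {comparison['pooled_overlap']:.3f}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
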