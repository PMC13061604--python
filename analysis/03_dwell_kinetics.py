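#!/usr/bin/env python
"""Interaction-lifetime kinetics of every reference chaperone-client pair.

For each condition of the study (single-exponential and two-component
lifetime models) this regenerates n = 5,000 threshold-truncated,
frame-discretized dwell samples, fits the shifted survival function with
both models, applies the selection rule, and tabulates the recovered
parameters next to the generating ones (results/dwell_recovery.csv).
"""

from pathlib import Path

import pandas as pd

from chaperotrack.study import DWELL_CONDITIONS, recover_dwell_model

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260927


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, model in DWELL_CONDITIONS.items():
        rec = recover_dwell_model(model, n=5000, n_replicates=10, seed=SEED)
        if model.is_mixture:
            rows.append({
                "condition": name, "model": "two",
                "true_tau1": model.tau1, "fit_tau1": round(rec["tau1_hat"], 3),
                "true_tau2": model.tau2, "fit_tau2": round(rec["tau2_hat"], 3),
                "true_frac_long": round(1 - model.alpha, 3),
                "fit_frac_long": round(rec["alpha_long_hat"], 3),
                "selected": rec["majority_model"],
            })
        else:
            rows.append({
                "condition": name, "model": "single",
                "true_tau1": model.tau1, "fit_tau1": round(rec["tau_hat"], 3),
                "selected": rec["majority_model"],
            })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "dwell_recovery.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nrecovery table written to {OUT / 'dwell_recovery.csv'}")


if __name__ == "__main__":
    main()
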