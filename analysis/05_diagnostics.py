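#!/usr/bin/env python
"""Diagnostic performance of single and combined tissue criteria.

Writes the diagnostic-performance table (all printed combinations), the
per-method ROC AUCs with DeLong comparisons, and the McNemar / Cochran's Q
tests over the criteria, under results/diagnostics/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from t1topo.diagnostics import cochran_q, mcnemar_test
from t1topo.pipeline import RunConfig, run_all

RESULTS = Path(__file__).resolve().parents[1] / "results" / "diagnostics"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    bundle = run_all(RunConfig(master_seed=args.seed))
    RESULTS.mkdir(parents=True, exist_ok=True)
    table2 = bundle["table2"]
    table2.to_csv(RESULTS / "table2.csv", index=False)
    bundle["roc"].to_csv(RESULTS / "roc.csv", index=False)

    ps = bundle["per_subject"]
    complete = ps[["t1", "t2w", "lge"]].dropna().astype(bool)
    paired = {
        "t1_vs_t2w": mcnemar_test(complete.t1, complete.t2w),
        "t1_vs_lge": mcnemar_test(complete.t1, complete.lge),
    }
    q, df, q_p = cochran_q(complete)
    tests = {"mcnemar": paired, "cochran_q": {"Q": q, "df": df, "p": q_p},
             "delong": bundle["delong"]}
    (RESULTS / "tests.json").write_text(json.dumps(tests, indent=1) + "\n")

    cols = ["criterion", "sensitivity", "specificity", "accuracy", "ppv", "npv"]
    print(table2[cols].round(0).to_string(index=False))
    print("\nAUCs:", bundle["roc"].round(3).to_dict("records"))
    print("McNemar:", {k: round(v, 4) for k, v in paired.items()})
    print(f"Cochran's Q = {q:.2f} (df {df}, p {q_p:.2g})")


if __name__ == "__main__":
    main()
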