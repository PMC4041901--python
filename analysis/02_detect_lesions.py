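#!/usr/bin/env python
"""Apply the three tissue criteria to every cohort subject.

Runs T1 (>= 990 ms, 40 mm^2, 8-connected, contiguous-slice confirmation for
low-extent subjects), dark-blood T2W (ratio >= 2 or remote + 2 SD) and LGE
(remote + 2 SD) detection over the default cohort, then writes per-subject
decisions/markers and the segmental extent table under results/.
"""

import argparse
from pathlib import Path

from t1topo.pipeline import RunConfig, run_all

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    bundle = run_all(RunConfig(master_seed=args.seed))
    RESULTS.mkdir(exist_ok=True)
    bundle["per_subject"].to_csv(RESULTS / "per_subject.csv")
    bundle["extent"].to_csv(RESULTS / "extent.csv", index=False)

    ps = bundle["per_subject"]
    print("criterion positives by group:")
    print(ps.groupby("group")[["t1", "t2w", "lge"]].sum().astype(int).to_string())
    g3 = ps[ps.group == "III"]
    print(f"\nGroup III detected by T1: {int(g3.t1.sum())} of {len(g3)} "
          "(small focal injury, confirmed on contiguous slices)")


if __name__ == "__main__":
    main()
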