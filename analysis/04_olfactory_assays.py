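"""Assay stage: per-stimulus movement summaries and Fisher exact tests.

Reads the synthetic Y-tube outcomes, tests each stimulus against the
control arm, and writes results/assays/assay_tests.csv in the layout of
the published summary bar chart: stimulus, n, % moved, Fisher p, star.
"""

from pathlib import Path

import pandas as pd

from scabra import io as sio
from scabra.assays import AssayRecord, assay_vs_control

IN = Path("results/synthetic/assays.csv")
OUT = Path("results/assays")
ALPHA = 0.05


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    stim, controls = sio.read_assays(IN)
    control = AssayRecord(
        "control", sum(c.moved for c in controls), sum(c.total for c in controls)
    )
    rows = []
    for rec in stim:
        r = assay_vs_control(rec, control, alpha=ALPHA)
        rows.append(
            {"stimulus": rec.stimulus, "n": rec.total,
             "pct_moved": round(r.percent_moved),
             "p_value": r.p_value, "significant": "*" if r.significant else ""}
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "assay_tests.csv", index=False)
    print(f"control: {control.moved}/{control.total} moved "
          f"({100 * control.moved / control.total:.0f}%)")
    for _, r in df.iterrows():
        print(f"  {r.stimulus:<45} n={r.n:>3}  {r.pct_moved:>3}% moved  "
              f"p={r.p_value:.3g} {r.significant}")


if __name__ == "__main__":
    main()
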