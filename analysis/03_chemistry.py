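#!/usr/bin/env python
"""Validate the packaged chemistry tables and summarize their structure.

Loads the chlorophyll-extraction table (120 fronds) and the sequential-
elution Cu table (105 frond pairs, 15 pre-dose controls), checks the
per-row chlorophyll totals against a + b, and contrasts control and
post-dose Cu levels per tray.  Derived-column copies go to results/.
"""

from pathlib import Path

from mosslif.chemistry import load_chemistry_tables

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    chl, cu = load_chemistry_tables()
    chl.to_csv(RESULTS / "chlorophyll_derived.csv", index=False)
    cu.to_csv(RESULTS / "set_cu_derived.csv", index=False)

    resid = (chl["chl_a_per_mg"] + chl["chl_b_per_mg"] - chl["total_per_mg"]).abs()
    print(f"chlorophyll records: {len(chl)}; max |a + b - total| = {resid.max():.3f}")
    print(f"SET records: {len(cu)} ({int(cu['is_control'].sum())} controls)")

    print("\nmean dry-weight Cu by tray (as printed):")
    summary = cu.groupby(["tray", "is_control"])["cu_dw"].mean().unstack()
    summary.columns = ["post-dose", "control"]
    print(summary.round(3).to_string())

    t0 = chl[chl["sample"].str.startswith("T0")]
    pre = chl[chl["sample"].str.startswith("Cont")]
    print("\nmedian recomputed a/b ratio, pre-dose vs dosing day:")
    for tray in (1, 2, 3):
        a = pre[pre["tray"] == tray]["ab_ratio_recomputed"].median()
        b = t0[t0["tray"] == tray]["ab_ratio_recomputed"].median()
        print(f"  tray {tray}: {a:.2f} -> {b:.2f}")


if __name__ == "__main__":
    main()
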