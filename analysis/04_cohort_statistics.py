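#!/usr/bin/env python
"""Cohort statistics: group comparisons, correlations, grade trend.

Reads results/cohort.csv and results/cohort_by_grade.csv (from
03_simulate_cohort.py), runs Mann-Whitney tests of each metric between
genotypes, the Kruskal-Wallis grade trend for SDC, and the Pearson
correlations among metrics and with Ki-67.  Writes
results/cohort_stats.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from sdc_glioma import group_summary, kruskal_wallis, mann_whitney, pearson

ROOT = Path(__file__).resolve().parents[1]
METRICS = ["sdc_au_per_s", "ddvd_au_per_pixel", "adc_e4_mm2_per_s"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    df = pd.read_csv(args.results / "cohort.csv")
    dg = pd.read_csv(args.results / "cohort_by_grade.csv")
    out: dict = {"groups": {}, "tests": {}, "correlations": {}}

    g0 = df[df.idh_gene == 0]
    g1 = df[df.idh_gene == 1]
    for m in METRICS:
        out["groups"][m] = group_summary(df, m, "group").to_dict("records")
        r = mann_whitney(g0[m], g1[m])
        out["tests"][f"mann_whitney_{m}"] = {"u": r.u, "p": r.p}
        print(f"{m}: wildtype vs mutant Mann-Whitney p = {r.p:.2e}")

    groups = [dg.loc[dg.grade == g, "sdc_au_per_s"] for g in (2, 3, 4)]
    h, p = kruskal_wallis(*groups)
    out["tests"]["kruskal_wallis_sdc_by_grade"] = {"h": h, "p": p}
    print(f"SDC by grade (n=19/6/33): Kruskal-Wallis H = {h:.2f}, "
          f"p = {p:.2e}")

    for a, b in [("sdc_au_per_s", "adc_e4_mm2_per_s"),
                 ("sdc_au_per_s", "ddvd_au_per_pixel"),
                 ("sdc_au_per_s", "ki67_pct")]:
        c = pearson(df[a], df[b])
        out["correlations"][f"{a}~{b}"] = {
            "r": c.r, "ci": [c.ci_low, c.ci_high], "p": c.p, "n": c.n}
        print(f"Pearson {a} ~ {b}: r = {c.r:+.3f} "
              f"(95% CI {c.ci_low:+.3f} to {c.ci_high:+.3f}, p = {c.p:.3g})")

    (args.results / "cohort_stats.json").write_text(
        json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
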