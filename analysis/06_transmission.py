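#!/usr/bin/env python
"""Vertical-transmission cross analysis and prevalence heterogeneity.

Summarizes per-cross offspring infection proportions, compares maternal
vs paternal transmission and daughters vs sons with exact Wilcoxon
rank-sum tests, checks the double-uninfected control crosses for
contamination, and tests prevalence heterogeneity across populations
with a Pearson chi-squared test.
"""

import argparse
import json
from pathlib import Path

from sigmapop.transmission import (
    maternal_paternal_test,
    prevalence_chisq,
    read_crosses,
    read_prevalence,
    sex_difference_test,
    summarize_crosses,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--datadir", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "transmission.json")
    args = ap.parse_args()

    crosses = read_crosses(args.datadir / "crosses.tsv")
    summary = summarize_crosses(crosses)
    print(f"mean proportion offspring infected: maternal crosses "
          f"{summary.maternal_mean:.2f}, paternal crosses {summary.paternal_mean:.2f}")
    print(f"infected offspring in control crosses: {summary.control_contamination}")

    mp = maternal_paternal_test(crosses, seed=args.seed)
    print(f"maternal vs paternal (Wilcoxon {mp.method} rank test): "
          f"W = {mp.W:.0f}, p = {mp.p:.4g}")
    sd = sex_difference_test(crosses, seed=args.seed)
    print(f"daughters vs sons: W = {sd.W:.0f}, p = {sd.p:.4g}")

    prev = read_prevalence(args.datadir / "prevalence.tsv")
    cs = prevalence_chisq(prev)
    print(f"mean prevalence {prev.mean_prevalence:.0%}; heterogeneity "
          f"chi2 = {cs.chi2:.2f}, d.f. = {cs.df}, p = {cs.p:.4g}")

    args.out.write_text(json.dumps({
        "maternal_mean": summary.maternal_mean,
        "paternal_mean": summary.paternal_mean,
        "control_contamination": summary.control_contamination,
        "maternal_vs_paternal": {"W": mp.W, "p": mp.p, "method": mp.method},
        "daughters_vs_sons": {"W": sd.W, "p": sd.p, "method": sd.method},
        "mean_prevalence": prev.mean_prevalence,
        "prevalence_chi2": {"chi2": cs.chi2, "df": cs.df, "p": cs.p},
    }, indent=2) + "\n")


if __name__ == "__main__":
    main()
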