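"""Validate both scores on the simulated cohort: restaging, c-index, KM curves.

Cross-tabulates clinical vs molecular staging (moderate categories merged),
computes Harrell's c per system and endpoint on the common evaluable subset,
and writes per-category Kaplan-Meier tables.  Output: results/validation/.
"""

from pathlib import Path

import pandas as pd

from mdsrisk import (
    build_report,
    km_estimate,
    load_coefficients,
    load_ipssr_table,
    read_cohort,
    score_cohort,
)
from mdsrisk.survival import curve_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = ROOT / "cohort"
    records = read_cohort(
        cohort / "clinical.tsv", cohort / "cytogenetics.tsv",
        cohort / "mutations.tsv", cohort / "endpoints.tsv",
    )
    coeffs = load_coefficients()
    scored = score_cohort(records, coeffs, load_ipssr_table())

    out = ROOT / "validation"
    out.mkdir(parents=True, exist_ok=True)
    report = build_report(records, scored, coeffs)
    report.write(out / "validation.json", out / "validation.txt")

    for label in coeffs.category_labels:
        sub = scored[scored["ipssm_category_mean"] == label]
        if len(sub):
            curve = km_estimate(sub["os_time"].to_numpy(), sub["os_event"].to_numpy())
            curve_table(curve).to_csv(out / f"km_os_{label}.tsv", sep="\t", index=False)

    print(report.to_text())
    rt = report.restaging
    print(
        f"headline: {rt.n_up} up-staged ({100 * rt.n_up / rt.n:.0f}%), "
        f"{rt.n_down} down-staged ({100 * rt.n_down / rt.n:.0f}%) of {rt.n} dual-scored patients"
    )
    print(f"full report under {out}")


if __name__ == "__main__":
    main()
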