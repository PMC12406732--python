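"""Cohort biomarker report and survival analysis.

Per-sample phenotype fractions, tumor-normalized NOS2/COX2 metrics and
ratio biomarkers (NOS2/CD8, NOS2s/IFN-γ, T_Eff/CD4 T_Reg,
T_Eff/PDL1-macrophage) are compared deceased vs alive (Mann-Whitney,
within-group Pearson correlations, P ≤ 0.05, no multiplicity correction),
and 5-year survival is analyzed with Kaplan-Meier curves,
Gehan-Breslow-Wilcoxon test and Mantel-Haenszel hazard ratio.
"""

import importlib.util
import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
spec = importlib.util.spec_from_file_location(
    "paths", Path(__file__).with_name("00_paths.py"))
paths = importlib.util.module_from_spec(spec)
spec.loader.exec_module(paths)

from immunoscape.cohort_stats import cohort_report, km_survival  # noqa: E402
from immunoscape.io import read_cell_table, write_json           # noqa: E402
from immunoscape.phenotyping import sample_metrics               # noqa: E402
from immunoscape.pipeline import DEFAULT_CORRELATIONS, DEFAULT_METRICS  # noqa: E402


def main():
    meta = pd.read_csv(paths.RESULTS / "metadata.csv")
    rows = []
    for f in sorted(paths.REGIONS.glob("S*.csv")):
        m = sample_metrics(read_cell_table(f))
        m["sample_id"] = f.stem
        rows.append(m)
    cohort = pd.DataFrame(rows).merge(meta, on="sample_id")
    cohort.to_csv(paths.TABLES / "cohort_metrics.csv", index=False)

    rep = cohort_report(cohort, list(DEFAULT_METRICS),
                        correlation_pairs=list(DEFAULT_CORRELATIONS))
    write_json({"results": [asdict(r) for r in rep["results"]],
                "correlations": rep["correlations"],
                "n_tests": rep["n_tests"],
                "multiplicity_correction": rep["multiplicity_correction"]},
               paths.TABLES / "biomarker_report.json")

    surv = km_survival(cohort["time_months"], cohort["event"], cohort["group"])
    write_json({"gbw_p": surv.gbw_p, "gbw_statistic": surv.gbw_statistic,
                "hazard_ratio": surv.hazard_ratio, "hr_ci": list(surv.hr_ci),
                "groups": list(surv.groups), "n_events": surv.n_events},
               paths.TABLES / "survival.json")

    sig = [r for r in rep["results"] if r.significant]
    print(f"{len(sig)}/{len(rep['results'])} metrics separate deceased from "
          f"alive at P <= 0.05:")
    for r in sorted(sig, key=lambda r: r.p_value):
        print(f"  {r.metric:<22s} P = {r.p_value:.2e}")
    print(f"survival: GBW P = {surv.gbw_p:.2e}, "
          f"HR ({surv.groups[0]} vs {surv.groups[1]}) = "
          f"{surv.hazard_ratio:.3f} [{surv.hr_ci[0]:.3f}, {surv.hr_ci[1]:.3f}]")


if __name__ == "__main__":
    main()
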