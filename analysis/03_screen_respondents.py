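"""Screen the raw survey: drop speeders (<5 min) and incompletes, score
eHealth literacy, and keep the retained respondents' choice rows.

Writes results/clean_population.csv, results/clean_choices.csv and
results/screening_report.json.
"""

import json
from pathlib import Path

import pandas as pd

from datashare_dce import apply_exclusions
from datashare_dce.screening import score_ehl_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    raw = pd.read_csv(OUT / "raw_population.csv")
    choices = pd.read_csv(OUT / "choices.csv")
    retained, report = apply_exclusions(raw, min_duration_minutes=5)
    retained = retained.assign(ehl_category=score_ehl_frame(retained))
    clean_choices = choices[
        choices["respondent_id"].isin(set(retained["respondent_id"]))
    ]
    retained.to_csv(OUT / "clean_population.csv", index=False)
    clean_choices.to_csv(OUT / "clean_choices.csv", index=False)
    with open(OUT / "screening_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    ehl = retained["ehl_category"].value_counts(normalize=True)
    print(
        f"received {report.n_received}; excluded {report.n_excluded_speed} speeders "
        f"and {report.n_excluded_incomplete} incompletes; retained "
        f"{report.n_retained} ({report.retention_percent:.2f}%)\n"
        f"  eHealth literacy: "
        + ", ".join(f"{k} {100 * v:.0f}%" for k, v in ehl.items())
        + f"\n  {len(clean_choices)} choice rows kept"
    )


if __name__ == "__main__":
    main()
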