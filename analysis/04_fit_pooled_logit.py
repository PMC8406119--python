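"""Fit the pooled accept/reject logit on the screened sample and render the
estimates table; fit each country separately for comparison.

Writes results/mnl.json and results/mnl_table.md.
"""

import json
from pathlib import Path

import pandas as pd

from datashare_dce import country_stratified_fits, defaults, fit_binary_logit
from datashare_dce.reporting import render_mnl_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = defaults.study_config()
    choices = pd.read_csv(OUT / "clean_choices.csv")
    est = fit_binary_logit(choices, config)
    with open(OUT / "mnl.json", "w") as fh:
        json.dump(est.to_dict(), fh, indent=2)
    (OUT / "mnl_table.md").write_text(render_mnl_table(est))
    print(
        f"pooled logit on {est.n_obs} observations: "
        f"LL={est.log_likelihood:.0f}, AIC={est.aic:.0f}, "
        f"intercept={est.asc:.2f}\n"
    )
    print(render_mnl_table(est))
    per_country = country_stratified_fits(choices, config)
    print("\nper-country intercepts:")
    for country, fit in per_country.items():
        print(f"  {country}: {fit.asc:.2f} (LL {fit.log_likelihood:.0f})")


if __name__ == "__main__":
    main()
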