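"""Post-estimation: relative attribute importance, the most/least preferred
data-sharing situations, and the class-adjusted acceptance-uptake grid for
scenarios sharing from a health care provider to a technological company.

Writes results/importance.csv, results/uptake_grid.csv and
results/uptake_table.md.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from datashare_dce import (
    acceptance_uptake,
    defaults,
    extreme_profiles,
    relative_importance,
    scenario_utility,
    uptake_grid,
)
from datashare_dce.latent_class import LatentClassEstimate
from datashare_dce.reporting import render_uptake_table

OUT = Path(__file__).resolve().parents[1] / "results"


def load_lc(config) -> LatentClassEstimate:
    with open(OUT / "latent_class.json") as fh:
        d = json.load(fh)
    return LatentClassEstimate(
        n_classes=d["n_classes"],
        class_betas=np.array(d["class_betas"]),
        class_asc=np.array(d["class_asc"]),
        membership_coefs=np.array(d["membership_coefs"]),
        membership_countries=tuple(d["membership_countries"]),
        average_class_probability=np.array(d["average_class_probability"]),
        posterior=np.zeros((0, d["n_classes"])),
        respondent_ids=np.zeros(0),
        log_likelihood=d["log_likelihood"],
        aic=d["aic"],
        bic=d["bic"],
        n_parameters=d["n_parameters"],
        n_obs=d["n_obs"],
        converged=d["converged"],
        config=config,
    )


def main() -> None:
    config = defaults.study_config()
    with open(OUT / "mnl.json") as fh:
        mnl = json.load(fh)
    source = {"beta": np.array(mnl["beta"]), "asc": mnl["asc"]}

    imp = relative_importance(source, config)
    imp.to_csv(OUT / "importance.csv", index=False)
    print("relative attribute importance (pooled model):")
    print(imp.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

    best, worst = extreme_profiles(source, config)
    v_best = scenario_utility(best, source, config)
    v_worst = scenario_utility(worst, source, config)
    print(
        f"\nmost preferred situation: {best}\n"
        f"  V={v_best:.2f}, uptake {100 * acceptance_uptake(v_best):.0f}%\n"
        f"least preferred situation: {worst}\n"
        f"  V={v_worst:.2f}, uptake {100 * acceptance_uptake(v_worst):.0f}%"
    )

    lc = load_lc(config)
    grid = uptake_grid(lc, config, "healthcare_provider", "tech_company")
    grid.to_csv(OUT / "uptake_grid.csv", index=False)
    (OUT / "uptake_table.md").write_text(render_uptake_table(grid))
    print("\nclass-adjusted uptake, health care provider -> technological company:")
    print(render_uptake_table(grid))


if __name__ == "__main__":
    main()
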