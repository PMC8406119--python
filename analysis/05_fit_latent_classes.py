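"""Latent class analysis: compare class counts by AIC, then fit the
four-class model with country-driven class membership.

Writes results/class_selection.csv, results/latent_class.json and
results/latent_class_table.md.
"""

import json
from pathlib import Path

import pandas as pd

from datashare_dce import defaults, fit_latent_class, select_n_classes
from datashare_dce.reporting import render_lc_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    config = defaults.study_config()
    choices = pd.read_csv(OUT / "clean_choices.csv")

    selection = select_n_classes(choices, config, (1, 2, 3, 4),
                                 n_starts=4, seed=seed)
    selection.to_csv(OUT / "class_selection.csv", index=False)
    print("class-count comparison:")
    print(selection[["n_classes", "log_likelihood", "aic", "bic",
                     "n_parameters", "best"]].to_string(index=False))

    lc = fit_latent_class(choices, config, n_classes=4, n_starts=10, seed=seed)
    with open(OUT / "latent_class.json", "w") as fh:
        json.dump(lc.to_dict(), fh, indent=2)
    (OUT / "latent_class_table.md").write_text(render_lc_table(lc))
    shares = ", ".join(f"{100 * p:.0f}%" for p in lc.average_class_probability)
    print(
        f"\nfour-class fit: LL={lc.log_likelihood:.0f}, AIC={lc.aic:.0f}, "
        f"{lc.n_parameters} parameters\n  average class probabilities: {shares}"
    )


if __name__ == "__main__":
    main()
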