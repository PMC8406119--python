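"""Scale-difference tests between country samples.

Runs the two-step scale/preference-equality test between each country's
choices and the United Kingdom sample, writing results/scale_tests.csv.
Because class membership depends on country, the pooled preferences of the
country samples genuinely differ, so rejections here are expected — the
heterogeneity that motivates the latent class model rather than a single
pooled logit per country.
"""

from pathlib import Path

import pandas as pd

from datashare_dce import defaults, swait_louviere_test

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = defaults.study_config()
    choices = pd.read_csv(OUT / "clean_choices.csv")
    uk = choices[choices["country"] == "uk"]
    rows = []
    for country in ("sweden", "norway", "iceland"):
        sample = choices[choices["country"] == country]
        res = swait_louviere_test(uk, sample, config)
        rows.append({
            "sample_a": "uk", "sample_b": country,
            "lambda_hat": res.lambda_hat, "lr_statistic": res.lr_statistic,
            "df": res.df, "p_value": res.p_value,
        })
        print(
            f"uk vs {country}: lambda={res.lambda_hat:.3f}, "
            f"LR={res.lr_statistic:.1f} (df={res.df}), p={res.p_value:.3f}"
        )
    pd.DataFrame(rows).to_csv(OUT / "scale_tests.csv", index=False)


if __name__ == "__main__":
    main()
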