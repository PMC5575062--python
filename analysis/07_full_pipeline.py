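"""End-to-end experiment: do growth cones that receive more EB3 comets
tread faster, when the generator makes it so?

Twenty replicate five-neurite cells are built with comet rate
proportional to flow speed, then pushed through the complete chain —
scene rendering, axis and neck kymographs, automatic slope estimation,
comet spot counting, standard-score Pearson correlation across
neurites. Finding: the pipeline recovers a strongly positive
correlation in essentially every replicate
(results/pipeline_correlation.csv).
"""

from pathlib import Path

import pandas as pd

import gcflow.recovery as R

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    out = R.pipeline_correlation(seed=SEED, n_replicates=20)
    df = pd.DataFrame([{"mean_r": out["mean_r"], "min_r": out["min_r"],
                        "fraction_positive": out["fraction_positive"],
                        "n_replicates": out["n_replicates"],
                        "units": "Pearson r"}])
    df.to_csv(OUT / "pipeline_correlation.csv", index=False,
              float_format="%.4f")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
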