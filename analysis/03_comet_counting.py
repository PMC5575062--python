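"""EB3 comet counting recovery: Poisson crossings vs detected spots.

Counting-line kymographs are generated with comets entering at 1, 2, 4
and 8 per minute over a 5-min window (50 seeds each) and counted with
the difference-of-Gaussians spot detector. Finding: mean counts track
rate x window within ~10% and detection F1 against resolvable
crossings stays above 0.95 (results/comet_recovery.csv).
"""

from pathlib import Path

import pandas as pd

import gcflow.recovery as R

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    out = R.comet_recovery(seed=SEED)
    rows = [{"rate_per_min": lam, "expected_count": d["expected_count"],
             "mean_detected": d["mean_count"],
             "relative_error_pct": 100 * d["relative_error"],
             "f1": d["f1"], "units": "count"}
            for lam, d in out["per_rate"].items()]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "comet_recovery.csv", index=False, float_format="%.4f")
    print(df.to_string(index=False))
    print(f"\nworst case: {100 * out['max_relative_error']:.1f}% count error, "
          f"F1 {out['min_f1']:.3f}")


if __name__ == "__main__":
    main()
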