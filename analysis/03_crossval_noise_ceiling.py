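"""Leave-one-observer-out cross-validation against the noise ceiling.

Holds out each of the ten observers in turn, refits the
Reliability-and-Learning model to the remaining group means, and scores the
squared Pearson correlation between the predicted and the held-out
observer's d' trajectory; compares the mean r^2 with the noise-ceiling
bounds defined by observer-to-group-mean correlations.
"""

import argparse
import json
from pathlib import Path

from vplsearch import SimSettings, loo_cross_validate, read_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--dataset", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--variant", default="RL")
    parser.add_argument("--n-starts", type=int, default=3)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    dataset = read_dataset(args.dataset)
    cv = loo_cross_validate(
        dataset, args.variant, sim=SimSettings(), rng=args.seed, n_starts=args.n_starts
    )
    print(f"variant {args.variant}: cross-validated r^2 = {cv.mean_r2:.3f} (SD {cv.sd_r2:.3f})")
    print(f"noise ceiling: [{cv.ceiling_lower:.3f}, {cv.ceiling_upper:.3f}]")
    within = cv.ceiling_lower <= cv.mean_r2 <= cv.ceiling_upper
    print("mean r^2 falls", "within" if within else "outside", "the ceiling band")

    args.out.mkdir(parents=True, exist_ok=True)
    payload = {
        "variant": args.variant,
        "mean_r2": cv.mean_r2,
        "sd_r2": cv.sd_r2,
        "ceiling_lower": cv.ceiling_lower,
        "ceiling_upper": cv.ceiling_upper,
        "per_observer_r2": {str(k): v for k, v in cv.per_observer_r2.items()},
    }
    with open(args.out / "crossval.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    print(f"wrote {args.out / 'crossval.json'}")


if __name__ == "__main__":
    main()
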