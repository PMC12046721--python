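#!/usr/bin/env python
"""Run the validation experiments and write their numbers.

Executes the oracle-equivalence, ICAR-covariance, parameter-recovery,
predictive-calibration and model-ranking experiments at reduced sizes
(full sizes run via scripts/acceptance.py) and writes the results to
results/validation.json.
"""

import json
from pathlib import Path

from lendingrisk import experiments as ex

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    out = {
        "worked_fold_ratios": ex.worked_fold_ratios(),
        "glm_oracle": ex.glm_oracle_experiment(seed=0),
        "icar_covariance": ex.icar_covariance_experiment(seed=0, n_draws=4000),
        "recovery": ex.recovery_experiment(seed=0, n_reps=20),
        "calibration": ex.calibration_experiment(seed=0, n_reps=20),
        "model_ranking": ex.model_ranking_experiment(seed=0, n_reps=3),
        "conservation": ex.conservation_check(seed=0),
    }
    with open(ROOT / "validation.json", "w") as fh:
        json.dump(out, fh, indent=1)
    for section, vals in out.items():
        print(f"{section}:")
        for k, v in vals.items():
            print(f"  {k} = {v:.6g}" if isinstance(v, float) else f"  {k} = {v}")
    print(f"\nwrote {ROOT / 'validation.json'}")


if __name__ == "__main__":
    main()
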