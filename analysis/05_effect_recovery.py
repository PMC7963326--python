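"""Effect-size recovery: does the GLMM recover a known 20% rate increase?

Simulates replicate two-arm labelling cohorts (OXPHOS-normal vs
CI-deficient with division rate x1.2, 40 mice x 50 crypts, mouse
frailty SD 0.2) and fits the Poisson random-intercept GLMM to the
dual-labelled LGR5-high counts each time.  Reports the mean recovered
percentage increase and the 95% CI coverage; scripts/acceptance.py runs
the full 200-replicate version, this driver defaults to a quicker 50.
"""

import argparse
from pathlib import Path

from cryptmosaic.studies import effect_recovery_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=50)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    study = effect_recovery_study(n_replicates=args.replicates, rate_ratio=1.2, seed=args.seed)
    study.estimates.to_csv(args.out_dir / "effect_recovery.csv", index=False)

    print(f"{args.replicates} replicate cohorts, true division-rate increase 20%:")
    print(f"  mean recovered increase : {study.mean_pct_increase:.2f}% "
          f"(Monte-Carlo SE {study.mc_se_pct:.2f})")
    print(f"  95% Wald CI coverage    : {study.coverage:.3f}")
    print(f"  all fits converged      : {bool(study.estimates['converged'].all())}")
    print(f"wrote per-replicate estimates -> {args.out_dir / 'effect_recovery.csv'}")


if __name__ == "__main__":
    main()
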