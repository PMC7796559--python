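#!/usr/bin/env python
"""CPMG T2 fits on synthetic decays mimicking the backbone-carbon series.

The symmetric conformer shows additional microsecond-millisecond exchange
broadening, i.e. shorter T2, than the asymmetric one.  This driver fits
mono-exponential decays for three synthetic sites on the ten-delay grid
(15.2-456 ms) -- two long-T2 "asymmetric" sites and one short-T2
"symmetric" site -- and reports a quick CI-calibration check.

Writes results/t2_fits.json.
"""

import argparse
from pathlib import Path

from depsikin import io, relaxation, synthetic

RESULTS = Path(__file__).resolve().parent.parent / "results"

# (site, T2 seconds): asymmetric backbone carbons relax slower than the
# exchange-broadened symmetric one
SITES = [("asym-Lac1", 0.35), ("asym-Lac5", 0.30), ("sym-Lac15", 0.08)]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    fits = {}
    for k, (site, t2) in enumerate(SITES):
        data = synthetic.gen_decay(
            synthetic.DecaySpec(seed=args.seed * 100 + k, T2=t2, noise=0.05, site=site)
        )
        fit = relaxation.fit_t2(data.curve)
        lo, hi = fit.t2_ci95
        fits[site] = fit
        print(f"{site}: true T2 {t2 * 1e3:.0f} ms -> fitted "
              f"{fit.T2 * 1e3:.1f} ms (95% CI {lo * 1e3:.1f}-{hi * 1e3:.1f} ms)")

    covered = 0
    n = 500
    for seed in range(n):
        data = synthetic.gen_decay(synthetic.DecaySpec(seed=seed, noise=0.05))
        lo, hi = relaxation.fit_t2(data.curve).t2_ci95
        covered += lo <= data.T2 <= hi
    print(f"\nCI calibration: 95% interval covered the true T2 in "
          f"{covered / n * 100:.1f}% of {n} replicates")

    io.write_results(
        {"fits": fits, "ci_coverage": covered / n, "n_replicates": n},
        RESULTS / "t2_fits.json", seed=args.seed,
    )
    print(f"written to {RESULTS / 't2_fits.json'}")


if __name__ == "__main__":
    main()
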