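"""Build and calibrate the control population of ventricular AP models.

Samples candidate conductance profiles inside the variability ranges,
paces each to steady state at 1 Hz and keeps the models whose nine AP/Ca2+
biomarkers fall inside the experimental calibration windows; writes the
population (scalings, steady states, control biomarkers, manifest) under
results/population/ and prints the acceptance summary.
"""

import argparse
import sys
import time
from pathlib import Path

from emwtrials import RunConfig, build_population, save_config


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fast", action="store_true",
                    help="reduced pre-pacing (desk protocol)")
    ap.add_argument("--seed", type=int, default=None)
    ap.add_argument("--size", type=int, default=None)
    ap.add_argument("--out", default="results/population")
    args = ap.parse_args(argv)

    cfg = RunConfig(fast=args.fast)
    if args.seed is not None:
        cfg.seed = args.seed
    if args.size is not None:
        cfg.population_size = args.size

    t0 = time.time()
    pop = build_population(ranges=cfg.sampling_ranges(),
                           windows=cfg.calibration_windows(),
                           protocol=cfg.control_protocol(),
                           solver=cfg.solver(),
                           progress=True)
    out = Path(args.out)
    pop.save(out)
    save_config(cfg, out / "config.yaml")
    frac = pop.provenance["acceptance_fraction"]
    print(f"accepted {len(pop)}/{cfg.population_size} candidate models "
          f"({frac:.1%}) in {time.time() - t0:.0f} s -> {out}")
    print("rejection reasons:",
          {m: r for m, r in list(pop.rejected.items())[:5]}, "...")
    return 0


if __name__ == "__main__":
    sys.exit(main())
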