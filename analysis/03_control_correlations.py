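"""Control-population structure: EMw against APD90 and CTD90.

Loads the calibrated population and quantifies how the electromechanical
window relates to its two parent durations across models (Pearson r and a
least-squares line): EMw tracks the Ca2+ transient duration strongly and
the AP duration only weakly/negatively, which is why it carries
information that APD90 alone does not.  Writes a correlation table and a
scatter figure.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from emwtrials import Population


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--population", default="results/population")
    ap.add_argument("--out", default="results/control_correlations.csv")
    ap.add_argument("--plot", default="results/control_correlations.png")
    args = ap.parse_args(argv)

    pop = Population.load(args.population)
    emw = np.array([pop.biomarkers[m].EMw for m in pop.model_ids])
    rows = []
    for name in ("APD90", "CTD90"):
        x = np.array([getattr(pop.biomarkers[m], name)
                      for m in pop.model_ids])
        r, p = stats.pearsonr(emw, x)
        slope, inter = np.polyfit(x, emw, 1)
        rows.append({"biomarker": name, "pearson_r": r, "p_value": p,
                     "slope": slope, "intercept": inter, "n": len(pop)})
        print(f"EMw ~ {name}: r = {r:+.3f} (p = {p:.2e}), n = {len(pop)}")
    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, name in zip(axes, ("APD90", "CTD90")):
        x = np.array([getattr(pop.biomarkers[m], name)
                      for m in pop.model_ids])
        ax.scatter(x, emw, c=emw, cmap="spring", s=18)
        sl, ic = np.polyfit(x, emw, 1)
        xs = np.linspace(x.min(), x.max(), 10)
        ax.plot(xs, sl * xs + ic, "k--")
        ax.set_xlabel(f"{name} (ms)")
    axes[0].set_ylabel("EMw (ms)")
    fig.tight_layout()
    fig.savefig(args.plot, dpi=120)
    print(f"-> {out}, {args.plot}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
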