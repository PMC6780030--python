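"""In-silico drug trials and TdP risk scoring on a compendium.

Runs multi-concentration population trials for every compound in a
compendium CSV (a synthetic archetype compendium is generated when none is
supplied), classifies each compound under the RA-only and RA+dEMw criteria
at every tested multiple of EFTPCmax, computes the concentration-weighted
TdP scores, and evaluates prediction metrics against the compendium's risk
categories.  Writes per-drug trial tables, risk calls, scores and metrics
under the output directory, plus a log-modulus dEMw summary figure.
"""

import argparse
import sys
import time
from pathlib import Path

import pandas as pd

from emwtrials import (Population, RunConfig, control_arm, load_compendium,
                       make_compendium, run_drug_trial, save_compendium,
                       classify, tdp_score, score_inputs_from_trial,
                       prediction_metrics, truth_label, log_modulus)


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--population", default="results/population")
    ap.add_argument("--compendium", default=None,
                    help="compendium CSV (default: generate synthetic)")
    ap.add_argument("--subsample", type=int, default=12)
    ap.add_argument("--multiples", default="1,3,10,30,100")
    ap.add_argument("--call-multiple", type=float, default=10.0,
                    help="concentration multiple used for the risk calls")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/drug_trials")
    args = ap.parse_args(argv)

    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    multiples = tuple(float(x) for x in args.multiples.split(","))

    if args.compendium:
        drugs = load_compendium(args.compendium)
    else:
        drugs = make_compendium(seed=args.seed, n_per_archetype=1)
        save_compendium(drugs, outdir / "synthetic_compendium.csv")
        print(f"generated synthetic compendium "
              f"({len(drugs)} compounds) -> {outdir}/synthetic_compendium.csv")

    pop = Population.load(args.population)
    if args.subsample:
        pop = pop.subsample(args.subsample, seed=args.seed)
    print(f"population: {len(pop)} models; multiples: {multiples}")

    t0 = time.time()
    controls = control_arm(pop)
    calls_ra, calls_emw, score_rows = [], [], []
    for drug in drugs:
        trial = run_drug_trial(pop, drug, multiples, controls=controls)
        trial.per_model.to_csv(outdir / f"trial_{drug.name}.csv")
        c_ra = classify(trial, "RA_only", args.call_multiple)
        c_em = classify(trial, "RA_plus_EMw", args.call_multiple)
        calls_ra.append(c_ra)
        calls_emw.append(c_em)
        si = score_inputs_from_trial(trial)
        score_rows.append({
            "drug": drug.name, "category": drug.category,
            "tdp_score_ra_emw": tdp_score(si),
            "tdp_score_ra_only": tdp_score(si, include_emw=False),
            "median_dEMw_at_call": c_em.median_dEMw,
            "log_modulus_dEMw": log_modulus(c_em.median_dEMw),
            "frac_ra_at_call": c_em.frac_ra,
            "risky_RA_only": c_ra.risky, "risky_RA_plus_EMw": c_em.risky,
        })
        print(f"{drug.name:20s} [{drug.category:11s}] "
              f"RA_only={'risky' if c_ra.risky else 'safe ':5s} "
              f"RA+dEMw={'risky' if c_em.risky else 'safe'} "
              f"(median dEMw {c_em.median_dEMw:+.1f}%, "
              f"RA {c_em.frac_ra:.0%})")
    scores = pd.DataFrame(score_rows)
    scores.to_csv(outdir / "tdp_scores.csv", index=False)

    truth = {d.name: truth_label(d.category) for d in drugs}
    rows = []
    for crit, calls in (("RA_only", calls_ra), ("RA_plus_EMw", calls_emw)):
        cm = prediction_metrics(calls, truth)
        rows.append({"criterion": crit, "multiple": args.call_multiple,
                     "TP": cm.TP, "TN": cm.TN, "FP": cm.FP, "FN": cm.FN,
                     "sensitivity": cm.sensitivity,
                     "specificity": cm.specificity,
                     "accuracy": cm.accuracy, "ppv": cm.ppv, "npv": cm.npv})
        print(f"{crit}: accuracy {cm.accuracy:.0%} "
              f"(TP {cm.TP}, TN {cm.TN}, FP {cm.FP}, FN {cm.FN})")
    pd.DataFrame(rows).to_csv(outdir / "metrics.csv", index=False)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.axhline(log_modulus(-10.0), color="r", ls="--", lw=1,
               label="-10% threshold")
    colors = {"known": "tab:red", "possible": "tab:orange",
              "conditional": "gold", "NC": "tab:green",
              "unlisted": "tab:green", "safe": "tab:green"}
    ax.bar(scores["drug"], scores["log_modulus_dEMw"],
           color=[colors.get(c, "gray") for c in scores["category"]])
    ax.set_ylabel("L(median dEMw %)")
    ax.tick_params(axis="x", rotation=75)
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "demw_log_modulus.png", dpi=120)
    print(f"{len(drugs)} compounds in {time.time() - t0:.0f} s -> {outdir}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
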