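"""Regenerate the frozen founder frequency spectrum in wffsim/_generic_spectrum.py.

Simulates the generic domestic-animal demography (diploid effective size
100 at present, 500 at 100 generations ago, stepwise up to 1e5 at one
million generations ago) with msprime, samples 6000 diploids, pools the
allele frequencies of segregating biallelic variants over independent
replicates, and writes 257 equally spaced quantiles as inverse-CDF knots.

Usage: python scripts/derive_generic_spectrum.py [--reps 60] [--seed 1000]
"""

import argparse
from pathlib import Path

import msprime
import numpy as np

STEPS = [(100, 500), (1000, 1500), (10000, 6000), (100000, 12000), (1000000, 100000)]


def simulate_sfs(reps: int, seed: int) -> np.ndarray:
    dem = msprime.Demography()
    dem.add_population(initial_size=100)
    for t, ne in STEPS:
        dem.add_population_parameters_change(time=t, initial_size=ne)
    freqs = []
    for rep in range(reps):
        ts = msprime.sim_ancestry(
            samples=6000, demography=dem, ploidy=2,
            sequence_length=1e5, recombination_rate=1e-8, random_seed=seed + rep,
        )
        mts = msprime.sim_mutations(
            ts, rate=2e-7, random_seed=seed + rep, model=msprime.BinaryMutationModel()
        )
        for var in mts.variants():
            f = var.genotypes.mean()
            if 0.0 < f < 1.0:
                freqs.append(f)
    return np.sort(np.asarray(freqs))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=60)
    ap.add_argument("--seed", type=int, default=1000)
    args = ap.parse_args()

    q = simulate_sfs(args.reps, args.seed)
    knots = np.quantile(q, np.linspace(0.0, 1.0, 257))
    print(f"{q.size} segregating sites; E[q]={q.mean():.4f} E[2pq]={(2*q*(1-q)).mean():.4f}")

    lines = []
    for i in range(0, 257, 8):
        lines.append("    " + ", ".join(f"{v:.6g}" for v in knots[i : i + 8]) + ",")
    body = "\n".join(lines)
    target = Path(__file__).resolve().parent.parent / "src" / "wffsim" / "_generic_spectrum.py"
    text = target.read_text()
    head = text.split("GENERIC_SPECTRUM_QUANTILES")[0]
    target.write_text(head + "GENERIC_SPECTRUM_QUANTILES = np.array([\n" + body + "\n])\n")
    print(f"wrote {target}")


if __name__ == "__main__":
    main()
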