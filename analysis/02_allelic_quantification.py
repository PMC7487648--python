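"""Allele-specific quantification: posterior sampling, combining, bias calls.

Simulates an F1-hybrid-style allelic contrast (4-fold upregulation planted
on the A1 allele of the focal locus in the KO group), runs the Gibbs
posterior sampler per sample, combines unidentifiable isoforms by posterior
correlation, and calls allelic bias per transcript group and allele.
Writes results/ase/ase_calls.tsv and transcript_groups.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from tuglocus.ase import test_allelic_differential
from tuglocus.combine import CombiningConfig, combine_transcripts
from tuglocus.quant import sample_posterior, to_tpm
from tuglocus.simulate import SimulationParams, simulate_ase_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/ase"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    p = SimulationParams(
        seed=args.seed,
        genome_length=30_000,
        n_loci=4,
        n_transcripts_per_locus=2,
        allelic_log2_effects={"locus0": 2.0},
    )
    data, locus_map = simulate_ase_experiment(p, n_fragments=100_000, n_per_group=3)
    rng = np.random.default_rng(args.seed + 7)
    post = {
        g: [
            to_tpm(sample_posterior(e, n_draws=250, burn_in=100, thin=1,
                                    seed=int(rng.integers(2**31))))
            for e in eccs
        ]
        for g, eccs in data.items()
    }

    all_posts = post["WT"] + post["KO"]
    groups, combined = combine_transcripts(
        all_posts, CombiningConfig(cutoff=-0.25, locus_map=locus_map)
    )
    n_wt = len(post["WT"])
    comb_wt, comb_ko = combined[:n_wt], combined[n_wt:]
    pd.DataFrame(
        [(gid, ",".join(members)) for gid, members in sorted(groups.items())],
        columns=["group_id", "members"],
    ).to_csv(args.out / "transcript_groups.tsv", sep="\t", index=False)
    print(f"combining: {sum(len(m) for m in groups.values())} transcripts "
          f"-> {len(groups)} groups (cutoff -0.25)")

    rows = []
    for gid in sorted(groups):
        for allele in ("A1", "A2"):
            call = test_allelic_differential(comb_wt, comb_ko, gid, allele)
            rows.append(
                {
                    "feature": gid,
                    "allele": allele,
                    "mean_tpm_wt": round(call.mean_a, 2),
                    "mean_tpm_ko": round(call.mean_b, 2),
                    "pp": round(call.pp, 4),
                    "direction": call.direction,
                    "significant": call.significant,
                }
            )
    calls = pd.DataFrame(rows)
    calls.to_csv(args.out / "ase_calls.tsv", sep="\t", index=False)
    sig = calls[calls["significant"]]
    print(f"allelic-bias calls at PP > 0.95: {len(sig)} of {len(calls)}")
    for _, r in sig.iterrows():
        print(f"  {r.feature} [{r.allele}] {r.direction} "
              f"(WT {r.mean_tpm_wt} -> KO {r.mean_tpm_ko} TPM, PP {r.pp})")
    focal = calls[calls["feature"].str.startswith("gene0")]
    a1 = focal[focal["allele"] == "A1"].iloc[0]
    a2 = focal[focal["allele"] == "A2"].iloc[0]
    print(f"focal locus: A1 {'UP, significant' if a1.significant and a1.direction == 'up' else 'NOT as planted'}; "
          f"A2 {'quiet' if not a2.significant else 'also called'} -- the planted one-allele-only pattern")
    print("note: mild 'down' calls on background loci are TPM closure -- the "
          "focal boost deflates everything else in this 4-locus toy library, "
          "and the background posteriors are tight enough to see it")


if __name__ == "__main__":
    main()
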