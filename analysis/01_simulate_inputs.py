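"""Generate every input the downstream analyses consume.

Writes a hybrid-style diploid locus (reference FASTA, strain variant TSV,
transcript GTF, liftover chain) and NB count matrices for the two-genotype
and three-genotype (rescue) designs under results/simulated/.
"""

import argparse
from pathlib import Path

from tuglocus.diploid import apply_variants
from tuglocus.io import (
    write_coordinate_map,
    write_fasta,
    write_gtf,
    write_variants_tsv,
)
from tuglocus.simulate import SimulationParams, simulate_count_matrix, simulate_diploid_locus


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/simulated"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    p = SimulationParams(seed=args.seed, genome_length=150_000)
    reference, variants, transcripts = simulate_diploid_locus(p)
    n_snp = sum(1 for v in variants if v.is_snp)
    print(f"simulated {len(reference['chr1']):,} bp reference; "
          f"{n_snp} SNPs (~1/{len(reference['chr1']) // max(n_snp, 1)} bp), "
          f"{len(variants) - n_snp} indels; {len(transcripts)} transcripts")

    write_fasta(reference, args.out / "reference.fa")
    write_variants_tsv(variants, args.out / "variants.tsv")
    write_gtf(transcripts, args.out / "annotation.gtf")
    personalized, cmap = apply_variants(reference, variants, "CAST")
    write_fasta(personalized, args.out / "reference_cast.fa")
    write_coordinate_map(cmap, args.out / "liftover_chain.tsv")

    cis = {f"g0000{i}": 2.0 for i in range(3)}
    trans = {f"g001{i:02d}": 1.5 for i in range(3)}
    pc = SimulationParams(
        seed=args.seed + 1,
        groups=("WT", "KO", "RESCUE"),
        cis_gene_log2fc=cis,
        trans_gene_log2fc=trans,
        nb_dispersion=0.05,
        base_mean_overrides={g: 500.0 for g in list(cis) + list(trans)},
    )
    cm, truth = simulate_count_matrix(pc)
    cm.counts.to_csv(args.out / "counts.tsv", sep="\t")
    cm.design.to_csv(args.out / "design.tsv", sep="\t")
    cm.gene_meta.to_csv(args.out / "gene_meta.tsv", sep="\t")
    truth.to_csv(args.out / "truth.tsv", sep="\t")
    print(f"count matrix: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples "
          f"({', '.join(pc.groups)}); planted {len(cis)} cis + {len(trans)} trans genes")


if __name__ == "__main__":
    main()
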