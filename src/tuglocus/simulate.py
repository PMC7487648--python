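"""Synthetic-data generation for every pipeline stage.

The generator emulates the statistical structure the analyses assume,
without any sequencing-read realism: an F1-hybrid-like diploid locus
(strain SNPs at ~1/150 bp and short indels at a tenth of that rate),
multinomial fragment-to-equivalence-class sampling in which a fragment is
allele-ambiguous exactly when its window covers no variant, and NB count
matrices (variance = mu + dispersion * mu^2) with cis-effect genes placed
around a focal locus and trans-effect genes reverted in the rescue group.
Every function takes an explicit seed and is bit-reproducible given it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .de import CountMatrix
from .diploid import Transcript, Variant, VariantTable, apply_variants, lift_annotation
from .quant import EquivalenceClassCounts, TranscriptAllele

BASES = np.array(list("ACGT"))


@dataclass
class SimulationParams:
    """Study conditions for the synthetic experiments.

    ``allelic_log2_effects`` maps a locus label to the log2 effect applied to
    one allele in the affected genotype group (the single-allele cis
    signature).  ``cis_gene_log2fc`` genes keep their effect in the rescue
    group (a DNA effect is not rescued); ``trans_gene_log2fc`` genes revert
    to baseline in the rescue group (an RNA effect is).
    """

    seed: int = 0
    snp_rate: float = 1.0 / 150.0
    indel_rate: float = 1.0 / 1500.0
    read_length: int = 100
    genome_length: int = 100_000
    n_loci: int = 4
    n_transcripts_per_locus: int = 3
    allelic_log2_effects: dict[str, float] = field(default_factory=dict)
    nb_mean: float = 100.0
    nb_dispersion: float = 0.1
    cis_gene_log2fc: dict[str, float] = field(default_factory=dict)
    trans_gene_log2fc: dict[str, float] = field(default_factory=dict)
    n_replicates_per_group: int = 4
    groups: tuple[str, ...] = ("WT", "KO")
    strain: str = "CAST"
    base_mean_overrides: dict[str, float] = field(default_factory=dict)
    # count-matrix geometry
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (500, 5000)
    focal_chrom: str = "chr11"
    focal_pos: int = 3_650_000
    cis_max_distance: int = 500_000
    region_span: int = 20_000_000
    mean_spread_sd: float = 1.0
    tissue: str = "testis"

    def __post_init__(self) -> None:
        if not 0.0 < self.snp_rate < 1.0:
            raise ValueError("snp_rate must be in (0, 1)")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel_rate must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        unknown = set(self.groups) - {"WT", "KO", "RESCUE"}
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _locus_exon_layout(params: SimulationParams) -> list[list[tuple[int, int]]]:
    """Deterministic exon layout per locus (independent of the random stream)."""
    layout: list[list[tuple[int, int]]] = []
    locus_span = params.genome_length // (params.n_loci + 1)
    n_exons = 4
    for li in range(params.n_loci):
        origin = locus_span // 2 + li * locus_span
        exon_len = max(locus_span // (2 * n_exons), params.read_length * 2)
        gap = exon_len // 2
        exons = []
        p = origin
        for _ in range(n_exons):
            exons.append((p, min(p + exon_len, params.genome_length)))
            p += exon_len + gap
        layout.append(exons)
    return layout


def _locus_exons(params: SimulationParams) -> list[tuple[int, int]]:
    return [iv for exons in _locus_exon_layout(params) for iv in exons]


def simulate_diploid_locus(
    params: SimulationParams,
) -> tuple[dict[str, str], VariantTable, list[Transcript]]:
    """Random reference, per-bp strain variants, and overlapping multi-isoform loci.

    SNP and indel positions are drawn independently per base pair at
    ``snp_rate`` / ``indel_rate``; indels are 1-3 nt, VCF-style anchored,
    and overlapping drawn variants are dropped left to right.  Each locus
    carries ``n_transcripts_per_locus`` isoforms sharing exons, so the
    posterior-correlation combining stage has genuinely entangled pairs.
    """
    if params.genome_length <= 0:
        raise ValueError("zero-length reference")
    rng = np.random.default_rng(params.seed)
    chrom = "chr1"
    seq = _random_dna(rng, params.genome_length)

    # exon layout is deterministic given params; indels are kept away from
    # exon-boundary bases so every simulated transcript lifts to both alleles
    exon_bounds: set[int] = set()
    for s, e in _locus_exons(params):
        exon_bounds.add(s)
        exon_bounds.add(e - 1)

    snp_pos = np.flatnonzero(rng.random(params.genome_length) < params.snp_rate)
    indel_pos = np.flatnonzero(rng.random(params.genome_length) < params.indel_rate)
    candidates: list[tuple[int, str]] = sorted(
        [(int(p), "snp") for p in snp_pos] + [(int(p), "indel") for p in indel_pos]
    )
    variants: list[Variant] = []
    last_end = -1
    for pos, kind in candidates:
        if pos <= last_end:
            continue
        if kind == "snp":
            ref = seq[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.append(Variant(chrom, pos, ref, alt, params.strain))
            last_end = pos
        else:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion after the anchor base
                ref = seq[pos]
                alt = ref + _random_dna(rng, length)
            else:  # deletion of `length` bases after the anchor
                if pos + 1 + length > len(seq):
                    continue
                if any(b in exon_bounds for b in range(pos + 1, pos + 1 + length)):
                    continue
                ref = seq[pos : pos + 1 + length]
                alt = seq[pos]
            variants.append(Variant(chrom, pos, ref, alt, params.strain))
            last_end = pos + len(ref) - 1
    reference = {chrom: seq}
    table = VariantTable(variants, reference)

    transcripts: list[Transcript] = []
    layout = _locus_exon_layout(params)
    n_exons = 4
    for li in range(params.n_loci):
        exons = layout[li]
        locus = f"locus{li}"
        gene = f"gene{li}"
        biotype = "lncRNA" if li == 0 else "protein_coding"
        for ti in range(params.n_transcripts_per_locus):
            # isoforms share exons: full model, 5' subset, 3' subset, ...
            if ti == 0:
                use = exons
            else:
                k = max(2, n_exons - 1)
                use = exons[: k] if ti % 2 == 1 else exons[n_exons - k :]
            transcripts.append(
                Transcript(
                    transcript_id=f"{gene}.t{ti + 1}",
                    gene_id=gene,
                    chrom=chrom,
                    strand="+",
                    exons=tuple(use),
                    biotype=biotype,
                    locus=locus,
                )
            )
    return reference, table, transcripts


@dataclass
class FragmentClassIndex:
    """Precomputed per-start equivalence classes for every transcript-allele.

    ``class_by_start[key][i]`` is the compatibility set of the read-length
    window of ``key`` starting at position i.  Building the index once and
    sharing it across samples avoids re-deriving fragment compatibility per
    sample; it encodes exactly the same relation as a verbatim substring
    search, because every fragment is a full window of its source.
    """

    read_length: int
    eff_lengths: dict[TranscriptAllele, float]
    class_by_start: dict[TranscriptAllele, list[frozenset[TranscriptAllele]]]


def build_fragment_class_index(
    transcripts: list[Transcript],
    reference: dict[str, str],
    variants: VariantTable,
    read_length: int = 100,
    strain: str = "CAST",
) -> FragmentClassIndex:
    """Enumerate all read-length windows of both alleles and group identical ones."""
    genome_a2, cmap = apply_variants(reference, variants, strain)
    lifted = {t.transcript_id: t for t in lift_annotation(transcripts, cmap)}
    tx_seq: dict[TranscriptAllele, str] = {}
    for tx in transcripts:
        tx_seq[(tx.transcript_id, "A1")] = tx.sequence(reference)
        if tx.transcript_id in lifted:
            tx_seq[(tx.transcript_id, "A2")] = lifted[tx.transcript_id].sequence(genome_a2)
    eff_lengths = {
        key: float(max(len(s) - read_length + 1, 1)) for key, s in tx_seq.items()
    }
    window_members: dict[str, set[TranscriptAllele]] = {}
    for key, seq in tx_seq.items():
        for i in range(int(eff_lengths[key])):
            window_members.setdefault(seq[i : i + read_length], set()).add(key)
    # transcripts shorter than the read length emit their full sequence,
    # which may occur inside longer transcripts: fall back to substring search
    for key, seq in tx_seq.items():
        if len(seq) < read_length:
            members = {k for k, s in tx_seq.items() if seq in s}
            window_members[seq] = window_members.get(seq, set()) | members
    class_by_start = {
        key: [
            frozenset(window_members[seq[i : i + read_length]])
            for i in range(int(eff_lengths[key]))
        ]
        for key, seq in tx_seq.items()
    }
    return FragmentClassIndex(
        read_length=read_length,
        eff_lengths=eff_lengths,
        class_by_start=class_by_start,
    )


def simulate_equivalence_counts(
    abundances: dict[TranscriptAllele, float],
    transcripts: list[Transcript],
    reference: dict[str, str],
    variants: VariantTable,
    n_fragments: int,
    read_length: int = 100,
    seed: int = 0,
    strain: str = "CAST",
    index: FragmentClassIndex | None = None,
) -> EquivalenceClassCounts:
    """Multinomial fragment sampling into (transcript, allele) equivalence classes.

    Fragments are single-end, error-free, with uniform start positions;
    a fragment's equivalence class is the set of all transcript-alleles
    whose sequence contains the fragment verbatim, so fragments whose
    window covers no strain variant are allele-ambiguous.  Total count is
    conserved by construction.  A prebuilt ``index`` may be supplied when
    many samples share the same locus.
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be non-negative")
    if any(v < 0 for v in abundances.values()):
        raise ValueError("negative abundance")
    if not any(v > 0 for v in abundances.values()):
        raise ValueError("abundances are all zero")
    if index is None:
        index = build_fragment_class_index(
            transcripts, reference, variants, read_length, strain
        )
    eff_lengths = index.eff_lengths
    for key in abundances:
        if key not in eff_lengths:
            raise KeyError(f"abundance given for unknown transcript-allele {key}")

    rng = np.random.default_rng(seed)
    keys = sorted(k for k, v in abundances.items() if v > 0)
    weights = np.array([abundances[k] * eff_lengths[k] for k in keys])
    alloc = rng.multinomial(n_fragments, weights / weights.sum())
    class_counts: Counter[frozenset[TranscriptAllele]] = Counter()
    for key, count in zip(keys, alloc):
        if count == 0:
            continue
        classes_here = index.class_by_start[key]
        starts = Counter(rng.integers(0, len(classes_here), size=count).tolist())
        for start, c in starts.items():
            class_counts[classes_here[start]] += c
    classes = [(m, int(c)) for m, c in sorted(class_counts.items(), key=lambda x: sorted(x[0]))]
    return EquivalenceClassCounts(classes=classes, eff_lengths=dict(eff_lengths))


def simulate_ase_experiment(
    params: SimulationParams,
    n_fragments: int,
    n_per_group: int = 2,
    effect_allele: str = "A1",
    effect_group: str = "KO",
    background_weight: float = 30.0,
) -> tuple[dict[str, list[EquivalenceClassCounts]], dict[str, str]]:
    """Per-sample equivalence-class counts for a two-genotype allelic contrast.

    In ``effect_group`` samples the ``effect_allele`` of every transcript at
    a locus named in ``allelic_log2_effects`` is scaled by 2^effect, leaving
    the other allele untouched -- the single-allele signature of a cis
    perturbation.  Loci without an effect carry ``background_weight`` times
    the abundance of the focal locus, standing in for the rest of the
    transcriptome: TPM is compositional, and in real data a single
    dysregulated locus is a small fraction of the library, so its
    perturbation must not visibly deflate everything else.

    Returns (group -> list of equivalence-class counts, transcript -> locus map).
    """
    reference, variants, transcripts = simulate_diploid_locus(params)
    locus_map = {t.transcript_id: t.locus for t in transcripts}
    base: dict[TranscriptAllele, float] = {}
    for t in transcripts:
        w = 1.0 if t.locus in params.allelic_log2_effects else background_weight
        base[(t.transcript_id, "A1")] = w
        base[(t.transcript_id, "A2")] = w
    effect = dict(base)
    for t in transcripts:
        if t.locus in params.allelic_log2_effects:
            effect[(t.transcript_id, effect_allele)] *= (
                2.0 ** params.allelic_log2_effects[t.locus]
            )
    index = build_fragment_class_index(
        transcripts, reference, variants, params.read_length, params.strain
    )
    rng = np.random.default_rng(params.seed)
    out: dict[str, list[EquivalenceClassCounts]] = {}
    for group in ("WT", effect_group):
        abund = effect if group == effect_group else base
        out[group] = [
            simulate_equivalence_counts(
                abund,
                transcripts,
                reference,
                variants,
                n_fragments,
                read_length=params.read_length,
                seed=int(rng.integers(2**31)),
                strain=params.strain,
                index=index,
            )
            for _ in range(n_per_group)
        ]
    return out, locus_map


def simulate_count_matrix(
    params: SimulationParams,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB count matrix with genotype design, cis/trans effect genes, and a truth table.

    Gene baselines are lognormal around ``nb_mean`` (``mean_spread_sd`` = 0
    gives a constant baseline); counts are NB with variance
    mu + dispersion * mu^2 (dispersion 0 degenerates to Poisson).  Genes
    named in ``cis_gene_log2fc`` are placed downstream of the focal point
    within ``cis_max_distance`` and keep their effect in RESCUE; genes in
    ``trans_gene_log2fc`` change in KO only.
    """
    if len(params.groups) < 2:
        raise ValueError("fewer than 2 groups")
    if params.n_replicates_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = np.random.default_rng(params.seed)
    genes = [f"g{i:05d}" for i in range(params.n_genes)]
    for g in list(params.cis_gene_log2fc) + list(params.trans_gene_log2fc):
        if g not in genes:
            raise KeyError(f"effect gene {g} outside the simulated gene universe")

    lo = params.focal_pos - params.region_span // 2
    hi = params.focal_pos + params.region_span // 2
    starts = rng.integers(max(lo, 0), hi, size=params.n_genes)
    lengths = rng.integers(*params.gene_length_range, size=params.n_genes)
    gene_meta = pd.DataFrame(
        {
            "chrom": params.focal_chrom,
            "start": starts,
            "end": starts + lengths,
            "strand": np.where(rng.random(params.n_genes) < 0.5, "+", "-"),
            "length": lengths,
        },
        index=genes,
    )
    for g in params.cis_gene_log2fc:
        s = int(rng.integers(10_000, params.cis_max_distance)) + params.focal_pos
        gene_meta.loc[g, ["start", "end"]] = (s, s + int(gene_meta.loc[g, "length"]))

    base = params.nb_mean * np.exp(
        rng.normal(0.0, params.mean_spread_sd, size=params.n_genes)
    )
    for g, m in params.base_mean_overrides.items():
        if g not in genes:
            raise KeyError(f"baseline override for unknown gene {g}")
        base[genes.index(g)] = m
    cis = np.array([params.cis_gene_log2fc.get(g, 0.0) for g in genes])
    trans = np.array([params.trans_gene_log2fc.get(g, 0.0) for g in genes])

    cols, design_rows, count_cols = [], [], []
    for group in params.groups:
        lfc = np.zeros(params.n_genes)
        if group in ("KO", "RESCUE"):
            lfc = lfc + cis
        if group == "KO":
            lfc = lfc + trans
        mu = base * 2.0**lfc
        for r in range(params.n_replicates_per_group):
            if params.nb_dispersion == 0:
                counts = rng.poisson(mu)
            else:
                n_param = 1.0 / params.nb_dispersion
                p_param = n_param / (n_param + mu)
                counts = rng.negative_binomial(n_param, p_param)
            name = f"{group}_{r + 1}"
            cols.append(name)
            count_cols.append(counts)
            design_rows.append(
                {"sample": name, "genotype": group, "tissue": params.tissue, "replicate": r + 1}
            )
    counts_df = pd.DataFrame(
        np.column_stack(count_cols), index=genes, columns=cols
    )
    design = pd.DataFrame(design_rows).set_index("sample")
    truth = pd.DataFrame(
        {"cis_log2fc": cis, "trans_log2fc": trans}, index=genes
    )
    cm = CountMatrix(counts=counts_df, design=design, gene_meta=gene_meta)
    return cm, truth


def simulate_tissue_panel(
    params: SimulationParams, tissues: list[str]
) -> dict[str, CountMatrix]:
    """Independent WT/KO count matrices per tissue with shared cis-effect genes.

    Each tissue gets its own derived seed and its own baseline draw, so
    profiles differ between tissues while the planted cis genes recur --
    the construction behind the across-tissue recurrence tally.
    """
    rng = np.random.default_rng(params.seed)
    panel = {}
    for tissue in tissues:
        p = dc_replace(
            params, seed=int(rng.integers(2**31)), tissue=tissue
        )
        panel[tissue], _ = simulate_count_matrix(p)
    return panel
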