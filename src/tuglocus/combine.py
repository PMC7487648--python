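"""Iterative agglomeration of lowly identifiable transcripts.

Isoforms that share most of their sequence cannot be quantified separately:
their posterior abundances trade off against each other, which shows up as
strongly negative Pearson correlation between their posterior TPM draws.
Pairs of same-locus transcripts whose mean posterior correlation across all
RNA-seq samples and both alleles falls below a cutoff (default -0.25) are
merged, and the process repeats on the merged groups until a fixpoint.
Merging is defined on transcript identity, not per-allele, so the resulting
combined transcripts are identical for the two alleles and can be tested for
allelically biased expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quant import PosteriorSamples, TranscriptAllele

DEFAULT_CUTOFF = -0.25


@dataclass
class CombiningConfig:
    cutoff: float = DEFAULT_CUTOFF
    locus_map: dict[str, str] = field(default_factory=dict)
    mode: str = "pooled"  # "pooled": mean over sample x allele; "per-allele": both allele means below cutoff

    def __post_init__(self) -> None:
        if not -1.0 <= self.cutoff <= 0.0:
            raise ValueError("cutoff must be in [-1, 0]")
        if self.mode not in ("pooled", "per-allele"):
            raise ValueError("mode must be 'pooled' or 'per-allele'")


def posterior_correlation(
    samples: PosteriorSamples,
    t_a: str,
    t_b: str,
    allele: str,
    locus_map: dict[str, str] | None = None,
) -> float:
    """Pearson r of two transcripts' posterior TPM draw vectors on one allele.

    Returns NaN (undefined marker) if either vector has zero variance, which
    is what floored (flat-0.01) transcripts produce.
    """
    if t_a == t_b:
        raise ValueError("correlation of a transcript with itself")
    if locus_map is not None and locus_map.get(t_a) != locus_map.get(t_b):
        raise ValueError(f"{t_a} and {t_b} are at different loci")
    x = samples.column((t_a, allele))
    y = samples.column((t_b, allele))
    return _pearson(x, y)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    # flat vectors (e.g. floored transcripts) have no defined correlation
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _pair_score(
    draws: dict[tuple[str, str], np.ndarray],
    g_a: str,
    g_b: str,
    alleles: list[str],
    n_samples: int,
    mode: str,
) -> tuple[float, bool]:
    """Mean posterior correlation for a candidate pair; (score, eligible-evidence)."""
    per_allele_means = []
    pooled: list[float] = []
    for allele in alleles:
        vals = []
        for s in range(n_samples):
            r = _pearson(draws[(g_a, allele)][s], draws[(g_b, allele)][s])
            if not np.isnan(r):
                vals.append(r)
                pooled.append(r)
        per_allele_means.append(np.mean(vals) if vals else np.nan)
    if not pooled:
        return np.nan, False
    if mode == "per-allele":
        if any(np.isnan(m) for m in per_allele_means):
            return np.nan, False
        return max(per_allele_means), True  # both alleles must clear the cutoff
    return float(np.mean(pooled)), True


def combine_transcripts(
    per_sample_posteriors: list[PosteriorSamples],
    config: CombiningConfig,
) -> tuple[dict[str, tuple[str, ...]], list[PosteriorSamples]]:
    """Greedy fixpoint agglomeration of same-locus transcript pairs.

    At each step the mean Pearson correlation over all (sample x allele)
    posterior TPM draw vectors is computed for every same-locus pair of
    current groups; among pairs below the cutoff the most negative is merged
    (ties broken lexicographically on group ids), the merged group's draws
    being the elementwise sum of its members' draws per allele per sample.
    Iteration stops when no pair falls below the cutoff.  Undefined
    correlations (zero-variance draws) are excluded from the mean; a pair
    with no defined value is ineligible.

    Returns the grouping (group id -> member transcript ids) and combined
    posterior samples per input sample.
    """
    if not per_sample_posteriors:
        raise ValueError("no posterior samples")
    first = per_sample_posteriors[0]
    if first.tpm is None:
        raise ValueError("posterior samples must carry the TPM view")
    universe = set(first.ids)
    for ps in per_sample_posteriors[1:]:
        if set(ps.ids) != universe:
            raise ValueError("mismatched transcript universes across samples")
    transcripts = sorted({t for t, _ in universe})
    alleles = sorted({a for _, a in universe})
    n_samples = len(per_sample_posteriors)
    locus = {t: config.locus_map.get(t, "_locus") for t in transcripts}

    # group id -> member transcripts; draws keyed by (group id, allele): (n_samples, D)
    groups: dict[str, tuple[str, ...]] = {t: (t,) for t in transcripts}
    draws: dict[tuple[str, str], np.ndarray] = {}
    for t in transcripts:
        for a in alleles:
            draws[(t, a)] = np.stack(
                [ps.column((t, a)) for ps in per_sample_posteriors]
            )

    merge_log: list[tuple[str, str, float]] = []
    while True:
        gids = sorted(groups)
        best: tuple[float, str, str] | None = None
        for i, g_a in enumerate(gids):
            for g_b in gids[i + 1 :]:
                if locus[groups[g_a][0]] != locus[groups[g_b][0]]:
                    continue
                score, ok = _pair_score(draws, g_a, g_b, alleles, n_samples, config.mode)
                if not ok or not score < config.cutoff:
                    continue
                if best is None or score < best[0] or (
                    score == best[0] and (g_a, g_b) < (best[1], best[2])
                ):
                    best = (score, g_a, g_b)
        if best is None:
            break
        score, g_a, g_b = best
        members = tuple(sorted(groups[g_a] + groups[g_b]))
        gid = "+".join(members)
        for a in alleles:
            draws[(gid, a)] = draws.pop((g_a, a)) + draws.pop((g_b, a))
        del groups[g_a], groups[g_b]
        groups[gid] = members
        merge_log.append((g_a, g_b, score))

    combined: list[PosteriorSamples] = []
    gids = sorted(groups)
    ids: list[TranscriptAllele] = [(g, a) for g in gids for a in alleles]
    for s, ps in enumerate(per_sample_posteriors):
        tpm = np.column_stack([draws[(g, a)][s] for g, a in ids])
        eff = {
            (g, a): sum(ps.eff_lengths[(t, a)] for t in groups[g])
            for g, a in ids
        }
        combined.append(
            PosteriorSamples(
                ids=list(ids),
                theta=tpm,  # combined draws live on the TPM scale
                eff_lengths=eff,
                n_draws=ps.n_draws,
                burn_in=ps.burn_in,
                thin=ps.thin,
                tpm=tpm,
                metadata={
                    "combined": True,
                    "cutoff": config.cutoff,
                    "mode": config.mode,
                    "mean_rule": "arithmetic mean over all sample x allele "
                    "correlations, undefined values excluded",
                    "merges": merge_log,
                },
            )
        )
    return groups, combined
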