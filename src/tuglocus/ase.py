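"""Allelic-bias calling between genotype groups from posterior samples.

A feature (a transcript or a combined transcript group) is compared between
two groups of RNA-seq samples on one allele.  For each posterior draw index
d, the difference of group-mean log TPM is computed; the posterior
probability (PP) of a directional difference is the larger of the fractions
of draws falling on either side of zero.  A call is significant when
PP > 0.95, the threshold used for the one-allele-only dysregulation readout.

The PP is a posterior quantity (probability of direction), computed on
paired posterior draws of group-mean log TPM; draws are paired by index
after verifying equal draw counts, so each sample's posterior uncertainty
propagates into the call.  No multiplicity adjustment is applied across
features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quant import PosteriorSamples

PP_THRESHOLD = 0.95


@dataclass
class AlleleCall:
    feature: str
    allele: str
    mean_a: float
    mean_b: float
    pp: float
    direction: str  # "up"/"down" of group B relative to group A
    significant: bool


def test_allelic_differential(
    group_a: list[PosteriorSamples],
    group_b: list[PosteriorSamples],
    feature: str,
    allele: str,
    pp_threshold: float = PP_THRESHOLD,
) -> AlleleCall:
    """Posterior probability of a directional allele-specific difference.

    Delta_d = mean over group-B samples of log TPM_d - mean over group-A
    samples of log TPM_d, per draw d; PP = max fraction of draws with a
    consistent sign (zero differences split evenly so that identical groups
    give PP = 0.5).  Swapping the groups flips the direction and preserves
    the PP exactly.
    """
    if not group_a or not group_b:
        raise ValueError("each group needs at least one sample")
    cols_a = [ps.column((feature, allele)) for ps in group_a]
    cols_b = [ps.column((feature, allele)) for ps in group_b]
    depths = {len(c) for c in cols_a + cols_b}
    if len(depths) != 1:
        raise ValueError(
            "unequal posterior draw counts across samples; resample upstream"
        )
    log_a = np.mean(np.log(np.stack(cols_a)), axis=0)
    log_b = np.mean(np.log(np.stack(cols_b)), axis=0)
    delta = log_b - log_a
    d = len(delta)
    p_up = (np.sum(delta > 0) + 0.5 * np.sum(delta == 0)) / d
    pp = float(max(p_up, 1.0 - p_up))
    direction = "up" if p_up >= 0.5 else "down"
    return AlleleCall(
        feature=feature,
        allele=allele,
        mean_a=float(np.mean(np.stack(cols_a))),
        mean_b=float(np.mean(np.stack(cols_b))),
        pp=pp,
        direction=direction,
        significant=pp > pp_threshold,
    )
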