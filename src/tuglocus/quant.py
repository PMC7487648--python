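"""Posterior inference of transcript-per-allele abundance from equivalence classes.

Sequenced fragments are summarized as equivalence classes: the set of
(transcript, allele) assignments each fragment is compatible with.  A
fragment covering no strain-distinguishing variant is allele-ambiguous and
belongs to both alleles of its transcript(s); that ambiguity is carried into
the posterior rather than resolved by assignment.

The model is the standard latent-allocation one: fragment counts from
transcript-allele t arise at rate theta_t * l_t (l_t the effective length),
with a Gamma(alpha, beta) prior on each theta_t.  A Gibbs sweep alternates
(i) multinomial allocation of each class's count among its members with
probability proportional to theta_t (member rates within a class share the
fragment's length factor through l_t at the rate level, see below) and
(ii) the conjugate Gamma(alpha + n_t, beta + l_t) update.  Posterior draws
are reported in TPM with the 0.01 floor used as the minimal measurable
expression level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TranscriptAllele = tuple[str, str]

DEFAULT_ALPHA = 0.01
DEFAULT_BETA = 0.001
TPM_FLOOR = 0.01


@dataclass
class EquivalenceClassCounts:
    """Fragment counts keyed by compatibility sets of (transcript_id, allele)."""

    classes: list[tuple[frozenset[TranscriptAllele], int]]
    eff_lengths: dict[TranscriptAllele, float]

    def __post_init__(self) -> None:
        seen: set[frozenset[TranscriptAllele]] = set()
        for members, count in self.classes:
            if not members:
                raise ValueError("empty equivalence-class member set")
            if members in seen:
                raise ValueError(f"duplicate equivalence class {sorted(members)}")
            seen.add(members)
            if count < 0:
                raise ValueError("negative class count")
            for m in members:
                if m not in self.eff_lengths:
                    raise ValueError(f"no effective length for {m}")
        for m, l in self.eff_lengths.items():
            if l <= 0:
                raise ValueError(f"non-positive effective length for {m}")

    @property
    def keys(self) -> list[TranscriptAllele]:
        return sorted(self.eff_lengths)

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.classes)

    def to_tsv(self, path) -> None:
        with open(path, "w") as f:
            f.write("members\tcount\n")
            for members, count in self.classes:
                tok = ",".join(f"{t}|{a}" for t, a in sorted(members))
                f.write(f"{tok}\t{count}\n")
            for (t, a), l in sorted(self.eff_lengths.items()):
                f.write(f"#efflen\t{t}|{a}\t{l}\n")

    @classmethod
    def from_tsv(cls, path) -> "EquivalenceClassCounts":
        classes: list[tuple[frozenset[TranscriptAllele], int]] = []
        eff: dict[TranscriptAllele, float] = {}
        with open(path) as f:
            for line in f:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "members":
                    continue
                if parts[0] == "#efflen":
                    t, a = parts[1].split("|")
                    eff[(t, a)] = float(parts[2])
                else:
                    members = frozenset(
                        tuple(tok.split("|")) for tok in parts[0].split(",")
                    )
                    classes.append((members, int(parts[1])))
        return cls(classes, eff)


@dataclass
class PosteriorSamples:
    """Matrix of posterior draws (draw x transcript-allele), with optional TPM view."""

    ids: list[TranscriptAllele]
    theta: np.ndarray  # (n_draws, K) abundance-scale draws
    eff_lengths: dict[TranscriptAllele, float]
    n_draws: int
    burn_in: int
    thin: int
    tpm: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def column(self, key: TranscriptAllele, view: str = "tpm") -> np.ndarray:
        j = self.ids.index(key)
        mat = self.tpm if view == "tpm" else self.theta
        if mat is None:
            raise ValueError("TPM view not populated; call to_tpm first")
        return mat[:, j]


def sample_posterior(
    counts: EquivalenceClassCounts,
    n_draws: int = 1024,
    burn_in: int = 512,
    thin: int = 2,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> PosteriorSamples:
    """Gibbs sampler over latent fragment allocations.

    Given abundances theta, each class's count is allocated multinomially
    among its members with probability proportional to theta_t / l_t (the
    per-position rate of the member); given allocations n_t,
    theta_t ~ Gamma(alpha + n_t, beta + l_t).  Draws are
    recorded after ``burn_in`` sweeps, keeping every ``thin``-th sweep.
    Deterministic given ``seed``.

    With all-singleton classes the chain reduces to independent draws from
    the closed-form conjugate posterior Gamma(alpha + n_t, beta + l_t).
    """
    if counts.total_count <= 0:
        raise ValueError("zero total fragment count")
    if n_draws < 1 or burn_in < 0 or thin < 1:
        raise ValueError("invalid sampler configuration")
    keys = counts.keys
    index = {k: i for i, k in enumerate(keys)}
    K = len(keys)
    lengths = np.array([counts.eff_lengths[k] for k in keys])
    class_idx = [
        (np.array(sorted(index[m] for m in members)), count)
        for members, count in counts.classes
    ]
    rng = np.random.default_rng(seed)
    theta = np.full(K, (alpha + counts.total_count / K) / (beta + lengths.mean()))
    draws = np.empty((n_draws, K))
    stored = 0
    sweep = 0
    while stored < n_draws:
        n = np.zeros(K)
        for idx, count in class_idx:
            if count == 0:
                continue
            p = theta[idx] / lengths[idx]
            tot = p.sum()
            if tot <= 0:
                p = np.full(len(idx), 1.0 / len(idx))
            else:
                p = p / tot
            alloc = rng.multinomial(count, p)
            assert alloc.sum() == count  # count conservation within the sweep
            n[idx] += alloc
        theta = rng.gamma(alpha + n, 1.0 / (beta + lengths))
        sweep += 1
        if sweep > burn_in and (sweep - burn_in) % thin == 0:
            draws[stored] = theta
            stored += 1
    return PosteriorSamples(
        ids=keys,
        theta=draws,
        eff_lengths=dict(counts.eff_lengths),
        n_draws=n_draws,
        burn_in=burn_in,
        thin=thin,
        metadata={"alpha": alpha, "beta": beta, "seed": seed},
    )


def to_tpm(samples: PosteriorSamples, floor: float = TPM_FLOOR) -> PosteriorSamples:
    """Populate the TPM view: per-draw normalization to 1e6, then flooring.

    Per draw, TPM_t = 1e6 * theta_t / sum(theta) (each draw sums to 1e6
    before flooring).  Values below ``floor`` are raised to it, and any
    transcript-allele whose posterior median TPM is below ``floor`` has all
    its draws set flat to ``floor`` -- the minimal measurable expression
    level.  Flat columns carry zero variance and are treated as undefined in
    downstream posterior correlations.
    """
    totals = samples.theta.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("draw with zero total abundance")
    tpm = 1e6 * samples.theta / totals
    med = np.median(tpm, axis=0)  # on the raw scale, before any flooring
    tpm = np.maximum(tpm, floor)
    tpm[:, med < floor] = floor
    out = PosteriorSamples(
        ids=list(samples.ids),
        theta=samples.theta,
        eff_lengths=dict(samples.eff_lengths),
        n_draws=samples.n_draws,
        burn_in=samples.burn_in,
        thin=samples.thin,
        tpm=tpm,
        metadata=dict(samples.metadata),
    )
    out.metadata["tpm_floor"] = floor
    return out
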