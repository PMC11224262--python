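"""Simulation studies over the synthetic generator.

These functions run the full pipeline (generate -> filter -> segment ->
embed -> coherence -> covariates -> model) under controlled conditions:
drift monotonicity, effect-size recovery, confound adjustment, null
calibration of the Tukey family, and the closed-form power check.

Problem sizes are desk-scale by design: simulated posts use a median of
3-4 sentences of ~7-8 words.  Effect-recovery and confound studies embed at
the pipeline default dimension (512, where the coherence construct is
defined); the replicate-heavy null-calibration study drops to a 16-dim
encoder, since type-I calibration is exchangeability-driven and does not
depend on embedding width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import HashingEncoder
from .pipeline import score_posts
from .stats import CoherenceModel, posthoc_power_two_group
from .synthetic import GroupSpec, default_topic_model, generate_corpus

__all__ = [
    "simulation_spec",
    "drift_monotonicity",
    "drift_effect_replicates",
    "confound_null_replicates",
    "null_family_error",
    "power_at_paper_scale",
]

#: compact per-post shape used across simulation studies
SIM_SENTENCE_MEDIAN = 4.0
SIM_SENTENCE_SIGMA = 0.45
SIM_LENGTH_MEAN = 8.0
SIM_LENGTH_SD = 2.5


def simulation_spec(
    group_name: str,
    n_posts: int,
    drift: float,
    seed: int,
    *,
    sentence_count_median: float = SIM_SENTENCE_MEDIAN,
    sentence_count_sigma: float = SIM_SENTENCE_SIGMA,
    sentence_length_mean: float = SIM_LENGTH_MEAN,
    sentence_length_sd: float = SIM_LENGTH_SD,
    valence_bias: float = 0.0,
    subjectivity_bias: float = 0.5,
) -> GroupSpec:
    """Desk-scale GroupSpec with the shared simulation post shape."""
    return GroupSpec(
        group_name=group_name,
        n_posts=n_posts,
        drift=drift,
        sentence_count_median=sentence_count_median,
        sentence_count_sigma=sentence_count_sigma,
        sentence_length_mean=sentence_length_mean,
        sentence_length_sd=sentence_length_sd,
        valence_bias=valence_bias,
        subjectivity_bias=subjectivity_bias,
        seed=seed,
    )


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31 - 1, size=n)


def drift_monotonicity(
    drifts: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_posts: int = 2000,
    dim: int = 512,
    seed: int = 0,
) -> pd.Series:
    """Mean pipeline coherence per drift arm (one corpus per arm).

    Higher drift resamples the topic more often between consecutive
    sentences, so mean coherence should decrease strictly along ``drifts``.
    """
    topics = default_topic_model()
    encoder = HashingEncoder(dim=dim)
    arm_seeds = _rep_seeds(seed, len(drifts))
    means = {}
    for drift, s in zip(drifts, arm_seeds):
        spec = simulation_spec(f"drift_{drift:g}", n_posts, drift, int(s))
        scored, _ = score_posts(generate_corpus([spec], topics), encoder)
        means[drift] = scored["coherence"].mean()
    return pd.Series(means, name="mean_coherence")


def drift_effect_replicates(
    n_reps: int = 100,
    n_per_arm: int = 2000,
    drift_low: float = 0.2,
    drift_high: float = 0.6,
    dim: int = 512,
    seed: int = 0,
) -> pd.DataFrame:
    """Adjusted low-vs-high-drift contrast per replicate.

    Returns one row per replicate with the Tukey contrast of the
    low-drift group minus the high-drift group (estimate, p, Cohen's d);
    the true effect is positive (lower drift -> higher coherence).
    """
    topics = default_topic_model()
    encoder = HashingEncoder(dim=dim)
    seeds = _rep_seeds(seed, 2 * n_reps).reshape(n_reps, 2)
    rows = []
    for r in range(n_reps):
        specs = [
            simulation_spec("lowdrift", n_per_arm, drift_low, int(seeds[r, 0])),
            simulation_spec("highdrift", n_per_arm, drift_high, int(seeds[r, 1])),
        ]
        scored, _ = score_posts(generate_corpus(specs, topics), encoder)
        res = CoherenceModel.from_dataframe(scored, reference_group="highdrift").fit()
        pair = res.pairwise().iloc[0]
        sign = 1.0 if pair["group1"] == "lowdrift" else -1.0
        rows.append(
            {
                "estimate": sign * pair["estimate"],
                "p_tukey": pair["p_tukey"],
                "cohens_d": sign * pair["cohens_d"],
            }
        )
    return pd.DataFrame(rows)


def confound_null_replicates(
    n_reps: int = 200,
    n_per_arm: int = 400,
    drift: float = 0.4,
    dim: int = 512,
    seed: int = 0,
) -> pd.DataFrame:
    """Pure-confound study: equal drift, unequal valence and length.

    Both groups share the same topic-drift level (so true coherence is
    equal); they differ in emotional valence bias (0 vs 0.3), sentence
    length (7 vs 9 words) and post length (median 4 vs 5 sentences).  The
    covariate-adjusted contrast should be non-significant in the vast
    majority of replicates.
    """
    topics = default_topic_model()
    encoder = HashingEncoder(dim=dim)
    seeds = _rep_seeds(seed, 2 * n_reps).reshape(n_reps, 2)
    rows = []
    for r in range(n_reps):
        specs = [
            simulation_spec(
                "neutral", n_per_arm, drift, int(seeds[r, 0]),
                sentence_length_mean=7.0, sentence_count_median=4.0, valence_bias=0.0,
            ),
            simulation_spec(
                "positive", n_per_arm, drift, int(seeds[r, 1]),
                sentence_length_mean=9.0, sentence_count_median=5.0, valence_bias=0.3,
            ),
        ]
        scored, _ = score_posts(generate_corpus(specs, topics), encoder)
        res = CoherenceModel.from_dataframe(scored, reference_group="neutral").fit()
        pair = res.pairwise().iloc[0]
        # unadjusted standardized mean difference, for attenuation checks
        g = scored.groupby("group")["coherence"]
        means, sds, ns = g.mean(), g.std(ddof=1), g.size()
        sp = np.sqrt(
            ((ns - 1) * sds**2).sum() / (ns.sum() - 2)
        )
        rows.append(
            {
                "p_tukey": pair["p_tukey"],
                "cohens_d_adj": pair["cohens_d"],
                "cohens_d_raw": (means["neutral"] - means["positive"]) / sp,
            }
        )
    return pd.DataFrame(rows)


def null_family_error(
    n_reps: int = 1000,
    n_groups: int = 5,
    n_posts_per_group: int = 500,
    dim: int = 16,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Family-wise Tukey error rate under a fully null design.

    All groups share identical generative parameters; a replicate counts as
    a family-wise error when any Tukey-adjusted pairwise p falls below
    ``alpha``.  Posts are kept short (median 3 sentences) so the study runs
    at desk scale.
    """
    topics = default_topic_model()
    encoder = HashingEncoder(dim=dim)
    seeds = _rep_seeds(seed, n_reps * n_groups).reshape(n_reps, n_groups)
    n_err = 0
    for r in range(n_reps):
        specs = [
            simulation_spec(
                f"g{j}", n_posts_per_group, 0.5, int(seeds[r, j]),
                sentence_count_median=3.0, sentence_count_sigma=0.35,
                sentence_length_mean=7.0, sentence_length_sd=2.0,
            )
            for j in range(n_groups)
        ]
        scored, _ = score_posts(generate_corpus(specs, topics), encoder)
        res = CoherenceModel.from_dataframe(scored).fit()
        if (res.pairwise()["p_tukey"] < alpha).any():
            n_err += 1
    return n_err / n_reps


def power_at_paper_scale(
    d: float = 0.255, n1: int = 27_422, n2: int = 242_233, alpha: float = 0.05
) -> float:
    """Closed-form post-hoc power at published-study scale.

    Defaults reproduce the achieved power of a two-group comparison with
    d = 0.255 at group sizes 27,422 and 242,233, which approaches 1.
    """
    return posthoc_power_two_group(d, n1, n2, alpha)
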