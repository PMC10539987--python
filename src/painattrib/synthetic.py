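"""Synthetic randomized-trial generator with known ground truth.

Emulates the data shape of a three-arm chronic-back-pain trial (pain
reprocessing therapy, open-label placebo injection, usual care) in which
each participant lists their 3 most important perceived causes of pain,
in rank order and free text, before and after treatment, and reports
0-10 pain intensity at baseline, posttreatment and 1-year follow-up.

The generative model, all of whose parameters are inspectable ground
truth:

* Each pre-treatment attribution draws a category from
  ``category_probs_pre`` (same in every arm); its text is sampled from a
  per-category pool of diagnostic words plus shared filler vocabulary,
  averaging ~3 words.
* Post-treatment, control arms redraw from the baseline distribution,
  while each PRT attribution is drawn from a mind/brain category
  (stress / psychological / brain, uniformly) with probability
  ``mindbrain_shift_prt`` and from the baseline distribution otherwise.
  The implied treatment effect on the change in mind-brain attribution
  score is  a = 3 · shift · (1 − p_mb)  with p_mb the baseline
  mind/brain probability mass; ``a_true`` and ``mindbrain_shift_prt``
  are therefore two parametrizations of the same knob and the config
  accepts either.
* Pain:  pain_1yr = pain_pre + direct·1{PRT} + b·Δscore + noise,
  truncated to [0, 10]; posttreatment pain follows the same structural
  form.  The product a·b is the built-in indirect (mediated) effect.
* Dropout is missing-completely-at-random per participant at the post
  and follow-up assessments.

Defaults mirror the trial's reported marginals: 0-10 baseline pain with
mean 4.10 (SD 1.26), ~3-word attributions, ~10% mind/brain attributions
at baseline, ~51% mind/brain attributions post-PRT, ~11% dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import DEFAULT_CODEBOOK, Codebook

ARMS = ("prt", "placebo", "usual_care")

# Baseline category distribution: prevalent categories follow the
# reported pretreatment prevalences (activity 25%, injury 19%,
# physiological 16%, stress 7%, psychological 2%, brain 0.2%); the
# remaining mass is spread over the unreported categories.
DEFAULT_CATEGORY_PROBS_PRE: dict[str, float] = {
    "spinal_condition": 0.120,
    "physiological": 0.160,
    "injury": 0.190,
    "activity": 0.250,
    "neglect": 0.026,
    "sedentariness": 0.080,
    "stress": 0.070,
    "psychological": 0.022,
    "brain": 0.002,
    "hereditary_congenital": 0.045,
    "age": 0.035,
}

# Per-category diagnostic word pools (first word of each attribution is
# always diagnostic of its category).
CATEGORY_WORD_POOLS: dict[str, tuple[str, ...]] = {
    "spinal_condition": ("scoliosis", "disc", "degenerative", "spine", "spinal",
                         "vertebrae", "bulge", "stenosis", "herniated", "arthritis",
                         "curvature", "compression"),
    "physiological": ("posture", "flexibility", "muscles", "weak", "core", "tight",
                      "imbalance", "hamstrings", "abdominal", "strength", "fitness"),
    "injury": ("injury", "fall", "falling", "accident", "crash", "fracture",
               "sprain", "childhood", "skating", "football", "lifting", "wreck"),
    "activity": ("gymnastics", "rowing", "sports", "running", "soccer", "basketball",
                 "skiing", "hiking", "dancing", "tennis", "climbing", "swimming"),
    "neglect": ("neglect", "untreated", "ignored", "care", "busy", "delayed",
                "postponing", "inattention"),
    "sedentariness": ("sedentary", "sitting", "desk", "computer", "inactive",
                      "inactivity", "couch", "driving", "chair", "immobility"),
    "stress": ("stress", "stressful", "stressed", "tension", "pressure",
               "overwhelm", "workload", "deadlines"),
    "psychological": ("anxiety", "personality", "guilt", "outlook", "emotions",
                      "emotional", "depression", "worry", "fear", "feelings",
                      "perfectionism", "anger"),
    "brain": ("neural", "pathways", "brain", "neuroplasticity", "sensitization",
              "signals", "overactive", "oversensitive", "wiring", "alarm"),
    "hereditary_congenital": ("genetics", "hereditary", "congenital", "birth",
                              "defect", "genes", "inherited", "familial"),
    "age": ("age", "aging", "older", "elderly", "wear", "tear", "getting", "years"),
}

# Shared filler vocabulary: connectives kept for realism (they are
# stopworded away in preprocessing) plus neutral content words.
FILLER_WORDS: tuple[str, ...] = (
    "my", "the", "of", "from", "and", "back", "pain", "years", "long", "time",
    "heavy", "poor", "bad", "daily", "constant", "lower", "chronic", "work",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic trial.

    ``mindbrain_shift_prt`` and ``a_true`` parametrize the same
    reattribution mechanism (a = 3·shift·(1−p_mb)); give one and the
    other is derived, give both and they must agree.
    """

    n_per_arm: int = 50
    seed: int = 0
    category_probs_pre: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS_PRE)
    )
    mindbrain_shift_prt: float | None = 0.46
    a_true: float | None = None
    b_true: float = -0.8
    direct_true: float = -1.0
    pain_pre_mean: float = 4.10
    pain_pre_sd: float = 1.26
    noise_sd: float = 1.5
    dropout_rate: float = 0.106
    words_per_attribution_mean: float = 3.11
    codebook: Codebook = DEFAULT_CODEBOOK

    def __post_init__(self) -> None:
        if self.n_per_arm < 0:
            raise ValueError("n_per_arm must be >= 0")
        probs = np.array([self.category_probs_pre.get(c, 0.0) for c in self.codebook.categories])
        if (probs < 0).any():
            raise ValueError("category_probs_pre entries must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"category_probs_pre must sum to 1 (got {probs.sum():.15f})"
            )
        unknown = set(self.category_probs_pre) - set(self.codebook.categories)
        if unknown:
            raise ValueError(f"category_probs_pre has unknown categories: {sorted(unknown)}")
        for name in ("pain_pre_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be a probability in [0, 1]")
        if self.words_per_attribution_mean <= 0:
            raise ValueError("words_per_attribution_mean must be > 0")

        shift, a = self.mindbrain_shift_prt, self.a_true
        pmb = self.prob_mindbrain_pre
        if shift is None and a is None:
            raise ValueError("give mindbrain_shift_prt or a_true")
        if shift is None:
            shift = a / (3.0 * (1.0 - pmb)) if a != 0 else 0.0
            object.__setattr__(self, "mindbrain_shift_prt", shift)
        if not (0.0 <= self.mindbrain_shift_prt <= 1.0):
            raise ValueError("mindbrain_shift_prt must be a probability in [0, 1]")
        implied_a = 3.0 * self.mindbrain_shift_prt * (1.0 - pmb)
        if a is None:
            object.__setattr__(self, "a_true", implied_a)
        elif abs(a - implied_a) > 1e-6:
            raise ValueError(
                f"a_true={a} inconsistent with mindbrain_shift_prt="
                f"{self.mindbrain_shift_prt} (implies a={implied_a:.6f})"
            )

    @property
    def prob_mindbrain_pre(self) -> float:
        return float(
            sum(self.category_probs_pre.get(c, 0.0) for c in self.codebook.mindbrain_subset)
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside a generated dataset."""

    categories: pd.DataFrame  # participant_id, timepoint, rank, category
    delta_score: pd.DataFrame  # participant_id, delta_score_true
    a_true: float
    b_true: float
    direct_true: float

    @property
    def indirect_true(self) -> float:
        return self.a_true * self.b_true

    def to_dict(self) -> dict:
        return {
            "a_true": self.a_true,
            "b_true": self.b_true,
            "direct_true": self.direct_true,
            "indirect_true": self.indirect_true,
        }


@dataclass(frozen=True)
class TrialDataset:
    participants: pd.DataFrame
    attributions: pd.DataFrame


def generate_attribution_text(
    category: str, rng: np.random.Generator, words_mean: float = 3.11
) -> str:
    """One short free-text attribution for a category.

    1-10 words; always contains at least one category-diagnostic token
    (the remaining words mix the category pool with shared fillers).
    Deterministic given the generator state.
    """
    if category not in CATEGORY_WORD_POOLS:
        raise ValueError(f"unknown category: {category!r}")
    pool = CATEGORY_WORD_POOLS[category]
    n_words = int(min(1 + rng.poisson(max(words_mean - 1.0, 0.0)), 10))
    words = [pool[rng.integers(len(pool))]]
    for _ in range(n_words - 1):
        if rng.random() < 0.45:
            words.append(pool[rng.integers(len(pool))])
        else:
            words.append(FILLER_WORDS[rng.integers(len(FILLER_WORDS))])
    rng.shuffle(words)
    return " ".join(words).capitalize()


def generate_trial(config: SimulationConfig) -> tuple[TrialDataset, SyntheticTruth]:
    """Generate one synthetic trial with its ground truth.

    Bit-reproducible for a given config (one named random stream seeded
    by ``config.seed`` drives every draw).
    """
    rng = np.random.default_rng(config.seed)
    cats = list(config.codebook.categories)
    probs = np.array([config.category_probs_pre.get(c, 0.0) for c in cats])
    mb_cats = [c for c in cats if c in config.codebook.mindbrain_subset]
    n_total = 3 * config.n_per_arm

    if n_total == 0:
        participants = pd.DataFrame(
            columns=["participant_id", "arm", "pain_pre", "pain_post", "pain_1yr", "completed"]
        )
        attributions = pd.DataFrame(columns=["participant_id", "timepoint", "rank", "text"])
        truth = SyntheticTruth(
            categories=pd.DataFrame(columns=["participant_id", "timepoint", "rank", "category"]),
            delta_score=pd.DataFrame(columns=["participant_id", "delta_score_true"]),
            a_true=config.a_true, b_true=config.b_true, direct_true=config.direct_true,
        )
        return TrialDataset(participants, attributions), truth

    pids = [f"p{i:04d}" for i in range(n_total)]
    arms = np.repeat(ARMS, config.n_per_arm)

    pain_pre = np.clip(
        rng.normal(config.pain_pre_mean, config.pain_pre_sd, n_total), 0.0, 10.0
    )
    dropout_post = rng.random(n_total) < config.dropout_rate
    dropout_1yr = rng.random(n_total) < config.dropout_rate

    # Vectorized category draws: baseline draws for all slots, a mind/brain
    # mixture overriding post-treatment PRT slots with probability `shift`.
    cum = np.cumsum(probs)
    idx_pre = np.searchsorted(cum, rng.random((n_total, 3)), side="right")
    idx_post = np.searchsorted(cum, rng.random((n_total, 3)), side="right")
    mb_override = (rng.random((n_total, 3)) < config.mindbrain_shift_prt) & (
        arms == "prt"
    )[:, None]
    mb_draw = rng.integers(len(mb_cats), size=(n_total, 3))
    mb_lookup = np.array([cats.index(c) for c in mb_cats])
    idx_post = np.where(mb_override, mb_lookup[mb_draw], idx_post)

    is_mb_cat = np.array([c in config.codebook.mindbrain_subset for c in cats])
    pre_score = is_mb_cat[idx_pre].sum(axis=1)
    post_score = is_mb_cat[idx_post].sum(axis=1)

    attr_rows, cat_rows = [], []
    for i, pid in enumerate(pids):
        for tp, idx in (("pre", idx_pre), ("post", idx_post)):
            for rank in (1, 2, 3):
                cat = cats[idx[i, rank - 1]]
                text = generate_attribution_text(cat, rng, config.words_per_attribution_mean)
                cat_rows.append((pid, tp, rank, cat))
                if tp == "pre" or not dropout_post[i]:
                    attr_rows.append((pid, tp, rank, text))

    delta = post_score - pre_score
    is_prt = (arms == "prt").astype(float)
    pain_post = np.clip(
        pain_pre + config.direct_true * is_prt + config.b_true * delta
        + rng.normal(0.0, config.noise_sd, n_total),
        0.0, 10.0,
    )
    pain_1yr = np.clip(
        pain_pre + config.direct_true * is_prt + config.b_true * delta
        + rng.normal(0.0, config.noise_sd, n_total),
        0.0, 10.0,
    )
    pain_post[dropout_post] = np.nan
    pain_1yr[dropout_post | dropout_1yr] = np.nan

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "arm": arms,
            "pain_pre": np.round(pain_pre, 6),
            "pain_post": np.round(pain_post, 6),
            "pain_1yr": np.round(pain_1yr, 6),
            "completed": ~dropout_post,
        }
    )
    attributions = pd.DataFrame(
        attr_rows, columns=["participant_id", "timepoint", "rank", "text"]
    )
    truth = SyntheticTruth(
        categories=pd.DataFrame(
            cat_rows, columns=["participant_id", "timepoint", "rank", "category"]
        ),
        delta_score=pd.DataFrame(
            {"participant_id": pids, "delta_score_true": delta}
        ),
        a_true=config.a_true,
        b_true=config.b_true,
        direct_true=config.direct_true,
    )
    return TrialDataset(participants, attributions), truth


def truth_to_codings(
    truth: SyntheticTruth, coders: tuple[str, ...] = ("coder1", "coder2")
) -> pd.DataFrame:
    """Expand true categories into a per-coder codings table.

    Both simulated coders return the true category (perfect agreement);
    tests engineer disagreements on top of this where needed.
    """
    frames = []
    for coder in coders:
        f = truth.categories.copy()
        f.insert(3, "coder_id", coder)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
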