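"""Synthetic crisis-chat corpus generator with known ground truth.

The confidential helpline corpus cannot ship, so this module generates
stand-in corpora whose every latent quantity is known: group membership
(gender x age cell), per-category per-stage planted phrase counts, the SR
label drawn from a logistic model on those counts, and the true
coefficients.  The generative direction matches the fitted model's
conditional form — counts first, then label — which makes parameter
recovery well-posed:

    X[j, s]  ~ Poisson(lambda[j, s] * mult[j, gender])        (stage s = 1..5)
    SR       ~ Bernoulli(logistic(b0[cell] + sum_js beta_j w_js X[j, s]))

With the default all-ones stage weights ``w`` the label depends only on the
per-category totals, exactly the multivariable model the pipeline fits.
Rising weights let a construct's late mentions carry more signal than its
early ones, which is the data-generating mechanism behind rising odds-ratio
trajectories across chat fractions.

Rendering guarantees exact count recovery by the matcher: filler vocabulary
is token-disjoint from every lexicon phrase, planted phrases are separated
by at least one filler token and never span messages, and all five stages of
a session are padded to identical help-seeker character lengths so the
character-fraction slice at f = s/5 captures exactly stages 1..s.

Intercepts are calibrated per (gender x age) cell so realized subgroup SR
prevalences match the published helpline margins; the calibration solves
E[logistic(b0 + beta . X)] = target by root finding over the exact (grid-
convolved) Poisson mixture rather than by Monte Carlo.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .corpus import COUNSELOR, HELP_SEEKER, ChatSession, Message, clean_text
from .features import DesignMatrix
from .lexicon import SRFLexicon, _TOKEN_RE, _normalize
from .risk_model import fit_logistic

__all__ = [
    "GeneratorError",
    "GeneratorConfig",
    "GroundTruth",
    "default_config",
    "trajectory_config",
    "trajectory_null_config",
    "calibrate_intercept",
    "calibrate_intercepts",
    "generate_counts",
    "generate_corpus",
    "write_ground_truth",
    "recovery_study",
    "trajectory_study",
    "stratification_study",
]

N_STAGES = 5
SIM_GENDERS = ("female", "male", "unknown")
SIM_AGES = ("10-17", "18-20", "21-40", "41+", "unknown")

#: published helpline sample margins: (total, SR cases) per subgroup
GENDER_MARGINS = {"female": (12074, 2173), "male": (5343, 908),
                 "unknown": (147, 16)}
AGE_MARGINS = {"10-17": (4179, 627), "18-20": (3283, 671),
              "21-40": (8603, 1482), "41+": (1467, 314), "unknown": (32, 3)}
OVERALL_MARGIN = (17564, 3097)

#: closed filler vocabulary; token-disjoint from the packaged toy lexicon
DEFAULT_FILLER = (
    "zuvela", "morvik", "telpane", "quandor", "bistrel", "favrock", "nelwist",
    "pordane", "saqueto", "rindle", "vostren", "halbrim", "jentova", "wexlor",
    "dumarin", "koventa", "lirquat", "tabrine", "ugoste", "yalvern",
)
#: padding tokens by length 2..10 (appending one adds len+1 cleaned chars)
_PAD_TOKENS = tuple("z" + "q" * (length - 1) for length in range(2, 11))

_LATE_STAGE_SHAPE = np.array([0.10, 0.14, 0.18, 0.26, 0.32]) * N_STAGES


class GeneratorError(ValueError):
    """Invalid generator configuration or filler/lexicon collision."""


def _uniform_stages(total_rate: float) -> np.ndarray:
    return np.full(N_STAGES, total_rate / N_STAGES)


def _late_stages(total_rate: float) -> np.ndarray:
    return _LATE_STAGE_SHAPE * (total_rate / N_STAGES)


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic corpus.

    ``stage_rates[cat]`` are per-stage Poisson means (shape 5); gender-
    specific intensity goes through ``rate_multipliers``.  ``true_or[cat]``
    maps gender to the per-mention odds ratio (1.0 = no effect); a missing
    "unknown" entry defaults to the geometric mean of the female and male
    values.  ``outcome_stage_weights`` defaults to all ones, in which case
    the label depends only on per-category totals.
    """

    n_sessions: int
    category_ids: tuple[str, ...]
    gender_probs: dict[str, float]
    age_probs: dict[str, float]
    stage_rates: dict[str, np.ndarray]
    true_or: dict[str, dict[str, float]] = field(default_factory=dict)
    rate_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    outcome_stage_weights: dict[str, np.ndarray] = field(default_factory=dict)
    target_prevalence: dict[tuple[str, str], float] | None = None
    beta0: dict[tuple[str, str], float] | None = None
    messages_per_stage: int = 2
    filler_vocab: tuple[str, ...] = DEFAULT_FILLER
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_sessions < 1:
            raise GeneratorError("n_sessions must be positive")
        for name, probs, keys in [("gender_probs", self.gender_probs, SIM_GENDERS),
                                  ("age_probs", self.age_probs, SIM_AGES)]:
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise GeneratorError(f"{name} must sum to 1")
            if not set(probs) <= set(keys):
                raise GeneratorError(f"{name} has unknown keys {set(probs) - set(keys)}")
            if any(p < 0 for p in probs.values()):
                raise GeneratorError(f"{name} must be non-negative")
        for cat in self.category_ids:
            rates = np.asarray(self.stage_rates.get(cat))
            if rates is None or rates.shape != (N_STAGES,) or np.any(rates < 0):
                raise GeneratorError(
                    f"stage_rates[{cat!r}] must be 5 non-negative Poisson means"
                )
        for cat, weights in self.outcome_stage_weights.items():
            w = np.asarray(weights)
            if w.shape != (N_STAGES,) or np.any(w < 0):
                raise GeneratorError(
                    f"outcome_stage_weights[{cat!r}] must be 5 non-negative values"
                )
        if self.target_prevalence is not None:
            for cell, t in self.target_prevalence.items():
                if not (0.0 < t < 1.0):
                    raise GeneratorError(f"target prevalence {t} for {cell} not in (0,1)")
        if self.messages_per_stage < 1:
            raise GeneratorError("messages_per_stage must be >= 1")
        if self.target_prevalence is None and self.beta0 is None:
            raise GeneratorError("either target_prevalence or beta0 is required")

    # -- canonical array views ------------------------------------------------

    @property
    def n_categories(self) -> int:
        return len(self.category_ids)

    def rates_for(self, gender: str) -> np.ndarray:
        """(categories x stages) Poisson means for one gender."""
        out = np.empty((self.n_categories, N_STAGES))
        for j, cat in enumerate(self.category_ids):
            mult = self.rate_multipliers.get(cat, {}).get(gender, 1.0)
            out[j] = np.asarray(self.stage_rates[cat]) * mult
        return out

    def beta_for(self, gender: str) -> np.ndarray:
        """Per-category true log odds ratios for one gender."""
        out = np.zeros(self.n_categories)
        for j, cat in enumerate(self.category_ids):
            ors = self.true_or.get(cat, {})
            if gender in ors:
                out[j] = np.log(ors[gender])
            elif gender == "unknown" and {"female", "male"} <= set(ors):
                out[j] = 0.5 * (np.log(ors["female"]) + np.log(ors["male"]))
        return out

    def weights(self) -> np.ndarray:
        """(categories x stages) outcome stage weights (default all ones)."""
        out = np.ones((self.n_categories, N_STAGES))
        for j, cat in enumerate(self.category_ids):
            if cat in self.outcome_stage_weights:
                out[j] = np.asarray(self.outcome_stage_weights[cat])
        return out

    def cells(self) -> list[tuple[str, str]]:
        return [(g, a) for g in self.gender_probs for a in self.age_probs]


# ---------------------------------------------------------------------------
# Intercept calibration
# ---------------------------------------------------------------------------

def _lp_grid(rates: np.ndarray, beta: np.ndarray, weights: np.ndarray,
             step: float = 2e-4) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of S = sum_js beta_j w_js X_js on a fine grid.

    Contributions with identical per-unit effect are merged by Poisson
    additivity before grid convolution; returns (support, probability).
    """
    contribs: dict[float, float] = {}
    for j in range(rates.shape[0]):
        for s in range(N_STAGES):
            b = beta[j] * weights[j, s]
            lam = rates[j, s]
            if b != 0.0 and lam > 0.0:
                contribs[round(b, 12)] = contribs.get(round(b, 12), 0.0) + lam
    if not contribs:
        return np.array([0.0]), np.array([1.0])

    atoms = []
    for b, lam in contribs.items():
        k_max = int(stats.poisson.ppf(1.0 - 1e-12, lam))
        pmf = stats.poisson.pmf(np.arange(k_max + 1), lam)
        atoms.append((b, pmf / pmf.sum()))

    lo = sum(min(0.0, b * (len(pmf) - 1)) for b, pmf in atoms)
    hi = sum(max(0.0, b * (len(pmf) - 1)) for b, pmf in atoms)
    n_pts = int(np.ceil((hi - lo) / step)) + 1
    origin = int(np.round(-lo / step))
    grid = np.zeros(n_pts)
    grid[origin] = 1.0
    for b, pmf in atoms:
        new = np.zeros_like(grid)
        for k, w in enumerate(pmf):
            if w == 0.0:
                continue
            shift = int(np.round(b * k / step))
            if shift >= 0:
                new[shift:] += w * grid[: n_pts - shift]
            else:
                new[: n_pts + shift] += w * grid[-shift:]
        grid = new
    support = (np.arange(n_pts) - origin) * step
    keep = grid > 0.0
    return support[keep], grid[keep]


def calibrate_intercept(target: float, rates: np.ndarray, beta: np.ndarray,
                        weights: np.ndarray | None = None,
                        tol: float = 1e-3) -> float:
    """Solve E[logistic(b0 + S)] = target for the intercept b0.

    With all-zero effects this is the closed form logit(target); otherwise a
    1-D root find over the exact Poisson-mixture expectation, accurate well
    inside ``tol`` on the prevalence scale.
    """
    if not (0.0 < target < 1.0):
        raise GeneratorError(f"target prevalence {target} not in (0, 1)")
    rates = np.asarray(rates, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if weights is None:
        weights = np.ones_like(rates)
    if np.all(beta == 0.0):
        return float(np.log(target / (1.0 - target)))
    support, prob = _lp_grid(rates, beta, weights)

    def gap(b0: float) -> float:
        z = b0 + support
        p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700))),
                     np.exp(np.clip(z, -700, 700)) / (1.0 + np.exp(np.clip(z, -700, 700))))
        return float(np.dot(prob, p)) - target

    lo, hi = -35.0, 15.0
    if gap(lo) > 0.0 or gap(hi) < 0.0:
        raise GeneratorError(f"target prevalence {target} unattainable")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def calibrate_intercepts(config: GeneratorConfig) -> dict[tuple[str, str], float]:
    """Per (gender x age) cell intercepts hitting the cell's target prevalence."""
    if config.target_prevalence is None:
        raise GeneratorError("config has no target_prevalence to calibrate")
    out: dict[tuple[str, str], float] = {}
    w = config.weights()
    for gender in config.gender_probs:
        rates = config.rates_for(gender)
        beta = config.beta_for(gender)
        support_cache = None
        for age in config.age_probs:
            cell = (gender, age)
            target = config.target_prevalence[cell]
            if np.all(beta == 0.0):
                out[cell] = float(np.log(target / (1.0 - target)))
                continue
            if support_cache is None:
                support_cache = _lp_grid(rates, beta, w)
            support, prob = support_cache

            def gap(b0: float) -> float:
                z = np.clip(b0 + support, -700, 700)
                return float(np.dot(prob, 1.0 / (1.0 + np.exp(-z)))) - target

            if gap(-35.0) > 0.0 or gap(15.0) < 0.0:
                raise GeneratorError(f"target {target} unattainable for {cell}")
            out[cell] = float(optimize.brentq(gap, -35.0, 15.0, xtol=1e-10))
    return out


# ---------------------------------------------------------------------------
# Count-layer generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst normally would not."""

    category_ids: tuple[str, ...]
    session_ids: list[str]
    gender: np.ndarray          # (n,) str
    age_group: np.ndarray       # (n,) str
    counts: np.ndarray          # (n, categories, stages) planted counts
    sr_label: np.ndarray        # (n,) 0/1
    linear_predictor: np.ndarray
    true_log_or: dict[str, np.ndarray]  # gender -> per-category log OR
    beta0: dict[tuple[str, str], float]

    def totals(self, stages: int = N_STAGES) -> np.ndarray:
        """Per-category counts cumulated over the first ``stages`` stages."""
        return self.counts[:, :, :stages].sum(axis=2)

    def realized_prevalence(self) -> pd.DataFrame:
        rows = []
        for dim, values in [("gender", self.gender), ("age", self.age_group)]:
            for val in np.unique(values):
                mask = values == val
                rows.append({
                    "block": dim, "subgroup": str(val), "n": int(mask.sum()),
                    "sr_cases": int(self.sr_label[mask].sum()),
                    "sr_prevalence_pct":
                        round(100.0 * float(self.sr_label[mask].mean()), 1),
                })
        return pd.DataFrame(rows)


def _resolved_beta0(config: GeneratorConfig) -> dict[tuple[str, str], float]:
    if config.beta0 is not None:
        return config.beta0
    config.beta0 = calibrate_intercepts(config)
    return config.beta0


def generate_counts(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw groups, planted stage counts, and SR labels (no text rendering)."""
    rng = rng or np.random.default_rng(config.seed)
    beta0 = _resolved_beta0(config)
    n, p = config.n_sessions, config.n_categories

    g_keys = list(config.gender_probs)
    a_keys = list(config.age_probs)
    gender = rng.choice(g_keys, size=n, p=[config.gender_probs[k] for k in g_keys])
    age = rng.choice(a_keys, size=n, p=[config.age_probs[k] for k in a_keys])

    counts = np.zeros((n, p, N_STAGES), dtype=np.int64)
    lp = np.zeros(n)
    w = config.weights()
    for g in g_keys:
        mask = gender == g
        m = int(mask.sum())
        if m == 0:
            continue
        lam = config.rates_for(g)
        counts[mask] = rng.poisson(lam[None, :, :], size=(m, p, N_STAGES))
        beta = config.beta_for(g)
        lp[mask] += np.einsum("ijs,j,js->i", counts[mask], beta, w)
    for (g, a), b0 in beta0.items():
        lp[(gender == g) & (age == a)] += b0

    prob = 1.0 / (1.0 + np.exp(-np.clip(lp, -700, 700)))
    labels = (rng.random(n) < prob).astype(np.int64)
    return GroundTruth(
        category_ids=tuple(config.category_ids),
        session_ids=[f"sim-{i:06d}" for i in range(n)],
        gender=gender, age_group=age, counts=counts, sr_label=labels,
        linear_predictor=lp,
        true_log_or={g: config.beta_for(g) for g in g_keys},
        beta0=dict(beta0),
    )


# ---------------------------------------------------------------------------
# Text rendering
# ---------------------------------------------------------------------------

def _phrase_token_set(lexicon: SRFLexicon) -> set[str]:
    tokens: set[str] = set()
    for cat in lexicon.categories:
        for phrase in cat.phrases:
            tokens.update(_TOKEN_RE.findall(_normalize(phrase.raw_phrase,
                                                       lexicon.settings)))
    return tokens


def _check_vocab(config: GeneratorConfig, lexicon: SRFLexicon) -> None:
    phrase_tokens = _phrase_token_set(lexicon)
    clash = (set(config.filler_vocab) | set(_PAD_TOKENS)) & phrase_tokens
    if clash:
        raise GeneratorError(
            f"filler vocabulary collides with lexicon tokens: {sorted(clash)}"
        )
    # exact-recovery guard: no phrase may be matchable inside another
    # category's phrase text (cross-category containment)
    for cat_a in lexicon.categories:
        for other in lexicon.categories:
            if other.id == cat_a.id:
                continue
            for pa in cat_a.phrases:
                norm = _normalize(pa.raw_phrase, lexicon.settings)
                for pb in other.phrases:
                    if pb.compiled.search(norm):
                        raise GeneratorError(
                            f"phrase {pb.raw_phrase!r} ({other.id}) matches "
                            f"inside {pa.raw_phrase!r} ({cat_a.id}); planted "
                            "counts would not be recoverable"
                        )


def _pad_lengths(deficit: int) -> list[int]:
    """Decompose a char deficit (>= 3 or 0) into pad-token increments 3..11."""
    out = []
    while deficit >= 14:
        out.append(11)
        deficit -= 11
    if deficit > 11:        # 12 or 13: split so the remainder stays >= 3
        out.append(deficit - 3)
        deficit = 3
    if deficit:
        out.append(deficit)  # 3..11
    return out


def _render_session(idx: int, planted: np.ndarray, gender: str, age: str,
                    label: int, lexicon: SRFLexicon,
                    config: GeneratorConfig,
                    rng: np.random.Generator) -> ChatSession:
    filler = config.filler_vocab
    m_per_stage = config.messages_per_stage

    def pick_filler() -> str:
        return filler[int(rng.integers(len(filler)))]

    stage_units: list[list[str]] = []
    for s in range(N_STAGES):
        units: list[str] = [pick_filler()]
        occurrences: list[str] = []
        for j, cat in enumerate(lexicon.categories):
            for _ in range(int(planted[j, s])):
                phrase = cat.phrases[int(rng.integers(len(cat.phrases)))]
                occurrences.append(clean_text(phrase.raw_phrase))
        rng.shuffle(occurrences)
        for occ in occurrences:
            units.extend([occ, pick_filler()])
        for _ in range(int(rng.integers(2, 6))):
            units.append(pick_filler())
        while len(units) < m_per_stage:
            units.append(pick_filler())
        stage_units.append(units)

    # equalize cleaned help-seeker char length across the five stages so the
    # fraction s/5 slice lands exactly at a stage boundary
    def stage_len(units: list[str]) -> int:
        return sum(len(u) for u in units) + len(units) - m_per_stage

    target = max(stage_len(u) for u in stage_units) + 12
    messages: list[Message] = []
    for units in stage_units:
        deficit = target - stage_len(units)
        for inc in _pad_lengths(deficit):
            units.append(_PAD_TOKENS[inc - 3])  # token of length inc - 1
        # contiguous near-equal chunks, each with at least one unit
        bounds = np.linspace(0, len(units), m_per_stage + 1).round().astype(int)
        for k in range(m_per_stage):
            chunk = units[bounds[k]: bounds[k + 1]]
            messages.append(Message(HELP_SEEKER, " ".join(chunk)))
            n_words = int(rng.integers(3, 7))
            messages.append(Message(
                COUNSELOR, " ".join(pick_filler() for _ in range(n_words))))

    return ChatSession(
        session_id=f"sim-{idx:06d}", messages=messages, gender=gender,
        age_group=age, sr_label=int(label),
    )


def generate_corpus(config: GeneratorConfig, lexicon: SRFLexicon,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[list[ChatSession], GroundTruth]:
    """Full corpus: counts, labels, and rendered chat text.

    Deterministic given ``config.seed`` (or an explicit ``rng``); the
    returned ground truth's planted counts are exactly what the matcher
    recovers from the rendered sessions.
    """
    if not lexicon.compiled:
        raise GeneratorError("lexicon must be compiled before generation")
    if tuple(lexicon.category_ids) != tuple(config.category_ids):
        raise GeneratorError(
            "config categories must match the lexicon's categories in order"
        )
    _check_vocab(config, lexicon)
    rng = rng or np.random.default_rng(config.seed)
    truth = generate_counts(config, rng)
    sessions = [
        _render_session(i, truth.counts[i], truth.gender[i],
                        truth.age_group[i], truth.sr_label[i],
                        lexicon, config, rng)
        for i in range(config.n_sessions)
    ]
    return sessions, truth


def write_ground_truth(truth: GroundTruth, sink: str | Path) -> None:
    """JSON sidecar with planted counts, labels, groups and true effects."""
    doc = {
        "category_ids": list(truth.category_ids),
        "true_log_or": {g: v.tolist() for g, v in truth.true_log_or.items()},
        "beta0": {f"{g}|{a}": b for (g, a), b in truth.beta0.items()},
        "sessions": [
            {
                "session_id": truth.session_ids[i],
                "gender": str(truth.gender[i]),
                "age_group": str(truth.age_group[i]),
                "sr_label": int(truth.sr_label[i]),
                "linear_predictor": float(truth.linear_predictor[i]),
                "stage_counts": truth.counts[i].tolist(),
            }
            for i in range(len(truth.session_ids))
        ],
    }
    Path(sink).write_text(json.dumps(doc), encoding="utf-8")


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _cell_targets() -> dict[tuple[str, str], float]:
    """Logit-additive joint targets from the published gender/age margins."""
    p_all = OVERALL_MARGIN[1] / OVERALL_MARGIN[0]
    out = {}
    for g, (ng, sg) in GENDER_MARGINS.items():
        for a, (na, sa) in AGE_MARGINS.items():
            z = _logit(sg / ng) + _logit(sa / na) - _logit(p_all)
            out[(g, a)] = 1.0 / (1.0 + np.exp(-z))
    return out


#: per-mention odds ratios by gender for the constructs with planted effects;
#: every other category is null (OR 1.0)
DEFAULT_TRUE_OR = {
    "previous_attempt": {"female": 1.29, "male": 1.26},
    "hopelessness": {"female": 1.24, "male": 1.29},
    "self_harm": {"female": 1.17, "male": 1.16},
    "loneliness": {"female": 1.07, "male": 1.00},
    "thwarted_belongingness": {"female": 1.06, "male": 1.12},
    "depression": {"female": 1.00, "male": 1.03},
    "bullying": {"female": 0.91, "male": 1.00},
}

#: expected mentions per chat (summed over the five stages)
DEFAULT_TOTAL_RATES = {
    "previous_attempt": 1.0,
    "hopelessness": 0.8,
    "self_harm": 2.5,
    "loneliness": 1.5,
    "thwarted_belongingness": 1.2,
    "depression": 4.0,
    "bullying": 1.5,
}
_DEFAULT_OTHER_RATE = 0.5
#: constructs whose phrase intensity concentrates late in the chat
DEFAULT_LATE_CATEGORIES = ("depression", "thwarted_belongingness")


def default_config(lexicon: SRFLexicon | None = None, n_sessions: int = 17564,
                   seed: int = 0) -> GeneratorConfig:
    """Study-condition defaults: published sample margins and effect sizes."""
    from .lexicon import packaged_lexicon

    lexicon = lexicon or packaged_lexicon(compiled=False)
    cats = tuple(lexicon.category_ids)
    n_all = OVERALL_MARGIN[0]
    stage_rates = {}
    for cat in cats:
        total = DEFAULT_TOTAL_RATES.get(cat, _DEFAULT_OTHER_RATE)
        stage_rates[cat] = (_late_stages(total)
                            if cat in DEFAULT_LATE_CATEGORIES
                            else _uniform_stages(total))
    return GeneratorConfig(
        n_sessions=n_sessions,
        category_ids=cats,
        gender_probs={g: n / n_all for g, (n, _) in GENDER_MARGINS.items()},
        age_probs={a: n / n_all for a, (n, _) in AGE_MARGINS.items()},
        stage_rates=stage_rates,
        true_or={k: dict(v) for k, v in DEFAULT_TRUE_OR.items()},
        target_prevalence=_cell_targets(),
        seed=seed,
    )


def _single_category_config(cat: str, n_sessions: int, seed: int,
                            stage_rates: np.ndarray, or_value: float,
                            weights: np.ndarray | None) -> GeneratorConfig:
    cfg = GeneratorConfig(
        n_sessions=n_sessions,
        category_ids=(cat,),
        gender_probs={"female": 0.5, "male": 0.5, "unknown": 0.0},
        age_probs={"10-17": 0.25, "18-20": 0.25, "21-40": 0.25, "41+": 0.25},
        stage_rates={cat: stage_rates},
        true_or={cat: {"female": or_value, "male": or_value}},
        outcome_stage_weights=({cat: weights} if weights is not None else {}),
        target_prevalence={(g, a): 0.30
                           for g in ("female", "male", "unknown")
                           for a in ("10-17", "18-20", "21-40", "41+")},
        seed=seed,
    )
    return cfg


def trajectory_config(n_sessions: int = 17564, seed: int = 0) -> GeneratorConfig:
    """An escalating construct: late-weighted intensity and rising per-stage
    outcome weights, the purpose-built corpus for the temporal signature."""
    return _single_category_config(
        "escalating", n_sessions, seed,
        stage_rates=np.array([0.8, 1.0, 1.2, 1.4, 1.6]),
        or_value=1.6,
        weights=np.array([0.50, 0.75, 1.00, 1.25, 1.50]),
    )


def trajectory_null_config(n_sessions: int = 17564,
                           seed: int = 0) -> GeneratorConfig:
    """A steady construct: uniform intensity, uniform outcome weights.

    The planted effect is modest (OR 1.2, 1.5 expected mentions per chat) so
    that the small marginalization-induced attenuation of early-prefix
    estimates is negligible against sampling noise and the trajectory is
    genuinely flat.
    """
    return _single_category_config(
        "steady", n_sessions, seed,
        stage_rates=_uniform_stages(1.5),
        or_value=1.20,
        weights=None,
    )


# ---------------------------------------------------------------------------
# Replicate studies (count layer)
# ---------------------------------------------------------------------------

def _fit_totals(truth: GroundTruth, mask: np.ndarray, stratum: str,
                stages: int = N_STAGES):
    design = DesignMatrix.from_arrays(
        truth.totals(stages)[mask], truth.sr_label[mask],
        list(truth.category_ids), stratum=stratum, fraction=stages / N_STAGES,
    )
    return fit_logistic(design), design


def recovery_study(config: GeneratorConfig, n_reps: int = 100,
                   seed: int = 0) -> pd.DataFrame:
    """Gender-stratified parameter recovery over independent replicates.

    For every category with a planted nonzero effect, reports the mean
    fitted log OR, its Monte-Carlo standard error, the recovery z-score
    (mean bias over MC SE), and 95% Wald CI coverage of the truth.
    Operates on the generator's count layer; the text layer reproduces the
    counts exactly, so the two routes estimate the same model.
    """
    children = np.random.SeedSequence(seed).spawn(n_reps)
    estimates: dict[tuple[str, str], list[float]] = {}
    covered: dict[tuple[str, str], list[bool]] = {}
    cats = list(config.category_ids)
    for child in children:
        truth = generate_counts(config, np.random.default_rng(child))
        for gender, stratum in [("female", "Women"), ("male", "Men")]:
            fit, _ = _fit_totals(truth, truth.gender == gender, stratum)
            se = fit.se
            for j, cat in enumerate(cats):
                true_b = truth.true_log_or[gender][j]
                if true_b == 0.0:
                    continue
                key = (stratum, cat)
                b = fit.coef[j]
                estimates.setdefault(key, []).append(b)
                covered.setdefault(key, []).append(
                    abs(b - true_b) <= 1.959963984540054 * se[j])
    rows = []
    for (stratum, cat), vals in estimates.items():
        arr = np.asarray(vals)
        gender = "female" if stratum == "Women" else "male"
        true_or = np.exp(config.beta_for(gender)[cats.index(cat)])
        mc_se = float(arr.std(ddof=1) / np.sqrt(len(arr)))
        bias = float(arr.mean() - np.log(true_or))
        rows.append({
            "stratum": stratum, "category_id": cat,
            "true_or": float(true_or), "mean_or": float(np.exp(arr.mean())),
            "mc_se_log": mc_se, "recovery_z": bias / mc_se,
            "coverage": float(np.mean(covered[(stratum, cat)])),
            "n_reps": len(arr),
        })
    return pd.DataFrame(rows)


def trajectory_study(config: GeneratorConfig, n_reps: int = 100,
                     seed: int = 0) -> pd.DataFrame:
    """Per-replicate odds-ratio path of the config's single category across
    the five cumulative fractions; reports monotonicity and the LS slope."""
    if config.n_categories != 1:
        raise GeneratorError("trajectory_study expects a single-category config")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    fracs = np.arange(1, N_STAGES + 1) / N_STAGES
    rows = []
    for rep, child in enumerate(children):
        truth = generate_counts(config, np.random.default_rng(child))
        betas = []
        for stages in range(1, N_STAGES + 1):
            fit, _ = _fit_totals(truth, np.ones(config.n_sessions, bool),
                                 "All", stages)
            betas.append(float(fit.coef[0]))
        betas = np.asarray(betas)
        slope = float(np.polyfit(fracs, betas, 1)[0])
        rows.append({
            "replicate": rep,
            **{f"log_or_{f:.1f}": b for f, b in zip(fracs, betas)},
            "monotone_nondecreasing": bool(np.all(np.diff(betas) >= 0.0)),
            "slope": slope,
        })
    return pd.DataFrame(rows)


def stratification_study(config: GeneratorConfig, category: str,
                         n_reps: int = 50, seed: int = 0,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Share of replicates in which a category is Wald-significant, per gender."""
    children = np.random.SeedSequence(seed).spawn(n_reps)
    j = list(config.category_ids).index(category)
    hits = {"Women": 0, "Men": 0}
    for child in children:
        truth = generate_counts(config, np.random.default_rng(child))
        for gender, stratum in [("female", "Women"), ("male", "Men")]:
            fit, _ = _fit_totals(truth, truth.gender == gender, stratum)
            z = fit.coef[j] / fit.se[j]
            p = 2.0 * stats.norm.sf(abs(z))
            hits[stratum] += int(p < alpha)
    return pd.DataFrame([
        {"stratum": s, "category_id": category,
         "significant_share": hits[s] / n_reps, "n_reps": n_reps}
        for s in ("Women", "Men")
    ])
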