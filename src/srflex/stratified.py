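"""Stratified model fits and temporal odds-ratio trajectories.

Stratification mirrors the reporting design of subgroup helpline analyses:
one model for the full sample ("All"), gender-stratified models ("Women",
"Men"), and age-stratified models over the four developmental bins.
Unknown-demographic sessions stay in "All" and drop out of the stratified
fits.  Temporal trajectories refit the full multivariable model on prefix
slices at the five chat fractions (repeated cross-sections, not a
longitudinal model), so the 100% trajectory point coincides exactly with the
static stratified fit.

No formal cross-stratum coefficient tests are part of the main outputs; a
Wald contrast utility is provided separately as an extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import FRACTIONS, ChatSession
from .features import FeatureOptions, build_design, counts_matrix
from .lexicon import SRFLexicon
from .risk_model import LogisticFit, PredictorEffect, effects_table, fit_logistic

__all__ = [
    "GENDER_STRATA",
    "AGE_STRATA",
    "StratumFit",
    "StratifiedResult",
    "Trajectory",
    "fit_by_stratum",
    "temporal_trajectories",
    "sample_accounting",
    "effects_frame",
    "trajectories_frame",
    "export_effects",
    "export_trajectories",
    "wald_contrast",
]

GENDER_STRATA: list[tuple[str, tuple[str, str] | None]] = [
    ("All", None),
    ("Women", ("gender", "female")),
    ("Men", ("gender", "male")),
]
AGE_STRATA: list[tuple[str, tuple[str, str] | None]] = [
    (a, ("age_group", a)) for a in ("10-17", "18-20", "21-40", "41+")
]


def _strata_for(stratification: str) -> list[tuple[str, tuple[str, str] | None]]:
    if stratification == "gender":
        return GENDER_STRATA
    if stratification == "age":
        return AGE_STRATA
    if stratification == "none":
        return [("All", None)]
    raise ValueError(f"unknown stratification {stratification!r}")


@dataclass
class StratumFit:
    name: str
    fit: LogisticFit
    effects: list[PredictorEffect]
    n: int
    n_sr: int

    @property
    def prevalence(self) -> float:
        return self.n_sr / self.n


@dataclass
class StratifiedResult:
    stratification: str
    strata: dict[str, StratumFit]

    def accounting(self) -> pd.DataFrame:
        rows = [
            {"stratum": s.name, "n": s.n, "sr_cases": s.n_sr,
             "sr_prevalence_pct": round(100.0 * s.prevalence, 1)}
            for s in self.strata.values()
        ]
        return pd.DataFrame(rows)


@dataclass
class Trajectory:
    stratum: str
    category_id: str
    points: list[PredictorEffect]  # ascending fraction, one per stage

    def __post_init__(self) -> None:
        fracs = [p.fraction for p in self.points]
        if fracs != sorted(fracs) or len(fracs) != len(set(fracs)):
            raise ValueError("trajectory points must have ascending fractions")


def _fit_one(sessions: Sequence[ChatSession], lexicon: SRFLexicon, name: str,
             flt: tuple[str, str] | None, fraction: float,
             options: FeatureOptions | None, alpha: float,
             bh_correction: bool, counts=None) -> StratumFit:
    try:
        design = build_design(sessions, lexicon, fraction, flt,
                              options, stratum_name=name,
                              precomputed_counts=counts)
        fit = fit_logistic(design)
        effects = effects_table(fit, alpha=alpha, bh_correction=bh_correction,
                                stratum=name, fraction=fraction)
    except Exception as exc:
        raise type(exc)(
            f"stratum {name!r} at fraction {fraction:g}: {exc}"
        ) from exc
    return StratumFit(name=name, fit=fit, effects=effects, n=design.n_obs,
                      n_sr=int(design.y.sum()))


def fit_by_stratum(sessions: Sequence[ChatSession], lexicon: SRFLexicon,
                   stratification: str = "gender", fraction: float = 1.0,
                   options: FeatureOptions | None = None, alpha: float = 0.05,
                   bh_correction: bool = False) -> StratifiedResult:
    """One full-lexicon logistic fit per stratum at a single chat fraction.

    The corpus is matched once per fraction; every stratum reuses the shared
    count matrix.
    """
    counts = counts_matrix(sessions, lexicon, fraction, options)
    strata = {}
    for name, flt in _strata_for(stratification):
        strata[name] = _fit_one(sessions, lexicon, name, flt, fraction,
                                options, alpha, bh_correction, counts)
    return StratifiedResult(stratification=stratification, strata=strata)


def temporal_trajectories(sessions: Sequence[ChatSession], lexicon: SRFLexicon,
                          stratification: str = "gender",
                          fractions: Sequence[float] = FRACTIONS,
                          options: FeatureOptions | None = None,
                          alpha: float = 0.05,
                          bh_correction: bool = False) -> list[Trajectory]:
    """Refit the full model on each prefix fraction; collect per-category paths."""
    fractions = sorted(fractions)
    per_stage: dict[float, StratifiedResult] = {
        f: fit_by_stratum(sessions, lexicon, stratification, f, options,
                          alpha, bh_correction)
        for f in fractions
    }
    trajectories = []
    for name, _ in _strata_for(stratification):
        by_cat: dict[str, list[PredictorEffect]] = {}
        for f in fractions:
            for eff in per_stage[f].strata[name].effects:
                by_cat.setdefault(eff.category_id, []).append(eff)
        for cat, points in by_cat.items():
            trajectories.append(Trajectory(stratum=name, category_id=cat,
                                           points=points))
    return trajectories


def sample_accounting(sessions: Sequence[ChatSession]) -> pd.DataFrame:
    """Sample size and SR prevalence by subgroup, unknowns included."""
    rows = []

    def add(block: str, name: str, subset: list[ChatSession]) -> None:
        if not subset:
            return
        n = len(subset)
        n_sr = sum(s.sr_label for s in subset)
        rows.append({"block": block, "subgroup": name, "n": n, "sr_cases": n_sr,
                     "sr_prevalence_pct": round(100.0 * n_sr / n, 1)})

    add("all", "All chats", list(sessions))
    for g, name in [("female", "Female"), ("male", "Male"),
                    ("unknown", "Unknown")]:
        add("gender", name, [s for s in sessions if s.gender == g])
    for a in ("10-17", "18-20", "21-40", "41+", "unknown"):
        add("age", a if a != "unknown" else "Unknown",
            [s for s in sessions if s.age_group == a])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular export (forest-plot-ready)
# ---------------------------------------------------------------------------

def effects_frame(result: StratifiedResult) -> pd.DataFrame:
    rows = [
        {"stratum": s.name, "fraction": e.fraction, "category_id": e.category_id,
         "OR": e.odds_ratio, "ci_low": e.ci_low, "ci_high": e.ci_high,
         "p": e.p_value, "significant": int(e.significant)}
        for s in result.strata.values()
        for e in s.effects
    ]
    return pd.DataFrame(rows)


def trajectories_frame(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    rows = [
        {"stratum": t.stratum, "category_id": t.category_id,
         "fraction": p.fraction, "OR": p.odds_ratio, "ci_low": p.ci_low,
         "ci_high": p.ci_high, "p": p.p_value, "significant": int(p.significant)}
        for t in trajectories
        for p in t.points
    ]
    return pd.DataFrame(rows)


def _write_tsv(frame: pd.DataFrame, sink: Union[str, Path, TextIO],
               provenance: str | None) -> None:
    text = frame.to_csv(sep="\t", index=False)
    if provenance:
        text = f"# {provenance}\n" + text
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text, encoding="utf-8")


def export_effects(result: StratifiedResult, sink,
                   provenance: str | None = None) -> None:
    _write_tsv(effects_frame(result), sink, provenance)


def export_trajectories(trajectories: Iterable[Trajectory], sink,
                        provenance: str | None = None) -> None:
    _write_tsv(trajectories_frame(trajectories), sink, provenance)


def wald_contrast(fit_a: LogisticFit, fit_b: LogisticFit,
                  category_id: str) -> tuple[float, float]:
    """EXTENSION: Wald z-test for a coefficient difference across two strata.

    Not part of the main reporting surface (within-group associations are
    reported without cross-group tests); provided for exploratory use only.
    Returns ``(z, two_sided_p)``.
    """
    ja = fit_a.column_names.index(category_id)
    jb = fit_b.column_names.index(category_id)
    diff = fit_a.coef[ja] - fit_b.coef[jb]
    se = float(np.sqrt(fit_a.se[ja] ** 2 + fit_b.se[jb] ** 2))
    z = float(diff / se)
    return z, float(2.0 * stats.norm.sf(abs(z)))
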