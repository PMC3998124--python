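"""Per-COG score-distribution statistics and prototypical-regulon calls.

For each COG the cumulative distribution of promoter-site scores is
computed in 1-bit intervals over the 12–20 bit range: ``C(t)`` is the
number of sites scoring strictly above ``t``.  Binding sites of genuinely
regulated genes have scores that are approximately normal around the
motif's information content (~16 bits), which makes the central range of
the cumulative distribution nearly linear.  A COG is called a
*prototypical* regulon member when an ordinary least-squares fit of
``C(t)`` against ``t`` gives R² > 0.85, at least one site scores above
16 bits, and at least 10 sites fall in the 12–20 bit range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genes import SiteGeneLink


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the prototypical-regulon rule.

    ``cum_strict`` controls the cumulative-count comparison (strictly
    above each threshold by default); ``range_inclusive`` controls the
    in-range site count (closed interval [12, 20] by default).
    """

    r2_min: float = 0.85
    high_score_min: float = 16.0
    n_min: int = 10
    bin_lo: int = 12
    bin_hi: int = 20
    bin_step: int = 1
    cum_strict: bool = True
    range_inclusive: bool = True

    @property
    def bins(self) -> np.ndarray:
        return np.arange(self.bin_lo, self.bin_hi + 1, self.bin_step)


@dataclass(frozen=True)
class CogScoreProfile:
    cog_id: str
    scores: tuple[float, ...]
    bins: tuple[int, ...]
    cum_counts: tuple[int, ...]
    slope: float
    intercept: float
    r2: float
    n_in_range: int
    max_score: float
    prototypical: bool


def cumulative_counts(
    scores: Sequence[float], cfg: ClassifierConfig = ClassifierConfig()
) -> np.ndarray:
    """C(t) = number of scores above t, for t = 12, 13, …, 20 bits."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        return np.zeros(len(cfg.bins), dtype=int)
    if cfg.cum_strict:
        return np.array([(s > t).sum() for t in cfg.bins], dtype=int)
    return np.array([(s >= t).sum() for t in cfg.bins], dtype=int)


def fit_cumulative(
    counts: Sequence[int], cfg: ClassifierConfig = ClassifierConfig()
) -> tuple[float, float, float]:
    """OLS fit of C(t) on t; returns (slope, intercept, r2).

    Zero-variance counts (all bins equal) get r2 := 0 by convention,
    never NaN.
    """
    y = np.asarray(counts, dtype=float)
    t = cfg.bins.astype(float)
    if len(y) != len(t):
        raise ValueError(f"expected {len(t)} bin counts, got {len(y)}")
    if len(y) < 2:
        raise ValueError("need at least 2 bins to fit")
    if np.ptp(y) == 0.0:
        return 0.0, float(y[0]), 0.0
    res = sps.linregress(t, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def n_in_range(
    scores: Sequence[float], cfg: ClassifierConfig = ClassifierConfig()
) -> int:
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        return 0
    if cfg.range_inclusive:
        return int(((s >= cfg.bin_lo) & (s <= cfg.bin_hi)).sum())
    return int(((s > cfg.bin_lo) & (s < cfg.bin_hi)).sum())


def make_profile(
    cog_id: str,
    scores: Sequence[float],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> CogScoreProfile:
    counts = cumulative_counts(scores, cfg)
    slope, intercept, r2 = fit_cumulative(counts, cfg)
    nir = n_in_range(scores, cfg)
    mx = float(max(scores)) if len(scores) else float("-inf")
    profile = CogScoreProfile(
        cog_id=cog_id,
        scores=tuple(float(s) for s in scores),
        bins=tuple(int(t) for t in cfg.bins),
        cum_counts=tuple(int(c) for c in counts),
        slope=slope,
        intercept=intercept,
        r2=r2,
        n_in_range=nir,
        max_score=mx,
        prototypical=False,
    )
    return replace(profile, prototypical=classify_prototypical(profile, cfg))


def classify_prototypical(
    profile: CogScoreProfile, cfg: ClassifierConfig = ClassifierConfig()
) -> bool:
    """True iff R² > r2_min AND max score > high_score_min AND the
    in-range site count reaches n_min (all three must hold)."""
    return (
        profile.r2 > cfg.r2_min
        and profile.max_score > cfg.high_score_min
        and profile.n_in_range >= cfg.n_min
    )


def profile_cogs(
    links: Sequence[SiteGeneLink],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> dict[str, CogScoreProfile]:
    """One profile per COG from decorated links; empty cog_ids excluded."""
    scores: dict[str, list[float]] = {}
    for ln in links:
        if ln.cog_id:
            scores.setdefault(ln.cog_id, []).append(ln.site.score)
    return {
        cog: make_profile(cog, sc, cfg) for cog, sc in sorted(scores.items())
    }


def profiles_to_frame(profiles: Mapping[str, CogScoreProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                p.cog_id,
                len(p.scores),
                p.n_in_range,
                p.max_score,
                p.slope,
                p.r2,
                p.prototypical,
            )
            for p in profiles.values()
        ],
        columns=[
            "cog_id", "n_sites", "n_in_range", "max_score",
            "slope", "r2", "prototypical",
        ],
    )


def category_distribution(
    links: Sequence[SiteGeneLink],
    thresholds: Sequence[float],
    reference: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-category proportion of links surviving each score threshold.

    Rows are one-letter COG categories, one column per threshold
    (fractions over categorised links, summing to 1 within a column).
    When a reference category distribution is given it is joined as a
    ``reference`` column for side-by-side comparison; no enrichment test
    is computed.
    """
    cat = [ln.cog_category for ln in links]
    score = [ln.site.score for ln in links]
    df = pd.DataFrame({"category": cat, "score": score})
    df = df[df["category"] != ""]
    if df.empty:
        out = pd.DataFrame(index=pd.Index([], name="category"))
    else:
        cols = {}
        for thr in thresholds:
            surv = df[df["score"] > thr]
            cols[thr] = (
                surv["category"].value_counts(normalize=True)
                if len(surv)
                else pd.Series(dtype=float)
            )
        out = pd.DataFrame(cols).fillna(0.0).sort_index()
        out.index.name = "category"
    if reference is not None:
        ref = reference / reference.sum()
        out = out.join(ref.rename("reference"), how="outer").fillna(0.0)
        out.index.name = "category"
    return out


def normalized_cog_counts(
    links: Sequence[SiteGeneLink], reference_cog: str = "COG1974"
) -> pd.Series:
    """Promoter-site count per COG divided by the reference COG's count.

    The default reference, COG1974, is the LexA/UmuD cluster — the
    repressor whose own operator gives the natural unit.
    """
    counts: dict[str, int] = {}
    for ln in links:
        if ln.cog_id:
            counts[ln.cog_id] = counts.get(ln.cog_id, 0) + 1
    ref = counts.get(reference_cog, 0)
    if ref == 0:
        raise ValueError(
            f"reference COG {reference_cog!r} absent or has zero sites"
        )
    return pd.Series(
        {cog: n / ref for cog, n in sorted(counts.items())}, name="ratio"
    )


def r2_cutoff_diagnostic(
    profiles: Mapping[str, CogScoreProfile],
    known_cogs: set[str] | frozenset[str],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """How the prototypical call set grows as the R² cutoff is relaxed.

    COGs passing the high-score and site-count clauses are ranked by R²;
    at each successive cutoff the table reports how many called COGs
    belong to the known reference regulon and how many do not.  This is
    the diagnostic used to justify a conservative cutoff: relax R² until
    novel calls start outnumbering known ones.
    """
    eligible = [
        p
        for p in profiles.values()
        if p.max_score > cfg.high_score_min and p.n_in_range >= cfg.n_min
    ]
    eligible.sort(key=lambda p: -p.r2)
    rows = []
    n_known = n_novel = 0
    for p in eligible:
        if p.cog_id in known_cogs:
            n_known += 1
        else:
            n_novel += 1
        rows.append((p.cog_id, p.r2, p.cog_id in known_cogs, n_known, n_novel))
    return pd.DataFrame(
        rows, columns=["cog_id", "r2", "known", "n_known_at_cutoff",
                       "n_novel_at_cutoff"]
    )


def plot_cog_profile(profile: CogScoreProfile, ax=None):
    """Cumulative counts and the fitted line for one COG (needs matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.array(profile.bins, dtype=float)
    ax.plot(t, profile.cum_counts, "o", label="C(t)")
    ax.plot(t, profile.slope * t + profile.intercept, "-",
            label=f"OLS fit (R²={profile.r2:.3f})")
    ax.set_xlabel("score threshold t (bits)")
    ax.set_ylabel("sites with score > t")
    ax.set_title(profile.cog_id)
    ax.legend()
    return ax
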