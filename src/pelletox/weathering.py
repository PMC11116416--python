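"""Visual weathering scores for plastic pellets and sample summaries.

Each pellet is inspected for two photo-oxidative stress indicators,
surface yellowing and cracking, and scored 1 (neither), 2 (exactly one)
or 3 (both).  A sample summary carries the score counts, exact
percentages, the mean score, and two derived metrics used downstream:

* ``pct_ge2`` — percentage of pellets scoring 2 or 3 ("weathered"),
* ``weathering_pct`` — 100 * mean_score / 2, a percentage scale where a
  uniform score of 2 maps to 100% (values above 100 are possible when
  score-3 pellets dominate).

Between-sample change is summarized as a ratio of weathered fractions
(test/reference * 100); the percent-change convention is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PelletObservation",
    "SampleWeatheringSummary",
    "score_pellet",
    "summarize_sample",
    "summarize_table",
    "weathering_increase",
    "read_observations",
]


@dataclass(frozen=True)
class PelletObservation:
    sample_id: str
    pellet_id: str
    yellowing: bool
    cracking: bool


@dataclass(frozen=True)
class SampleWeatheringSummary:
    sample_id: str
    n: int
    counts: tuple[int, int, int]  # scores 1, 2, 3
    pct: tuple[float, float, float]
    mean_score: float
    pct_ge2: float
    weathering_pct: float


def score_pellet(o: PelletObservation) -> int:
    """Weathering score: 1 + yellowing + cracking, i.e. 1, 2 or 3."""
    return 1 + int(bool(o.yellowing)) + int(bool(o.cracking))


def summarize_sample(obs: Sequence[PelletObservation]) -> SampleWeatheringSummary:
    """Aggregate one sample's observations into counts and percentages.

    All percentages are kept at full precision; rounding to integer
    percent is a display concern only.
    """
    if len(obs) == 0:
        raise ValueError("summarize_sample requires at least one observation")
    ids = {o.sample_id for o in obs}
    if len(ids) != 1:
        raise ValueError(f"mixed sample_ids in one summary: {sorted(ids)}")
    scores = [score_pellet(o) for o in obs]
    n = len(scores)
    counts = tuple(scores.count(s) for s in (1, 2, 3))
    pct = tuple(100.0 * c / n for c in counts)
    mean_score = sum(scores) / n
    pct_ge2 = pct[1] + pct[2]
    return SampleWeatheringSummary(
        sample_id=obs[0].sample_id,
        n=n,
        counts=counts,
        pct=pct,
        mean_score=mean_score,
        pct_ge2=pct_ge2,
        weathering_pct=100.0 * mean_score / 2.0,
    )


def weathering_increase(
    reference: SampleWeatheringSummary,
    test: SampleWeatheringSummary,
    convention: str = "ratio",
) -> float:
    """Change in the weathered (score >= 2) fraction between samples.

    ``convention="ratio"`` (default) returns 100 * test/reference — the
    reading under which a sixfold-plus increase reports as 640%;
    ``"percent_change"`` returns 100 * (test - reference)/reference.
    """
    if reference.pct_ge2 <= 0:
        raise ZeroDivisionError(
            "weathering increase undefined: reference has no pellets scoring >= 2"
        )
    ratio = 100.0 * test.pct_ge2 / reference.pct_ge2
    if convention == "ratio":
        return ratio
    if convention == "percent_change":
        return ratio - 100.0
    raise ValueError(f"unknown convention {convention!r}")


def read_observations(path) -> list[PelletObservation]:
    """Read a score CSV with columns sample_id, pellet_id, yellowing, cracking.

    Flag columns must be 0/1 (or true/false); missing values are an error.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "pellet_id", "yellowing", "cracking"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    if df[["yellowing", "cracking"]].isna().any().any():
        raise ValueError("yellowing/cracking flags must not be missing")
    return [
        PelletObservation(
            sample_id=str(r.sample_id),
            pellet_id=str(r.pellet_id),
            yellowing=bool(int(r.yellowing)),
            cracking=bool(int(r.cracking)),
        )
        for r in df.itertuples(index=False)
    ]


def summarize_table(obs: Iterable[PelletObservation]) -> pd.DataFrame:
    """Per-sample summary table over a mixed list of observations.

    One row per sample_id with exact and display-rounded percentages.
    """
    by_sample: dict[str, list[PelletObservation]] = {}
    for o in obs:
        by_sample.setdefault(o.sample_id, []).append(o)
    rows = []
    for sample_id in sorted(by_sample):
        s = summarize_sample(by_sample[sample_id])
        rows.append(
            dict(
                sample_id=s.sample_id,
                n=s.n,
                n1=s.counts[0],
                n2=s.counts[1],
                n3=s.counts[2],
                p1=s.pct[0],
                p2=s.pct[1],
                p3=s.pct[2],
                p1_rounded=round(s.pct[0]),
                p2_rounded=round(s.pct[1]),
                p3_rounded=round(s.pct[2]),
                mean_score=s.mean_score,
                pct_ge2=s.pct_ge2,
                weathering_pct=s.weathering_pct,
            )
        )
    return pd.DataFrame(rows)
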