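"""Silhouette-based cohort cleaning and pairwise experiment construction.

The achievement labels (HA/AA/LA) are treated as fixed clusters; each
participant gets a silhouette score s = (b - a) / max(a, b) with a the
mean Euclidean distance to their own class and b the smallest mean
distance to a foreign class, computed per feature-table variant.

A participant is flagged in a variant when two conditions hold: their
own score is <= 0, and more than 70% of that variant's participants
score > 0 (i.e. the variant itself is cohesive enough for a non-positive
score to be informative). A participant flagged in at least
``min_variants`` variants is removed cohort-wide.

The cleaned tables yield six pairwise class comparisons (HA-AA, HA-LA,
HA-OA, AA-LA, AA-OA, LA-OA; OA = a balanced pool of the two other
classes) for each of the 15 (band, metric) variants: 90 experiment
datasets named ``Co<pair>_B<band>_G<metric>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .graph_features import CLASS_COLUMN, CLASS_LABELS, FeatureTable

PAIRS = ("HA-AA", "HA-LA", "HA-OA", "AA-LA", "AA-OA", "LA-OA")

POSITIVE_FRACTION = 0.70  # cohesion condition on a variant

_NAME_RE = re.compile(
    r"^Co(?P<pair>(?:HA|AA|LA)-(?:HA|AA|LA|OA))"
    r"_B(?P<band>delta|theta|alpha|beta|broadband)"
    r"_G(?P<metric>dv|Ev|Cv)$"
)


@dataclass
class SilhouetteReport:
    """Per-participant silhouette scores for one feature-table variant."""

    variant: str
    scores: pd.Series           # index = participant ids
    cluster_sizes: dict[str, int]

    @property
    def positive_fraction(self) -> float:
        return float((self.scores > 0).mean())


@dataclass
class OutlierDecision:
    participant: str
    flagged_in: set[str] = field(default_factory=set)

    @property
    def is_outlier(self) -> bool:
        return bool(self.flagged_in)


@dataclass
class ExperimentDataset:
    """One pairwise classification dataset (Co_k, B_i, G_j)."""

    name: str
    data: pd.DataFrame   # 19 electrode columns + class column (two values)
    pair: str
    band: str
    metric: str

    def __post_init__(self) -> None:
        classes = set(self.data[CLASS_COLUMN].unique())
        if len(classes) != 2:
            raise ValueError(f"{self.name}: expected exactly 2 class values, got {classes}")


def experiment_name(pair: str, band: str, metric: str) -> str:
    name = f"Co{pair}_B{band}_G{metric}"
    if not _NAME_RE.match(name):
        raise ValueError(f"invalid experiment triple ({pair}, {band}, {metric})")
    return name


def parse_experiment_name(name: str) -> tuple[str, str, str]:
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a valid experiment dataset name: {name!r}")
    return m.group("pair"), m.group("band"), m.group("metric")


def silhouette_scores(table: FeatureTable) -> SilhouetteReport:
    """Silhouette score of every participant against the class labels.

    Members of singleton clusters have an undefined within-class distance
    and get score 0 by convention.
    """
    X = table.features.to_numpy()
    y = table.classes.to_numpy()
    counts = pd.Series(y).value_counts().to_dict()
    if len(counts) < 2:
        raise ValueError("silhouette needs at least two classes")
    scores = silhouette_samples(X, y, metric="euclidean")
    return SilhouetteReport(
        variant=table.tag,
        scores=pd.Series(scores, index=table.data.index),
        cluster_sizes={k: int(v) for k, v in counts.items()},
    )


def detect_outliers(
    reports: list[SilhouetteReport],
    positive_fraction: float = POSITIVE_FRACTION,
    min_variants: int = 1,
) -> dict[str, OutlierDecision]:
    """Apply the two-condition rule across all table variants.

    Within a variant, non-positive scores are flagged only when the
    variant's fraction of positive scores exceeds ``positive_fraction``.
    A participant is an outlier when flagged in >= ``min_variants``
    variants. Returns one decision per participant.
    """
    if not reports:
        raise ValueError("no silhouette reports given")
    cohorts = {tuple(r.scores.index) for r in reports}
    if len(cohorts) != 1:
        raise ValueError("silhouette reports cover inconsistent cohorts")

    decisions = {p: OutlierDecision(p) for p in reports[0].scores.index}
    for rep in reports:
        if rep.positive_fraction > positive_fraction:
            for p in rep.scores.index[rep.scores <= 0]:
                decisions[p].flagged_in.add(rep.variant)
    for d in decisions.values():
        if len(d.flagged_in) < min_variants:
            d.flagged_in = set()
    return decisions


def remove_outliers(
    tables: Mapping[str, FeatureTable], decisions: Mapping[str, OutlierDecision]
) -> dict[str, FeatureTable]:
    """Drop outlier participants from every table variant (cohort-wide)."""
    drop = [p for p, d in decisions.items() if d.is_outlier]
    out = {}
    for tag, t in tables.items():
        out[tag] = FeatureTable(
            data=t.data.drop(index=drop), band=t.band, metric=t.metric
        )
    return out


def _draw_oa(
    frame: pd.DataFrame, target_class: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the 'other achievement' side for a target class.

    OA matches the target class in size and is split as evenly as
    possible between the two complementary classes; with an odd target
    size the extra member's source class is chosen by a seeded coin flip.
    Sampling is without replacement.
    """
    others = [c for c in CLASS_LABELS if c != target_class]
    n_target = int((frame[CLASS_COLUMN] == target_class).sum())
    avail = {c: int((frame[CLASS_COLUMN] == c).sum()) for c in others}
    if sum(avail.values()) < n_target:
        raise ValueError(
            f"cannot build an OA side of {n_target} for {target_class}: only "
            f"{sum(avail.values())} participants in {others}"
        )
    base, extra = divmod(n_target, 2)
    shares = dict.fromkeys(others, base)
    if extra:
        shares[others[rng.integers(2)]] += 1
    # rebalance when one source class cannot supply its even share
    for c, other in (others, others[::-1]):
        if shares[c] > avail[c]:
            shares[other] += shares[c] - avail[c]
            shares[c] = avail[c]
    picked = []
    for cls in others:
        members = frame.index[frame[CLASS_COLUMN] == cls].to_numpy()
        picked.append(rng.choice(members, size=shares[cls], replace=False))
    idx = np.concatenate(picked)
    oa = frame.loc[np.sort(idx)].copy()
    oa[CLASS_COLUMN] = "OA"
    return oa


def define_experiments(
    tables: Mapping[str, FeatureTable], seed: int = 0
) -> list[ExperimentDataset]:
    """Build the pairwise experiment datasets from cleaned tables.

    Six class pairs x every table variant (90 for the 15 canonical
    variants). OA membership for a given pair is drawn once from the seed
    and shared across variants so the same participants are compared in
    every feature space.
    """
    first = next(iter(tables.values()))
    counts = first.classes.value_counts()
    if (counts < 2).any() or len(counts) < 3:
        raise ValueError(f"every class needs >= 2 members, got {counts.to_dict()}")

    # Pre-draw OA membership per pair from a pair-specific child seed.
    ss = np.random.SeedSequence(seed)
    oa_members: dict[str, pd.Index] = {}
    for pair, child in zip(PAIRS, ss.spawn(len(PAIRS))):
        left, right = pair.split("-")
        if right == "OA":
            rng = np.random.default_rng(child)
            oa_members[pair] = _draw_oa(first.data, left, rng).index

    datasets = []
    for tag in sorted(tables):
        t = tables[tag]
        for pair in PAIRS:
            left, right = pair.split("-")
            left_rows = t.data[t.data[CLASS_COLUMN] == left]
            if right == "OA":
                oa_rows = t.data.loc[oa_members[pair]].copy()
                oa_rows[CLASS_COLUMN] = "OA"
                frame = pd.concat([left_rows, oa_rows])
            else:
                right_rows = t.data[t.data[CLASS_COLUMN] == right]
                frame = pd.concat([left_rows, right_rows])
            datasets.append(
                ExperimentDataset(
                    name=experiment_name(pair, t.band, t.metric),
                    data=frame,
                    pair=pair,
                    band=t.band,
                    metric=t.metric,
                )
            )
    return datasets
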