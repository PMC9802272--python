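"""Intercoder reliability and the dictionary-validation design.

Implements Krippendorff's alpha at the nominal level via the
coincidence-matrix formulation — alpha = 1 - D_o/D_e, with observed
disagreement accumulated from pairable values within units and expected
disagreement from category marginals — which handles missing labels and
any number of coders.  Binary topic codes make nominal the appropriate
measurement level.  Also provides simple two-coder percent agreement,
discrepancy adjudication into a consensus coder, the purposive
positive/negative-per-topic validation sampler, and the per-topic
reliability summary (mean and range across the 8 topics).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .lexicons import CANONICAL_TOPICS
from .topics import TopicAssignment

logger = logging.getLogger(__name__)

Label = Hashable  # nominal category; None marks a missing entry


class ReliabilityError(ValueError):
    pass


@dataclass
class CodingMatrix:
    """Units x coders nominal label matrix; ``None`` entries are missing.

    A "computer" coder (the dictionary classifier) is an ordinary column,
    which is how the human-vs-computer comparison is set up.
    """

    unit_ids: list[str]
    coders: list[str]
    labels: list[list[Optional[Label]]]  # row per unit, column per coder
    categories: Optional[set[Label]] = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.unit_ids):
            raise ReliabilityError("label matrix row count != number of units")
        for row in self.labels:
            if len(row) != len(self.coders):
                raise ReliabilityError("label matrix column count != number of coders")
        observed = {v for row in self.labels for v in row if v is not None}
        if self.categories is None:
            self.categories = observed
        elif not observed <= self.categories:
            raise ReliabilityError(
                f"labels outside declared category set: {observed - self.categories}"
            )

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_coders(self) -> int:
        return len(self.coders)

    def column(self, coder: str) -> dict[str, Optional[Label]]:
        j = self.coders.index(coder)
        return {u: row[j] for u, row in zip(self.unit_ids, self.labels)}

    @classmethod
    def from_labelings(
        cls, labelings: Mapping[str, Mapping[str, Label]]
    ) -> "CodingMatrix":
        """Build a matrix from per-coder {unit: label} dicts (union of units)."""
        coders = list(labelings)
        units = sorted({u for lab in labelings.values() for u in lab})
        rows = [[labelings[c].get(u) for c in coders] for u in units]
        return cls(units, coders, rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["unit_id", *self.coders])
            for u, row in zip(self.unit_ids, self.labels):
                writer.writerow([u, *["" if v is None else v for v in row]])
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CodingMatrix":
        with Path(path).open("r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            coders = header[1:]
            units, rows = [], []
            for rec in reader:
                units.append(rec[0])
                rows.append([v if v != "" else None for v in rec[1:]])
        return cls(units, coders, rows)


@dataclass
class ReliabilityResult:
    """Alpha and bookkeeping for one coding matrix.

    ``alpha`` is ``None`` when expected disagreement is zero (a single
    category used throughout), where the coefficient is undefined.
    """

    alpha: Optional[float]
    n_units: int
    n_coders: int
    category_counts: dict[Label, int]
    percent_agreement: Optional[float] = None

    def to_json(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_units": self.n_units,
            "n_coders": self.n_coders,
            "category_counts": {str(k): v for k, v in self.category_counts.items()},
            "percent_agreement": self.percent_agreement,
        }


def krippendorff_alpha(matrix: CodingMatrix) -> ReliabilityResult:
    """Nominal-level Krippendorff's alpha.

    Units with fewer than two non-missing labels are excluded (their
    values are not pairable).  Raises when nothing is pairable; returns
    an undefined (None) alpha with a warning when every pairable value
    falls in one category, i.e. expected disagreement is zero.
    """
    if matrix.n_coders < 2:
        raise ReliabilityError("alpha needs at least 2 coders")
    pairable = [
        [v for v in row if v is not None]
        for row in matrix.labels
        if sum(v is not None for v in row) >= 2
    ]
    if not pairable:
        raise ReliabilityError("no units with >=2 non-missing labels")

    cats = sorted({v for row in pairable for v in row}, key=repr)
    index = {c: k for k, c in enumerate(cats)}
    q = len(cats)
    coincidence = np.zeros((q, q))
    for row in pairable:
        m = len(row)
        for a in row:
            for b in row:
                coincidence[index[a], index[b]] += 1.0 / (m - 1)
        # remove self-pairs added above
        for a in row:
            coincidence[index[a], index[a]] -= 1.0 / (m - 1)

    marginals = coincidence.sum(axis=1)
    n = marginals.sum()
    counts = {c: int(round(marginals[index[c]])) for c in cats}
    d_observed = coincidence.sum() - np.trace(coincidence)
    d_expected = (n * n - (marginals ** 2).sum()) / (n - 1)
    if d_expected == 0:
        warnings.warn(
            "Krippendorff's alpha undefined: a single category is used "
            "throughout (expected disagreement is zero)",
            stacklevel=2,
        )
        alpha = None
    else:
        alpha = float(1.0 - d_observed / d_expected)
    return ReliabilityResult(
        alpha=alpha,
        n_units=len(pairable),
        n_coders=matrix.n_coders,
        category_counts=counts,
    )


def percent_agreement(matrix: CodingMatrix) -> float:
    """Fraction of units on which two coders assign identical labels.

    Defined only for the complete two-coder case; use alpha otherwise.
    """
    if matrix.n_coders != 2:
        raise ReliabilityError(
            "percent agreement is defined for exactly 2 coders; use krippendorff_alpha"
        )
    if any(v is None for row in matrix.labels for v in row):
        raise ReliabilityError(
            "percent agreement requires complete data; use krippendorff_alpha"
        )
    if matrix.n_units == 0:
        raise ReliabilityError("empty coding matrix")
    agree = sum(row[0] == row[1] for row in matrix.labels)
    return agree / matrix.n_units


def adjudicate(
    matrix: CodingMatrix, resolutions: Mapping[str, Label] | None = None
) -> dict[str, Label]:
    """Resolve two-coder discrepancies into one consensus labeling.

    Concordant units keep the shared label; each discordant unit must
    appear in ``resolutions``.  The result is a {unit: label} dict usable
    as one coder in a human-vs-computer matrix.
    """
    if matrix.n_coders != 2:
        raise ReliabilityError("adjudication is defined for exactly 2 coders")
    resolutions = resolutions or {}
    consensus: dict[str, Label] = {}
    unresolved = []
    for u, (a, b) in zip(matrix.unit_ids, matrix.labels):
        if a == b:
            consensus[u] = a
        elif u in resolutions:
            consensus[u] = resolutions[u]
        else:
            unresolved.append(u)
    if unresolved:
        raise ReliabilityError(f"unresolved discordant units: {unresolved}")
    return consensus


# ---------------------------------------------------------------------------
# Purposive validation sampling
# ---------------------------------------------------------------------------

@dataclass
class ValidationSamplePlan:
    """Stratified draw: per topic, n classified-positive + n classified-negative.

    The canonical design is 60 + 60 across the 8 topics = 960 stratum draws.
    """

    per_topic_positive: int = 60
    per_topic_negative: int = 60
    topics: Sequence[str] = CANONICAL_TOPICS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_topic_positive < 1 or self.per_topic_negative < 1:
            raise ValueError("stratum counts must be >= 1")

    @property
    def total_draws(self) -> int:
        return len(self.topics) * (self.per_topic_positive + self.per_topic_negative)


@dataclass
class ValidationSample:
    """Result of a purposive draw.

    ``strata`` maps (topic, "positive"|"negative") to the drawn post ids;
    ``unit_ids`` aggregates them uniquely (a post drawn for two strata
    appears once but stays in both stratum ledgers).
    """

    strata: dict[tuple[str, str], list[str]]
    seed: int

    @property
    def unit_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ids in self.strata.values():
            for u in ids:
                seen.setdefault(u)
        return list(seen)

    @property
    def total_draws(self) -> int:
        return sum(len(v) for v in self.strata.values())


def draw_validation_sample(
    assignments: Iterable[TopicAssignment], plan: ValidationSamplePlan
) -> ValidationSample:
    """Seeded, reproducible without-replacement draws within each stratum."""
    assignments = list(assignments)
    rng = np.random.default_rng(plan.seed)
    strata: dict[tuple[str, str], list[str]] = {}
    for topic in plan.topics:
        positives = [a.post_id for a in assignments if topic in a.topics]
        negatives = [a.post_id for a in assignments if topic not in a.topics]
        for stratum, pool, want in (
            ("positive", positives, plan.per_topic_positive),
            ("negative", negatives, plan.per_topic_negative),
        ):
            if len(pool) < want:
                raise ReliabilityError(
                    f"stratum too small: topic {topic!r} {stratum} has "
                    f"{len(pool)} posts, plan requires {want}"
                )
            drawn = rng.choice(len(pool), size=want, replace=False)
            strata[(topic, stratum)] = [pool[i] for i in sorted(drawn)]
    return ValidationSample(strata=strata, seed=plan.seed)


# ---------------------------------------------------------------------------
# Per-topic reliability summary
# ---------------------------------------------------------------------------

def topic_matrices(
    labelings: Mapping[str, Mapping[str, Iterable[str]]],
    unit_ids: Sequence[str],
    topics: Sequence[str] = CANONICAL_TOPICS,
) -> dict[str, CodingMatrix]:
    """Explode per-coder topic-set labelings into 8 binary matrices.

    ``labelings`` maps coder -> {unit: set of topics assigned}.  For each
    topic, a unit's label is "present"/"absent" per coder.
    """
    out = {}
    for topic in topics:
        cols = {
            coder: {
                u: ("present" if topic in set(lab.get(u, ())) else "absent")
                for u in unit_ids
            }
            for coder, lab in labelings.items()
        }
        out[topic] = CodingMatrix.from_labelings(cols)
    return out


def summarize_topic_reliability(
    matrices: Mapping[str, CodingMatrix],
) -> dict:
    """Per-topic alpha plus the mean/range summary across topics.

    Topics whose alpha is undefined (single-category strata) are reported
    as null and excluded from the mean and range.
    """
    per_topic = {}
    for topic, matrix in matrices.items():
        result = krippendorff_alpha(matrix)
        per_topic[topic] = result.alpha
    defined = [a for a in per_topic.values() if a is not None]
    return {
        "per_topic_alpha": per_topic,
        "mean_alpha": float(np.mean(defined)) if defined else None,
        "range_alpha": (min(defined), max(defined)) if defined else None,
    }
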