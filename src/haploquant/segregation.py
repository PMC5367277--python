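"""Per-nest Mendelian segregation tests for presence/absence colour traits.

Under haplodiploidy with a monogamous foundress, a single-locus trait
can only segregate 0 : 1, 1 : 1 or 1 : 0 among full sisters: the haploid
father contributes the same allele to every daughter, so the only
segregating source is the mother's two alleles.  Nests in which the
fraction of daughters showing a trait differs significantly from one
half — without being fixed for presence or absence — therefore reject a
single-locus architecture.

The test is a one-sample proportion chi-square against 1/2 with Yates'
continuity correction.  Nests where every daughter (or none) shows the
trait are classified "all-or-none" and deliberately not tested: a single
discordant individual already falsifies the all-or-none Mendelian
outcomes, so a p-value would be uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import FEMALE, Pedigree

__all__ = [
    "AllOrNoneSegregation",
    "SegregationTest",
    "presence_from_score",
    "mendelian_test",
    "binomial_test",
    "classify_nest",
    "segregation_scan",
]

ALPHA_DEFAULT = 0.05


class AllOrNoneSegregation(ValueError):
    """Raised when k in {0, n}: the all-or-none outcomes are not chi-square tested."""


def presence_from_score(score: int) -> bool:
    """Collapse an ordinal 0-4 colour score to categorical presence."""
    score = int(score)
    if not 0 <= score <= 4:
        raise ValueError(f"ordinal score must be in 0..4, got {score}")
    return score > 0


def mendelian_test(k: int, n: int) -> tuple[float, float]:
    """Continuity-corrected chi-square of k/n against the 50:50 Mendelian null.

    chi2 = 2 * (max(0, |k - n/2| - 1/2))^2 / (n/2), with p the upper tail
    of chi-square(1).  The correction clamps to zero for |k - n/2| <= 1/2
    (e.g. 11 of 22 gives chi2 = 0, p = 1).
    """
    k, n = int(k), int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in 0..n, got k={k}, n={n}")
    if k in (0, n):
        raise AllOrNoneSegregation(
            f"k={k} of n={n}: all-or-none nests are classified, not tested"
        )
    expected = n / 2.0
    chi2 = 2.0 * max(0.0, abs(k - expected) - 0.5) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def binomial_test(k: int, n: int) -> float:
    """Exact two-sided binomial p-value against 1/2 (cross-check utility).

    Provided for comparison only; the study's reported p-values follow
    the corrected chi-square in :func:`mendelian_test`.
    """
    return float(stats.binomtest(int(k), int(n), 0.5).pvalue)


@dataclass(frozen=True)
class SegregationTest:
    """One nest x trait segregation result."""

    nest: str
    trait: str
    mother_has_trait: bool | None
    k: int
    n: int
    chi2: float | None
    p: float | None
    classification: str  # consistent | rejected | all-or-none

    def to_dict(self) -> dict:
        return {
            "nest": self.nest,
            "trait": self.trait,
            "mother_has_trait": self.mother_has_trait,
            "k": self.k,
            "n": self.n,
            "chi2": self.chi2,
            "p": self.p,
            "classification": self.classification,
        }


def classify_nest(
    nest: str,
    trait: str,
    k: int,
    n: int,
    mother_has_trait: bool | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> SegregationTest:
    if k in (0, n):
        return SegregationTest(nest, trait, mother_has_trait, k, n, None, None,
                               "all-or-none")
    chi2, p = mendelian_test(k, n)
    label = "rejected" if p < alpha else "consistent"
    return SegregationTest(nest, trait, mother_has_trait, k, n, chi2, p, label)


def segregation_scan(
    phenotypes: pd.DataFrame,
    ped: Pedigree,
    trait: str,
    min_n: int = 20,
    alpha: float = ALPHA_DEFAULT,
    logger=None,
) -> list[SegregationTest]:
    """One Mendelian test per single-foundress nest with >= min_n daughters.

    ``phenotypes`` is a long table (id, trait, score).  Nest membership
    and motherhood come from the pedigree: within each nest label, the
    mother is the female who is dam of the nest's daughters.  The
    ``min_n`` filter counts phenotyped daughters, not estimated brood
    size.  An unphenotyped mother yields ``mother_has_trait=None``.
    """
    scores = (
        phenotypes.loc[phenotypes["trait"] == trait]
        .set_index("id")["score"]
        .to_dict()
    )
    results: list[SegregationTest] = []
    for nest, members in sorted(ped.nests().items()):
        females = [i for i in members if ped[i].sex == FEMALE]
        dams_here = {ped[i].dam for i in females if ped[i].dam is not None}
        mothers = [d for d in dams_here if sum(ped[i].dam == d for i in females) > 0]
        if not mothers:
            continue
        # Single-foundress nests have exactly one dam among members.
        mother = max(mothers, key=lambda d: sum(ped[i].dam == d for i in females))
        daughters = [i for i in females if ped[i].dam == mother]
        present = [
            presence_from_score(scores[i]) for i in daughters if i in scores
        ]
        n = len(present)
        if n < min_n:
            continue
        k = int(sum(present))
        if mother in scores:
            mother_present = presence_from_score(scores[mother])
        else:
            mother_present = None
            if logger is not None:
                logger.warning(
                    "nest %s: mother %s unphenotyped for trait %s", nest, mother, trait
                )
        results.append(classify_nest(nest, trait, k, n, mother_present, alpha))
    return results


def scan_to_frame(results: list[SegregationTest]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
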