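"""Enrichment statistics for UTR features and GO terms.

Binary features (TOP/TOP-like, uORF, ARE, TISU presence) are compared
between a gene list and the rest of the chip with a Pearson chi-square test
on the 2x2 table (no continuity correction by default); continuous features
(5'UTR length, 5'UTR MFE) with a Welch two-sample t test.  GO terms are
tested per term with Fisher's exact test (one-sided, over-representation)
against a reference universe, with optional Benjamini-Hochberg adjustment.
The odds ratio reported is the sample odds ratio (a*d)/(b*c).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

BINARY_TEST = "chi2"
CONTINUOUS_TEST = "t"


@dataclass
class EnrichmentResult:
    """Outcome of one feature or term test."""

    feature: str
    table: tuple[int, int, int, int]  # a, b, c, d: (list +, list -, bg +, bg -)
    statistic: float
    p: float
    odds_ratio: float
    direction: str  # enriched | depleted
    test: str
    adjusted_p: float | None = None

    @property
    def untestable(self) -> bool:
        return not np.isfinite(self.p)


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)


def binary_feature_test(
    list_a: Iterable[str],
    background: Iterable[str],
    feature_flags: Mapping[str, bool],
    name: str = "feature",
    yates: bool = False,
) -> EnrichmentResult:
    """Chi-square test of a binary feature, list vs background.

    ``background`` is the rest of the chip (universe minus the list).  Tables
    with a zero margin are flagged untestable (p = NaN).
    """
    la, bg = list(list_a), list(background)
    a = sum(bool(feature_flags.get(g, False)) for g in la)
    b = len(la) - a
    c = sum(bool(feature_flags.get(g, False)) for g in bg)
    d = len(bg) - c
    table = np.array([[a, b], [c, d]])
    rate_a = a / len(la) if la else np.nan
    rate_bg = c / len(bg) if bg else np.nan
    direction = "enriched" if rate_a >= rate_bg else "depleted"
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return EnrichmentResult(name, (a, b, c, d), np.nan, np.nan,
                                _odds_ratio(a, b, c, d), direction, BINARY_TEST)
    if a / len(la) == c / len(bg):
        chi2, p = 0.0, 1.0  # identical rates: exact no-association case
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return EnrichmentResult(name, (a, b, c, d), float(chi2), float(p),
                            _odds_ratio(a, b, c, d), direction, BINARY_TEST)


def continuous_feature_test(
    list_a: Iterable[str],
    background: Iterable[str],
    values: Mapping[str, float],
    name: str = "feature",
) -> EnrichmentResult:
    """Welch two-sample t test of a continuous feature, list vs background."""
    xa = np.array([values[g] for g in list_a if g in values], dtype=float)
    xb = np.array([values[g] for g in background if g in values], dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("need >= 2 values per group")
    if np.var(xa) == 0 and np.var(xb) == 0:
        if xa.mean() == xb.mean():
            return EnrichmentResult(name, (0, 0, 0, 0), 0.0, 1.0, np.nan,
                                    "enriched", CONTINUOUS_TEST)
        raise ValueError("degenerate variance in both groups")
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    direction = "enriched" if xa.mean() >= xb.mean() else "depleted"
    return EnrichmentResult(name, (xa.size, 0, xb.size, 0), float(t), float(p),
                            np.nan, direction, CONTINUOUS_TEST)


def go_overrepresentation(
    list_a: Iterable[str],
    reference: Iterable[str],
    annotation_map: Mapping[str, set[str]],
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """Per-term over-representation of GO annotations in a gene list.

    The reference is the annotation universe (it may include the list, as
    when the reference is the whole genome); per term the 2x2 table splits
    (in list / reference not in list) x (annotated / not) and the one-sided
    Fisher exact p equals the hypergeometric tail sum.  Terms annotating no
    gene of list or reference are skipped; results are sorted by p.
    ``correction='bh'`` adds Benjamini-Hochberg adjusted p-values.
    """
    la = set(list_a)
    ref = set(reference)
    if not annotation_map:
        raise ValueError("empty annotation map")
    covered = sum(1 for g in la if annotation_map.get(g))
    if covered == 0:
        raise ValueError("annotation map covers no gene of the list")
    rest = ref - la
    terms: dict[str, int] = {}
    for g in la | ref:
        for t in annotation_map.get(g, ()):
            terms[t] = terms.get(t, 0) + 1
    results = []
    for term in sorted(terms):
        a = sum(1 for g in la if term in annotation_map.get(g, ()))
        c = sum(1 for g in rest if term in annotation_map.get(g, ()))
        if a + c == 0:
            continue
        b = len(la) - a
        d = len(rest) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rate_a = a / len(la) if la else np.nan
        rate_bg = c / len(rest) if rest else rate_a
        direction = "enriched" if not rest or rate_a >= rate_bg else "depleted"
        results.append(
            EnrichmentResult(term, (a, b, c, d), np.nan, float(p),
                             _odds_ratio(a, b, c, d), direction, "fisher")
        )
    results.sort(key=lambda r: (r.p, r.feature))
    if correction == "bh" and results:
        adj = stats.false_discovery_control([r.p for r in results], method="bh")
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
    elif correction not in (None, "none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    return results


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results with the odds-ratio / p-value column layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "feature": r.feature,
                "test": r.test,
                "a": r.table[0],
                "b": r.table[1],
                "c": r.table[2],
                "d": r.table[3],
                "statistic": r.statistic,
                "odds_ratio": r.odds_ratio,
                "direction": r.direction,
                "p": r.p,
                "adjusted_p": r.adjusted_p if r.adjusted_p is not None else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
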