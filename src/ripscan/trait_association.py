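"""Genotype-trait association: per-genotype summaries, Kruskal-Wallis
omnibus test, Dunn's pairwise post-hoc comparisons, and two-tier compact
letter displays.

The analysis follows the standard nonparametric workflow for independent
samples: ranks pooled across genotype groups, a tie-corrected H statistic
against chi-square with k-1 degrees of freedom, and Dunn's z tests for
each genotype pair.  Letters summarize the pairwise matrix at two levels:
lowercase at alpha = 0.05 (significant) and uppercase at alpha = 0.01
(highly significant); two groups share a letter iff their pairwise
p-value is >= alpha at that tier.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPE_ORDER = ("+/+", "+/-", "-/-")
TRAITS = ("TNB", "NBA", "LW")


@dataclass(frozen=True)
class GroupSummary:
    genotype: str
    n: int
    mean: float
    sd: Optional[float]  # None for singleton groups


@dataclass(frozen=True)
class AssociationResult:
    locus: str
    trait: str
    groups: tuple[GroupSummary, ...]
    h_statistic: Optional[float]
    p_value: Optional[float]
    pairwise_p: Optional[pd.DataFrame]  # raw (or adjusted) two-sided p per pair
    letters_05: dict
    letters_01: dict
    testable: bool


def group_summary(
    traits: pd.DataFrame, genotypes: pd.DataFrame, locus: str, trait: str
) -> list[GroupSummary]:
    """Per-genotype n / mean / sample SD (n-1 denominator) for one trait."""
    merged = _merge(traits, genotypes, locus, trait)
    out = []
    for genotype in GENOTYPE_ORDER:
        values = merged.loc[merged["genotype"] == genotype, trait].to_numpy(float)
        if values.size == 0:
            continue
        sd = float(np.std(values, ddof=1)) if values.size > 1 else None
        out.append(GroupSummary(genotype=genotype, n=int(values.size), mean=float(values.mean()), sd=sd))
    return out


def _merge(traits: pd.DataFrame, genotypes: pd.DataFrame, locus: str, trait: str) -> pd.DataFrame:
    geno = genotypes[genotypes["locus"] == locus].dropna(subset=["genotype"])
    merged = traits.merge(geno[["individual_id", "genotype"]], on="individual_id")
    return merged[["individual_id", "genotype", trait]]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square (k-1 df) p-value.

    A degenerate pooled sample where every observation is identical gives
    H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(h), float(p)


def pairwise_dunn(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    adjust: str = "none",
) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks with tie correction.

    Returns a symmetric matrix of two-sided p-values with unit diagonal.
    ``adjust="bonferroni"`` multiplies each p by the number of pairs
    (capped at 1).  Empty groups are excluded.
    """
    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    kept = [(i, np.asarray(g, dtype=float)) for i, g in enumerate(groups) if len(g) > 0]
    if len(kept) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if labels is None:
        labels = [str(i) for i, _ in kept]
    else:
        labels = [labels[i] for i, _ in kept]
    samples = [g for _, g in kept]
    sizes = np.array([len(g) for g in samples])
    pooled = np.concatenate(samples)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term: sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))

    mean_ranks = []
    offset = 0
    for size in sizes:
        mean_ranks.append(ranks[offset : offset + size].mean())
        offset += size

    k = len(samples)
    n_pairs = k * (k - 1) // 2
    pmat = np.ones((k, k))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * n_pairs)
        pmat[i, j] = pmat[j, i] = p
    return pd.DataFrame(pmat, index=labels, columns=labels)


def pairwise_mannwhitney(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    adjust: str = "none",
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests (alternative post-hoc engine)."""
    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    kept = [(i, np.asarray(g, dtype=float)) for i, g in enumerate(groups) if len(g) > 0]
    if len(kept) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if labels is None:
        labels = [str(i) for i, _ in kept]
    else:
        labels = [labels[i] for i, _ in kept]
    samples = [g for _, g in kept]
    k = len(samples)
    n_pairs = k * (k - 1) // 2
    pmat = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        if np.all(np.concatenate([samples[i], samples[j]]) == samples[i][0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided").pvalue)
        if adjust == "bonferroni":
            p = min(1.0, p * n_pairs)
        pmat[i, j] = pmat[j, i] = p
    return pd.DataFrame(pmat, index=labels, columns=labels)


def compact_letters(pairwise: pd.DataFrame, alpha: float, uppercase: bool = False) -> dict:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their pairwise p-value is >= alpha.
    Letters are assigned greedily in group order and absorbed when
    redundant; the result is checked to be consistent with the matrix.
    """
    groups = list(pairwise.index)
    letter_sets: list[set] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if pairwise.loc[a, b] >= alpha:
            continue
        # insert: split every letter set containing both members of a
        # significant pair into one copy without each
        next_sets: list[set] = []
        for s in letter_sets:
            if a in s and b in s:
                next_sets.extend([s - {a}, s - {b}])
            else:
                next_sets.append(s)
        # absorb: drop sets contained in another
        letter_sets = [
            s
            for i, s in enumerate(next_sets)
            if s
            and not any(
                (s < t) or (s == t and i > j) for j, t in enumerate(next_sets)
            )
        ]
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = string.ascii_uppercase if uppercase else string.ascii_lowercase
    assignment = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                assignment[g] += letter
    return assignment


def letters_consistent(pairwise: pd.DataFrame, letters: dict, alpha: float) -> bool:
    """Check the defining property: shared letter iff p >= alpha."""
    for a, b in itertools.combinations(pairwise.index, 2):
        shared = bool(set(letters[a]) & set(letters[b]))
        if shared != (pairwise.loc[a, b] >= alpha):
            return False
    return True


def associate(
    traits: pd.DataFrame,
    genotypes: pd.DataFrame,
    loci: Sequence[str],
    traits_list: Sequence[str] = TRAITS,
    engine: str = "dunn",
    adjust: str = "none",
    alphas: tuple[float, float] = (0.05, 0.01),
) -> list[AssociationResult]:
    """Full association analysis: one result per locus x trait.

    ``engine`` selects the pairwise post-hoc test ("dunn" or
    "mannwhitney"); p-values are raw by default.  Loci with fewer than two
    genotype classes present are flagged not-testable.
    """
    post_hoc = {"dunn": pairwise_dunn, "mannwhitney": pairwise_mannwhitney}[engine]
    out = []
    for locus in loci:
        for trait in traits_list:
            merged = _merge(traits, genotypes, locus, trait)
            summaries = group_summary(traits, genotypes, locus, trait)
            labels = [s.genotype for s in summaries]
            samples = [
                merged.loc[merged["genotype"] == g, trait].to_numpy(float) for g in labels
            ]
            if len(labels) < 2:
                out.append(
                    AssociationResult(
                        locus=locus, trait=trait, groups=tuple(summaries),
                        h_statistic=None, p_value=None, pairwise_p=None,
                        letters_05={}, letters_01={}, testable=False,
                    )
                )
                continue
            h, p = kruskal_wallis(samples)
            pmat = post_hoc(samples, labels=labels, adjust=adjust)
            out.append(
                AssociationResult(
                    locus=locus, trait=trait, groups=tuple(summaries),
                    h_statistic=h, p_value=p, pairwise_p=pmat,
                    letters_05=compact_letters(pmat, alphas[0], uppercase=False),
                    letters_01=compact_letters(pmat, alphas[1], uppercase=True),
                    testable=True,
                )
            )
    return out


def render_association_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Format results as 'mean ± sd ^letters' per genotype row.

    At each tier only the informative letters are shown: when a pair
    differs at the 0.01 tier the uppercase letters carry the signal,
    otherwise the lowercase tier is shown.
    """
    rows: dict[tuple[str, str], dict] = {}
    for r in results:
        for g in r.groups:
            key = (r.locus, g.genotype)
            row = rows.setdefault(
                key, {"locus": r.locus, "genotype": g.genotype, "n": g.n}
            )
            sd = "NA" if g.sd is None else f"{g.sd:.2f}"
            lo = r.letters_05.get(g.genotype, "")
            hi = r.letters_01.get(g.genotype, "")
            letters = hi if _any_difference(r.letters_01) else lo
            row[r.trait] = f"{g.mean:.2f} ± {sd} {letters}".rstrip()
    return pd.DataFrame(rows.values())


def _any_difference(letters: dict) -> bool:
    if not letters:
        return False
    sets = [set(v) for v in letters.values()]
    return any(not (a & b) for a, b in itertools.combinations(sets, 2))
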