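"""Population-genetic summaries of RIP genotype counts.

For each locus x breed cell the pipeline reports genotype and allele
frequencies, a Hardy-Weinberg equilibrium chi-square test, the polymorphic
information content (PIC), and a qualitative polymorphism class.

Statistical conventions:

* HWE test: expected counts (n p^2, 2 n p q, n q^2) from the estimated
  insertion-allele frequency p; chi2 = sum (obs - exp)^2 / exp over the
  three genotype classes, **no continuity correction**, p-value from the
  upper tail of chi-square with **1 degree of freedom** (three classes,
  one estimated allele frequency).  A monomorphic sample (p in {0, 1}) has
  no test; chi2/p-value/balance are undefined and rendered "N".
* PIC (Botstein): 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2; for a
  biallelic marker 1 - p^2 - q^2 - 2 p^2 q^2, maximum 0.375 at p = 0.5.
* Polymorphism class: PIC > 0.5 high, 0.25 < PIC <= 0.5 moderate,
  PIC <= 0.25 low, undefined -> none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

HWE_ALPHA = 0.05


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one locus in one breed: +/+, +/-, -/-."""

    breed: str
    locus: str
    n_pp: int
    n_pm: int
    n_mm: int

    def __post_init__(self) -> None:
        if min(self.n_pp, self.n_pm, self.n_mm) < 0:
            raise ValueError("negative genotype count")
        if self.n < 1:
            raise ValueError("need at least one genotyped individual")

    @property
    def n(self) -> int:
        return self.n_pp + self.n_pm + self.n_mm


@dataclass(frozen=True)
class PopGenStats:
    """One locus x breed summary row."""

    breed: str
    locus: str
    n: int
    genotype_freqs: tuple[float, float, float]
    p: float  # insertion allele "+"
    q: float
    chi2: Optional[float]
    p_value: Optional[float]
    hwe_balanced: Optional[bool]
    pic: Optional[float]
    polymorphism_class: str


def counts_from_frequencies(
    n: int, freqs_percent: Sequence[float], breed: str = "", locus: str = ""
) -> GenotypeCounts:
    """Reconstruct integer genotype counts from printed percentages.

    Each frequency (in %) is multiplied by n and rounded to the nearest
    integer; the rounded counts must re-sum to n, otherwise the printed
    frequencies are inconsistent with the stated sample size.
    """
    counts = [round(f / 100.0 * n) for f in freqs_percent]
    if sum(counts) != n:
        raise ValueError(
            f"{breed}/{locus}: rounded counts {counts} do not re-sum to n={n}"
        )
    return GenotypeCounts(breed=breed, locus=locus, n_pp=counts[0], n_pm=counts[1], n_mm=counts[2])


def allele_frequencies(counts: GenotypeCounts) -> tuple[float, float]:
    """(p, q): frequency of the insertion (+) and empty (-) alleles."""
    p = (2 * counts.n_pp + counts.n_pm) / (2 * counts.n)
    return p, 1.0 - p


def hwe_chi_square(
    counts: GenotypeCounts,
) -> tuple[Optional[float], Optional[float], Optional[bool]]:
    """Hardy-Weinberg chi-square test (df=1, no continuity correction).

    Returns (chi2, p_value, balanced) or (None, None, None) for a
    monomorphic sample, where no test is defined.
    """
    p, q = allele_frequencies(counts)
    if p == 0.0 or p == 1.0:
        return None, None, None
    n = counts.n
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (counts.n_pp, counts.n_pm, counts.n_mm)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return chi2, p_value, p_value > HWE_ALPHA


def pic(allele_freqs: Sequence[float]) -> float:
    """Polymorphic information content (Botstein form) for any allele count."""
    if not math.isclose(sum(allele_freqs), 1.0, abs_tol=1e-9):
        raise ValueError(f"allele frequencies sum to {sum(allele_freqs)}, not 1")
    het = 1.0 - sum(f * f for f in allele_freqs)
    cross = sum(
        2 * allele_freqs[i] ** 2 * allele_freqs[j] ** 2
        for i in range(len(allele_freqs))
        for j in range(i + 1, len(allele_freqs))
    )
    return het - cross


def classify_polymorphism(pic_value: Optional[float]) -> str:
    """Qualitative informativeness class from PIC."""
    if pic_value is None:
        return "none"
    if pic_value > 0.5:
        return "high"
    if pic_value > 0.25:
        return "moderate"
    return "low"


def stats_from_counts(counts: GenotypeCounts) -> PopGenStats:
    p, q = allele_frequencies(counts)
    chi2, p_value, balanced = hwe_chi_square(counts)
    pic_value = pic([p, q])
    n = counts.n
    return PopGenStats(
        breed=counts.breed,
        locus=counts.locus,
        n=n,
        genotype_freqs=(counts.n_pp / n, counts.n_pm / n, counts.n_mm / n),
        p=p,
        q=q,
        chi2=chi2,
        p_value=p_value,
        hwe_balanced=balanced,
        pic=pic_value,
        polymorphism_class=classify_polymorphism(pic_value),
    )


def counts_from_table(genotype_table: pd.DataFrame, breed: str, locus: str) -> GenotypeCounts:
    sub = genotype_table[
        (genotype_table["breed"] == breed) & (genotype_table["locus"] == locus)
    ]
    sub = sub.dropna(subset=["genotype"])
    if sub.empty:
        raise ValueError(f"no non-missing genotypes for {breed}/{locus}")
    tally = sub["genotype"].value_counts()
    return GenotypeCounts(
        breed=breed,
        locus=locus,
        n_pp=int(tally.get("+/+", 0)),
        n_pm=int(tally.get("+/-", 0)),
        n_mm=int(tally.get("-/-", 0)),
    )


def summarize_locus(genotype_table: pd.DataFrame, breed: str, locus: str) -> PopGenStats:
    """Full summary row for one (breed, locus) cell of a genotype table."""
    return stats_from_counts(counts_from_table(genotype_table, breed, locus))


def _fmt(value: Optional[float], digits: int) -> str:
    return "N" if value is None else f"{value:.{digits}f}"


def diversity_table(genotype_table: pd.DataFrame) -> pd.DataFrame:
    """Diversity summary for every (locus, breed) cell, formatted at the
    conventional precision (frequencies in % to 2 dp, chi2/PIC to 2-3 dp)."""
    rows = []
    pairs = (
        genotype_table.dropna(subset=["genotype"])[["locus", "breed"]]
        .drop_duplicates()
        .sort_values(["locus", "breed"])
    )
    for locus, breed in pairs.itertuples(index=False):
        s = summarize_locus(genotype_table, breed, locus)
        rows.append(
            {
                "locus": locus,
                "breed": breed,
                "n": s.n,
                "freq_pp_pct": f"{100 * s.genotype_freqs[0]:.2f}",
                "freq_pm_pct": f"{100 * s.genotype_freqs[1]:.2f}",
                "freq_mm_pct": f"{100 * s.genotype_freqs[2]:.2f}",
                "allele_p_pct": f"{100 * s.p:.2f}",
                "allele_q_pct": f"{100 * s.q:.2f}",
                "hwe_chi2": _fmt(s.chi2, 3),
                "hwe_p": _fmt(s.p_value, 3),
                "pic": _fmt(s.pic, 3),
                "polymorphism": s.polymorphism_class,
            }
        )
    return pd.DataFrame(rows)
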