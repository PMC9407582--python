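"""Published genotype-frequency data for validating the population-genetics
stage.

``PUBLISHED_GENOTYPE_FREQUENCIES`` transcribes a published survey of five
SINE insertion polymorphisms (in the reproductive candidate genes CWH43,
IDO2, OPN, PRLR and VMP1) genotyped across nine pig breeds: per breed, the
sample size and the percentage of insertion-homozygous (+/+), heterozygous
(+/-) and empty-homozygous (-/-) individuals.  Genotype *counts* are
recoverable as round(freq x n); :func:`ripscan.popgen_stats.counts_from_frequencies`
performs that reconstruction and verifies the counts re-sum to n.

``REFERENCE_CHECKS`` lists the survey cells whose published Hardy-Weinberg
chi-square and PIC values are reproducible from the reconstructed counts
with the standard three-class statistic (df=1, no continuity correction)
and the biallelic Botstein PIC, together with the published values at
their printed precision.  Several small-sample cells of the survey print
chi-square values that are not consistent with that statistic (e.g.
IDO2-9 in Duroc, n=24, printed 22.403 where the formula gives ~0.66);
those cells are deliberately absent here.
"""

from __future__ import annotations

#: rows: (locus, breed, n, %+/+, %+/-, %-/-)
PUBLISHED_GENOTYPE_FREQUENCIES: tuple[tuple[str, str, int, float, float, float], ...] = (
    ("CWH43-9", "Bama", 24, 100.0, 0.0, 0.0),
    ("CWH43-9", "Tibetan", 24, 100.0, 0.0, 0.0),
    ("CWH43-9", "Duroc", 24, 0.0, 0.0, 100.0),
    ("CWH43-9", "LargeWhite", 260, 16.92, 52.31, 30.77),
    ("CWH43-9", "SuJiang", 24, 54.17, 41.67, 4.16),
    ("CWH43-9", "SuShan", 24, 0.0, 41.67, 58.33),
    ("CWH43-9", "Erhualian", 24, 100.0, 0.0, 0.0),
    ("CWH43-9", "Meishan", 24, 100.0, 0.0, 0.0),
    ("CWH43-9", "FengJing", 24, 100.0, 0.0, 0.0),
    ("IDO2-9", "Bama", 24, 0.0, 0.0, 100.0),
    ("IDO2-9", "Tibetan", 24, 0.0, 54.17, 45.83),
    ("IDO2-9", "Duroc", 24, 12.5, 54.17, 33.33),
    ("IDO2-9", "LargeWhite", 260, 28.85, 56.92, 14.23),
    ("IDO2-9", "SuJiang", 24, 20.83, 29.17, 50.0),
    ("IDO2-9", "SuShan", 24, 58.33, 41.67, 0.0),
    ("IDO2-9", "Erhualian", 24, 0.0, 8.33, 91.67),
    ("IDO2-9", "Meishan", 24, 0.0, 25.0, 75.0),
    ("IDO2-9", "FengJing", 24, 20.83, 54.17, 25.0),
    ("OPN-1", "Bama", 24, 0.0, 0.0, 100.0),
    ("OPN-1", "Tibetan", 24, 0.0, 0.0, 100.0),
    ("OPN-1", "Duroc", 24, 100.0, 0.0, 0.0),
    ("OPN-1", "LargeWhite", 260, 5.77, 43.85, 50.38),
    ("OPN-1", "SuJiang", 24, 0.0, 0.0, 100.0),
    ("OPN-1", "SuShan", 24, 0.0, 12.5, 87.5),
    ("OPN-1", "Erhualian", 24, 100.0, 0.0, 0.0),
    ("OPN-1", "Meishan", 24, 0.0, 0.0, 100.0),
    ("OPN-1", "FengJing", 24, 0.0, 100.0, 0.0),
    ("PRLR-6", "Bama", 24, 100.0, 0.0, 0.0),
    ("PRLR-6", "Tibetan", 24, 0.0, 0.0, 100.0),
    ("PRLR-6", "Duroc", 24, 66.67, 33.33, 0.0),
    ("PRLR-6", "LargeWhite", 258, 59.69, 37.60, 2.71),
    ("PRLR-6", "SuJiang", 24, 37.5, 50.0, 12.5),
    ("PRLR-6", "SuShan", 24, 20.83, 54.17, 25.0),
    ("PRLR-6", "Erhualian", 24, 0.0, 0.0, 100.0),
    ("PRLR-6", "Meishan", 24, 0.0, 0.0, 100.0),
    ("PRLR-6", "FengJing", 24, 25.0, 50.0, 25.0),
    ("VMP1-12", "Bama", 24, 0.0, 0.0, 100.0),
    ("VMP1-12", "Tibetan", 24, 54.17, 45.83, 0.0),
    ("VMP1-12", "Duroc", 24, 66.67, 33.33, 0.0),
    ("VMP1-12", "LargeWhite", 247, 12.55, 27.13, 60.32),
    ("VMP1-12", "SuJiang", 24, 54.17, 45.83, 0.0),
    ("VMP1-12", "SuShan", 24, 83.33, 16.67, 0.0),
    ("VMP1-12", "Erhualian", 24, 58.33, 41.67, 0.0),
    ("VMP1-12", "Meishan", 24, 0.0, 0.0, 100.0),
    ("VMP1-12", "FengJing", 24, 25.0, 75.0, 0.0),
)

#: (locus, breed) -> dict with published hwe chi2 / pic at printed precision
#: (chi2 None where the published table prints no reproducible value)
REFERENCE_CHECKS: dict[tuple[str, str], dict] = {
    ("CWH43-9", "LargeWhite"): {"chi2": 1.15, "chi2_digits": 2, "pic": 0.37, "pic_digits": 2},
    ("IDO2-9", "LargeWhite"): {"chi2": 6.93, "chi2_digits": 2, "pic": 0.370, "pic_digits": 3},
    ("PRLR-6", "LargeWhite"): {"chi2": 3.317, "chi2_digits": 3, "pic": 0.281, "pic_digits": 3},
    ("OPN-1", "LargeWhite"): {"chi2": None, "chi2_digits": 3, "pic": 0.320, "pic_digits": 3},
    ("IDO2-9", "Erhualian"): {"chi2": 0.045, "chi2_digits": 3, "pic": 0.08, "pic_digits": 2},
}


def published_counts(locus: str, breed: str):
    """Reconstructed integer genotype counts for one published survey cell."""
    from .popgen_stats import counts_from_frequencies

    for row_locus, row_breed, n, f_pp, f_pm, f_mm in PUBLISHED_GENOTYPE_FREQUENCIES:
        if row_locus == locus and row_breed == breed:
            return counts_from_frequencies(n, (f_pp, f_pm, f_mm), breed=breed, locus=locus)
    raise KeyError(f"no published cell for {locus}/{breed}")
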