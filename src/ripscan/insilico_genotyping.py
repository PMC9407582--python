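"""Dry-lab PCR surrogate: primer-site location, amplicon-size prediction,
and band-pattern genotype calls.

A locus is genotyped the way a gel would read it: the filled (insertion)
and empty haplotypes of an individual each yield an amplicon whose size
differs by the insertion length, and the pair of band sizes maps to
+/+ (two filled-size bands), +/- (one each) or -/- (two empty-size
bands).  Amplicon lengths include both primer footprints, matching how
insertion lengths manifest as band-size differences on a gel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .io_formats import SequenceRecord

DEFAULT_MAX_PRODUCT = 3000


@dataclass(frozen=True)
class PrimerPair:
    """A locus-specific primer pair; ``rev`` is 5'->3' on the minus strand."""

    locus: str
    fwd: str
    rev: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        for name, p in (("fwd", self.fwd), ("rev", self.rev)):
            if not 15 <= len(p) <= 35:
                raise ValueError(f"{self.locus} {name} primer length {len(p)} outside [15, 35]")
        if not 0 <= self.max_mismatch <= 3:
            raise ValueError("max_mismatch must be in [0, 3]")


@dataclass(frozen=True)
class GenotypeCall:
    individual_id: str
    locus: str
    bands: tuple[int, ...]
    genotype: Optional[str]  # "+/+" | "+/-" | "-/-" | None (undetermined)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_primer_sites(
    template: str, primer: str, max_mismatch: int = 0
) -> list[tuple[int, str, int]]:
    """All primer binding sites on both strands of a template.

    Returns (position, strand, mismatches) sorted by position, where
    position is the 1-based start of the matched stretch on the plus
    strand of the template.  A "-" strand site is a match of the primer's
    reverse complement on the plus strand (i.e. the primer binds the minus
    strand there).
    """
    if len(primer) >= len(template):
        raise ValueError("primer must be shorter than the template")
    t = _encode(template)
    sites: list[tuple[int, str, int]] = []
    for strand, probe in (("+", primer), ("-", reverse_complement(primer))):
        p = _encode(probe)
        n = len(t) - len(p) + 1
        # sliding-window mismatch counts, vectorized over offsets
        windows = np.lib.stride_tricks.sliding_window_view(t, len(p))
        mism = (windows != p).sum(axis=1)
        for pos in np.nonzero(mism <= max_mismatch)[0]:
            sites.append((int(pos) + 1, strand, int(mism[pos])))
    sites.sort()
    return sites


def predict_amplicons(
    template: str,
    pair: PrimerPair,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> list[int]:
    """Predicted amplicon lengths for a primer pair on one haplotype.

    A product forms when one primer has a plus-strand site upstream of the
    other primer's minus-strand site within ``max_product``; its length
    runs from the start of the upstream footprint to the end of the
    downstream one (both primer footprints included).  An empty list means
    "no band".
    """
    fwd_sites = find_primer_sites(template, pair.fwd, pair.max_mismatch)
    rev_sites = find_primer_sites(template, pair.rev, pair.max_mismatch)
    lengths: set[int] = set()
    for a, a_len, b, b_len in (
        (fwd_sites, len(pair.fwd), rev_sites, len(pair.rev)),
        (rev_sites, len(pair.rev), fwd_sites, len(pair.fwd)),
    ):
        for pos_a, strand_a, _ in a:
            if strand_a != "+":
                continue
            for pos_b, strand_b, _ in b:
                if strand_b != "-":
                    continue
                end_b = pos_b + b_len - 1
                length = end_b - pos_a + 1
                if len(pair.fwd) + len(pair.rev) <= length <= max_product:
                    lengths.add(length)
    return sorted(lengths)


def call_genotype(
    hap1_bands: Sequence[int],
    hap2_bands: Sequence[int],
    expected_empty: int,
    expected_filled: int,
    tol: int = 10,
    individual_id: str = "",
    locus: str = "",
) -> GenotypeCall:
    """Call +/+, +/- or -/- from the band sizes of the two haplotypes.

    Each haplotype must yield exactly one band within ``tol`` bp of one
    expected size; any other pattern (no band, multiple bands, off-size
    band) gives an undetermined call.  Requires the expected sizes to be
    separated by more than 2 x tol.
    """
    if abs(expected_filled - expected_empty) <= 2 * tol:
        raise ValueError("expected amplicon sizes too close to distinguish")

    def classify(bands: Sequence[int]) -> Optional[str]:
        if len(bands) != 1:
            return None
        b = bands[0]
        if abs(b - expected_filled) <= tol:
            return "filled"
        if abs(b - expected_empty) <= tol:
            return "empty"
        return None

    states = (classify(hap1_bands), classify(hap2_bands))
    genotype: Optional[str]
    if None in states:
        genotype = None
    elif states == ("filled", "filled"):
        genotype = "+/+"
    elif states == ("empty", "empty"):
        genotype = "-/-"
    else:
        genotype = "+/-"
    bands = tuple(sorted(set(hap1_bands) | set(hap2_bands)))
    return GenotypeCall(individual_id=individual_id, locus=locus, bands=bands, genotype=genotype)


def design_flanking_primers(
    empty_seq: str,
    insert_after: int,
    locus: str,
    primer_len: int = 20,
    flank: int = 150,
    max_mismatch: int = 0,
) -> PrimerPair:
    """Design a primer pair flanking an insertion point on the empty allele.

    ``insert_after`` is the 1-based base after which the insertion sits.
    The forward primer ends ``flank`` bp upstream of the insertion point
    and the reverse primer starts ``flank`` bp downstream, giving an empty
    amplicon of 2*flank bp.
    """
    fwd_start = insert_after - flank  # 0-based start of fwd footprint
    rev_end = insert_after + flank  # 0-based exclusive end of rev footprint
    if fwd_start < 0 or rev_end > len(empty_seq):
        raise ValueError(f"{locus}: flank {flank} exceeds sequence bounds")
    fwd = empty_seq[fwd_start : fwd_start + primer_len]
    rev = reverse_complement(empty_seq[rev_end - primer_len : rev_end])
    return PrimerPair(locus=locus, fwd=fwd, rev=rev, max_mismatch=max_mismatch)


def genotype_panel(
    genotypes_truth: pd.DataFrame,
    empty_seqs: dict[str, str],
    filled_seqs: dict[str, str],
    primers: dict[str, PrimerPair],
    tol: int = 10,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> pd.DataFrame:
    """In-silico genotype every individual in a panel.

    ``genotypes_truth`` supplies each individual's true diploid state per
    locus (which haplotype sequences to amplify); the returned table holds
    the *called* genotypes in the standard genotype-table schema, with
    undetermined calls as missing.
    """
    hap_bands: dict[tuple[str, bool], list[int]] = {}
    expected: dict[str, tuple[int, int]] = {}
    for locus, pair in primers.items():
        empty_bands = predict_amplicons(empty_seqs[locus], pair, max_product)
        filled_bands = predict_amplicons(filled_seqs[locus], pair, max_product)
        hap_bands[(locus, False)] = empty_bands
        hap_bands[(locus, True)] = filled_bands
        if len(empty_bands) != 1 or len(filled_bands) != 1:
            raise ValueError(f"{locus}: primer pair does not yield a single band per allele")
        expected[locus] = (empty_bands[0], filled_bands[0])

    rows = []
    for rec in genotypes_truth.itertuples(index=False):
        if rec.genotype is None:
            rows.append((rec.individual_id, rec.breed, rec.locus, None))
            continue
        filled_haps = {"+/+": (True, True), "+/-": (True, False), "-/-": (False, False)}[rec.genotype]
        h1 = hap_bands[(rec.locus, filled_haps[0])]
        h2 = hap_bands[(rec.locus, filled_haps[1])]
        empty_size, filled_size = expected[rec.locus]
        call = call_genotype(
            h1, h2, empty_size, filled_size, tol=tol,
            individual_id=rec.individual_id, locus=rec.locus,
        )
        rows.append((rec.individual_id, rec.breed, rec.locus, call.genotype))
    return pd.DataFrame(rows, columns=["individual_id", "breed", "locus", "genotype"])
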