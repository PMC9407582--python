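"""Indel structural-variant discovery from pairwise locus alignments.

Orthologous locus sequences from different assemblies are globally aligned
against a designated reference assembly under affine-gap scoring; maximal
gap runs are merged into indel events, events >= 50 bp are kept as
candidate retrotransposon insertion polymorphisms, and per-assembly calls
are unified into sites with a filled/empty/unknown presence map.

Coordinates are 1-based inclusive on the reference locus.  A pure
insertion (sequence present in the alternate assembly only) is anchored
*between* reference bases with the convention end = begin - 1.

Scoring convention: a gap of length L costs open + (L - 1) * extend, i.e.
the opening score already pays for the first gapped column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from statistics import median_low
from typing import Mapping, Sequence

from Bio import Align

from .io_formats import SequenceRecord

#: maximum DP matrix size (cells) for full dynamic programming; longer
#: sequence pairs go through anchor-seeded alignment
FULL_DP_CELL_LIMIT = 64_000_000

ANCHOR_K = 31  # seed k-mer size for long-locus alignment


@dataclass(frozen=True)
class Scoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of one locus between two assemblies."""

    ref_id: str
    alt_id: str
    aligned_ref: str
    aligned_alt: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_alt):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class StructuralVariant:
    """An indel >= min length between a reference and alternate assembly.

    ``sv_type`` is relative to the reference: "insertion" means the
    sequence is present in the alternate assembly and absent from the
    reference.  ``presence`` maps assembly -> "filled"/"empty"/"unknown"
    (filled = carries the insertion allele).
    """

    locus: str
    ref_begin: int
    ref_end: int
    sv_type: str  # "insertion" | "deletion"
    length: int
    sv_seq: str
    presence: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sv_type not in ("insertion", "deletion"):
            raise ValueError(f"bad sv_type {self.sv_type!r}")
        if self.length != len(self.sv_seq):
            raise ValueError("length must equal len(sv_seq)")
        if self.ref_begin < 1:
            raise ValueError("ref_begin must be >= 1")

    @property
    def anchor(self) -> int:
        return self.ref_begin


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_locus_pair(
    ref: SequenceRecord,
    alt: SequenceRecord,
    scoring: Scoring = DEFAULT_SCORING,
) -> PairwiseAlignment:
    """Optimal global alignment of one locus between two assemblies.

    Affine-gap scoring (defaults match=+2, mismatch=-3, open=-5,
    extend=-1); the aligner's first optimal alignment is returned, which is
    deterministic for fixed inputs.  Sequence pairs whose DP matrix would
    exceed the memory limit are aligned by anchor seeding: shared unique
    31-mers are chained and full DP is run only between anchors.
    """
    if not ref.seq or not alt.seq:
        raise ValueError("cannot align an empty sequence")
    for rec in (ref, alt):
        if rec.seq.count("N") > 0.10 * len(rec.seq):
            warnings.warn(f"{rec.id} ({rec.assembly}): more than 10% N bases")
    if (len(ref.seq) + 1) * (len(alt.seq) + 1) > FULL_DP_CELL_LIMIT:
        a_ref, a_alt, score = _anchored_align(ref.seq, alt.seq, scoring)
        return PairwiseAlignment(ref.id, alt.id, a_ref, a_alt, score)
    aligner = _make_aligner(scoring)
    aln = aligner.align(ref.seq, alt.seq)[0]
    return PairwiseAlignment(ref.id, alt.id, str(aln[0]), str(aln[1]), float(aln.score))


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] = counts.get(seq[i : i + k], 0) + 1
    first = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if counts[kmer] == 1:
            first[kmer] = i
    return first


def _anchored_align(ref: str, alt: str, scoring: Scoring) -> tuple[str, str, float]:
    """Anchor-seeded global alignment for long loci.

    Shared unique k-mers define collinear anchor points; the segments
    between consecutive anchors are aligned by full DP and stitched.
    """
    ref_kmers = _unique_kmers(ref, ANCHOR_K)
    alt_kmers = _unique_kmers(alt, ANCHOR_K)
    shared = sorted(
        (ref_kmers[k], alt_kmers[k]) for k in ref_kmers.keys() & alt_kmers.keys()
    )
    # longest strictly-increasing chain in alt coordinate (anchors collinear)
    chain: list[tuple[int, int]] = []
    for r, a in shared:
        if not chain or (r >= chain[-1][0] + ANCHOR_K and a >= chain[-1][1] + ANCHOR_K):
            chain.append((r, a))
    if not chain:
        raise ValueError("no shared unique anchors; sequences too divergent for seeded alignment")
    aligner = _make_aligner(scoring)
    parts_ref: list[str] = []
    parts_alt: list[str] = []
    score = 0.0
    pr = pa = 0
    segments = [(r, a, ANCHOR_K) for r, a in chain]
    for r, a, k in segments + [(len(ref), len(alt), 0)]:
        seg_ref, seg_alt = ref[pr:r], alt[pa:a]
        if seg_ref or seg_alt:
            if seg_ref and seg_alt:
                aln = aligner.align(seg_ref, seg_alt)[0]
                parts_ref.append(str(aln[0]))
                parts_alt.append(str(aln[1]))
                score += float(aln.score)
            elif seg_ref:
                parts_ref.append(seg_ref)
                parts_alt.append("-" * len(seg_ref))
                score += scoring.gap_open + (len(seg_ref) - 1) * scoring.gap_extend
            else:
                parts_ref.append("-" * len(seg_alt))
                parts_alt.append(seg_alt)
                score += scoring.gap_open + (len(seg_alt) - 1) * scoring.gap_extend
        if k:
            parts_ref.append(ref[r : r + k])
            parts_alt.append(alt[a : a + k])
            score += k * scoring.match
        pr, pa = r + k, a + k
    return "".join(parts_ref), "".join(parts_alt), score


# ---------------------------------------------------------------------------
# indel extraction


def _gap_runs(aligned: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as (start_col, end_col) half-open, 0-based."""
    runs = []
    start = None
    for i, c in enumerate(aligned):
        if c == "-" and start is None:
            start = i
        elif c != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(aligned)))
    return runs


def extract_indels(
    alignment: PairwiseAlignment,
    min_sv_len: int = 50,
    merge_within: int = 10,
) -> list[StructuralVariant]:
    """Extract indel SVs >= ``min_sv_len`` from a pairwise alignment.

    Maximal gap runs in each aligned string are identified; runs of the
    same type separated by <= ``merge_within`` aligned columns are merged
    (merged length = sum of gap lengths).  Gaps in the reference string are
    insertions relative to the reference, gaps in the alternate string are
    deletions.  Insertions are anchored between reference bases
    (end = begin - 1).
    """
    a_ref, a_alt = alignment.aligned_ref, alignment.aligned_alt
    # reference coordinate before each column: ref_before[i] = number of
    # reference bases strictly before column i
    ref_before = [0] * (len(a_ref) + 1)
    acc = 0
    for i, c in enumerate(a_ref):
        ref_before[i] = acc
        if c != "-":
            acc += 1
        ref_before[i + 1] = acc

    out: list[StructuralVariant] = []
    for sv_type, gapped, other in (
        ("insertion", a_ref, a_alt),
        ("deletion", a_alt, a_ref),
    ):
        runs = _gap_runs(gapped)
        merged: list[list[tuple[int, int]]] = []
        for run in runs:
            if merged and run[0] - merged[-1][-1][1] <= merge_within:
                merged[-1].append(run)
            else:
                merged.append([run])
        for group in merged:
            sv_seq = "".join(other[s:e] for s, e in group).replace("-", "")
            if len(sv_seq) < min_sv_len:
                continue
            first_col = group[0][0]
            last_col = group[-1][1] - 1
            if sv_type == "insertion":
                begin = ref_before[first_col] + 1
                end = begin - 1
            else:
                begin = ref_before[first_col] + 1
                end = ref_before[last_col] + 1
            out.append(
                StructuralVariant(
                    locus=alignment.ref_id,
                    ref_begin=begin,
                    ref_end=end,
                    sv_type=sv_type,
                    length=len(sv_seq),
                    sv_seq=sv_seq,
                )
            )
    out.sort(key=lambda sv: (sv.ref_begin, sv.sv_type))
    return out


# ---------------------------------------------------------------------------
# cross-assembly unification


def unify_svs(
    per_assembly_svs: Mapping[str, Sequence[StructuralVariant]],
    reference: str = "",
    anchor_tol: int = 20,
    len_sim: float = 0.8,
) -> list[StructuralVariant]:
    """Merge per-assembly SV calls into candidate RIP sites.

    SVs of the same type whose reference anchors lie within ``anchor_tol``
    bp and whose lengths agree to at least ``len_sim`` (min/max ratio) are
    one site.  The presence map marks each assembly that reported the event
    as filled (insertion) or empty (deletion); assemblies present in the
    input map but silent at the site get the complementary state, and
    assemblies absent from the map are "unknown".  The reference assembly,
    if named, is empty at insertion sites and filled at deletion sites.
    """
    loci = {sv.locus for svs in per_assembly_svs.values() for sv in svs}
    if len(loci) > 1:
        raise ValueError(f"unify_svs mixes loci: {sorted(loci)}")

    calls = [
        (assembly, sv)
        for assembly, svs in per_assembly_svs.items()
        for sv in svs
    ]
    calls.sort(key=lambda item: (item[1].anchor, item[1].length, item[0]))

    clusters: list[list[tuple[str, StructuralVariant]]] = []
    for assembly, sv in calls:
        placed = False
        for cluster in clusters:
            rep = cluster[0][1]
            if rep.sv_type != sv.sv_type:
                continue
            if abs(rep.anchor - sv.anchor) > anchor_tol:
                continue
            lo, hi = sorted((rep.length, sv.length))
            if lo / hi < len_sim:
                continue
            cluster.append((assembly, sv))
            placed = True
            break
        if not placed:
            clusters.append([(assembly, sv)])

    observed = set(per_assembly_svs.keys())
    sites: list[StructuralVariant] = []
    for cluster in clusters:
        rep = max((sv for _, sv in cluster), key=lambda sv: sv.length)
        carriers = {assembly for assembly, _ in cluster}
        hit_state, silent_state = (
            ("filled", "empty") if rep.sv_type == "insertion" else ("empty", "filled")
        )
        presence = {a: (hit_state if a in carriers else silent_state) for a in observed}
        if reference:
            presence[reference] = silent_state
        anchor = median_low(sorted(sv.anchor for _, sv in cluster))
        shift = anchor - rep.ref_begin
        sites.append(
            replace(
                rep,
                ref_begin=anchor,
                ref_end=rep.ref_end + shift,
                presence=presence,
            )
        )
    sites.sort(key=lambda sv: sv.ref_begin)
    return sites


def discover_panel(
    records: Sequence[SequenceRecord],
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
    min_sv_len: int = 50,
    merge_within: int = 10,
    anchor_tol: int = 20,
    len_sim: float = 0.8,
) -> dict[str, list[StructuralVariant]]:
    """Run pairwise discovery + unification for every locus in a panel.

    ``records`` hold one sequence per (locus id, assembly); the assembly
    named ``reference`` is the alignment target.  Returns locus -> unified
    sites.
    """
    by_locus: dict[str, dict[str, SequenceRecord]] = {}
    for rec in records:
        by_locus.setdefault(rec.id, {})[rec.assembly] = rec
    out: dict[str, list[StructuralVariant]] = {}
    for locus, per_assembly in sorted(by_locus.items()):
        if reference not in per_assembly:
            raise ValueError(f"locus {locus!r}: reference assembly {reference!r} missing")
        ref = per_assembly[reference]
        per_assembly_svs: dict[str, list[StructuralVariant]] = {}
        for assembly, alt in per_assembly.items():
            if assembly == reference:
                continue
            aln = align_locus_pair(ref, alt, scoring)
            per_assembly_svs[assembly] = extract_indels(aln, min_sv_len, merge_within)
        out[locus] = unify_svs(per_assembly_svs, reference, anchor_tol, len_sim)
    return out


def svs_to_rows(sites: Mapping[str, Sequence[StructuralVariant]]) -> list[dict]:
    """Flatten unified sites to TSV-ready rows (one per site)."""
    rows = []
    for locus in sorted(sites):
        for sv in sites[locus]:
            filled = sorted(a for a, s in sv.presence.items() if s == "filled")
            empty = sorted(a for a, s in sv.presence.items() if s == "empty")
            rows.append(
                {
                    "locus": locus,
                    "begin": sv.ref_begin,
                    "end": sv.ref_end,
                    "type": sv.sv_type,
                    "length": sv.length,
                    "filled_assemblies": ",".join(filled),
                    "empty_assemblies": ",".join(empty),
                }
            )
    return rows
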