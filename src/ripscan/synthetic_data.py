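"""Synthetic data generators: repeat libraries, multi-assembly locus panels
with planted retrotransposon insertions, Hardy-Weinberg genotypes, and
reproductive traits with additive genotype effects.

The generators provide exact ground truth for every downstream stage: the
planted insertion interval and family for SV discovery/annotation, the true
genotype per individual for in-silico genotyping and the population
statistics, and the noise-free trait mean per individual for association.

Determinism: every generator draws from its own RNG stream seeded by
``(stream offset, seed)``, so identical inputs give byte-identical outputs
and adding loci to a config does not perturb the genotype draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GENOTYPE_DOSE,
    RepeatConsensus,
    SequenceRecord,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# fixed per-generator stream offsets (see module docstring)
_STREAM_LIBRARY = 11
_STREAM_PANEL = 23
_STREAM_GENOTYPES = 37
_STREAM_TRAITS = 53


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class LocusSpec:
    """One simulated locus: a base sequence plus one planted TE insertion."""

    locus_id: str
    base_length: int
    family: str
    insertion_length: int
    divergence: float = 0.0  # per-base substitution rate of the planted copy
    tsd_length: int = 10  # target-site duplication flanking the insertion
    truncate_5p: int = 0  # optional 5' truncation, mimics partial SINE copies

    def __post_init__(self) -> None:
        if self.insertion_length < 50:
            raise ValueError(
                f"{self.locus_id}: insertion length {self.insertion_length} < 50 bp"
            )
        if not 0.0 <= self.divergence <= 0.2:
            raise ValueError(f"{self.locus_id}: divergence outside [0, 0.2]")
        if not 0 <= self.tsd_length <= 15:
            raise ValueError(f"{self.locus_id}: tsd_length outside [0, 15]")


@dataclass(frozen=True)
class BreedSpec:
    """One breed: insertion-allele frequency per locus and a sample size."""

    breed: str
    freqs: Mapping[str, float]  # locus_id -> insertion allele frequency p
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.breed}: n must be >= 1")
        for locus, p in self.freqs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.breed}/{locus}: p={p} outside [0, 1]")


@dataclass(frozen=True)
class TraitModel:
    """Additive trait model: trait = baseline + sum(effect * dose) + noise.

    ``effects`` maps locus -> {trait: per-allele additive effect}; dose is
    the insertion-allele count 0/1/2.  Litter counts (TNB, NBA) are rounded
    to integers and clipped at 0; NBA is clipped at TNB.
    """

    baselines: Mapping[str, float]  # trait -> baseline mean
    noise_sd: Mapping[str, float]  # trait -> Gaussian noise SD
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    TRAITS = ("TNB", "NBA", "LW")

    def __post_init__(self) -> None:
        for t, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"negative noise SD for {t}")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    loci: Sequence[LocusSpec]
    breeds: Sequence[BreedSpec]
    trait_model: TraitModel
    assemblies: Sequence[str] = ()
    #: locus_id -> assemblies carrying the insertion
    filled_assemblies: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


@dataclass(frozen=True)
class PlantedInsertion:
    """Ground truth for one planted insertion.

    ``begin``/``end`` are 1-based inclusive coordinates of the diverged TE
    copy on the *filled* haplotype; ``insert_after`` is the 1-based base on
    the empty haplotype after which the insertion sits.
    """

    locus_id: str
    family: str
    length: int
    begin: int
    end: int
    insert_after: int
    tsd_length: int
    te_copy: str
    filled_in: tuple[str, ...]


@dataclass(frozen=True)
class TruthSet:
    insertions: Mapping[str, PlantedInsertion]  # locus_id -> truth
    empty_seqs: Mapping[str, str]
    filled_seqs: Mapping[str, str]


# ---------------------------------------------------------------------------
# generators


def simulate_repeat_library(
    seed: int, spec: Sequence[tuple[str, str, int]]
) -> list[RepeatConsensus]:
    """Generate a library of random TE family consensus sequences.

    ``spec`` rows are (family, te_class, length); lengths must be >= 100.
    Deterministic given the seed; distinct families get independent
    sequences (expected identity ~25%).
    """
    rng = _rng(seed, _STREAM_LIBRARY)
    seen: set[str] = set()
    out: list[RepeatConsensus] = []
    for family, te_class, length in spec:
        if family in seen:
            raise ValueError(f"duplicate family name {family!r}")
        seen.add(family)
        out.append(RepeatConsensus(family=family, te_class=te_class, seq=_random_seq(rng, int(length))))
    return out


def _diverge(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at the given per-base rate (no indels)."""
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    for i in np.nonzero(hit)[0]:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_locus_panel(
    config: SimulationConfig, library: Sequence[RepeatConsensus]
) -> tuple[list[SequenceRecord], TruthSet]:
    """Build per-assembly locus sequences with planted TE insertions.

    Assemblies listed in ``config.filled_assemblies[locus]`` carry the base
    locus with a diverged copy of the locus's TE family inserted at a fixed
    internal position and flanked by a duplicated target site of
    ``tsd_length`` bases; all other assemblies carry the bare base locus.
    Record ids are ``{locus_id}``, grouped by the ``assembly`` field.
    """
    families = {c.family: c for c in library}
    rng = _rng(config.seed, _STREAM_PANEL)
    records: list[SequenceRecord] = []
    insertions: dict[str, PlantedInsertion] = {}
    empty_seqs: dict[str, str] = {}
    filled_seqs: dict[str, str] = {}

    for spec in config.loci:
        if spec.family not in families:
            raise ValueError(f"{spec.locus_id}: family {spec.family!r} not in library")
        consensus = families[spec.family].seq
        copy = consensus[: spec.insertion_length]
        if len(copy) < spec.insertion_length:
            copy = copy + _random_seq(rng, spec.insertion_length - len(copy))
        if spec.truncate_5p:
            copy = copy[spec.truncate_5p:]
        copy = _diverge(copy, spec.divergence, rng)

        base = _random_seq(rng, spec.base_length)
        pos = spec.base_length // 2  # insert after this many bases
        if pos + spec.tsd_length > spec.base_length:
            raise ValueError(f"{spec.locus_id}: insertion position outside locus")
        tsd = base[pos : pos + spec.tsd_length]
        filled = base[:pos] + tsd + copy + base[pos:]
        begin = pos + spec.tsd_length + 1
        end = pos + spec.tsd_length + len(copy)
        assert filled[begin - 1 : end] == copy

        filled_in = tuple(config.filled_assemblies.get(spec.locus_id, ()))
        insertions[spec.locus_id] = PlantedInsertion(
            locus_id=spec.locus_id,
            family=spec.family,
            length=len(copy),
            begin=begin,
            end=end,
            insert_after=pos,
            tsd_length=spec.tsd_length,
            te_copy=copy,
            filled_in=filled_in,
        )
        empty_seqs[spec.locus_id] = base
        filled_seqs[spec.locus_id] = filled

        for assembly in config.assemblies:
            seq = filled if assembly in filled_in else base
            records.append(SequenceRecord(id=spec.locus_id, seq=seq, assembly=assembly))

    return records, TruthSet(insertions=insertions, empty_seqs=empty_seqs, filled_seqs=filled_seqs)


def simulate_genotypes(
    p: float,
    n: int,
    seed: int,
    breed: str = "synthetic",
    locus: str = "locus",
    id_offset: int = 0,
) -> pd.DataFrame:
    """Draw n genotypes i.i.d. under Hardy-Weinberg proportions.

    Genotype probabilities are (p^2, 2pq, q^2) for (+/+, +/-, -/-) where p
    is the insertion-allele frequency.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency p={p} outside [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed, _STREAM_GENOTYPES)
    q = 1.0 - p
    probs = np.array([p * p, 2 * p * q, q * q])
    probs = probs / probs.sum()
    draws = rng.choice(3, size=n, p=probs)
    symbols = np.array(["+/+", "+/-", "-/-"])
    return pd.DataFrame(
        {
            "individual_id": [f"{breed}_{i + 1 + id_offset}" for i in range(n)],
            "breed": breed,
            "locus": locus,
            "genotype": symbols[draws],
        }
    )


def simulate_breed_panel(config: SimulationConfig) -> pd.DataFrame:
    """Genotype every configured breed at every configured locus."""
    tables = []
    for b_i, breed in enumerate(config.breeds):
        for l_i, locus in enumerate(config.loci):
            p = breed.freqs.get(locus.locus_id)
            if p is None:
                continue
            tables.append(
                simulate_genotypes(
                    p,
                    breed.n,
                    # distinct deterministic stream per breed x locus
                    seed=config.seed + 1000 * (b_i + 1) + l_i,
                    breed=breed.breed,
                    locus=locus.locus_id,
                )
            )
    return pd.concat(tables, ignore_index=True)


def simulate_traits(
    genotypes: pd.DataFrame, model: TraitModel, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate TNB/NBA/LW for every individual in a genotype table.

    trait = baseline + sum over effect loci of (effect x allele dose) +
    Normal(0, sd).  Litter counts are rounded to integers and clipped at 0;
    NBA is additionally clipped at TNB.  Returns (trait table, noise-free
    per-individual means) — the second frame is the generator's truth.
    """
    rng = _rng(seed, _STREAM_TRAITS)
    doses = genotypes.dropna(subset=["genotype"]).pivot_table(
        index="individual_id",
        columns="locus",
        values="genotype",
        aggfunc=lambda g: GENOTYPE_DOSE[g.iloc[0]],
    )
    for locus in model.effects:
        if locus not in doses.columns:
            raise ValueError(f"effect locus {locus!r} missing from genotype table")
        if doses[locus].isna().any():
            raise ValueError(f"individuals lack a genotype at effect locus {locus!r}")

    individuals = doses.index.to_list()
    n = len(individuals)
    means = pd.DataFrame(index=individuals, columns=list(TraitModel.TRAITS), dtype=float)
    values = {}
    for trait in TraitModel.TRAITS:
        mu = np.full(n, float(model.baselines[trait]))
        for locus, eff in model.effects.items():
            mu = mu + float(eff.get(trait, 0.0)) * doses[locus].to_numpy(dtype=float)
        means[trait] = mu
        noise = rng.normal(0.0, float(model.noise_sd[trait]), size=n)
        values[trait] = mu + noise

    tnb = np.maximum(np.rint(values["TNB"]), 0).astype(int)
    nba = np.minimum(np.maximum(np.rint(values["NBA"]), 0).astype(int), tnb)
    lw = np.maximum(values["LW"], 0.0)
    table = pd.DataFrame(
        {"individual_id": individuals, "TNB": tnb, "NBA": nba, "LW": np.round(lw, 2)}
    )
    truth = means.reset_index(names="individual_id")
    return table, truth


# ---------------------------------------------------------------------------
# bundled default study configuration


#: TE families mirroring the pig repeat classes observed at reproductive loci
DEFAULT_LIBRARY_SPEC = (
    ("SINEA", "SINE", 300),
    ("ERVI", "LTR", 1500),
    ("ERVIII", "LTR", 1200),
    ("LINE1", "LINE", 2000),
)


def default_config(seed: int = 1) -> SimulationConfig:
    """The bundled study configuration.

    Five SINE insertion loci in reproductive candidate genes with insertion
    lengths 281-315 bp, a Large White population of 260 individuals at the
    observed insertion-allele frequencies, two indigenous-breed panels of 24
    individuals, and additive trait effects at CWH43-9 (positive on litter
    size) and IDO2-9 (negative on litter weight).
    """
    loci = (
        LocusSpec("CWH43-9", 2000, "SINEA", 281, divergence=0.05, tsd_length=12),
        LocusSpec("IDO2-9", 2000, "SINEA", 304, divergence=0.05, tsd_length=8),
        LocusSpec("OPN-1", 2000, "SINEA", 312, divergence=0.05, tsd_length=10),
        LocusSpec("PRLR-6", 2000, "SINEA", 290, divergence=0.05, tsd_length=14),
        LocusSpec("VMP1-12", 2000, "SINEA", 315, divergence=0.05, tsd_length=6),
    )
    assemblies = (
        "Sscrofa11.1",
        "Duroc",
        "Berkshire",
        "Pietrain",
        "Landrace",
        "Meishan",
        "Bama",
        "Wuzhishan",
    )
    filled = {
        "CWH43-9": ("Berkshire", "Pietrain", "Bama", "Wuzhishan"),
        "IDO2-9": ("Landrace", "Berkshire"),
        "OPN-1": ("Pietrain",),
        "PRLR-6": ("Bama", "Landrace", "Wuzhishan", "Pietrain"),
        "VMP1-12": ("Duroc", "Berkshire"),
    }
    breeds = (
        BreedSpec(
            "LargeWhite",
            {
                "CWH43-9": 0.4308,
                "IDO2-9": 0.5731,
                "OPN-1": 0.2770,
                "PRLR-6": 0.7849,
                "VMP1-12": 0.2912,
            },
            n=260,
        ),
        BreedSpec(
            "Meishan",
            {"CWH43-9": 1.0, "IDO2-9": 0.125, "OPN-1": 0.0, "PRLR-6": 0.0, "VMP1-12": 0.0},
            n=24,
        ),
        BreedSpec(
            "Erhualian",
            {"CWH43-9": 1.0, "IDO2-9": 0.0417, "OPN-1": 1.0, "PRLR-6": 0.0, "VMP1-12": 0.7917},
            n=24,
        ),
    )
    trait_model = TraitModel(
        baselines={"TNB": 9.7, "NBA": 9.3, "LW": 12.6},
        noise_sd={"TNB": 2.9, "NBA": 2.8, "LW": 3.9},
        effects={
            "CWH43-9": {"TNB": 0.6, "NBA": 0.6, "LW": 0.7},
            "IDO2-9": {"LW": -0.45},
        },
    )
    return SimulationConfig(
        seed=seed,
        loci=loci,
        breeds=breeds,
        trait_model=trait_model,
        assemblies=assemblies,
        filled_assemblies=filled,
    )
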