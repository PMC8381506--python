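"""Synthetic genomes with planted repeats and ground-truth annotation.

The generator emulates the structural archetypes of the four repeat
classes on a uniform ACGT background:

* HSAT2,3-like: tandem arrays of a noisy 5-bp motif (default ATTCC);
  satellites of this class have no consistent repeat-unit reference,
  only motif variations.
* alphoid-like: tandem arrays of a fixed random 171-bp monomer with
  per-copy substitutions (alpha-satellite monomer length).
* Alu-like: dispersed copies of one random ~300-bp consensus with
  substitutions and small indels.
* LINE-1-like: dispersed copies of one random ~6000-bp consensus, each
  optionally 5'-truncated (uniform truncation point), mimicking the
  heterogeneous truncated insertions of real LINE-1 elements.

Repeat families are drawn once (``make_families``) and can be shared
between several simulated genomes, so that training, validation and
test genomes carry copies of the same families — as chromosomes of one
genome do.  Insertions replace background (the genome length is exact),
never overlap and never nest, so the truth intervals are unambiguous.
Everything is determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import DnaSequence
from .io_formats import AnnotationRecord, RepeatClass

__all__ = [
    "SimConfig",
    "RepeatFamilies",
    "SimResult",
    "make_families",
    "simulate_genome",
    "write_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a simulated genome.

    Densities are target fractions of base pairs per class (the planted
    amount lands within a few percent of the target, always inside
    +-20%); ``mutation_rate`` is the per-base substitution probability
    applied to planted copies relative to their consensus and
    ``indel_rate`` the per-base insertion/deletion probability for the
    dispersed (Alu/LINE-like) elements.
    """

    genome_length: int = 200_000
    hsat_density: float = 0.02
    alphoid_density: float = 0.02
    alu_density: float = 0.05
    line_density: float = 0.08
    mutation_rate: float = 0.05
    indel_rate: float = 0.01
    seed: int = 0
    hsat_motif: str = "ATTCC"
    alphoid_monomer_length: int = 171
    alu_length: int = 300
    line_length: int = 6000
    line_truncation_prob: float = 0.5

    def __post_init__(self) -> None:
        densities = (
            self.hsat_density,
            self.alphoid_density,
            self.alu_density,
            self.line_density,
        )
        if any(d < 0 for d in densities) or sum(densities) >= 1.0:
            raise ValueError("per-class densities must be >= 0 and sum to < 1")
        if not (0 <= self.mutation_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("mutation and indel rates must be in [0, 1)")

    def density(self, repeat_class: RepeatClass) -> float:
        return {
            RepeatClass.HSAT23: self.hsat_density,
            RepeatClass.ALPHOID: self.alphoid_density,
            RepeatClass.ALU: self.alu_density,
            RepeatClass.LINE1: self.line_density,
        }[repeat_class]


@dataclass(frozen=True)
class RepeatFamilies:
    """The consensus sequences shared by all genomes of one simulation."""

    hsat_motif: str
    alphoid_monomer: str
    alu_consensus: str
    line_consensus: str


@dataclass(frozen=True)
class SimResult:
    sequence: DnaSequence
    truth: list[AnnotationRecord]
    provenance: list[dict] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def make_families(config: SimConfig, rng: np.random.Generator | None = None) -> RepeatFamilies:
    """Draw the per-simulation consensus sequences."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return RepeatFamilies(
        hsat_motif=config.hsat_motif,
        alphoid_monomer=_random_sequence(rng, config.alphoid_monomer_length),
        alu_consensus=_random_sequence(rng, config.alu_length),
        line_consensus=_random_sequence(rng, config.line_length),
    )


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    if rate == 0 or not seq:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), len(hits)


def _indel(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    if rate == 0 or not seq:
        return seq, 0
    out: list[str] = []
    n_events = 0
    for base in seq:
        u = rng.random()
        if u < rate / 2:  # deletion
            n_events += 1
            continue
        if u < rate:  # insertion before the base
            out.append(_BASES[rng.integers(0, 4)].tobytes().decode())
            n_events += 1
        out.append(base)
    return "".join(out), n_events


def _tandem_elements(rng, consensus: str, target_bp: int, mutation_rate: float,
                     archetype: str, copies_range: tuple[int, int]) -> list[dict]:
    """Tandem arrays of >= 3 mutated consensus copies totalling ~target bp."""
    unit = len(consensus)
    elements = []
    remaining = target_bp
    while remaining >= 3 * unit:
        n_copies = int(rng.integers(*copies_range))
        n_copies = max(3, min(n_copies, remaining // unit))
        copies = []
        n_subs = 0
        for _ in range(n_copies):
            copy, subs = _substitute(rng, consensus, mutation_rate)
            copies.append(copy)
            n_subs += subs
        seq = "".join(copies)
        elements.append(
            {"archetype": archetype, "sequence": seq, "consensus": archetype,
             "n_copies": n_copies, "n_substitutions": n_subs, "n_indels": 0}
        )
        remaining -= len(seq)
    return elements


def _build_elements(config: SimConfig, families: RepeatFamilies,
                    rng: np.random.Generator) -> list[dict]:
    length = config.genome_length
    elements: list[dict] = []

    elements += _tandem_elements(
        rng, families.hsat_motif, int(config.hsat_density * length),
        config.mutation_rate, "HSAT23",
        copies_range=(60, 300),  # 300-1500 bp arrays of the 5-bp motif
    )
    elements += _tandem_elements(
        rng, families.alphoid_monomer, int(config.alphoid_density * length),
        config.mutation_rate, "ALPHOID",
        copies_range=(3, 13),  # 3-12 monomers per array
    )

    remaining = int(config.alu_density * length)
    while remaining >= config.alu_length:
        seq, n_subs = _substitute(rng, families.alu_consensus, config.mutation_rate)
        seq, n_indels = _indel(rng, seq, config.indel_rate)
        elements.append(
            {"archetype": "ALU", "sequence": seq, "consensus": "ALU",
             "n_copies": 1, "n_substitutions": n_subs, "n_indels": n_indels}
        )
        remaining -= len(seq)

    min_piece = min(300, config.line_length)
    remaining = int(config.line_density * length)
    while remaining >= min_piece:
        if rng.random() < config.line_truncation_prob:
            keep = int(rng.integers(min_piece, config.line_length + 1))
        else:
            keep = config.line_length
        keep = min(keep, remaining)
        if keep < min_piece:
            break
        consensus_piece = families.line_consensus[-keep:]  # 5' truncation keeps 3' end
        seq, n_subs = _substitute(rng, consensus_piece, config.mutation_rate)
        seq, n_indels = _indel(rng, seq, config.indel_rate)
        elements.append(
            {"archetype": "LINE1", "sequence": seq, "consensus": "LINE1",
             "truncated_to": keep, "n_copies": 1,
             "n_substitutions": n_subs, "n_indels": n_indels}
        )
        remaining -= keep
    return elements


def _place(elements: list[dict], length: int, rng: np.random.Generator,
           gap: int = 10, max_attempts: int = 2000) -> list[tuple[int, dict]]:
    """Choose non-overlapping loci (uniform, rejection sampling)."""
    placed: list[tuple[int, int]] = []  # (start, end) sorted
    result = []
    order = rng.permutation(len(elements))
    for idx in order:
        element = elements[idx]
        size = len(element["sequence"])
        if size + 2 * gap > length:
            raise ValueError(
                f"element of {size} bp does not fit a genome of {length} bp"
            )
        for _ in range(max_attempts):
            start = int(rng.integers(gap, length - size - gap + 1))
            end = start + size
            if all(end + gap <= s or start >= e + gap for s, e in placed):
                placed.append((start, end))
                result.append((start, element))
                break
        else:
            raise ValueError(
                "could not place all elements without overlap; "
                "densities too high for this genome length"
            )
    return sorted(result, key=lambda item: item[0])


def simulate_genome(
    config: SimConfig, families: RepeatFamilies | None = None,
    sequence_name: str = "chr1",
) -> SimResult:
    """Simulate one genome; pass ``families`` to share repeat families
    between several genomes (train/validation/test)."""
    rng = np.random.default_rng(config.seed)
    if families is None:
        families = make_families(config, rng)
    elements = _build_elements(config, families, rng)
    background = np.frombuffer(
        _random_sequence(rng, config.genome_length).encode(), dtype=np.uint8
    ).copy()
    truth: list[AnnotationRecord] = []
    provenance: list[dict] = []
    for start, element in _place(elements, config.genome_length, rng):
        seq = element["sequence"]
        end = start + len(seq)
        background[start:end] = np.frombuffer(seq.encode(), dtype=np.uint8)
        truth.append(
            AnnotationRecord(
                sequence_name=sequence_name,
                start=start,
                end=end,
                repeat_class=RepeatClass[element["archetype"]],
                source_id=element["consensus"],
            )
        )
        row = {k: v for k, v in element.items() if k != "sequence"}
        row.update(start=start, end=end, length=len(seq))
        provenance.append(row)
    return SimResult(
        sequence=DnaSequence(background.tobytes().decode(), origin=0),
        truth=truth,
        provenance=provenance,
    )


def write_fixture(sim: SimResult, directory: str | Path,
                  sequence_name: str = "chr1") -> dict[str, Path]:
    """Write FASTA + truth BED + provenance TSV; round-trips through
    the readers in :mod:`repgru.io_formats`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "genome.fa",
        "bed": directory / "truth.bed",
        "provenance": directory / "provenance.tsv",
    }
    with open(paths["fasta"], "w") as handle:
        handle.write(f">{sequence_name}\n")
        bases = sim.sequence.bases
        for i in range(0, len(bases), 80):
            handle.write(bases[i : i + 80] + "\n")
    with open(paths["bed"], "w") as handle:
        for record in sim.truth:
            handle.write(
                f"{record.sequence_name}\t{record.start}\t{record.end}"
                f"\t{record.repeat_class.name}\t0\n"
            )
    pd.DataFrame(sim.provenance).to_csv(paths["provenance"], sep="\t", index=False)
    return paths
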