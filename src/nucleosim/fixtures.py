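"""Synthetic test inputs: phased DNA sequences and fragment cohorts.

Generators are seed-deterministic and carry their full specification, so
every generated input is reconstructible from its manifest.  They emulate
the *structure* of real inputs (dinucleotide-phased promoter sequences,
single-cell nucleosomal fragment tables) with known ground truth, not the
composition of any real genome.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhasingSpec",
    "FragmentCohortSpec",
    "generate_sequence",
    "generate_fragment_cohort",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PhasingSpec:
    """Dinucleotide planting: period, class and per-site probability."""

    period_bp: float = 10.0
    dinucleotide: str = "AA"
    strength: float = 0.0  # probability of planting at each periodic site

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("strength must be in [0, 1]")
        if len(self.dinucleotide) != 2:
            raise ValueError("dinucleotide must have length 2")


def generate_sequence(
    length: int,
    phasing: PhasingSpec | None = None,
    seed: int = 0,
) -> str:
    """Random DNA with optional periodic dinucleotide planting.

    Background bases are iid uniform ACGT; with probability ``strength``
    the chosen dinucleotide is written at each position closest to a
    multiple of the period.  ``strength = 0`` returns a pure iid sequence.
    """
    if length < 147:
        raise ValueError("sequence must be at least one footprint (147 bp) long")
    phasing = phasing or PhasingSpec()
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    if phasing.strength > 0:
        sites = np.unique(np.round(
            np.arange(0, length - 1, phasing.period_bp)
        ).astype(int))
        sites = sites[sites < length - 1]
        plant = rng.random(sites.size) < phasing.strength
        for s in sites[plant]:
            seq[s] = phasing.dinucleotide[0]
            seq[s + 1] = phasing.dinucleotide[1]
    return "".join(seq)


@dataclass(frozen=True)
class FragmentCohortSpec:
    """Ground-truth design of a synthetic single-molecule fragment cohort.

    Each molecule carries a nucleosome array whose first (+1) dyad is
    drawn from a normal distribution with per-gene mean (uniform across
    ``plus_one_mean_range``) and standard deviation ``plus_one_sd``;
    downstream nucleosomes follow at ``repeat_length_bp`` spacing.
    Individual nucleosomes drop out with probability ``missing_rate``
    (emulating sparse single-cell coverage) and fragment lengths are drawn
    uniformly from ``fragment_length_range``; a ``contaminant_rate``
    fraction of fragments instead get lengths outside the mono-nucleosome
    band (sub- or di-nucleosomal) and should be removed by filtering.
    """

    n_genes: int = 50
    molecules_per_gene: int = 100
    plus_one_mean_range: tuple[float, float] = (30.0, 120.0)
    plus_one_sd: float = 40.0
    repeat_length_bp: float = 165.0
    downstream_count: int = 6
    missing_rate: float = 0.0
    contaminant_rate: float = 0.0
    fragment_length_range: tuple[int, int] = (140, 180)

    def __post_init__(self) -> None:
        for name in ("missing_rate", "contaminant_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.plus_one_sd < 0:
            raise ValueError("plus_one_sd must be >= 0")

    def manifest(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def generate_fragment_cohort(
    spec: FragmentCohortSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesise a fragment table with known +1 ground truth.

    Returns ``(fragments, truth)``: the fragment table with columns
    gene_id, molecule_id, start, end, and a per-gene truth table with the
    planted +1 mean and sd.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.plus_one_mean_range
    gene_means = rng.uniform(lo, hi, size=spec.n_genes)
    rows = []
    truth_rows = []
    for g in range(spec.n_genes):
        gene_id = f"gene{g:04d}"
        truth_rows.append({
            "gene_id": gene_id,
            "true_plus_one_mean": gene_means[g],
            "true_plus_one_sd": spec.plus_one_sd,
        })
        for m in range(spec.molecules_per_gene):
            mol_id = f"{gene_id}:mol{m:04d}"
            first = gene_means[g] + rng.normal(0.0, spec.plus_one_sd)
            dyads = first + spec.repeat_length_bp * np.arange(
                spec.downstream_count + 1
            )
            keep = rng.random(dyads.size) >= spec.missing_rate
            for dyad in dyads[keep]:
                if rng.random() < spec.contaminant_rate:
                    # sub- or di-nucleosomal contaminant length
                    flen = int(rng.choice([rng.integers(60, 130),
                                           rng.integers(200, 320)]))
                else:
                    flen = int(rng.integers(spec.fragment_length_range[0],
                                            spec.fragment_length_range[1] + 1))
                start = int(round(dyad)) - flen // 2
                rows.append((gene_id, mol_id, start, start + flen))
    fragments = pd.DataFrame(rows, columns=["gene_id", "molecule_id", "start", "end"])
    truth = pd.DataFrame(truth_rows)
    return fragments, truth
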