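"""Per-species genetic diversity and genetic distance statistics.

Nucleotide diversity is the heterozygous SNV count divided by genome size
(per-bp heterozygosity). Genetic distance is the homozygous-alternate SNV
count divided by genome size and by divergence time in MYA (per-bp per-MYA
accumulation of fixed differences from the family reference). Both are
restricted to autosomes; "genome size" defaults to the summed autosomal
contig lengths unless overridden in configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_io import HET, HOM_ALT, ContigTable, SpeciesCallSet

__all__ = ["SpeciesDiversity", "FamilyDiversitySummary", "species_diversity", "family_summary"]


@dataclass(frozen=True)
class SpeciesDiversity:
    species_id: str
    n_hom_snv: int
    n_het_snv: int
    genome_size: int
    divergence_mya: float

    @property
    def nucleotide_diversity(self) -> float:
        return self.n_het_snv / self.genome_size

    @property
    def genetic_distance(self) -> float:
        return self.n_hom_snv / self.genome_size / self.divergence_mya


@dataclass(frozen=True)
class FamilyDiversitySummary:
    family_id: str
    divergence_mya: float
    species: tuple[SpeciesDiversity, ...]

    @property
    def mean_diversity(self) -> float:
        return sum(s.nucleotide_diversity for s in self.species) / len(self.species)

    @property
    def mean_distance(self) -> float:
        return sum(s.genetic_distance for s in self.species) / len(self.species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": [s.species_id for s in self.species],
                "n_hom_snv": [s.n_hom_snv for s in self.species],
                "n_het_snv": [s.n_het_snv for s in self.species],
                "genome_size": [s.genome_size for s in self.species],
                "divergence_mya": [s.divergence_mya for s in self.species],
                "diversity": [s.nucleotide_diversity for s in self.species],
                "distance": [s.genetic_distance for s in self.species],
            }
        )


def species_diversity(
    callset: SpeciesCallSet,
    genome_size: int,
    divergence_mya: float,
    contigs: ContigTable | None = None,
) -> SpeciesDiversity:
    """Diversity/distance statistics for one species' call set.

    Counts SNVs only (heterozygous indels do not enter the diversity
    numerator). When a contig table is given, counting is restricted to its
    autosomes; otherwise every contig in the call set contributes.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if divergence_mya <= 0:
        raise ValueError("divergence_mya must be positive")
    autosomes = contigs.autosome_names if contigs is not None else None
    return SpeciesDiversity(
        species_id=callset.species_id,
        n_hom_snv=callset.count_snvs(HOM_ALT, autosomes),
        n_het_snv=callset.count_snvs(HET, autosomes),
        genome_size=int(genome_size),
        divergence_mya=float(divergence_mya),
    )


def family_summary(
    species: list[SpeciesDiversity], family_id: str = "family", divergence_mya: float = 0.0
) -> FamilyDiversitySummary:
    """Arithmetic-mean family summary over member species."""
    if not species:
        raise ValueError("family has no species")
    return FamilyDiversitySummary(
        family_id=family_id, divergence_mya=divergence_mya, species=tuple(species)
    )
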