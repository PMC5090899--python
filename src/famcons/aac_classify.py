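"""Classification of amino-acid changes (AACs) across diet groups.

Three definitions, applied per alignment column of a one-sequence-per-
species protein alignment:

* group-specific AAC — every target species carries the same residue and no
  background species carries it;
* convergent AAC — several independent target clades are jointly unanimous
  for a residue absent from the background (the classic example being a
  residue shared by all carnivoran lineages but no omnivore/herbivore);
* group-specific function-altered gene — every species of a diet group has
  at least one AAC flagged as function-altering by an upstream effect
  predictor (PolyPhen-2/PROVEAN-style calls are consumed as an input table,
  never recomputed), while no species of the other diet groups has any.

Columns containing a gap or an ambiguity code in any involved species are
skipped: the definitions presume an aligned residue in every species.
Positions are 0-based internally and 1-based in reports ("269th residue").
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinAlignmentSet",
    "AacRecord",
    "read_alignment_fasta",
    "read_flag_table",
    "group_specific_aacs",
    "convergent_aacs",
    "function_altered_genes",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: effect-predictor verdicts that set the function-altering flag
DAMAGING_CALLS = {"deleterious", "damaging", "probably_damaging", "possibly_damaging"}


@dataclass
class ProteinAlignmentSet:
    """One gene's aligned protein sequences, one per species."""

    gene_id: str
    sequences: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths {lengths}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def column(self, index: int, species: list[str]) -> list[str]:
        return [self.sequences[s][index].upper() for s in species]

    def require_species(self, species) -> None:
        absent = sorted(set(species) - set(self.sequences))
        if absent:
            raise KeyError(f"{self.gene_id}: species missing from alignment: {absent}")


@dataclass(frozen=True)
class AacRecord:
    """One reported alignment column.

    ``column_index`` is 0-based; ``position`` (reports) is 1-based.
    ``function_altering`` maps species to the upstream predictor flag and is
    populated when a flag table is joined in.
    """

    gene_id: str
    column_index: int
    target_residue: str
    background_residues: tuple[str, ...]
    is_convergent: bool = False
    function_altering: dict = field(default_factory=dict, compare=False, hash=False)

    @property
    def position(self) -> int:
        return self.column_index + 1


def read_alignment_fasta(path: str | Path, gene_id: str | None = None) -> ProteinAlignmentSet:
    """Read an aligned FASTA (headers = species ids) into an alignment set."""
    sequences: dict[str, str] = {}
    name, chunks = None, []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                sequences[name] = "".join(chunks)
            name = line[1:].split()[0]
            if name in sequences:
                raise ValueError(f"{path}: duplicate species {name!r}")
            chunks = []
        elif name is not None:
            chunks.append(line.strip())
    if name is not None:
        sequences[name] = "".join(chunks)
    gid = gene_id or Path(path).stem
    return ProteinAlignmentSet(gene_id=gid, sequences=sequences)


def read_flag_table(path: str | Path) -> pd.DataFrame:
    """Read the function-altering-call TSV: gene_id, column_1based, species_id, tool, call."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "species_id": str, "tool": str, "call": str})
    required = {"gene_id", "column_1based", "species_id", "tool", "call"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def _usable_column(residues: list[str]) -> bool:
    return all(r in STANDARD_RESIDUES for r in residues)


def group_specific_aacs(
    aln: ProteinAlignmentSet,
    targets: set[str] | list[str],
    backgrounds: set[str] | list[str],
) -> list[AacRecord]:
    """Columns where all targets share a residue absent from every background."""
    targets, backgrounds = sorted(set(targets)), sorted(set(backgrounds))
    if not targets or not backgrounds:
        raise ValueError("targets and backgrounds must be non-empty")
    if set(targets) & set(backgrounds):
        raise ValueError("targets and backgrounds overlap")
    aln.require_species(targets + backgrounds)
    out = []
    for i in range(aln.length):
        t = aln.column(i, targets)
        b = aln.column(i, backgrounds)
        if not _usable_column(t + b):
            continue
        if len(set(t)) == 1 and t[0] not in b:
            out.append(
                AacRecord(
                    gene_id=aln.gene_id,
                    column_index=i,
                    target_residue=t[0],
                    background_residues=tuple(b),
                )
            )
    return out


def convergent_aacs(
    aln: ProteinAlignmentSet,
    clades: list[set[str] | list[str]],
    backgrounds: set[str] | list[str],
    require_absent_in_background: bool = True,
) -> list[AacRecord]:
    """Columns unanimously shared across >= 2 independent target clades.

    By default the shared residue must also be absent from every background
    species (the stricter reading); ``require_absent_in_background=False``
    relaxes to unanimity among the clades only.
    """
    clades = [sorted(set(c)) for c in clades]
    if len(clades) < 2:
        raise ValueError("need at least two target clades")
    seen: Counter = Counter()
    for c in clades:
        seen.update(c)
    if any(v > 1 for v in seen.values()):
        raise ValueError("clades must be pairwise disjoint")
    backgrounds = sorted(set(backgrounds))
    all_targets = sorted(seen)
    aln.require_species(all_targets + backgrounds)
    out = []
    for i in range(aln.length):
        t = aln.column(i, all_targets)
        b = aln.column(i, backgrounds)
        if not _usable_column(t + b):
            continue
        if len(set(t)) != 1:
            continue
        if require_absent_in_background and t[0] in b:
            continue
        out.append(
            AacRecord(
                gene_id=aln.gene_id,
                column_index=i,
                target_residue=t[0],
                background_residues=tuple(b),
                is_convergent=True,
            )
        )
    return out


def function_altered_genes(
    flags: pd.DataFrame,
    group: set[str] | list[str],
    other_diet_species: set[str] | list[str],
) -> set[str]:
    """Genes function-altered in every group species and in no other-diet species.

    ``flags`` is the upstream predictor table (see :func:`read_flag_table`);
    any damaging/deleterious call from either tool marks a (gene, species)
    pair as flagged.
    """
    group, others = set(group), set(other_diet_species)
    if not group:
        raise ValueError("group must be non-empty")
    damaging = flags[flags["call"].str.lower().isin(DAMAGING_CALLS)]
    out = set()
    for gene, sub in damaging.groupby("gene_id"):
        species = set(sub["species_id"])
        if group <= species and not (species & others):
            out.add(gene)
    return out
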