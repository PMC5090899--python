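"""Readers and writers for the standard formats the pipeline touches.

Everything is normalized into a single internal convention on the way in:
0-based half-open coordinates, per-contig numpy interval arrays for masks,
and a pandas DataFrame of variant records per species. VCF input (1-based)
and BED input (already 0-based half-open) both land in that convention.

Variant semantics follow the downstream scan's needs only: a record is kept
when the sample genotype carries at least one non-reference allele; two
identical non-reference alleles are ``HOM_ALT``, two different called
alleles are ``HET`` (whichever alleles they are); a call involving any
allele of length != 1 is an ``INDEL``, otherwise ``SNV``. Missing genotypes
are not calls — coverage is the mask's job, not the VCF's.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import intervals as iv

logger = logging.getLogger(__name__)

HET = "HET"
HOM_ALT = "HOM_ALT"
SNV = "SNV"
INDEL = "INDEL"

#: Contig names treated as non-autosomal by default: sex chromosomes,
#: mitochondrion, and common unplaced-scaffold prefixes.
DEFAULT_NON_AUTOSOME = re.compile(
    r"(?i)^(chr)?(x|y|z|w|m|mt)$|^(chr)?un|random$|alt$|scaffold"
)


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# contig table


@dataclass(frozen=True)
class ContigTable:
    """Reference contigs with lengths and an autosome flag.

    The autosome flag gates every downstream computation: windows are only
    enumerated, and diversity denominators only accumulated, on autosomes.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    is_autosome: tuple[bool, ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise FormatError("duplicate contig names")
        if any(l <= 0 for l in self.lengths):
            raise FormatError("contig lengths must be positive")

    def length_of(self, name: str) -> int:
        return self.lengths[self.names.index(name)]

    def autosomes(self) -> list[tuple[str, int]]:
        return [
            (n, l)
            for n, l, a in zip(self.names, self.lengths, self.is_autosome)
            if a
        ]

    @property
    def autosome_names(self) -> set[str]:
        return {n for n, _ in self.autosomes()}

    @property
    def autosome_length(self) -> int:
        return sum(l for _, l in self.autosomes())


def read_contig_table(
    path: str | Path, non_autosome_pattern: str | re.Pattern | None = None
) -> ContigTable:
    """Read a contig length table (FASTA ``.fai`` dialect accepted).

    Only the first two whitespace-separated columns (name, length) are used;
    extra ``.fai`` columns are ignored. Autosome flags come from a name
    pattern (default: X/Y/MT and unplaced-scaffold names are excluded).
    """
    pattern = (
        re.compile(non_autosome_pattern)
        if isinstance(non_autosome_pattern, str)
        else (non_autosome_pattern or DEFAULT_NON_AUTOSOME)
    )
    names: list[str] = []
    lengths: list[int] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{i}: expected at least 2 columns")
        name, length_s = parts[0], parts[1]
        try:
            length = int(length_s)
        except ValueError:
            raise FormatError(f"{path}:{i}: non-integer length {length_s!r}") from None
        if name in names:
            raise FormatError(f"{path}:{i}: duplicate contig {name!r}")
        names.append(name)
        lengths.append(length)
    is_auto = tuple(not pattern.search(n) for n in names)
    return ContigTable(tuple(names), tuple(lengths), is_auto)


# ---------------------------------------------------------------------------
# species call sets


@dataclass
class SpeciesCallSet:
    """One species' variant calls plus its callable-region mask.

    ``variants`` columns: contig (str), pos (int, 0-based), zygosity
    (HET/HOM_ALT), var_class (SNV/INDEL), alt (str; the called non-reference
    allele, informational). ``mask`` maps contig -> normalized (n,2) interval
    array; ``None`` means "no mask supplied": the whole contig is callable.
    """

    species_id: str
    variants: pd.DataFrame
    mask: dict[str, np.ndarray] | None = None
    n_skipped_no_gt: int = 0

    def het_positions(self, contig: str, include_indels: bool = False) -> np.ndarray:
        return self._positions(contig, HET, include_indels)

    def hom_alt_positions(self, contig: str, include_indels: bool = False) -> np.ndarray:
        return self._positions(contig, HOM_ALT, include_indels)

    def _positions(self, contig, zygosity, include_indels):
        v = self.variants
        sel = (v["contig"] == contig) & (v["zygosity"] == zygosity)
        if not include_indels:
            sel &= v["var_class"] == SNV
        return v.loc[sel, "pos"].to_numpy(dtype=np.int64)

    def hom_alt_records(self, contig: str) -> pd.DataFrame:
        v = self.variants
        return v[(v["contig"] == contig) & (v["zygosity"] == HOM_ALT)]

    def mask_bool(self, contig: str, length: int) -> np.ndarray:
        """Callable indicator over [0, length) for one contig."""
        if self.mask is None:
            logger.warning(
                "%s: no callable mask supplied; treating contig %s as fully callable",
                self.species_id,
                contig,
            )
            return np.ones(length, dtype=bool)
        return iv.to_bool(self.mask.get(contig, np.zeros((0, 2), np.int64)), length)

    def count_snvs(self, zygosity: str, contigs: set[str] | None = None) -> int:
        v = self.variants
        sel = (v["zygosity"] == zygosity) & (v["var_class"] == SNV)
        if contigs is not None:
            sel &= v["contig"].isin(contigs)
        return int(sel.sum())

    def validate_against(self, contigs: ContigTable) -> None:
        lengths = dict(zip(contigs.names, contigs.lengths))
        for contig, grp in self.variants.groupby("contig", sort=False):
            if contig not in lengths:
                raise FormatError(
                    f"{self.species_id}: variant contig {contig!r} not in contig table"
                )
            if int(grp["pos"].max()) >= lengths[contig] or int(grp["pos"].min()) < 0:
                raise FormatError(
                    f"{self.species_id}: variant position outside contig {contig!r}"
                )


_VARIANT_COLUMNS = ["contig", "pos", "zygosity", "var_class", "alt"]


def empty_variants() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "zygosity": pd.Series(dtype=str),
            "var_class": pd.Series(dtype=str),
            "alt": pd.Series(dtype=str),
        }
    )


def read_variants(path: str | Path, sample: str) -> SpeciesCallSet:
    """Read one sample's calls from a VCF into a :class:`SpeciesCallSet`.

    Positions are converted from VCF's 1-based to 0-based. Records whose
    genotype for the sample is missing are skipped and counted; homozygous
    reference genotypes produce no record.
    """
    vcf = VCF(str(path))
    if sample not in vcf.samples:
        raise ValueError(f"sample {sample!r} not in {path} (has {vcf.samples})")
    si = vcf.samples.index(sample)

    rows: list[tuple] = []
    n_skipped = 0
    for rec in vcf:
        gt = rec.genotypes[si]
        alleles = [a for a in gt[:-1] if isinstance(a, int)]
        if len(alleles) < 2 or any(a < 0 for a in alleles):
            n_skipped += 1
            continue
        a1, a2 = alleles[0], alleles[1]
        if a1 == 0 and a2 == 0:
            continue
        all_alleles = [rec.REF] + list(rec.ALT)
        called = {all_alleles[a1], all_alleles[a2], rec.REF}
        var_class = INDEL if any(len(a) != 1 for a in called) else SNV
        if a1 == a2:
            zyg, alt = HOM_ALT, all_alleles[a1]
        else:
            zyg = HET
            alt = all_alleles[a2] if a2 != 0 else all_alleles[a1]
        rows.append((rec.CHROM, rec.POS - 1, zyg, var_class, alt))
    if n_skipped:
        logger.info("%s: skipped %d records with missing GT", sample, n_skipped)
    df = (
        pd.DataFrame(rows, columns=_VARIANT_COLUMNS)
        if rows
        else empty_variants()
    )
    return SpeciesCallSet(species_id=sample, variants=df, n_skipped_no_gt=n_skipped)


# ---------------------------------------------------------------------------
# BED masks / intervals


def read_mask(path: str | Path) -> dict[str, np.ndarray]:
    """Read a BED3 file into per-contig normalized interval arrays."""
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{i}: expected 3 BED columns")
        contig = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise FormatError(f"{path}:{i}: non-integer coordinates") from None
        if start >= end:
            raise FormatError(f"{path}:{i}: start {start} >= end {end}")
        per_contig.setdefault(contig, []).append((start, end))
    return {c: iv.merge(ints) for c, ints in per_contig.items()}


def write_intervals(intervals: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-contig intervals as BED3 (contigs in insertion order)."""
    with open(path, "w") as fh:
        for contig in intervals:
            arr = np.asarray(intervals[contig], dtype=np.int64).reshape(-1, 2)
            for s, e in arr:
                fh.write(f"{contig}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# gene tables


@dataclass
class GeneTable:
    """Gene intervals on one family's reference.

    ``symbol`` is the cross-family key used to compare gene content between
    families whose coordinates live on different references; it defaults to
    ``gene_id`` when the input table has no symbol column.
    """

    genes: pd.DataFrame  # columns: gene_id, contig, start, end, symbol
    n_missing_key: int = 0

    def __post_init__(self):
        if self.genes["gene_id"].duplicated().any():
            raise FormatError("duplicate gene_id in gene table")
        if (self.genes["start"] >= self.genes["end"]).any():
            raise FormatError("gene with start >= end")


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a TSV gene table: gene_id, contig, start, end[, symbol].

    Genes with an empty cross-family symbol are dropped (counted and
    logged); coordinates are 0-based half-open as in BED.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str})
    required = {"gene_id", "contig", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "symbol" not in df.columns:
        df["symbol"] = df["gene_id"]
    bad = df["symbol"].isna() | (df["symbol"].astype(str).str.strip() == "")
    n_missing = int(bad.sum())
    if n_missing:
        logger.info("%s: dropped %d genes without a cross-family symbol", path, n_missing)
    df = df[~bad].reset_index(drop=True)
    return GeneTable(genes=df, n_missing_key=n_missing)
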