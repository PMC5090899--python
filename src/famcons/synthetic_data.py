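"""Synthetic multi-species panels with planted signal, plus truth scoring.

Two generators:

* :func:`simulate_panel` — per-species variant call sets against a shared
  reference. Every site draws independently (no linkage; the scan statistic
  only consumes per-position zygosity): heterozygous with rate *h*,
  homozygous-alternate with rate *q*, reference otherwise. Inside planted
  intervals the heterozygous rate is suppressed to ``h * f`` jointly in all
  species, emulating family-shared conserved regions. Callable masks drop a
  fixed fraction of fixed-size chunks per species.
* :func:`simulate_protein_panel` — per-gene protein alignments over diet
  groups with planted group-specific columns, convergent columns, and
  function-altered genes, plus the predictor flag table.

All generators are pure functions of (seed, parameters): reruns are
byte-identical, and every emitted file parses back through
:mod:`famcons.genome_io`. Truth objects record exactly what was planted so
recovery can be scored at nucleotide / column / gene level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals as iv
from .genome_io import HET, HOM_ALT, SNV, SpeciesCallSet, empty_variants

__all__ = [
    "SimPanelParams",
    "SimTruth",
    "ProteinPanelParams",
    "ProteinTruth",
    "simulate_panel",
    "simulate_protein_panel",
    "score_recovery",
    "evenly_planted_intervals",
]

_ALT_CHOICES = np.array(["C", "G", "T"])


@dataclass(frozen=True)
class SimPanelParams:
    """Parameters of the variant-panel generator.

    Default rates sit in the range family resequencing panels show: per-site
    heterozygosity 2e-3, fixed-difference (hom-alt) rate 5e-3, and 2% of
    each genome masked out in 1-kb chunks. ``planted`` intervals are
    (contig, start, end, f) with suppression factor f in [0, 1).
    """

    n_species: int = 5
    contig_lengths: dict = field(default_factory=lambda: {"chr1": 20_000_000})
    het_rate: float = 0.002
    hom_rate: float = 0.005
    planted: tuple = ()
    mask_dropout: float = 0.02
    dropout_chunk: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.het_rate < 1 and 0 <= self.hom_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.het_rate + self.hom_rate >= 1:
            raise ValueError("per-site het + hom rate must be < 1")
        if not (0 <= self.mask_dropout < 1):
            raise ValueError("mask_dropout must lie in [0, 1)")
        for contig, start, end, f in self.planted:
            if contig not in self.contig_lengths:
                raise ValueError(f"planted interval on unknown contig {contig!r}")
            if not (0 <= start < end <= self.contig_lengths[contig]):
                raise ValueError(f"planted interval [{start},{end}) outside {contig}")
            if not (0 <= f < 1):
                raise ValueError("suppression factor must lie in [0, 1)")


@dataclass
class SimTruth:
    """Planted low-diversity intervals and the generating parameters."""

    planted: dict[str, np.ndarray]  # contig -> merged (n,2) intervals
    params: SimPanelParams

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": {
                    c: np.asarray(a).tolist() for c, a in self.planted.items()
                },
                "params": {
                    "n_species": self.params.n_species,
                    "contig_lengths": dict(self.params.contig_lengths),
                    "het_rate": self.params.het_rate,
                    "hom_rate": self.params.hom_rate,
                    "planted": [list(p) for p in self.params.planted],
                    "mask_dropout": self.params.mask_dropout,
                    "dropout_chunk": self.params.dropout_chunk,
                    "seed": self.params.seed,
                },
            },
            indent=2,
            sort_keys=True,
        )


def evenly_planted_intervals(
    contig: str,
    contig_length: int,
    n: int,
    size: int,
    suppression: float,
    rng: np.random.Generator,
) -> tuple:
    """Place n non-overlapping planted intervals, one per equal-length block."""
    block = contig_length // n
    if size > block:
        raise ValueError("planted intervals would overlap")
    out = []
    for i in range(n):
        start = i * block + int(rng.integers(0, block - size + 1))
        out.append((contig, start, start + size, suppression))
    return tuple(out)


def _segment_rates(length: int, planted: list[tuple[int, int, float]], h: float):
    """Split [0, length) into segments with their effective het rates."""
    edges = [0, length]
    for s, e, _ in planted:
        edges += [s, e]
    edges = sorted(set(edges))
    segs = []
    for s, e in zip(edges[:-1], edges[1:]):
        rate = h
        for ps, pe, f in planted:
            if ps <= s and e <= pe:
                rate = h * f
                break
        segs.append((s, e, rate))
    return segs


def simulate_panel(
    params: SimPanelParams, out_dir: str | Path | None = None
) -> tuple[list[SpeciesCallSet], SimTruth, dict | None]:
    """Draw a multi-species call-set panel; optionally write VCF/BED/.fai files.

    Returns (panel, truth, paths); ``paths`` maps file roles to Paths when
    ``out_dir`` was given, else ``None``. Species are named sp01, sp02, ...
    """
    rng_root = np.random.SeedSequence(params.seed)
    species_seqs = rng_root.spawn(params.n_species)
    species_ids = [f"sp{i + 1:02d}" for i in range(params.n_species)]

    planted_by_contig: dict[str, list[tuple[int, int, float]]] = {
        c: [] for c in params.contig_lengths
    }
    for contig, s, e, f in params.planted:
        planted_by_contig[contig].append((int(s), int(e), float(f)))

    panel: list[SpeciesCallSet] = []
    for sp, seq in zip(species_ids, species_seqs):
        rng = np.random.default_rng(seq)
        rows = []
        mask: dict[str, np.ndarray] = {}
        for contig, length in params.contig_lengths.items():
            for s, e, rate in _segment_rates(length, planted_by_contig[contig], params.het_rate):
                seg_len = e - s
                n_het, n_hom, _ = rng.multinomial(
                    seg_len, [rate, params.hom_rate, 1 - rate - params.hom_rate]
                )
                pos = rng.choice(seg_len, size=n_het + n_hom, replace=False) + s
                alts = _ALT_CHOICES[rng.integers(0, 3, size=n_het + n_hom)]
                for p, a in zip(pos[:n_het], alts[:n_het]):
                    rows.append((contig, int(p), HET, SNV, str(a)))
                for p, a in zip(pos[n_het:], alts[n_het:]):
                    rows.append((contig, int(p), HOM_ALT, SNV, str(a)))
            mask[contig] = _dropout_mask(length, params, rng)
        df = (
            pd.DataFrame(rows, columns=["contig", "pos", "zygosity", "var_class", "alt"])
            if rows
            else empty_variants()
        )
        df = df.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)
        panel.append(SpeciesCallSet(species_id=sp, variants=df, mask=mask))

    truth = SimTruth(
        planted={
            c: iv.merge([(s, e) for s, e, _ in ints]) if ints else np.zeros((0, 2), np.int64)
            for c, ints in planted_by_contig.items()
        },
        params=params,
    )
    paths = _write_panel(panel, truth, params, Path(out_dir)) if out_dir else None
    return panel, truth, paths


def _dropout_mask(length: int, params: SimPanelParams, rng: np.random.Generator) -> np.ndarray:
    chunk = params.dropout_chunk
    n_chunks = length // chunk
    n_drop = int(round(params.mask_dropout * n_chunks))
    if n_drop == 0:
        return np.array([[0, length]], dtype=np.int64)
    dropped = rng.choice(n_chunks, size=n_drop, replace=False)
    keep = np.ones(n_chunks + (length % chunk > 0), dtype=bool)
    keep[dropped] = False
    starts = np.flatnonzero(keep) * chunk
    ends = np.minimum(starts + chunk, length)
    return iv.merge(np.column_stack((starts, ends)))


def _write_panel(panel, truth, params, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    fai = out_dir / "ref.fai"
    with open(fai, "w") as fh:
        for contig, length in params.contig_lengths.items():
            fh.write(f"{contig}\t{length}\n")
    paths["fai"] = fai
    for cs in panel:
        vcf_path = out_dir / f"{cs.species_id}.vcf"
        _write_vcf(cs, params.contig_lengths, vcf_path)
        bed_path = out_dir / f"{cs.species_id}.mask.bed"
        with open(bed_path, "w") as fh:
            for contig, arr in cs.mask.items():
                for s, e in arr:
                    fh.write(f"{contig}\t{s}\t{e}\n")
        paths[f"vcf:{cs.species_id}"] = vcf_path
        paths[f"mask:{cs.species_id}"] = bed_path
    truth_bed = out_dir / "truth.bed"
    with open(truth_bed, "w") as fh:
        for contig, arr in truth.planted.items():
            for s, e in np.asarray(arr).reshape(-1, 2):
                fh.write(f"{contig}\t{s}\t{e}\n")
    paths["truth_bed"] = truth_bed
    truth_json = out_dir / "truth.json"
    truth_json.write_text(truth.to_json() + "\n")
    paths["truth_json"] = truth_json
    return paths


def _write_vcf(cs: SpeciesCallSet, contig_lengths: dict, path: Path) -> None:
    # synthetic sites have no real reference base; REF is written as 'A'
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cs.species_id}\n")
        for row in cs.variants.itertuples(index=False):
            gt = "0/1" if row.zygosity == HET else "1/1"
            fh.write(
                f"{row.contig}\t{row.pos + 1}\t.\tA\t{row.alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )


# ---------------------------------------------------------------------------
# protein panels


@dataclass(frozen=True)
class ProteinPanelParams:
    """Parameters of the protein-alignment generator.

    ``groups`` maps group labels to species lists. The ``target_group``
    (one family) receives planted group-specific columns, with every other
    species as background. Convergent columns are planted jointly across
    the target group plus the singleton clades of ``convergent_group``
    (independent lineages sharing the target diet), with the remaining
    groups as background — so a planted group-specific column is never
    convergent and vice versa. ``noise`` is the per-residue substitution
    rate in unplanted columns.
    """

    n_genes: int = 50
    length: int = 300
    groups: dict = field(
        default_factory=lambda: {
            "felidae": ["cat", "tiger", "leopard"],
            "other_carnivore": ["polar_bear", "killer_whale"],
            "omnivore": ["human", "mouse", "pig"],
            "herbivore": ["cow", "horse", "rabbit"],
        }
    )
    target_group: str = "felidae"
    convergent_group: str = "other_carnivore"
    n_specific_columns: int = 10
    n_convergent_columns: int = 5
    n_function_altered_genes: int = 8
    noise: float = 0.01
    benign_flag_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for g in (self.target_group, self.convergent_group):
            if g not in self.groups:
                raise ValueError(f"group {g!r} not in groups")
        all_sp = [s for g in self.groups.values() for s in g]
        if len(all_sp) != len(set(all_sp)):
            raise ValueError("groups must be disjoint")

    @property
    def target_species(self) -> list[str]:
        return list(self.groups[self.target_group])

    @property
    def specific_backgrounds(self) -> list[str]:
        """Backgrounds for group-specific calls: every non-target species."""
        return [
            s
            for g, members in self.groups.items()
            if g != self.target_group
            for s in members
        ]

    @property
    def effective_clades(self) -> list[list[str]]:
        """Target clades for convergence: the family + each independent lineage."""
        return [list(self.target_species)] + [
            [s] for s in self.groups[self.convergent_group]
        ]

    @property
    def convergent_backgrounds(self) -> list[str]:
        return [
            s
            for g, members in self.groups.items()
            if g not in (self.target_group, self.convergent_group)
            for s in members
        ]

    @property
    def other_diet_species(self) -> list[str]:
        """Species of the *other* diet groups, for function-altered-gene calls."""
        return self.convergent_backgrounds


@dataclass
class ProteinTruth:
    """Planted columns (0-based) and genes, keyed by gene_id."""

    specific_columns: dict[str, list[tuple[int, str]]]
    convergent_columns: dict[str, list[tuple[int, str]]]
    function_altered: set[str]
    params: ProteinPanelParams


_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def simulate_protein_panel(
    params: ProteinPanelParams, out_dir: str | Path | None = None
) -> tuple[dict, pd.DataFrame, ProteinTruth]:
    """Generate per-gene alignments, the predictor flag table, and truth.

    Unplanted columns share one ancestral residue with independent
    per-species substitution noise; planted columns set a target residue
    never used by background species in that column. Near-miss decoys (one
    target species deviating; flag patterns violating the function-altered
    definition) are included so exact recovery is informative.
    """
    from .aac_classify import ProteinAlignmentSet

    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    species = [s for members in params.groups.values() for s in members]
    gene_ids = [f"gene{g + 1:03d}" for g in range(params.n_genes)]

    # assign planted columns to random (gene, column) slots, no collisions
    slots = [(g, c) for g in gene_ids for c in range(params.length)]
    n_planted = params.n_specific_columns + params.n_convergent_columns
    chosen = rng.choice(len(slots), size=n_planted, replace=False)
    specific_slots = [slots[i] for i in chosen[: params.n_specific_columns]]
    convergent_slots = [slots[i] for i in chosen[params.n_specific_columns :]]

    aln_cols: dict[str, np.ndarray] = {}
    for gene in gene_ids:
        base = _RESIDUES[rng.integers(0, 20, size=params.length)]
        cols = np.tile(base, (len(species), 1))
        if params.noise > 0:
            noisy = rng.random(cols.shape) < params.noise
            cols[noisy] = _RESIDUES[rng.integers(0, 20, size=int(noisy.sum()))]
        aln_cols[gene] = cols

    sp_index = {s: i for i, s in enumerate(species)}
    t_rows = [sp_index[s] for s in params.target_species]
    spec_bg_rows = [sp_index[s] for s in params.specific_backgrounds]
    clade_rows = [sp_index[s] for clade in params.effective_clades for s in clade]
    conv_bg_rows = [sp_index[s] for s in params.convergent_backgrounds]

    specific_truth: dict[str, list[tuple[int, str]]] = {}
    for gene, col in specific_slots:
        res, others = _pick_residues(rng)
        aln_cols[gene][t_rows, col] = res
        aln_cols[gene][spec_bg_rows, col] = rng.choice(others, size=len(spec_bg_rows))
        specific_truth.setdefault(gene, []).append((col, res))

    convergent_truth: dict[str, list[tuple[int, str]]] = {}
    for gene, col in convergent_slots:
        res, others = _pick_residues(rng)
        aln_cols[gene][clade_rows, col] = res
        aln_cols[gene][conv_bg_rows, col] = rng.choice(others, size=len(conv_bg_rows))
        convergent_truth.setdefault(gene, []).append((col, res))

    # decoy: a near-specific column where one target species deviates
    decoy_gene = gene_ids[int(rng.integers(0, len(gene_ids)))]
    decoy_col = int(rng.integers(0, params.length))
    if not any(
        (decoy_gene, decoy_col) in lst
        for lst in (specific_slots, convergent_slots)
    ):
        res, others = _pick_residues(rng)
        aln_cols[decoy_gene][t_rows, decoy_col] = res
        aln_cols[decoy_gene][t_rows[0], decoy_col] = others[0]
        aln_cols[decoy_gene][spec_bg_rows, decoy_col] = rng.choice(
            others, size=len(spec_bg_rows)
        )

    alignments = {
        gene: ProteinAlignmentSet(
            gene_id=gene,
            sequences={s: "".join(aln_cols[gene][sp_index[s]]) for s in species},
        )
        for gene in gene_ids
    }

    flags, fa_genes = _plant_flags(params, rng, gene_ids, species)
    truth = ProteinTruth(
        specific_columns=specific_truth,
        convergent_columns=convergent_truth,
        function_altered=fa_genes,
        params=params,
    )
    if out_dir:
        _write_protein_panel(alignments, flags, truth, Path(out_dir))
    return alignments, flags, truth


def _pick_residues(rng: np.random.Generator) -> tuple[str, np.ndarray]:
    """A planted residue plus the pool backgrounds may draw from (excludes it)."""
    i = int(rng.integers(0, 20))
    return str(_RESIDUES[i]), np.delete(_RESIDUES, i)


def _plant_flags(params, rng, gene_ids, species):
    """Flag table with planted function-altered genes and decoy patterns."""
    targets = params.target_species
    others = params.other_diet_species
    n_fa = min(params.n_function_altered_genes, len(gene_ids))
    fa_genes = set(
        gene_ids[i] for i in rng.choice(len(gene_ids), size=n_fa, replace=False)
    )
    rows = []
    for gene in gene_ids:
        if gene in fa_genes:
            for s in targets:
                col = int(rng.integers(0, params.length)) + 1
                tool = "polyphen2" if rng.random() < 0.5 else "provean"
                rows.append((gene, col, s, tool, "deleterious"))
        else:
            # decoys: incomplete target coverage, or contamination of others
            mode = rng.random()
            if mode < 0.3 and len(targets) > 1:
                for s in targets[:-1]:
                    rows.append((gene, int(rng.integers(0, params.length)) + 1, s, "provean", "deleterious"))
            elif mode < 0.5:
                for s in targets:
                    rows.append((gene, int(rng.integers(0, params.length)) + 1, s, "provean", "deleterious"))
                other = others[int(rng.integers(0, len(others)))]
                rows.append((gene, int(rng.integers(0, params.length)) + 1, other, "polyphen2", "damaging"))
        for s in species:  # benign background calls everywhere
            if rng.random() < params.benign_flag_rate:
                rows.append((gene, int(rng.integers(0, params.length)) + 1, s, "provean", "neutral"))
    flags = pd.DataFrame(
        rows, columns=["gene_id", "column_1based", "species_id", "tool", "call"]
    )
    return flags, fa_genes


def _write_protein_panel(alignments, flags, truth, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for gene, aln in alignments.items():
        with open(out_dir / f"{gene}.aln.fasta", "w") as fh:
            for sp, seq in aln.sequences.items():
                fh.write(f">{sp}\n{seq}\n")
    flags.to_csv(out_dir / "flags.tsv", sep="\t", index=False)
    (out_dir / "protein_truth.json").write_text(
        json.dumps(
            {
                "specific_columns": {g: v for g, v in truth.specific_columns.items()},
                "convergent_columns": {g: v for g, v in truth.convergent_columns.items()},
                "function_altered": sorted(truth.function_altered),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


# ---------------------------------------------------------------------------
# recovery scoring


def score_recovery(
    called: dict[str, np.ndarray], truth: dict[str, np.ndarray]
) -> tuple[float, float]:
    """Nucleotide-level (sensitivity, precision) of called vs planted intervals.

    sensitivity = |called & truth| / |truth|; precision = |called & truth| /
    |called|. An empty called set has undefined precision, reported as NaN.
    """
    contigs = set(called) | set(truth)
    inter = tot_called = tot_truth = 0
    empty = np.zeros((0, 2), np.int64)
    for c in contigs:
        a = np.asarray(called.get(c, empty), dtype=np.int64).reshape(-1, 2)
        t = np.asarray(truth.get(c, empty), dtype=np.int64).reshape(-1, 2)
        inter += iv.total_length(iv.intersect(a, t))
        tot_called += iv.total_length(a)
        tot_truth += iv.total_length(t)
    sensitivity = inter / tot_truth if tot_truth else math.nan
    precision = inter / tot_called if tot_called else math.nan
    return sensitivity, precision
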