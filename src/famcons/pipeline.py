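"""Pipeline orchestration: scan, diversity, and AAC stages from one config.

Each stage writes its own tabular outputs under the configured output
directory and contributes a section to a JSON report that also records
every mode flag and threshold in effect, so a run is auditable and
reproducible byte-for-byte from config + inputs (the timestamp lives in a
sidecar, not in the report).
"""

from __future__ import annotations

import datetime
import json
import logging
import traceback
from pathlib import Path

from . import aac_classify as aac
from . import diversity_stats as div
from . import genome_io as gio
from .config import RunConfig
from .conservation_scan import genes_in_regions, scan_family

logger = logging.getLogger(__name__)

__all__ = ["run_all", "run_scan_stage", "run_diversity_stage", "run_aac_stage"]


def _load_family_panel(fam) -> tuple[list[gio.SpeciesCallSet], gio.ContigTable]:
    contigs = gio.read_contig_table(fam.contig_table)
    panel = []
    for sp in fam.species:
        cs = gio.read_variants(sp.vcf, sp.species_id)
        if sp.mask is not None:
            cs.mask = gio.read_mask(sp.mask)
        cs.validate_against(contigs)
        panel.append(cs)
    return panel, contigs


def run_scan_stage(config: RunConfig, out_dir: Path) -> dict:
    report: dict = {"families": {}}
    hcr_sets, gene_tables = {}, {}
    for fam in config.families:
        panel, contigs = _load_family_panel(fam)
        windows, backgrounds, hcrs = scan_family(
            panel, contigs, config.scan, family_id=fam.name
        )
        fam_dir = out_dir / fam.name
        fam_dir.mkdir(parents=True, exist_ok=True)
        windows.to_csv(fam_dir / "windows.tsv", sep="\t", index=False)
        gio.write_intervals(hcrs.intervals, fam_dir / "hcrs.bed")
        summary = {
            "n_windows": int(len(windows)),
            "n_usable": int(windows["usable"].sum()),
            "n_called": int(windows["called"].sum()),
            "hcr_total_bp": hcrs.total_length,
            "hcr_unmerged_bp": hcrs.unmerged_total,
            "metadata": hcrs.metadata,
        }
        (fam_dir / "scan_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        report["families"][fam.name] = summary
        hcr_sets[fam.name] = hcrs
        if fam.genes is not None:
            gene_tables[fam.name] = gio.read_gene_table(fam.genes)
    if gene_tables and set(gene_tables) == set(hcr_sets):
        partition = genes_in_regions(hcr_sets, gene_tables)
        report["genes"] = {
            "per_family": {f: sorted(s) for f, s in partition["per_family"].items()},
            "shared": sorted(partition["shared"]),
            "specific": {f: sorted(s) for f, s in partition["specific"].items()},
        }
        with open(out_dir / "hcr_genes.tsv", "w") as fh:
            fh.write("set\tfamily\tsymbol\n")
            for sym in sorted(partition["shared"]):
                fh.write(f"shared\tall\t{sym}\n")
            for famname, syms in sorted(partition["specific"].items()):
                for sym in sorted(syms):
                    fh.write(f"specific\t{famname}\t{sym}\n")
    return report


def run_diversity_stage(config: RunConfig, out_dir: Path) -> dict:
    report: dict = {}
    rows = []
    for fam in config.families:
        panel, contigs = _load_family_panel(fam)
        genome_size = fam.genome_size or contigs.autosome_length
        stats = []
        for sp_cfg, cs in zip(fam.species, panel):
            stats.append(
                div.species_diversity(
                    cs,
                    genome_size,
                    sp_cfg.divergence_mya or fam.divergence_mya,
                    contigs,
                )
            )
        summary = div.family_summary(stats, family_id=fam.name, divergence_mya=fam.divergence_mya)
        df = summary.to_frame()
        rows.append(df.assign(family=fam.name))
        report[fam.name] = {
            "mean_diversity": summary.mean_diversity,
            "mean_distance": summary.mean_distance,
            "n_species": len(stats),
        }
    if rows:
        import pandas as pd

        pd.concat(rows, ignore_index=True).to_csv(
            out_dir / "diversity.tsv", sep="\t", index=False
        )
    return report


def run_aac_stage(config: RunConfig, out_dir: Path) -> dict:
    cfg = config.aac
    if cfg is None:
        return {}
    targets = set(cfg.groups[cfg.target_group])
    backgrounds = {
        s for g, members in cfg.groups.items() if g != cfg.target_group for s in members
    }
    flags = aac.read_flag_table(cfg.flags)
    records = []
    for path in cfg.alignments:
        aln = aac.read_alignment_fasta(path)
        for rec in aac.group_specific_aacs(aln, targets, backgrounds):
            records.append((rec.gene_id, rec.position, rec.target_residue, "group_specific"))
        if cfg.convergent_clades:
            clade_species = {s for c in cfg.convergent_clades for s in c}
            conv_bg = backgrounds - clade_species
            for rec in aac.convergent_aacs(aln, cfg.convergent_clades, conv_bg):
                records.append((rec.gene_id, rec.position, rec.target_residue, "convergent"))
    other_diet = backgrounds
    if cfg.convergent_clades:
        other_diet = backgrounds - {s for c in cfg.convergent_clades for s in c}
    altered = aac.function_altered_genes(flags, targets, other_diet)
    with open(out_dir / "aac_records.tsv", "w") as fh:
        fh.write("gene_id\tposition\ttarget_residue\tkind\n")
        for gene, pos, res, kind in records:
            fh.write(f"{gene}\t{pos}\t{res}\t{kind}\n")
    with open(out_dir / "function_altered_genes.tsv", "w") as fh:
        fh.write("gene_id\n")
        for gene in sorted(altered):
            fh.write(f"{gene}\n")
    return {
        "n_group_specific": sum(1 for r in records if r[3] == "group_specific"),
        "n_convergent": sum(1 for r in records if r[3] == "convergent"),
        "n_function_altered_genes": len(altered),
    }


def run_all(config: RunConfig) -> dict:
    """Run every configured stage; failures are recorded, later stages still run."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "scan_params": config.scan.metadata(),
        "stages": {},
        "errors": {},
    }
    stages = [
        ("scan", run_scan_stage),
        ("diversity", run_diversity_stage),
    ]
    if config.aac is not None:
        stages.append(("aac", run_aac_stage))
    for name, fn in stages:
        try:
            report["stages"][name] = fn(config, out_dir)
        except Exception as exc:  # keep independent stages running
            logger.error("stage %s failed: %s", name, exc)
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
            logger.debug("%s", traceback.format_exc())
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out_dir / "report.timestamp").write_text(
        datetime.datetime.now().isoformat() + "\n"
    )
    return report
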