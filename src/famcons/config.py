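"""Run configuration: YAML schema, loading, and collected validation.

Validation never fails fast — every problem found (missing file, unknown
key, bad type, a species listed in two families) is collected so one pass
reports them all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .conservation_scan import ScanParams

__all__ = ["SpeciesConfig", "FamilyConfig", "AacConfig", "RunConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass
class SpeciesConfig:
    species_id: str
    vcf: Path
    mask: Path | None
    divergence_mya: float | None = None  # falls back to the family age


@dataclass
class FamilyConfig:
    name: str
    contig_table: Path
    divergence_mya: float
    species: list[SpeciesConfig]
    genes: Path | None = None
    genome_size: int | None = None  # default: summed autosome lengths


@dataclass
class AacConfig:
    alignments: list[Path]
    flags: Path
    groups: dict[str, list[str]]
    target_group: str
    convergent_clades: list[list[str]] = field(default_factory=list)


@dataclass
class RunConfig:
    families: list[FamilyConfig]
    scan: ScanParams
    out_dir: Path
    seed: int = 0
    aac: AacConfig | None = None


_SPECIES_KEYS = {"id", "vcf", "mask", "divergence_mya"}
_FAMILY_KEYS = {"name", "contig_table", "divergence_mya", "species", "genes", "genome_size"}
_SCAN_KEYS = {"bin_size", "step_size", "coverage_fraction", "alpha_adj", "require_reduced", "mode", "include_indels"}
_TOP_KEYS = {"families", "scan", "out_dir", "seed", "aac"}
_AAC_KEYS = {"alignments", "flags", "groups", "target_group", "convergent_clades"}


def _check_path(value, what: str, base: Path, errors: list[str], required=True) -> Path | None:
    if value is None:
        if required:
            errors.append(f"{what}: missing path")
        return None
    p = Path(value)
    if not p.is_absolute():
        p = base / p
    if not p.exists():
        errors.append(f"{what}: file not found: {p}")
        return None
    return p


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` carrying the full list of validation
    failures; paths are resolved relative to the config file's directory.
    """
    path = Path(path)
    errors: list[str] = []
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"not valid YAML: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    base = path.parent

    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown top-level key {key!r}")

    scan = ScanParams()
    scan_raw = raw.get("scan", {}) or {}
    if not isinstance(scan_raw, dict):
        errors.append("scan: must be a mapping")
    else:
        unknown = set(scan_raw) - _SCAN_KEYS
        if unknown:
            errors.append(f"scan: unknown keys {sorted(unknown)}")
        try:
            scan = ScanParams(**{k: v for k, v in scan_raw.items() if k in _SCAN_KEYS})
        except (TypeError, ValueError) as exc:
            errors.append(f"scan: {exc}")

    families: list[FamilyConfig] = []
    seen_species: dict[str, str] = {}
    fams_raw = raw.get("families")
    if not isinstance(fams_raw, list) or not fams_raw:
        errors.append("families: must be a non-empty list")
        fams_raw = []
    for fi, fam in enumerate(fams_raw):
        label = f"families[{fi}]"
        if not isinstance(fam, dict):
            errors.append(f"{label}: must be a mapping")
            continue
        unknown = set(fam) - _FAMILY_KEYS
        if unknown:
            errors.append(f"{label}: unknown keys {sorted(unknown)}")
        name = fam.get("name")
        if not name:
            errors.append(f"{label}: missing name")
            name = f"family{fi}"
        contig_table = _check_path(fam.get("contig_table"), f"{label}.contig_table", base, errors)
        genes = _check_path(fam.get("genes"), f"{label}.genes", base, errors, required=False)
        try:
            divergence = float(fam.get("divergence_mya"))
            if divergence <= 0:
                raise ValueError
        except (TypeError, ValueError):
            errors.append(f"{label}: divergence_mya must be a positive number")
            divergence = 1.0
        genome_size = fam.get("genome_size")
        if genome_size is not None and (not isinstance(genome_size, int) or genome_size <= 0):
            errors.append(f"{label}: genome_size must be a positive integer")
            genome_size = None
        species_list: list[SpeciesConfig] = []
        sp_raw = fam.get("species")
        if not isinstance(sp_raw, list) or not sp_raw:
            errors.append(f"{label}: species must be a non-empty list")
            sp_raw = []
        for si, sp in enumerate(sp_raw):
            slabel = f"{label}.species[{si}]"
            if not isinstance(sp, dict):
                errors.append(f"{slabel}: must be a mapping")
                continue
            unknown = set(sp) - _SPECIES_KEYS
            if unknown:
                errors.append(f"{slabel}: unknown keys {sorted(unknown)}")
            sid = sp.get("id")
            if not sid:
                errors.append(f"{slabel}: missing id")
                continue
            if sid in seen_species:
                errors.append(
                    f"{slabel}: species {sid!r} already belongs to family {seen_species[sid]!r}"
                )
            seen_species[sid] = name
            vcf = _check_path(sp.get("vcf"), f"{slabel}.vcf", base, errors)
            mask = _check_path(sp.get("mask"), f"{slabel}.mask", base, errors, required=False)
            sp_div = sp.get("divergence_mya")
            species_list.append(
                SpeciesConfig(
                    species_id=sid,
                    vcf=vcf,
                    mask=mask,
                    divergence_mya=float(sp_div) if sp_div is not None else None,
                )
            )
        families.append(
            FamilyConfig(
                name=name,
                contig_table=contig_table,
                divergence_mya=divergence,
                species=species_list,
                genes=genes,
                genome_size=genome_size,
            )
        )

    aac = None
    aac_raw = raw.get("aac")
    if aac_raw is not None:
        if not isinstance(aac_raw, dict):
            errors.append("aac: must be a mapping")
        else:
            unknown = set(aac_raw) - _AAC_KEYS
            if unknown:
                errors.append(f"aac: unknown keys {sorted(unknown)}")
            alignments = []
            for ai, a in enumerate(aac_raw.get("alignments", []) or []):
                p = _check_path(a, f"aac.alignments[{ai}]", base, errors)
                if p:
                    alignments.append(p)
            flags = _check_path(aac_raw.get("flags"), "aac.flags", base, errors)
            groups = aac_raw.get("groups") or {}
            if not isinstance(groups, dict) or not groups:
                errors.append("aac.groups: must be a non-empty mapping")
                groups = {}
            members = [s for g in groups.values() for s in g]
            if len(members) != len(set(members)):
                errors.append("aac.groups: groups must be disjoint")
            target = aac_raw.get("target_group")
            if groups and target not in groups:
                errors.append(f"aac.target_group {target!r} not among groups")
            aac = AacConfig(
                alignments=alignments,
                flags=flags,
                groups=groups,
                target_group=target,
                convergent_clades=[list(c) for c in aac_raw.get("convergent_clades", []) or []],
            )

    out_dir = Path(raw.get("out_dir", "famcons_out"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
        seed = 0

    if errors:
        raise ConfigError(errors)
    return RunConfig(families=families, scan=scan, out_dir=out_dir, seed=seed, aac=aac)
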