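"""Family-wide highly conserved region (HCR) detection.

The scan slides a 100-kb window in 10-kb steps along each autosome. Within
a window, a position is *covered* when it is callable in every species of
the family, and a covered position is *non-conserved* when at least one
species carries a heterozygous SNV there (default "zygosity" mode;
homozygous-alternate calls do not break conservation, since a fixed
difference from the reference is still conserved within the family). Each
window with joint coverage above 80% of its size is tested for a reduced
non-conserved fraction against its chromosome's position-wise totals with a
two-sided Fisher's exact test; p-values are Benjamini-Hochberg corrected
once across all usable autosomal windows of a family, and windows with
adjusted P below 1e-4 (and, by default, variation below the chromosome
background) contribute their middle 10 kb to the HCR set. Overlapping or
adjacent tiles are merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from . import intervals as iv
from .genome_io import ContigTable, GeneTable, SpeciesCallSet

logger = logging.getLogger(__name__)

__all__ = [
    "ScanParams",
    "ChromBackground",
    "HcrSet",
    "enumerate_windows",
    "count_window",
    "chrom_background",
    "fisher_exact_2x2",
    "bh_adjust",
    "call_hcrs",
    "scan_family",
    "genes_in_regions",
]


@dataclass(frozen=True)
class ScanParams:
    """Tunable parameters of the window scan.

    bin_size / step_size are the window and slide lengths in bp;
    coverage_fraction is the strict lower bound on joint coverage for a
    window to be tested; alpha_adj is the strict upper bound on the
    BH-adjusted p-value; require_reduced keeps only windows whose
    non-conserved fraction lies below the chromosome background (the scan
    targets *reduced* variation, and the Fisher test alone is two-sided).
    mode is "zygosity" (default) or "identity"; the latter additionally
    breaks conservation where species' homozygous states differ.
    """

    bin_size: int = 100_000
    step_size: int = 10_000
    coverage_fraction: float = 0.8
    alpha_adj: float = 1e-4
    require_reduced: bool = True
    mode: str = "zygosity"
    include_indels: bool = False

    def __post_init__(self):
        if not (0 < self.step_size <= self.bin_size):
            raise ValueError("need 0 < step_size <= bin_size")
        if not (0 < self.coverage_fraction < 1):
            raise ValueError("coverage_fraction must be in (0, 1)")
        if not (0 < self.alpha_adj < 1):
            raise ValueError("alpha_adj must be in (0, 1)")
        if self.mode not in ("zygosity", "identity"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def tile_offset(self) -> int:
        """Start of the middle step_size-long tile within a window."""
        return (self.bin_size - self.step_size) // 2

    def metadata(self) -> dict:
        return {
            "bin_size": self.bin_size,
            "step_size": self.step_size,
            "coverage_fraction": self.coverage_fraction,
            "alpha_adj": self.alpha_adj,
            "require_reduced": self.require_reduced,
            "mode": self.mode,
            "include_indels": self.include_indels,
            "test": "fisher_exact_two_sided",
            "background": "per_chromosome_including_window",
            "bh_scope": "all_usable_autosomal_windows_per_family",
        }


@dataclass(frozen=True)
class ChromBackground:
    """Position-wise conserved/non-conserved totals of one contig."""

    contig: str
    n_conserved_total: int
    n_nonconserved_total: int

    @property
    def nonconserved_fraction(self) -> float:
        tot = self.n_conserved_total + self.n_nonconserved_total
        return self.n_nonconserved_total / tot if tot else float("nan")


@dataclass
class HcrSet:
    """Called HCR intervals (merged middle-tile unions) for one family."""

    family_id: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    #: sum of per-window tiles before merging (overlaps double-counted)
    unmerged_total: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(iv.total_length(a) for a in self.intervals.values())


def enumerate_windows(contig_length: int, params: ScanParams) -> np.ndarray:
    """Start coordinates of all full windows on a contig (may be empty)."""
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    if contig_length < params.bin_size:
        return np.zeros(0, dtype=np.int64)
    n = (contig_length - params.bin_size) // params.step_size + 1
    return np.arange(n, dtype=np.int64) * params.step_size


# ---------------------------------------------------------------------------
# position-wise counting


def _position_arrays(
    contig: str,
    start: int,
    end: int,
    panel: list[SpeciesCallSet],
    params: ScanParams,
) -> tuple[np.ndarray, np.ndarray]:
    """(covered, nonconserved) boolean arrays over [start, end) of a contig.

    covered[i]: position callable in every species. nonconserved[i]: covered
    and carrying variation that breaks family-wide conservation under the
    chosen mode.
    """
    if not panel:
        raise ValueError("empty species panel")
    length = end - start
    covered = np.ones(length, dtype=bool)
    broken = np.zeros(length, dtype=bool)
    for cs in panel:
        covered &= cs.mask_bool(contig, end)[start:end]
        het = cs.het_positions(contig, include_indels=params.include_indels)
        het = het[(het >= start) & (het < end)] - start
        broken[het] = True
    if params.mode == "identity":
        broken |= _identity_breaks(contig, start, end, panel, params)
    return covered, covered & broken


def _identity_breaks(contig, start, end, panel, params) -> np.ndarray:
    """Positions where species' homozygous states disagree.

    A position with any HOM_ALT call is conserved under identity mode only
    when *every* species is HOM_ALT there with the same alternate allele
    (species without a call sit at the reference state).
    """
    frames = []
    for cs in panel:
        recs = cs.hom_alt_records(contig)
        if not params.include_indels:
            recs = recs[recs["var_class"] == "SNV"]
        recs = recs[(recs["pos"] >= start) & (recs["pos"] < end)]
        if len(recs):
            frames.append(recs[["pos", "alt"]])
    out = np.zeros(end - start, dtype=bool)
    if not frames:
        return out
    allhom = pd.concat(frames)
    grouped = allhom.groupby("pos")["alt"]
    counts = grouped.size()
    nuniq = grouped.nunique()
    bad = counts.index[(counts < len(panel)) | (nuniq > 1)]
    out[np.asarray(bad, dtype=np.int64) - start] = True
    return out


def count_window(
    window: tuple[str, int, int],
    panel: list[SpeciesCallSet],
    params: ScanParams | None = None,
) -> tuple[int, int, int]:
    """(n_conserved, n_nonconserved, n_covered) for one window."""
    params = params or ScanParams()
    contig, start, end = window
    covered, noncons = _position_arrays(contig, start, end, panel, params)
    n_covered = int(covered.sum())
    n_noncons = int(noncons.sum())
    return n_covered - n_noncons, n_noncons, n_covered


def chrom_background(
    contig: str,
    contig_length: int,
    panel: list[SpeciesCallSet],
    params: ScanParams | None = None,
) -> ChromBackground:
    """Position-wise totals over a whole contig (= one contig-sized window)."""
    params = params or ScanParams()
    cons, noncons, cov = count_window((contig, 0, contig_length), panel, params)
    if cov == 0:
        logger.warning("contig %s has no jointly covered positions", contig)
    return ChromBackground(contig, cons, noncons)


# ---------------------------------------------------------------------------
# Fisher's exact test

_REL_TOL = 1e-7  # relative tie tolerance when summing tail tables


def _fisher_family_pvalues(m: int, n: int, k: int) -> np.ndarray:
    """Two-sided p for every table with row margins (m, n) and column margin k.

    Returns p[a] for a in [max(0, k-n), min(k, m)], computed in log space in
    one vectorized pass: p(a) = sum of hypergeometric probabilities not
    exceeding prob(a) by more than relative tolerance 1e-7.
    """
    lo, hi = max(0, k - n), min(k, m)
    a = np.arange(lo, hi + 1)
    logw = (
        gammaln(m + 1)
        - gammaln(a + 1)
        - gammaln(m - a + 1)
        + gammaln(n + 1)
        - gammaln(k - a + 1)
        - gammaln(n - k + a + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    order = np.argsort(w, kind="stable")
    w_sorted = w[order]
    csum = np.cumsum(w_sorted)
    # for each observed table, include all tables with w <= w_obs*(1+tol)
    idx = np.searchsorted(w_sorted, w * (1.0 + _REL_TOL), side="right")
    p = csum[idx - 1] / csum[-1]
    return np.minimum(p, 1.0)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test p-value for the table [[a, b], [c, d]].

    Degenerate tables (any zero margin) return 1.0 by convention so a
    genome-wide scan never aborts on an empty window or contig.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    m, n, k = a + b, c + d, a + c
    if m == 0 or n == 0 or k == 0 or b + d == 0:
        return 1.0
    return float(_fisher_family_pvalues(m, n, k)[a - max(0, k - n)])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# scan driver


def scan_contig(
    contig: str,
    contig_length: int,
    panel: list[SpeciesCallSet],
    params: ScanParams,
) -> tuple[pd.DataFrame, ChromBackground]:
    """Window counts plus background for one contig, in one vectorized pass."""
    covered, noncons = _position_arrays(contig, 0, contig_length, panel, params)
    background = ChromBackground(
        contig, int(covered.sum()) - int(noncons.sum()), int(noncons.sum())
    )
    starts = enumerate_windows(contig_length, params)
    ccov = np.concatenate(([0], np.cumsum(covered, dtype=np.int64)))
    cnon = np.concatenate(([0], np.cumsum(noncons, dtype=np.int64)))
    ends = starts + params.bin_size
    n_covered = ccov[ends] - ccov[starts]
    n_noncons = cnon[ends] - cnon[starts]
    usable = n_covered > params.coverage_fraction * params.bin_size
    df = pd.DataFrame(
        {
            "contig": contig,
            "start": starts,
            "end": ends,
            "n_conserved": n_covered - n_noncons,
            "n_nonconserved": n_noncons,
            "n_covered": n_covered,
            "usable": usable,
        }
    )
    return df, background


def scan_family(
    panel: list[SpeciesCallSet],
    contigs: ContigTable,
    params: ScanParams | None = None,
    family_id: str = "family",
) -> tuple[pd.DataFrame, dict[str, ChromBackground], HcrSet]:
    """Run the full HCR scan over all autosomes of one family.

    Returns the per-window statistics table (with raw and adjusted
    p-values and the called flag), per-contig backgrounds, and the merged
    HCR set.
    """
    params = params or ScanParams()
    if not panel:
        raise ValueError("empty species panel")
    frames, backgrounds = [], {}
    for contig, length in contigs.autosomes():
        df, bg = scan_contig(contig, length, panel, params)
        frames.append(df)
        backgrounds[contig] = bg
        logger.info(
            "%s: %d windows, %d usable (%.1f%%); background %d/%d non-conserved",
            contig,
            len(df),
            int(df["usable"].sum()),
            100 * df["usable"].mean() if len(df) else 0.0,
            bg.n_nonconserved_total,
            bg.n_conserved_total + bg.n_nonconserved_total,
        )
    if not frames:
        raise ValueError("contig table contains no autosomes")
    windows = pd.concat(frames, ignore_index=True)

    p_raw = np.full(len(windows), np.nan)
    usable_idx = np.flatnonzero(windows["usable"].to_numpy())
    for i in usable_idx:
        row = windows.iloc[i]
        bg = backgrounds[row["contig"]]
        if bg.n_conserved_total + bg.n_nonconserved_total == 0:
            continue
        p_raw[i] = fisher_exact_2x2(
            int(row["n_conserved"]),
            int(row["n_nonconserved"]),
            bg.n_conserved_total,
            bg.n_nonconserved_total,
        )
    windows["p_raw"] = p_raw
    tested = np.flatnonzero(~np.isnan(p_raw))
    logger.info("Fisher tests: %d usable windows across %d contigs", len(tested), len(backgrounds))
    p_adj = np.full(len(windows), np.nan)
    if len(tested):
        p_adj[tested] = bh_adjust(p_raw[tested])
    windows["p_adj"] = p_adj

    hcrs = call_hcrs(windows, params, backgrounds, family_id=family_id)
    windows["called"] = _called_flags(windows, params, backgrounds)
    return windows, backgrounds, hcrs


def _called_flags(
    windows: pd.DataFrame,
    params: ScanParams,
    backgrounds: dict[str, ChromBackground],
) -> np.ndarray:
    called = (
        windows["usable"].to_numpy()
        & (windows["p_adj"].to_numpy() < params.alpha_adj)
    )
    if params.require_reduced:
        bg_frac = windows["contig"].map(
            {c: b.nonconserved_fraction for c, b in backgrounds.items()}
        ).to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            win_frac = (
                windows["n_nonconserved"].to_numpy()
                / windows["n_covered"].to_numpy().clip(min=1)
            )
            called &= win_frac < bg_frac
    return called


def call_hcrs(
    windows: pd.DataFrame,
    params: ScanParams,
    backgrounds: dict[str, ChromBackground],
    family_id: str = "family",
) -> HcrSet:
    """Extract the middle tile of every called window and merge per contig."""
    called = _called_flags(windows, params, backgrounds)
    offset = params.tile_offset
    out: dict[str, np.ndarray] = {}
    sel = windows[called]
    for contig, grp in sel.groupby("contig", sort=True):
        tiles = np.column_stack(
            (
                grp["start"].to_numpy(np.int64) + offset,
                grp["start"].to_numpy(np.int64) + offset + params.step_size,
            )
        )
        out[contig] = iv.merge(tiles)
    meta = params.metadata()
    meta["family_id"] = family_id
    return HcrSet(
        family_id=family_id,
        intervals=out,
        unmerged_total=int(called.sum()) * params.step_size,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# gene overlap


def genes_in_regions(
    hcr_sets: dict[str, HcrSet], gene_tables: dict[str, GeneTable]
) -> dict:
    """Per-family HCR gene sets and the shared/specific cross-family partition.

    A gene is "in HCRs" when its interval overlaps at least one HCR interval
    by >= 1 bp (half-open semantics: touching endpoints do not overlap).
    Families are compared through the gene tables' cross-family symbol.
    """
    per_family: dict[str, set[str]] = {}
    for fam, hcrs in hcr_sets.items():
        table = gene_tables[fam]
        symbols: set[str] = set()
        for _, g in table.genes.iterrows():
            arr = hcrs.intervals.get(g["contig"])
            if arr is None or arr.size == 0:
                continue
            gene = np.array([[g["start"], g["end"]]], dtype=np.int64)
            if iv.intersect(gene, arr).size:
                symbols.add(g["symbol"])
        per_family[fam] = symbols
    families = list(per_family)
    shared = set.intersection(*per_family.values()) if per_family else set()
    specific = {
        fam: per_family[fam]
        - set.union(*(per_family[o] for o in families if o != fam))
        if len(families) > 1
        else set(per_family[fam])
        for fam in families
    }
    return {"per_family": per_family, "shared": shared, "specific": specific}
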