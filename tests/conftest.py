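import numpy as np
import pandas as pd
import pytest

from famcons.genome_io import HET, HOM_ALT, SNV, INDEL, SpeciesCallSet, empty_variants


def make_callset(species_id, records, mask=None):
    """Build a SpeciesCallSet from (contig, pos, zygosity, var_class) tuples."""
    if records:
        df = pd.DataFrame(
            [(c, p, z, v, "T") for c, p, z, v in records],
            columns=["contig", "pos", "zygosity", "var_class", "alt"],
        )
    else:
        df = empty_variants()
    mask_arrays = (
        {c: np.asarray(ints, dtype=np.int64).reshape(-1, 2) for c, ints in mask.items()}
        if mask is not None
        else None
    )
    return SpeciesCallSet(species_id=species_id, variants=df, mask=mask_arrays)


def brute_force_window_counts(window, panel, include_indels=False):
    """Position-by-position reference implementation of window counting."""
    contig, start, end = window
    masks, het_sets = [], []
    for cs in panel:
        if cs.mask is None:
            masks.append(None)
        else:
            ints = cs.mask.get(contig, np.zeros((0, 2), np.int64))
            masks.append([(int(s), int(e)) for s, e in ints])
        v = cs.variants
        sel = (v["contig"] == contig) & (v["zygosity"] == HET)
        if not include_indels:
            sel &= v["var_class"] == SNV
        het_sets.append(set(int(p) for p in v.loc[sel, "pos"]))
    n_cov = n_non = 0
    for pos in range(start, end):
        covered = all(
            m is None or any(s <= pos < e for s, e in m) for m in masks
        )
        if not covered:
            continue
        n_cov += 1
        if any(pos in hs for hs in het_sets):
            n_non += 1
    return n_cov - n_non, n_non, n_cov


def random_toy_panel(rng, n_species=3, contig="chr1", length=10_000, het_rate=0.01):
    """Small panel with random masks and variants for oracle comparisons."""
    panel = []
    for i in range(n_species):
        n_var = rng.binomial(length, het_rate)
        pos = rng.choice(length, size=n_var, replace=False)
        zyg = rng.choice([HET, HOM_ALT], size=n_var)
        cls = rng.choice([SNV, INDEL], size=n_var, p=[0.9, 0.1])
        records = [(contig, int(p), z, c) for p, z, c in zip(pos, zyg, cls)]
        # random mask: a few kept blocks
        edges = np.sort(rng.choice(length, size=6, replace=False))
        ints = [(int(edges[j]), int(edges[j + 1])) for j in range(0, 6, 2) if edges[j] < edges[j + 1]]
        panel.append(make_callset(f"sp{i}", records, mask={contig: ints}))
    return panel


@pytest.fixture
def rng():
    return np.random.default_rng(20160913)
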