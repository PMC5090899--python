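import numpy as np
import pandas as pd
import pytest

from famcons.aac_classify import (
    ProteinAlignmentSet,
    STANDARD_RESIDUES,
    convergent_aacs,
    function_altered_genes,
    group_specific_aacs,
    read_alignment_fasta,
)


def aln_from_columns(columns, species):
    """Build an alignment whose i-th column is columns[i] (one char/species)."""
    seqs = {
        sp: "".join(col[j] for col in columns) for j, sp in enumerate(species)
    }
    return ProteinAlignmentSet(gene_id="g", sequences=seqs)


TARGETS = ["t1", "t2", "t3"]
BACKGROUNDS = ["b1", "b2", "b3"]
SPECIES = TARGETS + BACKGROUNDS


class TestGroupSpecific:
    def test_unanimous_target_absent_in_background(self):
        aln = aln_from_columns(["KKKEEQ"], SPECIES)
        recs = group_specific_aacs(aln, TARGETS, BACKGROUNDS)
        assert len(recs) == 1 and recs[0].target_residue == "K"
        assert recs[0].position == 1  # 1-based report of 0-based column

    def test_non_unanimous_targets_not_reported(self):
        aln = aln_from_columns(["KKREEE"], SPECIES)
        assert group_specific_aacs(aln, TARGETS, BACKGROUNDS) == []

    def test_residue_in_background_not_reported(self):
        aln = aln_from_columns(["KKKEKQ"], SPECIES)
        assert group_specific_aacs(aln, TARGETS, BACKGROUNDS) == []

    @pytest.mark.parametrize("col", ["KK-EEQ", "KKXEEQ", "KKKE-Q"])
    def test_gap_or_ambiguity_skips_column(self, col):
        aln = aln_from_columns([col], SPECIES)
        assert group_specific_aacs(aln, TARGETS, BACKGROUNDS) == []

    def test_missing_species_raises_with_names(self):
        aln = aln_from_columns(["KKKEE"], SPECIES[:-1])
        with pytest.raises(KeyError, match="b3"):
            group_specific_aacs(aln, TARGETS, BACKGROUNDS)

    def test_overlapping_groups_rejected(self):
        aln = aln_from_columns(["KKKEEQ"], SPECIES)
        with pytest.raises(ValueError):
            group_specific_aacs(aln, TARGETS, TARGETS[:1] + BACKGROUNDS)

    def test_matches_brute_force_on_random_columns(self, rng):
        residues = np.array(list(STANDARD_RESIDUES) + ["-", "X"])
        cols = ["".join(rng.choice(residues, size=len(SPECIES))) for _ in range(500)]
        aln = aln_from_columns(cols, SPECIES)
        got = {(r.column_index, r.target_residue)
               for r in group_specific_aacs(aln, TARGETS, BACKGROUNDS)}
        expected = set()
        for i, col in enumerate(cols):
            t, b = col[:3], col[3:]
            if any(ch not in STANDARD_RESIDUES for ch in col):
                continue
            if len(set(t)) == 1 and t[0] not in b:
                expected.add((i, t[0]))
        assert got == expected

    def test_species_order_invariance(self, rng):
        residues = np.array(list(STANDARD_RESIDUES))
        cols = ["".join(rng.choice(residues, size=len(SPECIES))) for _ in range(200)]
        aln = aln_from_columns(cols, SPECIES)
        a = group_specific_aacs(aln, TARGETS, BACKGROUNDS)
        b = group_specific_aacs(aln, list(reversed(TARGETS)), list(reversed(BACKGROUNDS)))
        assert [(r.column_index, r.target_residue) for r in a] == [
            (r.column_index, r.target_residue) for r in b
        ]

    def test_mutual_exclusivity_when_background_moves_to_targets(self, rng):
        residues = np.array(list(STANDARD_RESIDUES))
        cols = ["".join(rng.choice(residues, size=len(SPECIES))) for _ in range(300)]
        aln = aln_from_columns(cols, SPECIES)
        a = {(r.column_index, r.target_residue)
             for r in group_specific_aacs(aln, TARGETS, BACKGROUNDS)}
        b = {(r.column_index, r.target_residue)
             for r in group_specific_aacs(aln, TARGETS + BACKGROUNDS[:1], BACKGROUNDS[1:])}
        assert not (a & b)


class TestConvergent:
    CLADES = [["t1", "t2"], ["t3"]]

    def test_joint_unanimity_absent_in_background(self):
        aln = aln_from_columns(["VVVEEQ"], SPECIES)
        recs = convergent_aacs(aln, self.CLADES, BACKGROUNDS)
        assert len(recs) == 1 and recs[0].is_convergent

    def test_one_clade_differs_not_convergent(self):
        aln = aln_from_columns(["VVAEEQ"], SPECIES)
        assert convergent_aacs(aln, self.CLADES, BACKGROUNDS) == []

    def test_background_presence_respects_strictness_flag(self):
        aln = aln_from_columns(["VVVVEQ"], SPECIES)
        assert convergent_aacs(aln, self.CLADES, BACKGROUNDS) == []
        relaxed = convergent_aacs(
            aln, self.CLADES, BACKGROUNDS, require_absent_in_background=False
        )
        assert len(relaxed) == 1

    def test_overlapping_clades_rejected(self):
        aln = aln_from_columns(["VVVEEQ"], SPECIES)
        with pytest.raises(ValueError):
            convergent_aacs(aln, [["t1", "t2"], ["t2"]], BACKGROUNDS)

    def test_carnivore_style_panel_single_column(self):
        """One column where all carnivoran clades share a residue that no
        omnivore/herbivore carries; only that column is reported."""
        carnivores = ["cat", "tiger", "leopard", "polar_bear", "killer_whale"]
        others = [f"bg{i}" for i in range(10)]
        clades = [["cat", "tiger", "leopard"], ["polar_bear"], ["killer_whale"]]
        n_cols, planted = 40, 17
        rng = np.random.default_rng(2)
        base = rng.choice(list("ACDEFGHIKLMN"), size=n_cols)
        cols = []
        for i in range(n_cols):
            col = {sp: base[i] for sp in carnivores + others}
            if i == planted:
                col.update({sp: "W" for sp in carnivores})
            cols.append("".join(col[sp] for sp in carnivores + others))
        aln = aln_from_columns(cols, carnivores + others)
        recs = convergent_aacs(aln, clades, others)
        assert [(r.column_index, r.target_residue) for r in recs] == [(planted, "W")]


class TestFunctionAlteredGenes:
    GROUP = ["c1", "c2", "c3", "c4"]
    OTHERS = [f"o{i}" for i in range(10)]

    def _flags(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "column_1based", "species_id", "tool", "call"]
        )

    def test_all_group_flagged_no_others(self):
        rows = [("geneA", i + 1, s, "provean", "Deleterious") for i, s in enumerate(self.GROUP)]
        rows += [("geneA", 50, "o1", "provean", "neutral")]
        assert function_altered_genes(self._flags(rows), self.GROUP, self.OTHERS) == {"geneA"}

    def test_one_group_member_missing_disqualifies(self):
        rows = [("geneA", i + 1, s, "provean", "deleterious") for i, s in enumerate(self.GROUP[:-1])]
        assert function_altered_genes(self._flags(rows), self.GROUP, self.OTHERS) == set()

    def test_other_diet_flag_disqualifies(self):
        rows = [("geneA", i + 1, s, "polyphen2", "damaging") for i, s in enumerate(self.GROUP)]
        rows += [("geneA", 99, "o5", "provean", "deleterious")]
        assert function_altered_genes(self._flags(rows), self.GROUP, self.OTHERS) == set()

    def test_planted_table_recovered_exactly(self, rng):
        rows, planted = [], set()
        for g in range(50):
            gene = f"g{g:02d}"
            kind = rng.integers(0, 4)
            if kind == 0:
                planted.add(gene)
                for s in self.GROUP:
                    rows.append((gene, int(rng.integers(1, 100)), s, "provean", "deleterious"))
            elif kind == 1:  # incomplete group
                for s in self.GROUP[:-1]:
                    rows.append((gene, int(rng.integers(1, 100)), s, "provean", "deleterious"))
            elif kind == 2:  # contaminated by an other-diet species
                for s in self.GROUP:
                    rows.append((gene, int(rng.integers(1, 100)), s, "provean", "deleterious"))
                rows.append((gene, 3, "o2", "polyphen2", "probably_damaging"))
            else:  # benign calls only
                rows.append((gene, 1, self.GROUP[0], "provean", "neutral"))
        got = function_altered_genes(self._flags(rows), self.GROUP, self.OTHERS)
        assert got == planted


def test_alignment_fasta_round_trip(tmp_path):
    p = tmp_path / "geneX.aln.fasta"
    p.write_text(">cat\nMKV-\n>dog\nMKVA\n")
    aln = read_alignment_fasta(p)
    assert aln.gene_id == "geneX.aln"
    assert aln.sequences == {"cat": "MKV-", "dog": "MKVA"}
    with pytest.raises(ValueError):
        ProteinAlignmentSet("g", {"a": "MK", "b": "MKV"})
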