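"""Tests for the label-free co-IP enrichment chain and its packaged example."""

import itertools

import numpy as np
import pandas as pd
import pytest

from synaptoquant import coip
from synaptoquant.exceptions import PipelineOrderError, ValidationError
from synaptoquant.simulate import simulate_coip


def _matrix(values: dict, stage: str = "raw") -> coip.AbundanceMatrix:
    """Build an AbundanceMatrix from {protein: {(exp, group): value}}."""
    cols = sorted({c for row in values.values() for c in row})
    data = pd.DataFrame(
        {c: [values[p].get(c, np.nan) for p in values] for c in cols},
        index=pd.Index(list(values), name="protein_id"),
    )
    data.columns = pd.MultiIndex.from_tuples(cols, names=["experiment", "group"])
    return coip.AbundanceMatrix(data=data, stage=stage)


def _full(bait: dict, control: dict) -> coip.AbundanceMatrix:
    """Complete 3-experiment matrix from per-protein bait/control triples."""
    values = {
        p: {
            **{(e, "bait"): bait[p][e - 1] for e in (1, 2, 3)},
            **{(e, "control"): control[p][e - 1] for e in (1, 2, 3)},
        }
        for p in bait
    }
    return _matrix(values)


class TestTop3:
    def _table(self, intensities, exp=1, group="bait", protein="P1"):
        return pd.DataFrame(
            {
                "protein_id": protein,
                "peptide_id": [f"pep{i}" for i in range(len(intensities))],
                "experiment": exp,
                "group": group,
                "intensity": intensities,
            }
        )

    def test_mean_of_three_highest(self):
        m = coip.top3_abundance(self._table([5, 4, 3, 2, 1]))
        assert m.data.loc["P1", (1, "bait")] == pytest.approx(4.0)

    def test_fewer_than_three_peptides_uses_available(self):
        m = coip.top3_abundance(self._table([6, 2]))
        assert m.data.loc["P1", (1, "bait")] == pytest.approx(4.0)
        assert m.peptide_counts.loc["P1", (1, "bait")] == 2

    def test_permutation_invariance(self, rng):
        vals = rng.uniform(1, 100, 7)
        a = coip.top3_abundance(self._table(vals))
        b = coip.top3_abundance(self._table(vals[rng.permutation(7)]))
        assert a.data.loc["P1", (1, "bait")] == pytest.approx(b.data.loc["P1", (1, "bait")])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            coip.top3_abundance(pd.DataFrame({"protein_id": ["P1"]}))


class TestPresenceFilter:
    def test_single_experiment_protein_dropped(self):
        m = _matrix(
            {
                "only1": {(1, "bait"): 5.0},
                "both": {(1, "bait"): 5.0, (2, "control"): 3.0},
            }
        )
        out = coip.presence_filter(m)
        assert list(out.data.index) == ["both"]
        assert "only1" in out.dropped.index

    def test_two_experiments_same_group_kept(self):
        m = _matrix({"p": {(1, "bait"): 2.0, (3, "bait"): 4.0}})
        assert list(coip.presence_filter(m).data.index) == ["p"]

    def test_matches_exhaustive_pattern_oracle(self):
        """All 2^6 presence patterns over (3 experiments x 2 groups), checked
        against an independent bit-counting oracle."""
        cells = list(itertools.product((1, 2, 3), ("bait", "control")))
        values = {}
        for bits in range(64):
            pattern = [(bits >> k) & 1 for k in range(6)]
            values[f"pat{bits:02d}"] = {
                c: 10.0 for c, b in zip(cells, pattern) if b
            } or {}
        # drop the all-absent protein (no observable row) and add an anchor so
        # every experiment has at least one value
        del values["pat00"]
        values["anchor"] = {c: 1.0 for c in cells}
        out = coip.presence_filter(_matrix(values))
        kept = set(out.data.index)
        for bits in range(1, 64):
            pattern = [(bits >> k) & 1 for k in range(6)]
            n_exp = sum(
                1
                for e in (1, 2, 3)
                if any(b for c, b in zip(cells, pattern) if c[0] == e)
            )
            assert (f"pat{bits:02d}" in kept) == (n_exp >= 2), bits


class TestImputation:
    def test_missing_cell_gets_experiment_minimum(self):
        m = _matrix(
            {
                "a": {(1, "bait"): 7.2, (1, "control"): 9.0, (2, "bait"): 8.0, (2, "control"): 8.0},
                "b": {(1, "bait"): 10.0, (2, "bait"): 12.0, (2, "control"): 11.0},
            }
        )
        out = coip.impute_missing(coip.presence_filter(m))
        assert out.data.loc["b", (1, "control")] == pytest.approx(7.2)

    def test_identity_when_nothing_missing(self):
        m = _full({"a": (2, 2, 2), "b": (3, 3, 3)}, {"a": (1, 1, 1), "b": (1, 1, 1)})
        out = coip.impute_missing(coip.presence_filter(m))
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_experiment_minimum_unchanged_by_imputation(self):
        m = _matrix(
            {
                "a": {(1, "bait"): 5.0, (2, "bait"): 6.0},
                "b": {(1, "bait"): 3.0, (1, "control"): 4.0, (2, "control"): 2.0},
            }
        )
        out = coip.impute_missing(coip.presence_filter(m))
        assert np.nanmin(out.data[1].to_numpy()) == 3.0
        assert np.nanmin(out.data[2].to_numpy()) == 2.0

    def test_out_of_order_call_raises(self):
        m = _full({"a": (2, 2, 2)}, {"a": (1, 1, 1)})
        with pytest.raises(PipelineOrderError):
            coip.impute_missing(m)  # skipped presence_filter
        with pytest.raises(PipelineOrderError):
            coip.log2_ratios(coip.presence_filter(m))  # skipped imputation


class TestRatiosAndCall:
    def _ratios(self, bait, control):
        return coip.log2_ratios(coip.impute_missing(coip.presence_filter(_full(bait, control))))

    def test_eight_over_two_is_two(self):
        r = self._ratios({"p": (8, 8, 8)}, {"p": (2, 2, 2)})
        assert r.table.loc["p", "log2_R1"] == pytest.approx(2.0)

    def test_equal_abundance_is_zero(self):
        r = self._ratios({"p": (5, 5, 5)}, {"p": (5, 5, 5)})
        assert r.table.loc["p", "log2_R2"] == pytest.approx(0.0)

    def test_swapping_groups_negates_ratios(self):
        r1 = self._ratios({"p": (8, 6, 12)}, {"p": (2, 3, 3)})
        r2 = self._ratios({"p": (2, 3, 3)}, {"p": (8, 6, 12)})
        for c in ("log2_R1", "log2_R2", "log2_R3"):
            assert r1.table.loc["p", c] == pytest.approx(-r2.table.loc["p", c])

    def test_boundary_inclusive_at_twofold(self):
        r = self._ratios(
            {"edge": (2, 2, 2), "below": (2, 2, 2 * 2**-0.001)},
            {"edge": (1, 1, 1), "below": (1, 1, 1)},
        )
        called = coip.call_enriched(r, fold_threshold=2)
        assert bool(called.table.loc["edge", "enriched"]) is True
        assert bool(called.table.loc["below", "enriched"]) is False

    def test_call_invariant_under_experiment_rescaling(self):
        bait = {"p": (8.0, 6.0, 9.0), "q": (2.0, 2.0, 2.0)}
        ctrl = {"p": (2.0, 1.5, 2.0), "q": (1.9, 2.0, 2.1)}
        base = coip.call_enriched(self._ratios(bait, ctrl))
        scaled_bait = {k: (v[0] * 50, v[1], v[2]) for k, v in bait.items()}
        scaled_ctrl = {k: (v[0] * 50, v[1], v[2]) for k, v in ctrl.items()}
        scaled = coip.call_enriched(self._ratios(scaled_bait, scaled_ctrl))
        pd.testing.assert_series_equal(base.table["enriched"], scaled.table["enriched"])


class TestAnnotation:
    def test_empty_gene_list_flags_nothing(self):
        r = coip.call_enriched(coip.load_table3())
        out = coip.annotate_vatpase(r, subunit_genes=[])
        assert out.table["is_vatpase"].sum() == 0

    def test_annotation_requires_enrichment_call(self):
        with pytest.raises(PipelineOrderError):
            coip.annotate_vatpase(coip.load_table3())


class TestPackagedTable:
    def test_twelve_rows_parse_bit_for_bit(self):
        r = coip.load_table3()
        assert len(r.table) == 12
        assert r.table.loc["FBgn0037671", "log2_R1"] == 6.154281057
        assert r.table.loc["FBgn0028671", "log2_R2"] == 8.012982519
        # the one comma-decimal entry in the source table
        assert r.table.loc["FBgn0051030", "log2_R3"] == 5.19465574

    def test_all_twelve_called_enriched(self):
        r = coip.call_enriched(coip.load_table3())
        assert r.n_enriched == 12

    def test_three_vatpase_subunits_beside_the_bait(self):
        r = coip.annotate_vatpase(coip.call_enriched(coip.load_table3()))
        hits = set(r.table.loc[r.table["is_vatpase"], "gene_symbol"])
        assert hits == {"ATP6AP2", "Vha100-1", "VhaAC39-1"}
        assert set(r.table.loc[r.table["is_bait"], "gene_symbol"]) == {"CG31030"}
        assert r.n_vatpase_nonbait == 3


class TestSyntheticRecovery:
    def test_spiked_proteins_recovered_exactly(self):
        spiked = {"P0007": 4.0, "P0123": 6.0, "P0200": 8.0}
        table, truth = simulate_coip(n_proteins=250, spiked=spiked, seed=21)
        res = coip.run_chain(coip.top3_abundance(table))
        hits = set(res.table.index[res.table["enriched"]])
        assert hits == set(spiked)

    def test_unspiked_ratios_centred_at_zero(self):
        table, _ = simulate_coip(n_proteins=150, spiked=None, seed=5)
        res = coip.log2_ratios(
            coip.impute_missing(coip.presence_filter(coip.top3_abundance(table)))
        )
        med = res.table[["log2_R1", "log2_R2", "log2_R3"]].median()
        assert np.all(np.abs(med.to_numpy()) < 0.1)
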