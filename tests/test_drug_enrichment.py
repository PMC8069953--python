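"""Interaction-type classification and direction-aware drug enrichment."""

import numpy as np
import pandas as pd
import pytest

from dmdnet.drug_enrichment import (
    classify_interaction,
    enrich_drugs,
    load_vocabulary,
    normalize_types,
    read_dgidb_table,
    reversal_targets,
)
from dmdnet.signature import GeneSignature
from dmdnet.stats import hypergeom_tail
from dmdnet.synthetic import gene_names, generate_drug_gene_table

from ._reference import BACKGROUND_N, CANDIDATE_K, ENRICHMENT_ROWS, printed_match


class TestClassification:
    @pytest.mark.parametrize(
        "types,expected",
        [
            ("inhibitor", "inhibiting"),
            ("agonist", "activating"),
            ("binder", "other"),
            ("agonist, inhibitor", "inhibiting"),  # full-string vocabulary entry
            ("antagonist, activator", "inhibiting"),
            ("agonist, activator", "activating"),
            ("AGONIST|Inhibitor", "inhibiting"),  # pipe-separated, mixed case
            ("negative modulator, binder, inhibitor", "inhibiting"),
            ("", "other"),
        ],
    )
    def test_vocabulary_classification(self, types, expected):
        assert classify_interaction(types) == expected

    def test_vocabulary_shape(self):
        inhibiting, activating = load_vocabulary()
        assert len(inhibiting) == 43 and len(activating) == 22
        assert not (inhibiting & activating)

    def test_normalization(self):
        assert normalize_types(" Agonist |  INHIBITOR ") == "agonist, inhibitor"
        assert normalize_types(["blocker"]) == "blocker"


class TestReversalTargets:
    sig = GeneSignature(up={"U1", "U2"}, down={"D1"})

    def records(self, rows):
        df = pd.DataFrame(rows, columns=["drug", "gene", "interaction_types"])
        return df

    def test_direction_logic(self):
        hits = reversal_targets(
            self.records(
                [
                    ("dx", "U1", "inhibitor"),   # up + inhibiting: counted
                    ("dx", "U2", "agonist"),     # up + activating: excluded
                    ("dx", "D1", "agonist"),     # down + activating: counted
                    ("dx", "X9", "inhibitor"),   # outside signature: excluded
                    ("dy", "U1", "binder"),      # other: excluded
                ]
            ),
            self.sig,
        )
        assert hits == {"dx": {"U1", "D1"}}

    def test_deduplication(self):
        hits = reversal_targets(
            self.records([("dx", "U1", "inhibitor"), ("dx", "U1", "antagonist")]),
            self.sig,
        )
        assert hits["dx"] == {"U1"}


class TestEnrichment:
    @pytest.mark.parametrize("drug,k,n,printed,kind", ENRICHMENT_ROWS)
    def test_published_pvalues_reproduce_at_printed_precision(self, drug, k, n,
                                                              printed, kind):
        p = hypergeom_tail(BACKGROUND_N, CANDIDATE_K, n, k)
        assert printed_match(p, printed, kind), (drug, p, printed)

    def test_published_rows_through_the_engine(self):
        """The engine reproduces the published p-values from raw records."""
        background = set(gene_names(BACKGROUND_N))
        bg = sorted(background)
        candidates = set(bg[:CANDIDATE_K])
        rows = []
        for i, (drug, k, n, _printed, _kind) in enumerate(ENRICHMENT_ROWS):
            hit_genes = bg[:k]
            offset = CANDIDATE_K + 100 + i * 30  # disjoint non-candidate blocks
            miss_genes = bg[offset: offset + (n - k)]
            for g in hit_genes + miss_genes:
                rows.append((drug, g, "inhibitor"))
        records = pd.DataFrame(rows, columns=["drug", "gene", "interaction_types"])
        sig = GeneSignature(up=candidates)
        result = enrich_drugs(records, candidates, background, signature=sig)
        assert len(result) == len(ENRICHMENT_ROWS)
        by_drug = result.set_index("drug")
        for drug, k, n, printed, kind in ENRICHMENT_ROWS:
            assert by_drug.loc[drug, "n_hits"] == k
            assert by_drug.loc[drug, "n_total_targets"] == n
            assert printed_match(by_drug.loc[drug, "p"], printed, kind), drug

    def test_delegation_identity_full_overlap(self):
        background = set(gene_names(200))
        candidates = set(sorted(background)[:40])
        genes = sorted(candidates)[:3]
        records = pd.DataFrame(
            [("dx", g, "inhibitor") for g in genes],
            columns=["drug", "gene", "interaction_types"],
        )
        result = enrich_drugs(records, candidates, background,
                              signature=GeneSignature(up=candidates))
        assert result.loc[0, "p"] == pytest.approx(hypergeom_tail(200, 40, 3, 3))

    def test_targets_restricted_to_background(self):
        background = {"A", "B", "C"}
        records = pd.DataFrame(
            [("dx", "A", "inhibitor"), ("dx", "ZZ", "inhibitor")],
            columns=["drug", "gene", "interaction_types"],
        )
        result = enrich_drugs(records, {"A"}, background,
                              signature=GeneSignature(up={"A"}))
        assert result.loc[0, "n_total_targets"] == 1  # ZZ outside background

    def test_drug_without_background_targets_excluded(self):
        records = pd.DataFrame(
            [("dx", "ZZ", "inhibitor")], columns=["drug", "gene", "interaction_types"]
        )
        result = enrich_drugs(records, {"A"}, {"A", "B"},
                              signature=GeneSignature(up={"A"}), min_hits=0)
        assert len(result) == 0

    def test_p_strictly_decreasing_in_hits(self):
        ps = [hypergeom_tail(1000, 50, 10, k) for k in range(0, 6)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_null_pvalues_are_sub_uniform(self):
        """With no planted reversers the enrichment p-values are valid:
        P(p <= x) never exceeds x beyond Monte-Carlo error (the exact test
        is conservative on discrete counts)."""
        universe = gene_names(2000)
        rng = np.random.default_rng(1)
        sig_genes = set(np.array(universe)[rng.choice(2000, 100, replace=False)])
        table, _ = generate_drug_gene_table(
            universe, n_drugs=600, targets_per_drug=(50, 300), seed=17
        )
        records = table.rename(columns={"gene_name": "gene", "drug_name": "drug"})
        result = enrich_drugs(records, sig_genes, set(universe), min_hits=0)
        p = result["p"].to_numpy()
        for x in np.linspace(0.05, 0.95, 19):
            ecdf = float((p <= x).mean())
            se = np.sqrt(x * (1 - x) / len(p))
            assert ecdf <= x + 3 * se

    def test_dgidb_reader(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text(
            "gene_name\tdrug_name\tinteraction_types\n"
            "G1\tDX\tinhibitor\nG2\tDY\tagonist|activator\n"
        )
        df = read_dgidb_table(path)
        assert list(df["action_class"]) == ["inhibiting", "activating"]
        bad = tmp_path / "bad.tsv"
        bad.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError, match="expected columns"):
            read_dgidb_table(bad)
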