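import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy as scipy_hier
from scipy.spatial.distance import pdist

from _oracles import brute_force_complete_linkage
from conftest import make_site, make_variant
from pfssnv.io_model import PfsSnvError, ProteinRecord, ProteinSet
from pfssnv.pancancer_prioritize import (
    FOLD_CAP,
    combine_key_lists,
    build_pancancer_matrix,
    hierarchical_cluster,
    intersect_gene_lists,
    keys_frame,
    select_key_multi_cancer,
    select_key_patient_enriched,
)
from pfssnv.enrichment import flag_significant, patient_enrichment
from pfssnv.site_effects import annotate_neighborhood, site_offset_denominators


@pytest.fixture
def small_world(tolerance):
    proteome = ProteinSet([ProteinRecord("P1", "A" * 101)])
    sites = [make_site("P1", 51, "binding_site", "A")]
    denominators = site_offset_denominators(sites, proteome)
    return proteome, sites, denominators


class TestPanCancerMatrix:
    def test_uniform_cancer_near_one(self, small_world, tolerance):
        proteome, sites, denom = small_world
        # one variant at every window position: occurrence identical at
        # offset 0 and neighbors -> fold change exactly 1
        variants = [
            make_variant("P1", pos, "A", "V", cancers={"ca": {"p1"}})
            for pos in range(31, 72)
        ]
        ann = annotate_neighborhood(variants, sites, proteome, tolerance)
        m = build_pancancer_matrix(ann, variants, denom)
        assert m.values.loc["ca", "binding_site"] == pytest.approx(1.0)

    def test_depleted_cell(self, small_world, tolerance):
        proteome, sites, denom = small_world
        variants = [
            make_variant("P1", pos, "A", "V", cancers={"ca": {"p1"}})
            for pos in range(31, 72)
            if pos != 51  # nothing at the site itself
        ]
        ann = annotate_neighborhood(variants, sites, proteome, tolerance)
        m = build_pancancer_matrix(ann, variants, denom)
        assert m.values.loc["ca", "binding_site"] == pytest.approx(0.0)

    def test_missing_cell_when_no_variants(self, tolerance):
        # the cancer has variants near the active site but none anywhere in
        # the binding-site window: that cell stays missing, never 0
        proteome = ProteinSet([ProteinRecord("P1", "A" * 201)])
        sites = [
            make_site("P1", 51, "binding_site", "A"),
            make_site("P1", 150, "active_site", "A"),
        ]
        denom = site_offset_denominators(sites, proteome)
        variants = [make_variant("P1", 150, "A", "V", cancers={"ca": {"p1"}})]
        ann = annotate_neighborhood(variants, sites, proteome, tolerance)
        m = build_pancancer_matrix(ann, variants, denom)
        assert np.isnan(m.values.loc["ca", "binding_site"])
        assert not np.isnan(m.values.loc["ca", "active_site"])

    def test_capped_sentinel(self, small_world, tolerance):
        proteome, sites, denom = small_world
        variants = [make_variant("P1", 51, "A", "V", cancers={"ca": {"p1"}})]
        ann = annotate_neighborhood(variants, sites, proteome, tolerance)
        m = build_pancancer_matrix(ann, variants, denom)
        assert m.values.loc["ca", "binding_site"] == FOLD_CAP
        assert ("ca", "binding_site") in m.capped_cells

    def test_synonymous_matrix_separate(self, small_world, tolerance):
        proteome, sites, denom = small_world
        variants = [
            make_variant("P1", 51, "A", "A", consequence="synonymous",
                         cancers={"ca": {"p1"}})
        ]
        ann = annotate_neighborhood(variants, sites, proteome, tolerance)
        m_ns = build_pancancer_matrix(ann, variants, denom, "non-synonymous")
        m_s = build_pancancer_matrix(ann, variants, denom, "synonymous")
        assert len(m_ns.values) == 0 or np.isnan(
            m_ns.values.loc["ca", "binding_site"]
        )
        assert m_s.values.loc["ca", "binding_site"] == FOLD_CAP


class TestHierarchicalCluster:
    def test_derived_three_row_example(self):
        df = pd.DataFrame(
            [[0.0, 0.0], [0.0, 1.0], [4.0, 4.0]], index=["r1", "r2", "r3"]
        )
        result = hierarchical_cluster(df)
        assert result.merges[0].height == pytest.approx(1.0)
        assert set(result.merges[0].left + result.merges[0].right) == {"r1", "r2"}
        assert result.merges[1].height == pytest.approx(np.sqrt(32))

    def test_identical_rows_tie_break(self):
        df = pd.DataFrame([[1.0, 1.0]] * 3, index=["b", "c", "a"])
        result = hierarchical_cluster(df)
        # all distances 0; first merge must be the lexicographically first pair
        assert set(result.merges[0].left + result.merges[0].right) == {"a", "b"}
        assert all(m.height == 0 for m in result.merges)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(6, 4))
        labels = [f"c{i}" for i in range(6)]
        df = pd.DataFrame(data, index=labels)
        perm = [3, 1, 5, 0, 4, 2]
        df_perm = df.iloc[perm]
        r1 = hierarchical_cluster(df)
        r2 = hierarchical_cluster(df_perm)
        key = lambda m: (m.height, tuple(sorted(m.left + m.right)))
        assert [key(m) for m in r1.merges] == [key(m) for m in r2.merges]

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            df = pd.DataFrame(rng.normal(size=(7, 3)))
            heights = [m.height for m in hierarchical_cluster(df).merges]
            assert heights == sorted(heights)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            data = rng.normal(size=(5, 4))
            labels = [f"r{i}" for i in range(5)]
            df = pd.DataFrame(data, index=labels)
            got = hierarchical_cluster(df)
            expected = brute_force_complete_linkage(
                {lab: data[i] for i, lab in enumerate(labels)}
            )
            assert len(got.merges) == len(expected)
            for m, (ea, eb, eh) in zip(got.merges, expected):
                assert {tuple(sorted(m.left)), tuple(sorted(m.right))} == {
                    tuple(sorted(ea)), tuple(sorted(eb))
                }
                assert m.height == pytest.approx(eh)

    def test_matches_scipy_heights(self):
        rng = np.random.default_rng(13)
        data = rng.normal(size=(8, 5))
        df = pd.DataFrame(data, index=[f"r{i}" for i in range(8)])
        got = [m.height for m in hierarchical_cluster(df).merges]
        Z = scipy_hier.linkage(pdist(data), method="complete")
        assert np.allclose(sorted(got), sorted(Z[:, 2]))

    def test_missing_imputed_and_reported(self):
        df = pd.DataFrame(
            [[1.0, np.nan], [1.0, 1.0]], index=["a", "b"], columns=["x", "y"]
        )
        result = hierarchical_cluster(df)
        assert result.imputed_cells == [("a", "y")]
        assert result.merges[0].height == pytest.approx(0.0)

    def test_single_row(self):
        df = pd.DataFrame([[1.0]], index=["only"])
        result = hierarchical_cluster(df)
        assert result.order == ["only"] and result.merges == []

    def test_empty_errors(self):
        with pytest.raises(PfsSnvError):
            hierarchical_cluster(pd.DataFrame())

    def test_newick_leaves(self):
        df = pd.DataFrame(
            [[0.0, 0.0], [0.0, 1.0], [4.0, 4.0]], index=["r1", "r2", "r3"]
        )
        nwk = hierarchical_cluster(df).newick()
        assert nwk.endswith(";")
        for lab in ("r1", "r2", "r3"):
            assert lab in nwk


def _annotated_world(tolerance, counts_by_variant):
    """Variants on a single binding site with given cancer counts."""
    proteome = ProteinSet([ProteinRecord("P1", "A" * 101)])
    sites = [make_site("P1", 51, "binding_site", "A")]
    variants = []
    for i, n_cancers in enumerate(counts_by_variant):
        alt = "CDEFGHIKLMNPQRSTVWY"[i]
        cancers = {f"cancer{j}": {f"p{j}"} for j in range(n_cancers)}
        variants.append(
            make_variant("P1", 51, "A", alt, cancers=cancers, gene=f"g{i+1}")
        )
    ann = annotate_neighborhood(variants, sites, proteome, tolerance)
    return ann, variants


class TestKeySelection:
    def test_threshold_boundary(self, tolerance):
        ann, variants = _annotated_world(tolerance, [31, 4, 5])
        keys = select_key_multi_cancer(ann, variants, min_types=5)
        assert [k.cancer_type_count for k in keys] == [31, 5]
        assert keys[0].effect == "loss"

    def test_superset_on_lower_threshold(self, tolerance):
        ann, variants = _annotated_world(tolerance, [2, 4, 6, 8])
        strict = {k.variant.key for k in select_key_multi_cancer(ann, variants, 5)}
        loose = {k.variant.key for k in select_key_multi_cancer(ann, variants, 3)}
        assert strict <= loose

    def test_gain_phospho_variant_selected(self, tolerance):
        proteome = ProteinSet([ProteinRecord("P1", "A" * 101)])
        variants = [
            make_variant(
                "P1", 10, "A", "V", gene="g1", gain_phospho=True,
                cancers={f"c{j}": {f"p{j}"} for j in range(6)},
            )
        ]
        ann = annotate_neighborhood(variants, [], proteome, tolerance)
        keys = select_key_multi_cancer(ann, variants, min_types=5)
        assert len(keys) == 1
        assert keys[0].effect == "gain"
        assert keys[0].site_type == "phosphorylation"

    def test_patient_enriched_selection_and_union(self, tolerance):
        ann, variants = _annotated_world(tolerance, [6, 1])
        # give the second variant a deep enrichment in one cancer
        variants[1].patients_by_cancer = {"cancer0": {f"p{i}" for i in range(30)}}
        results = patient_enrichment(variants, "cancer0", {"cancer0": 100}, p_c=0.01)
        flag_significant(results, n_tests=len(results))
        enriched = select_key_patient_enriched(ann, variants, results)
        assert [k.variant.alt_aa for k in enriched] == [variants[1].alt_aa]
        multi = select_key_multi_cancer(ann, variants, min_types=5)
        combined = combine_key_lists(multi, enriched)
        criteria = {k.variant.alt_aa: k.criterion for k in combined}
        assert criteria[variants[0].alt_aa] == "multi_cancer"
        assert criteria[variants[1].alt_aa] == "patient_enriched"


class TestGeneLists:
    def test_membership_flags(self, tolerance):
        ann, variants = _annotated_world(tolerance, [6, 7])
        keys = select_key_multi_cancer(ann, variants, min_types=5)
        summary = intersect_gene_lists(keys, smg={"g1", "g2"}, cgc={"g2", "g3"})
        flags = {k.variant.gene: (k.smg, k.cgc) for k in keys}
        assert flags["g1"] == (True, False)
        assert flags["g2"] == (True, True)
        assert summary["both"] == {"g2"}

    def test_empty_lists(self, tolerance):
        ann, variants = _annotated_world(tolerance, [6])
        keys = select_key_multi_cancer(ann, variants, min_types=5)
        summary = intersect_gene_lists(keys, set(), set())
        assert not any(k.smg or k.cgc for k in keys)
        assert summary["both"] == set()

    def test_triple_intersection_set_algebra(self, tolerance):
        ann, variants = _annotated_world(tolerance, [6, 6, 6, 6, 6])
        keys = select_key_multi_cancer(ann, variants, min_types=5)
        summary = intersect_gene_lists(keys, smg={"g1", "g2"}, cgc={"g2", "g3"})
        assert summary["smg"] == {"g1", "g2"}
        assert summary["cgc"] == {"g2", "g3"}
        assert summary["both"] == {"g2"}

    def test_frame_columns(self, tolerance):
        ann, variants = _annotated_world(tolerance, [6])
        keys = select_key_multi_cancer(ann, variants, min_types=5)
        df = keys_frame(keys)
        assert list(df["functional_site"]) == ["[L]binding_site"]
        assert list(df["cancer_type_count"]) == [6]
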