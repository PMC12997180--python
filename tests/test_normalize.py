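"""Label canonicalization and cross-model synonym clustering."""

import itertools

import numpy as np
import pytest

from medley.errors import ValidationError
from medley.normalize import AliasTable, canonicalize_label, cluster_candidates


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw,canonical",
        [
            ("Familial Mediterranean Fever.", "familial mediterranean fever"),
            ("  IgA   Nephropathy ", "iga nephropathy"),
            ("Behçet's Disease", "behcets disease"),
            ("Wilson's Disease", "wilsons disease"),
        ],
    )
    def test_folding(self, raw, canonical):
        assert canonicalize_label(raw).canonical == canonical

    def test_trailing_parenthetical_split_as_alias(self):
        got = canonicalize_label("McArdle Disease (Glycogen Storage Disease V)")
        assert got.canonical == "mcardle disease"
        assert got.alias == "glycogen storage disease v"

    def test_empty_label_rejected(self):
        with pytest.raises(ValidationError):
            canonicalize_label("   ")


class TestClustering:
    def test_identical_code_merges(self, mk_response):
        a = mk_response("A", "c1", ("FMF", ["M04.1"], 0.8))
        b = mk_response("B", "c1", ("Familial Mediterranean Fever", ["M04.1"], 0.7))
        clusters = cluster_candidates([a, b], AliasTable.empty())
        assert len(clusters) == 1
        assert set(clusters[0].supporting_model_ids) == {"A", "B"}

    def test_unlinked_labels_stay_separate(self, mk_response):
        a = mk_response("A", "c1", ("Pericarditis", ["I30"], 0.8))
        b = mk_response("B", "c1", ("Anxiety disorder", ["F41"], 0.7))
        clusters = cluster_candidates([a, b], AliasTable.empty())
        assert len(clusters) == 2

    def test_alias_table_links(self, mk_response):
        a = mk_response("A", "c1", ("FMF", [], 0.8))
        b = mk_response("B", "c1", ("Familial Mediterranean Fever", [], 0.7))
        assert len(cluster_candidates([a, b], AliasTable.empty())) == 2
        assert len(cluster_candidates([a, b], AliasTable.default())) == 1

    def test_category_codes_do_not_merge_by_default(self, mk_response):
        # distinct diseases within one 3-character category stay apart
        a = mk_response("A", "c1", ("Hemochromatosis", ["E83.110"], 0.8))
        b = mk_response("B", "c1", ("Wilson's Disease", ["E83.01"], 0.7))
        assert len(cluster_candidates([a, b], AliasTable.empty())) == 2
        merged = cluster_candidates([a, b], AliasTable.empty(), category_level_codes=True)
        assert len(merged) == 1

    def test_model_supports_cluster_once(self, mk_response):
        a = mk_response("A", "c1", ("FMF", ["M04.1"], 0.9), ("Familial fever (FMF)", ["M04.1"], 0.5))
        clusters = cluster_candidates([a], AliasTable.empty())
        assert len(clusters) == 1
        assert clusters[0].supporting_model_ids == ("A",)

    def test_mixed_case_ids_rejected(self, mk_response):
        a = mk_response("A", "c1", ("X", [], 0.5))
        b = mk_response("B", "c2", ("X", [], 0.5))
        with pytest.raises(ValidationError):
            cluster_candidates([a, b])

    def test_canonical_label_most_frequent_tie_lexicographic(self, mk_response):
        rs = [
            mk_response("A", "c1", ("FMF", ["M04.1"], 0.5)),
            mk_response("B", "c1", ("Familial Mediterranean Fever", ["M04.1"], 0.5)),
        ]
        cluster = cluster_candidates(rs, AliasTable.empty())[0]
        # tie 1-1: lexicographically smaller verbatim label wins
        assert cluster.canonical_label == canonicalize_label("FMF").canonical

    def test_permutation_invariance(self, mk_response):
        rs = [
            mk_response("A", "c1", ("FMF", ["M04.1"], 0.8), ("Pericarditis", ["I30.9"], 0.4)),
            mk_response("B", "c1", ("Familial Mediterranean Fever", ["M04.1"], 0.7)),
            mk_response("C", "c1", ("Anxiety", ["F41.9"], 0.6)),
        ]
        base = cluster_candidates(rs, AliasTable.empty())
        for perm in itertools.permutations(rs):
            assert cluster_candidates(list(perm), AliasTable.empty()) == base

    def test_partition_every_candidate_in_exactly_one_cluster(self, mk_response):
        rng = np.random.default_rng(0)
        labels = [f"dx{i}" for i in range(6)]
        codes = ["A00.1", "B00.2", "C00.3", None]
        rs = []
        for m in range(8):
            k = rng.integers(1, 4)
            picks = rng.choice(len(labels), size=k, replace=False)
            cands = []
            for i in picks:
                code = codes[rng.integers(0, 4)]
                cands.append((labels[i], [code] if code else [], 0.5))
            rs.append(mk_response(f"m{m}", "c1", *cands))
        clusters = cluster_candidates(rs, AliasTable.empty())
        n_candidates = sum(len(r.candidates) for r in rs)
        # every verbatim label instance accounted for exactly once
        total_members = 0
        for r in rs:
            for cand in r.candidates:
                homes = [
                    c for c in clusters
                    if cand.label in c.member_labels and r.model_id in c.supporting_model_ids
                ]
                assert len(homes) == 1
                total_members += 1
        assert total_members == n_candidates

    def test_alias_pair_never_increases_cluster_count(self, mk_response):
        rs = [
            mk_response("A", "c1", ("Lupus", [], 0.5)),
            mk_response("B", "c1", ("SLE", [], 0.5)),
            mk_response("C", "c1", ("Gout", [], 0.5)),
        ]
        table = AliasTable.empty()
        before = len(cluster_candidates(rs, table))
        linked = table.with_pair("Lupus", "SLE")
        after = len(cluster_candidates(rs, linked))
        assert after <= before
        assert after == 2

    def test_matches_transitive_closure_oracle(self, mk_response):
        """Clustering equals connected components of the pairwise link graph."""
        rng = np.random.default_rng(123)
        label_pool = [f"disease {i}" for i in range(8)]
        code_pool = ["A10.1", "B20.2", "C30.3", "D40.4", None, None]
        for trial in range(50):
            rs = []
            for m in range(rng.integers(2, 7)):
                k = int(rng.integers(1, 4))
                picks = rng.choice(len(label_pool), size=k, replace=False)
                cands = []
                for i in picks:
                    code = code_pool[rng.integers(0, len(code_pool))]
                    cands.append((label_pool[i], [code] if code else [], 0.5))
                rs.append(mk_response(f"m{m}", "c1", *cands))
            # random alias graph
            table = AliasTable.empty()
            for _ in range(rng.integers(0, 3)):
                i, j = rng.choice(len(label_pool), size=2, replace=False)
                table = table.with_pair(label_pool[i], label_pool[j])

            clusters = cluster_candidates(rs, table)

            # oracle: brute-force pairwise links + transitive closure
            entries = [
                (r.model_id, c) for r in rs for c in r.candidates
            ]
            n = len(entries)
            linked = [[False] * n for _ in range(n)]
            for i in range(n):
                for j in range(n):
                    ci, cj = entries[i][1], entries[j][1]
                    same_label = canonicalize_label(ci.label).canonical == canonicalize_label(cj.label).canonical
                    gi = table.group_of(canonicalize_label(ci.label).canonical)
                    gj = table.group_of(canonicalize_label(cj.label).canonical)
                    alias_link = gi is not None and gi == gj
                    code_link = bool(set(ci.icd10_codes) & set(cj.icd10_codes))
                    linked[i][j] = same_label or alias_link or code_link or i == j
            # Floyd-Warshall style closure
            for k2 in range(n):
                for i in range(n):
                    for j in range(n):
                        if linked[i][k2] and linked[k2][j]:
                            linked[i][j] = True
            comp_ids = [-1] * n
            n_comps = 0
            for i in range(n):
                if comp_ids[i] == -1:
                    for j in range(n):
                        if linked[i][j]:
                            comp_ids[j] = n_comps
                    n_comps += 1
            assert len(clusters) == n_comps, f"trial {trial}"
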