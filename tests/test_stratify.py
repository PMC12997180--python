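"""Agreement rates, stratum boundaries, model categories, summaries."""

import itertools

import numpy as np
import pytest

from medley.errors import ValidationError
from medley.normalize import DiagnosisCluster, cluster_candidates
from medley.stratify import (
    STRATA,
    StratificationConfig,
    categorize_model_consensus,
    compute_agreement_rates,
    ensemble_summary,
    stratify_differential,
)


def mk_cluster(label, supporters, rate=None, confidence=0.5):
    return DiagnosisCluster(
        canonical_label=label,
        member_labels=(label,),
        supporting_model_ids=tuple(supporters),
        agreement_rate=rate,
        mean_confidence=confidence,
    )


class TestAgreementRates:
    def test_single_model_single_diagnosis_rate_one(self):
        [c] = compute_agreement_rates([mk_cluster("dx", ["m1"])], 1, 1)
        assert c.agreement_rate == 1.0

    def test_fraction_of_responding_models(self):
        [c] = compute_agreement_rates([mk_cluster("dx", [f"m{i}" for i in range(6)])], 20, 20)
        assert c.agreement_rate == pytest.approx(0.30)

    def test_denominator_policy(self):
        clusters = [mk_cluster("dx", ["m1", "m2"])]
        responding = compute_agreement_rates(clusters, 10, 4)
        assert responding[0].agreement_rate == pytest.approx(0.5)
        literal = compute_agreement_rates(
            clusters, 10, 4, StratificationConfig(denominator_policy="all_queried_models")
        )
        assert literal[0].agreement_rate == pytest.approx(0.2)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            compute_agreement_rates([mk_cluster("dx", ["m1"])], 0, 0)

    def test_rates_match_brute_force_tally(self, mk_response):
        rng = np.random.default_rng(5)
        labels = [f"dx{i}" for i in range(5)]
        for _ in range(20):
            n = int(rng.integers(2, 9))
            rs = []
            for m in range(n):
                k = int(rng.integers(1, 4))
                picks = rng.choice(5, size=k, replace=False)
                rs.append(mk_response(f"m{m}", "c", *[(labels[i], [], 0.5) for i in picks]))
            clusters = compute_agreement_rates(
                cluster_candidates(rs), n, n
            )
            # oracle: direct per-label tally over responses
            for c in clusters:
                tally = sum(
                    1 for r in rs if any(cand.label in c.member_labels for cand in r.candidates)
                )
                assert c.agreement_rate == pytest.approx(tally / n)


class TestStratumBoundaries:
    @pytest.mark.parametrize(
        "rate,stratum",
        [
            (0.30, "PRIMARY"),
            (0.31, "PRIMARY"),
            (1.0, "PRIMARY"),
            (0.2999, "ALTERNATIVE"),
            (0.10, "ALTERNATIVE"),
            (0.0999, "MINORITY"),
            (0.01, "MINORITY"),
        ],
    )
    def test_threshold_classification(self, rate, stratum):
        assert StratificationConfig().classify_rate(rate) == stratum

    def test_exhaustive_enumeration_matches_inequalities(self):
        """All (k supporters, n models) with n <= 12 agree with direct
        evaluation of the three stratum inequalities."""
        config = StratificationConfig()
        for n in range(1, 13):
            clusters = [mk_cluster(f"d{k}", [f"m{i}" for i in range(k)]) for k in range(1, n + 1)]
            clusters = compute_agreement_rates(clusters, n, n, config)
            strat = stratify_differential(clusters, config, case_id="x",
                                          total_models=n, responding_models=n)
            placed = {c.canonical_label: s for s in STRATA for c in strat.strata[s]}
            for k in range(1, n + 1):
                rate = k / n
                if rate >= 0.30:
                    expected = "PRIMARY"
                elif rate >= 0.10:
                    expected = "ALTERNATIVE"
                else:
                    expected = "MINORITY"
                assert placed[f"d{k}"] == expected, (k, n)

    def test_partition_and_ordering(self):
        rng = np.random.default_rng(9)
        clusters = [
            mk_cluster(f"d{i}", [f"m{j}" for j in range(int(rng.integers(1, 21)))],
                       confidence=float(rng.random()))
            for i in range(15)
        ]
        clusters = compute_agreement_rates(clusters, 20, 20)
        strat = stratify_differential(clusters, case_id="x", total_models=20, responding_models=20)
        all_placed = [c for s in STRATA for c in strat.strata[s]]
        assert sorted(c.canonical_label for c in all_placed) == sorted(
            c.canonical_label for c in clusters
        )
        for s in STRATA:
            entries = strat.strata[s]
            keys = [(-c.agreement_rate, -c.mean_confidence, c.canonical_label) for c in entries]
            assert keys == sorted(keys)

    def test_adding_supporter_never_demotes(self):
        config = StratificationConfig()
        n = 20
        for k in range(1, n):
            before = config.classify_rate(k / n)
            after = config.classify_rate((k + 1) / n)
            assert STRATA.index(after) <= STRATA.index(before)

    def test_missing_rate_rejected(self):
        with pytest.raises(ValidationError, match="agreement rate"):
            stratify_differential([mk_cluster("dx", ["m1"])])


class TestModelConsensus:
    def _setup(self, mk_response, aligned_cases, total_cases):
        """One model aligned on `aligned_cases` of `total_cases`; majority from 3 others."""
        responses_by_case = {}
        stratified = {}
        for i in range(total_cases):
            cid = f"c{i}"
            rs = [mk_response(f"maj{j}", cid, ("Sepsis", [], 0.8)) for j in range(3)]
            if i < aligned_cases:
                rs.append(mk_response("probe", cid, ("Sepsis", [], 0.6)))
            else:
                rs.append(mk_response("probe", cid, ("Gout", [], 0.6)))
            clusters = compute_agreement_rates(cluster_candidates(rs), 4, 4)
            stratified[cid] = stratify_differential(
                clusters, case_id=cid, total_models=4, responding_models=4
            )
            responses_by_case[cid] = rs
        return responses_by_case, stratified

    @pytest.mark.parametrize(
        "aligned,total,category",
        [
            (5, 6, "high"),  # 83.3%
            (3, 5, "high"),  # 0.60 boundary -> high
            (3, 10, "moderate"),  # 0.30 boundary -> moderate
            (2, 7, "low"),  # 0.286 -> low
        ],
    )
    def test_category_boundaries(self, mk_response, aligned, total, category):
        responses_by_case, stratified = self._setup(mk_response, aligned, total)
        records = categorize_model_consensus(responses_by_case, stratified)
        probe = next(r for r in records if r.model_id == "probe")
        assert probe.majority_alignment_rate == pytest.approx(aligned / total)
        assert probe.category == category

    def test_grid_matches_direct_threshold_evaluation(self):
        config = StratificationConfig()
        for rate in np.arange(0.0, 1.001, 0.005):
            got = config.classify_model_rate(float(rate))
            expected = "high" if rate >= 0.60 else ("moderate" if rate >= 0.30 else "low")
            assert got == expected, rate

    def test_display_rounding_one_decimal(self, mk_response):
        responses_by_case, stratified = self._setup(mk_response, 5, 6)
        records = categorize_model_consensus(responses_by_case, stratified)
        probe = next(r for r in records if r.model_id == "probe")
        assert probe.alignment_pct == "83.3%"


class TestEnsembleSummary:
    def test_consensus_breadth_alternatives(self, mk_response):
        rs = [mk_response(f"m{i}", "c1", ("Sarcoidosis", [], 0.9)) for i in range(19)]
        rs.append(mk_response("m19", "c1", ("Sarcoidosis", [], 0.9), ("Gout", [], 0.3)))
        rs.append(mk_response("m20", "c1", ("Lupus", [], 0.4)))
        rs.append(mk_response("m21", "c1", ("Lyme", [], 0.4)))
        # 22 responding; sarcoidosis 20/22 ~ 0.909
        clusters = compute_agreement_rates(cluster_candidates(rs), 22, 22)
        strat = stratify_differential(clusters, case_id="c1", total_models=22, responding_models=22)
        summary = ensemble_summary(strat, rs)
        assert summary.diagnostic_breadth == 4
        assert summary.alternative_count == 3
        assert summary.consensus_display == 91

    def test_single_cluster_zero_alternatives(self, mk_response):
        rs = [mk_response("m0", "c1", ("Sepsis", [], 0.9))]
        clusters = compute_agreement_rates(cluster_candidates(rs), 1, 1)
        strat = stratify_differential(clusters, case_id="c1", total_models=1, responding_models=1)
        s = ensemble_summary(strat, rs)
        assert s.alternative_count == 0
        assert s.consensus_display == 100

    def test_no_clusters_consensus_null(self, mk_response):
        strat = stratify_differential([], case_id="c1", total_models=2, responding_models=2)
        s = ensemble_summary(strat, [mk_response("m0", "c1")])
        assert s.diagnostic_breadth == 0
        assert s.consensus_rate is None

    def test_permutation_invariance_over_model_order(self, mk_response):
        rs = [
            mk_response("a", "c", ("X", [], 0.5)),
            mk_response("b", "c", ("X", [], 0.5), ("Y", [], 0.4)),
            mk_response("d", "c", ("Z", [], 0.3)),
        ]
        base = None
        for perm in itertools.permutations(rs):
            clusters = compute_agreement_rates(cluster_candidates(list(perm)), 3, 3)
            strat = stratify_differential(clusters, case_id="c", total_models=3, responding_models=3)
            if base is None:
                base = strat
            else:
                assert strat == base


def test_model_with_zero_responses_gets_undefined_low_record(mk_response, caplog):
    rs = [mk_response(f"m{j}", "c0", ("Sepsis", [], 0.8)) for j in range(3)]
    clusters = compute_agreement_rates(cluster_candidates(rs), 3, 3)
    stratified = {"c0": stratify_differential(clusters, case_id="c0",
                                              total_models=3, responding_models=3)}
    with caplog.at_level("WARNING"):
        records = categorize_model_consensus({"c0": rs}, stratified,
                                             model_ids=["m0", "m1", "m2", "silent"])
    silent = next(r for r in records if r.model_id == "silent")
    assert silent.majority_alignment_rate is None
    assert silent.category == "low"
    assert silent.cases_evaluated == 0
    assert any("silent" in r.message for r in caplog.records)
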