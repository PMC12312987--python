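import numpy as np
import pandas as pd
import pytest

from fedstats.federation import (
    AggregateMessage,
    DisclosurePolicy,
    Federation,
    MaskedResultError,
    Node,
    QuerySpec,
    check_disclosure,
    pool_mean,
    pool_quantiles,
    pool_sd,
    pool_table,
    run_query,
)

POLICY = DisclosurePolicy()


class TestCheckDisclosure:
    def test_small_subset_masked(self):
        assert check_disclosure(2, POLICY) == "masked"
        assert check_disclosure(3, POLICY) == "ok"

    def test_small_cell_masked(self):
        assert check_disclosure(42, POLICY, bin_counts=[2, 40]) == "masked"
        assert check_disclosure(43, POLICY, bin_counts=[3, 40]) == "ok"

    def test_zero_subset_masked(self):
        assert check_disclosure(0, POLICY) == "masked"

    def test_empty_cells_pass(self):
        # a zero cell singles out nobody; only 1..threshold-1 disclose
        assert check_disclosure(40, POLICY, bin_counts=[0, 40]) == "ok"

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            DisclosurePolicy(min_cell_count=0)


class TestQuerySpec:
    def test_epsilon_required_with_dp(self):
        with pytest.raises(ValueError):
            QuerySpec("creatinemia", "mean", dp="local")

    def test_epsilon_forbidden_without_dp(self):
        with pytest.raises(ValueError):
            QuerySpec("creatinemia", "mean", epsilon=1.0)

    def test_quantile_needs_q(self):
        with pytest.raises(ValueError):
            QuerySpec("creatinemia", "quantile")


class TestMessages:
    def test_masked_payload_forbidden(self):
        with pytest.raises(ValueError):
            AggregateMessage("n1", 2, {"x": 1}, status="masked")

    def test_no_record_level_data_in_payloads(self, fixture_nodes):
        """Payloads only ever hold scalars / short vectors, never rows."""
        fed = Federation(fixture_nodes[:1])
        for spec in (
            QuerySpec("creatinemia", "mean"),
            QuerySpec("creatinemia", "percentiles"),
            QuerySpec("gender", "histogram"),
        ):
            msg = fed.run_query(spec).messages[0]
            flat = []
            for v in msg.payload.values():
                flat.extend(v if isinstance(v, (list, tuple)) else [v])
            assert len(flat) < msg.n


class TestExactQueries:
    def test_pooled_count(self, fixture_nodes, fixture_pooled):
        res = run_query(fixture_nodes, QuerySpec("creatinemia", "count"))
        assert res.value == len(fixture_pooled)

    def test_pooled_mean_matches_raw(self, fixture_nodes, fixture_pooled):
        res = run_query(fixture_nodes, QuerySpec("creatinemia", "mean"))
        assert res.value == pytest.approx(fixture_pooled["creatinemia"].mean(), rel=1e-12)

    def test_pooled_sd_matches_raw(self, fixture_nodes, fixture_pooled):
        res = run_query(fixture_nodes, QuerySpec("creatinemia", "sd"))
        raw = fixture_pooled["creatinemia"].dropna().to_numpy()
        n = raw.size
        expected = np.sqrt(raw.var() * n / (n - 1))
        assert res.value == pytest.approx(expected, rel=1e-12)

    def test_filter(self, fixture_nodes, fixture_pooled):
        res = run_query(
            fixture_nodes, QuerySpec("creatinemia", "mean", filter={"period": "before"})
        )
        raw = fixture_pooled.loc[fixture_pooled["period"] == "before", "creatinemia"]
        assert res.value == pytest.approx(raw.mean(), rel=1e-12)

    def test_histogram_pools_counts(self, fixture_nodes, fixture_pooled):
        res = run_query(fixture_nodes, QuerySpec("gender", "histogram"))
        expected = fixture_pooled["gender"].value_counts()
        assert res.value["Female"] == expected["Female"]
        assert res.value["Male"] == expected["Male"]

    def test_grouped_histogram_is_crosstab(self, fixture_nodes, fixture_pooled):
        res = run_query(
            fixture_nodes, QuerySpec("treatment_category", "histogram", group_by="period")
        )
        ct = pd.crosstab(fixture_pooled["treatment_category"], fixture_pooled["period"])
        for cat in res.value.index:
            for period in ("before", "after"):
                assert res.value.loc[cat, period] == (
                    ct.loc[cat, period] if cat in ct.index else 0
                )

    def test_min_max(self, fixture_nodes, fixture_pooled):
        lo = run_query(fixture_nodes, QuerySpec("creatinemia", "min")).value
        hi = run_query(fixture_nodes, QuerySpec("creatinemia", "max")).value
        raw = fixture_pooled["creatinemia"].dropna()
        assert lo == pytest.approx(raw.min())
        assert hi == pytest.approx(raw.max())


class TestMasking:
    def test_all_masked_raises(self, make_cohort_table):
        nodes = [Node("tiny", make_cohort_table(n=2))]
        with pytest.raises(MaskedResultError):
            run_query(nodes, QuerySpec("creatinemia", "mean"))

    def test_partial_masking_pools_survivors(self, make_cohort_table):
        big = make_cohort_table(center="big", n=30, creatinemia=np.full(30, 50.0))
        tiny = make_cohort_table(center="tiny", n=2)
        res = run_query([Node("big", big), Node("tiny", tiny)], QuerySpec("creatinemia", "mean"))
        assert res.value == pytest.approx(50.0)
        assert len(res.warnings) == 1
        masked = [m for m in res.messages if m.status == "masked"]
        assert masked[0].payload is None

    def test_strict_policy_raises_on_any_mask(self, make_cohort_table):
        big = make_cohort_table(center="big", n=30)
        tiny = make_cohort_table(center="tiny", n=2)
        fed = Federation(
            [Node("big", big), Node("tiny", tiny)], DisclosurePolicy(strict=True)
        )
        with pytest.raises(MaskedResultError):
            fed.run_query(QuerySpec("creatinemia", "mean"))

    def test_histogram_small_cell_masks_node(self, make_cohort_table):
        g = np.array(["Female"] * 28 + ["Male"] * 2)
        t = make_cohort_table(n=30, gender=g)
        with pytest.raises(MaskedResultError):
            run_query([Node("n1", t)], QuerySpec("gender", "histogram"))

    def test_masking_independent_of_noise(self, make_cohort_table):
        """The disclosure check runs on true counts, not noisy ones."""
        g = np.array(["Female"] * 28 + ["Male"] * 2)
        t = make_cohort_table(n=30, gender=g)
        for seed in range(20):
            with pytest.raises(MaskedResultError):
                run_query(
                    [Node("n1", t)],
                    QuerySpec("gender", "histogram", dp="local", epsilon=100.0),
                    root_seed=seed,
                )


class TestPooling:
    def test_pool_mean_weighted(self):
        assert pool_mean([(10, 1.0), (30, 5.0)]) == pytest.approx(4.0)

    def test_pool_sd_equals_concatenated(self):
        rng = np.random.default_rng(0)
        parts = [rng.normal(i, 2.0, 20 + 5 * i) for i in range(3)]
        msgs = [(len(p), p.mean(), p.std(ddof=1)) for p in parts]
        allv = np.concatenate(parts)
        assert pool_sd(msgs) == pytest.approx(allv.std(ddof=1), rel=1e-12)

    def test_pool_table_sums(self):
        a = pd.DataFrame([[1, 2], [3, 4]], index=["x", "y"], columns=["u", "v"])
        b = pd.DataFrame([[5, 6], [7, 8]], index=["x", "y"], columns=["u", "v"])
        out = pool_table([a, b])
        assert out.loc["y", "v"] == 12

    def test_pool_table_mismatch_rejected(self):
        a = pd.DataFrame([[1, 2]], index=["x"], columns=["u", "v"])
        b = pd.DataFrame([[1, 2]], index=["y"], columns=["u", "v"])
        with pytest.raises(ValueError):
            pool_table([a, b])

    def test_pool_quantiles_weighted(self):
        out = pool_quantiles([(10, [1.0, 2.0]), (30, [5.0, 6.0])])
        assert out == pytest.approx([4.0, 5.0])

    def test_pool_quantiles_grid_mismatch(self):
        with pytest.raises(ValueError):
            pool_quantiles([(10, [1.0]), (10, [1.0, 2.0])])


class TestDP:
    def test_local_dp_deterministic_per_seed(self, fixture_tables):
        def run(seed):
            nodes = [Node(t.center, t) for t in fixture_tables]
            return Federation(nodes, root_seed=seed).run_query(
                QuerySpec("creatinemia", "mean", dp="local", epsilon=5.0)
            ).value

        assert run(11) == run(11)
        assert run(11) != run(12)

    def test_local_dp_charges_every_node(self, fixture_tables):
        nodes = [Node(t.center, t) for t in fixture_tables]
        fed = Federation(nodes, root_seed=0)
        fed.run_query(QuerySpec("creatinemia", "mean", dp="local", epsilon=5.0))
        for nd in nodes:
            assert nd.ledger.total(nd.id) == 5.0

    def test_central_dp_charges_coordinator_once(self, fixture_tables):
        nodes = [Node(t.center, t) for t in fixture_tables]
        fed = Federation(nodes, root_seed=0)
        fed.run_query(QuerySpec("creatinemia", "count", dp="central", epsilon=2.0))
        assert fed.central_ledger.total("coordinator") == 2.0
        for nd in nodes:
            assert nd.ledger.total(nd.id) == 0.0

    def test_local_noise_approximately_unbiased(self, fixture_tables):
        truth = run_query(
            [Node(t.center, t) for t in fixture_tables], QuerySpec("creatinemia", "count")
        ).value
        vals = []
        for seed in range(300):
            nodes = [Node(t.center, t) for t in fixture_tables]
            vals.append(
                Federation(nodes, root_seed=seed)
                .run_query(QuerySpec("creatinemia", "count", dp="local", epsilon=1.0))
                .value
            )
        assert abs(np.mean(vals) - truth) < 0.5

    def test_noise_free_equals_exact(self, fixture_tables):
        exact = run_query(
            [Node(t.center, t) for t in fixture_tables], QuerySpec("creatinemia", "mean")
        ).value
        nodes = [Node(t.center, t) for t in fixture_tables]
        nf = Federation(nodes, root_seed=5, noise_free=True).run_query(
            QuerySpec("creatinemia", "mean", dp="local", epsilon=5.0)
        )
        assert nf.value == pytest.approx(exact, rel=1e-9)
        # budget accounting unchanged in noise-free mode
        for nd in nodes:
            assert nd.ledger.total(nd.id) == 5.0

    def test_message_log_grows(self, fixture_tables):
        nodes = [Node(t.center, t) for t in fixture_tables]
        fed = Federation(nodes)
        fed.run_query(QuerySpec("creatinemia", "mean"))
        fed.run_query(QuerySpec("gender", "histogram"))
        assert len(fed.message_log) == 6
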