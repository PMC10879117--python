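"""Editing statistics: efficiency formulas, purity, indels, filters,
outcome distributions and bias groupings, checked against independent
brute-force recounts and hand-derived values."""

import numpy as np
import pytest

from bescope import (
    AlleleRow,
    RunConfig,
    SiteError,
    SiteEditingSummary,
    average_replicates,
    be_indel_ratio,
    classify_efficiency_bias,
    classify_outcome_consistency,
    collapse_outcomes,
    cooccurrence_matrix,
    edited_base_count_distribution,
    filter_outcome_replicates,
    indel_position_profile,
    summarize_site,
)
from bescope.quant import OutcomeAllele, OutcomeDistribution, pattern_string
from bescope.sites import TRANSITIONS

from conftest import CONTEXT, make_table, edit_at_position, edited


# ---------------------------------------------------------------------------
# independent read-by-read oracle (deliberately naive: expands each
# allele row into individual reads and recounts)

def brute_force_summary(table, site, cfg):
    window = set(range(cfg.window[0], cfg.window[1] + 1))
    offset = table.reference.find(site.protospacer)
    product = {"ABE": "G", "CBE": "T"}[site.editor]
    reads = []
    for row in table.rows:
        reads.extend([row] * row.n_reads)
    total = len(reads)
    n_overall = n_modified = 0
    per_pos = np.zeros(20)
    trans = {sc: dict.fromkeys(TRANSITIONS, 0) for sc in ("overall", "in_window", "outside_window")}
    for row in reads:
        intended_window = False
        mutated = bool(row.insertions) or "-" in row.aligned
        seen = {sc: set() for sc in trans}
        for p in range(1, 21):
            i = offset + p - 1
            a, r = row.aligned[i], table.reference[i]
            if a in ("-",) or a == r:
                continue
            seen["overall"].add(f"{r}>{a}")
            seen["in_window" if p in window else "outside_window"].add(f"{r}>{a}")
            if r == site.target_base and a == product:
                per_pos[p - 1] += 1
                if p in window:
                    intended_window = True
        for i, (a, r) in enumerate(zip(row.aligned, table.reference)):
            if a != r and a != "-":
                mutated = True
        if intended_window:
            n_overall += 1
        if mutated:
            n_modified += 1
        for sc, ts in seen.items():
            for t in ts:
                trans[sc][t] += 1
    props = {}
    for sc in trans:
        s = sum(trans[sc].values())
        props[sc] = {t: c / s for t, c in trans[sc].items() if c} if s else {}
    return {
        "overall": n_overall / total,
        "modified": n_modified / total,
        "per_position": per_pos / total,
        "transition_proportions": props,
    }


class TestSummarizeSite:
    def test_direct_formula(self, abe_site, abe_cfg):
        table = make_table([
            dict(aligned=CONTEXT, n_reads=850),
            dict(aligned=edit_at_position(CONTEXT, 5), n_reads=150),
        ])
        s = summarize_site(table, abe_site, abe_cfg)
        assert s.overall_efficiency == pytest.approx(0.15)
        assert s.per_position_efficiency[4] == pytest.approx(0.15)
        assert s.modified_efficiency == pytest.approx(0.15)

    def test_all_wild_type(self, abe_site, abe_cfg):
        s = summarize_site(make_table([dict(aligned=CONTEXT, n_reads=10)]),
                           abe_site, abe_cfg)
        assert s.overall_efficiency == 0
        assert s.modified_efficiency == 0
        assert all(not v for v in s.transition_proportions.values())

    def test_unintended_transition_counts_in_purity_not_efficiency(self, abe_site, abe_cfg):
        # C->T edits under ABE: zero intended efficiency, pure C>T purity
        table = make_table([
            dict(aligned=CONTEXT, n_reads=90),
            dict(aligned=edited(CONTEXT, {10 + 3: "T"}), n_reads=10),  # C4->T
        ])
        s = summarize_site(table, abe_site, abe_cfg)
        assert s.overall_efficiency == 0
        assert s.transition_proportions["overall"]["C>T"] == pytest.approx(1.0)
        assert s.transition_proportions["in_window"] == {}

    def test_matches_brute_force_oracle(self, abe_site, abe_cfg, random_tables):
        for table in random_tables:
            s = summarize_site(table, abe_site, abe_cfg)
            oracle = brute_force_summary(table, abe_site, abe_cfg)
            assert s.overall_efficiency == oracle["overall"]
            assert s.modified_efficiency == oracle["modified"]
            got = [0.0 if v is None else v for v in s.per_position_efficiency]
            exp = [
                oracle["per_position"][p - 1] if abe_site.base_at(p) == "A" else 0.0
                for p in range(1, 21)
            ]
            assert got == pytest.approx(exp)
            assert s.transition_proportions == oracle["transition_proportions"]

    def test_overall_never_exceeds_modified(self, abe_site, abe_cfg, random_tables):
        for table in random_tables:
            s = summarize_site(table, abe_site, abe_cfg)
            assert s.overall_efficiency <= s.modified_efficiency + 1e-12

    def test_purity_scopes_sum_to_one(self, abe_site, abe_cfg, random_tables):
        for table in random_tables:
            s = summarize_site(table, abe_site, abe_cfg)
            for scope, props in s.transition_proportions.items():
                if props:
                    assert sum(props.values()) == pytest.approx(1.0)

    def test_reference_mismatch_errors(self, abe_site, abe_cfg):
        table = make_table([dict(aligned="A" * 40, n_reads=5)], reference="A" * 40)
        with pytest.raises(SiteError, match="mismatch"):
            summarize_site(table, abe_site, abe_cfg)


class TestAverageReplicates:
    def _summary(self, eff, reads):
        return SiteEditingSummary(
            site_id="s1", editor="ABE", overall_efficiency=eff,
            modified_efficiency=eff, total_reads=reads,
        )

    def test_low_coverage_replicate_excluded(self, abe_cfg):
        avg = average_replicates([self._summary(0.9, 99), self._summary(0.1, 500)], abe_cfg)
        assert avg.overall_efficiency == pytest.approx(0.1)
        assert avg.n_replicates == 1

    def test_mean_of_surviving_replicates(self, abe_cfg):
        avg = average_replicates([self._summary(0.2, 500), self._summary(0.4, 500)], abe_cfg)
        assert avg.overall_efficiency == pytest.approx(0.3)

    def test_all_below_coverage_drops_site(self, abe_cfg):
        assert average_replicates([self._summary(0.2, 50), self._summary(0.4, 99)], abe_cfg) is None


class TestIndelProfile:
    def _site_with_freq(self, f, pos=5, length=-1):
        return SiteEditingSummary(site_id=f"s{f}", editor="ABE",
                                  indel_by_position_length={(pos, length): f})

    def test_interquartile_retention(self):
        # frequencies 1..8: Q25 = 2.75, Q75 = 6.25 -> retain {3, 4, 5, 6}
        sites = [self._site_with_freq(f) for f in range(1, 9)]
        profile = indel_position_profile(sites, lengths=(-1,))
        assert profile[-1][4] == pytest.approx(np.mean([3, 4, 5, 6]))

    def test_identical_sites_all_retained(self):
        sites = [self._site_with_freq(0.02) for _ in range(6)]
        profile = indel_position_profile(sites, lengths=(-1,))
        assert profile[-1][4] == pytest.approx(0.02)

    def test_insertion_peak_position_preserved(self):
        sites = [self._site_with_freq(0.01, pos=18, length=1) for _ in range(4)]
        profile = indel_position_profile(sites, lengths=(1,))
        assert int(np.argmax(profile[1])) + 1 == 18

    def test_too_few_sites(self):
        with pytest.raises(SiteError, match="insufficient sites"):
            indel_position_profile([self._site_with_freq(1)] * 3)


class TestBeIndelRatio:
    def _summary(self, eff, indel, sid="s"):
        return SiteEditingSummary(site_id=sid, editor="ABE",
                                  overall_efficiency=eff, deaminase_indel_freq=indel)

    def test_geometric_mean(self):
        sites = [self._summary(0.5, 0.05, "a"), self._summary(0.5, 0.0005, "b")]
        gm, ratios = be_indel_ratio(sites, "deaminase")
        assert ratios == {"a": pytest.approx(10.0), "b": pytest.approx(1000.0)}
        assert gm == pytest.approx(100.0)

    def test_zero_indel_sites_excluded(self):
        sites = [self._summary(0.5, 0.05, "a"), self._summary(0.5, 0.0, "b")]
        gm, ratios = be_indel_ratio(sites, "deaminase")
        assert set(ratios) == {"a"} and gm == pytest.approx(10.0)

    def test_no_usable_site_errors(self):
        with pytest.raises(SiteError):
            be_indel_ratio([self._summary(0.5, 0.0)], "deaminase")


class TestOutcomeFiltering:
    def test_identical_replicates_all_retained(self, abe_cfg):
        rows = [dict(aligned=edit_at_position(CONTEXT, 5), n_reads=95),
                dict(aligned=CONTEXT, n_reads=5)]
        tables = [make_table(rows, replicate_id=f"r{i}") for i in range(3)]
        assert len(filter_outcome_replicates(tables, abe_cfg)) == 3

    def test_low_edited_fraction_removed(self, abe_cfg):
        good = make_table([dict(aligned=edit_at_position(CONTEXT, 5), n_reads=95),
                           dict(aligned=CONTEXT, n_reads=5)], replicate_id="r1")
        bad = make_table([dict(aligned=edit_at_position(CONTEXT, 5), n_reads=50),
                          dict(aligned=CONTEXT, n_reads=50)], replicate_id="r2")
        kept = filter_outcome_replicates([good, bad], abe_cfg)
        assert [t.replicate_id for t in kept] == ["r1"]


class TestCollapseOutcomes:
    def test_wildtype_removed_and_renormalized(self, abe_site, abe_cfg):
        tables = [make_table([
            dict(aligned=CONTEXT, n_reads=900),
            dict(aligned=edit_at_position(CONTEXT, 5), n_reads=60),
            dict(aligned=edit_at_position(CONTEXT, [5, 6]), n_reads=40),
        ])]
        dist = collapse_outcomes(tables, abe_site, abe_cfg)
        props = dist.by_pattern()
        assert props[pattern_string([5])] == pytest.approx(0.6)
        assert props[pattern_string([5, 6])] == pytest.approx(0.4)

    def test_rare_allele_dropped(self, abe_site, abe_cfg):
        tables = [make_table([
            dict(aligned=edit_at_position(CONTEXT, 5), n_reads=96),
            dict(aligned=edit_at_position(CONTEXT, 6), n_reads=4),
        ])]
        dist = collapse_outcomes(tables, abe_site, abe_cfg)
        assert dist.by_pattern() == {pattern_string([5]): pytest.approx(1.0)}

    def test_single_edited_allele(self, abe_site, abe_cfg):
        tables = [make_table([dict(aligned=edit_at_position(CONTEXT, 7), n_reads=10)])]
        dist = collapse_outcomes(tables, abe_site, abe_cfg)
        assert dist.total() == pytest.approx(1.0)
        assert len(dist.alleles) == 1

    def test_idempotent_on_own_output(self, abe_site, abe_cfg):
        tables = [make_table([
            dict(aligned=CONTEXT, n_reads=500),
            dict(aligned=edit_at_position(CONTEXT, 5), n_reads=300),
            dict(aligned=edit_at_position(CONTEXT, [5, 6]), n_reads=150),
            dict(aligned=edit_at_position(CONTEXT, [5, 6, 7]), n_reads=50),
        ])]
        dist = collapse_outcomes(tables, abe_site, abe_cfg)
        # feed the distribution back as scaled read counts
        rows = []
        for a in dist.alleles:
            rows.append(dict(
                aligned=edit_at_position(CONTEXT, list(a.edited_positions)),
                n_reads=int(round(a.proportion * 1e6)),
            ))
        again = collapse_outcomes([make_table(rows)], abe_site, abe_cfg)
        first, second = dist.by_pattern(), again.by_pattern()
        assert set(first) == set(second)
        for k in first:
            assert first[k] == pytest.approx(second[k], abs=1e-5)

    def test_indel_reads_excluded(self, abe_site, abe_cfg):
        tables = [make_table([
            dict(aligned=edit_at_position(CONTEXT, 5), n_reads=50),
            dict(aligned=edit_at_position(CONTEXT, 5, base="-"), n_reads=50, n_deleted=1),
        ])]
        dist = collapse_outcomes(tables, abe_site, abe_cfg)
        assert dist.by_pattern() == {pattern_string([5]): pytest.approx(1.0)}


def _dist(patterns_props, site_id="s"):
    return OutcomeDistribution(
        site_id=site_id,
        alleles=[OutcomeAllele(pattern=pattern_string(p), proportion=v)
                 for p, v in patterns_props],
    )


class TestOutcomeConsistency:
    def test_same_sets_different_proportions(self):
        endo = _dist([([5], 0.7), ([6], 0.3)])
        inte = _dist([([5], 0.2), ([6], 0.8)])
        assert classify_outcome_consistency(endo, inte) == "Consistent"

    def test_strict_superset_is_bias(self):
        endo = _dist([([5], 0.5), ([6], 0.5)])
        inte = _dist([([5], 1.0)])
        assert classify_outcome_consistency(endo, inte) == "Endo-bias"
        assert classify_outcome_consistency(inte, endo) == "Inte-bias"

    def test_mutual_unique_alleles_discordant(self):
        endo = _dist([([5], 0.5), ([6], 0.5)])
        inte = _dist([([5], 0.5), ([7], 0.5)])
        assert classify_outcome_consistency(endo, inte) == "Discordant"

    def test_label_symmetry(self):
        swap = {"Endo-bias": "Inte-bias", "Inte-bias": "Endo-bias",
                "Consistent": "Consistent", "Discordant": "Discordant"}
        cases = [
            (_dist([([5], 1.0)]), _dist([([5], 1.0)])),
            (_dist([([5], 0.5), ([6], 0.5)]), _dist([([5], 1.0)])),
            (_dist([([5], 1.0)]), _dist([([6], 1.0)])),
        ]
        for a, b in cases:
            assert classify_outcome_consistency(b, a) == \
                swap[classify_outcome_consistency(a, b)]

    def test_empty_distribution_errors(self):
        with pytest.raises(SiteError):
            classify_outcome_consistency(_dist([]), _dist([([5], 1.0)]))


class TestEfficiencyBias:
    def test_derived_residual_grouping(self):
        # x chosen so the residuals of y = x + r are exactly r = (-2,-1,0,1,2):
        # sum(r) = 0 and sum(r*x) = 0 keep OLS at slope 1, intercept 0.
        x = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        r = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = x + r
        groups = classify_efficiency_bias([f"s{i}" for i in range(5)], y, x)
        assert groups.slope == pytest.approx(1.0)
        assert groups.residual_sigma == pytest.approx(np.sqrt(2.0))  # population sd
        assert groups.labels == ["Inte-bias", "Consistent", "Consistent",
                                 "Consistent", "Endo-bias"]

    def test_zero_sigma_all_consistent(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        groups = classify_efficiency_bias(list("abcd"), 2 * x, x)
        assert groups.residual_sigma == pytest.approx(0.0)
        assert set(groups.labels) == {"Consistent"}

    def test_degenerate_regressor_errors(self):
        with pytest.raises(SiteError, match="degenerate"):
            classify_efficiency_bias(list("abc"), [0.1, 0.2, 0.3], [0.5, 0.5, 0.5])


class TestPatternStatistics:
    def test_cooccurrence_single_allele(self):
        positions, m = cooccurrence_matrix(_dist([([5, 6], 1.0)]))
        i, j = positions.index(5), positions.index(6)
        assert m[i, j] == pytest.approx(1.0)
        assert m[i, i] == pytest.approx(1.0)

    def test_disjoint_singles_have_zero_off_diagonal(self):
        positions, m = cooccurrence_matrix(_dist([([5], 0.5), ([7], 0.5)]))
        assert m[positions.index(5), positions.index(7)] == 0.0
        assert np.diag(m) == pytest.approx([0.5, 0.5])

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(0)
        alleles = [(sorted(rng.choice(range(1, 9), size=rng.integers(1, 4),
                                      replace=False).tolist()), 0.2)
                   for _ in range(5)]
        _, m = cooccurrence_matrix(_dist(alleles))
        assert np.allclose(m, m.T)

    def test_edited_base_count_histogram(self):
        hist = edited_base_count_distribution(_dist([([5], 0.7), ([5, 6], 0.3)]))
        assert hist == {1: pytest.approx(0.7), 2: pytest.approx(0.3)}
        assert edited_base_count_distribution(_dist([])) == {}
        assert edited_base_count_distribution(
            _dist([([5, 6], 0.4), ([6, 7], 0.6)])) == {2: pytest.approx(1.0)}
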