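"""Feature-to-state assignment, enrichment folds, gene pairs, promoters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chromband.feature_enrichment import (
    HEAD_TO_HEAD,
    HEAD_TO_TAIL,
    MULTI_STATE,
    NO_DATA,
    TAIL_TO_TAIL,
    assign_features_to_states,
    classify_gene_pairs,
    enrichment_report,
    fold_enrichment,
    orientation_state_summary,
    overlap_percentages,
    promoter_class_distribution,
)
from chromband.genomic_io import FeatureSet, GeneModels
from chromband.state_model import StateFragments
from _oracles import chi_square_by_hand


@pytest.fixture
def fragments():
    # chrX: cyan [0,1000) blue [1000,2000) gap [2000,2400) magenta [2400,4000)
    return StateFragments(pd.DataFrame([
        {"chrom": "chrX", "start": 0, "end": 1000, "state": "cyan"},
        {"chrom": "chrX", "start": 1000, "end": 2000, "state": "blue"},
        {"chrom": "chrX", "start": 2400, "end": 4000, "state": "magenta"},
    ]))


class TestAssignment:
    def test_point_inside_fragment(self, fragments):
        fs = FeatureSet.points([("chrX", 500)])
        a = assign_features_to_states(fs, fragments)
        assert a.labels.tolist() == ["cyan"]

    def test_interval_straddling_boundary_excluded_multi_state(self, fragments):
        fs = FeatureSet.from_records([("chrX", 900, 1100)])
        a = assign_features_to_states(fs, fragments)
        assert a.labels.tolist() == [MULTI_STATE]

    def test_feature_in_gap_excluded_no_data(self, fragments):
        fs = FeatureSet.points([("chrX", 2200)])
        a = assign_features_to_states(fs, fragments)
        assert a.labels.tolist() == [NO_DATA]

    def test_interval_spilling_into_gap_is_no_data(self, fragments):
        fs = FeatureSet.from_records([("chrX", 1900, 2100)])
        a = assign_features_to_states(fs, fragments)
        assert a.labels.tolist() == [NO_DATA]

    def test_conservation_of_counts(self, fragments):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 4000, size=200)
        fs = FeatureSet.points([("chrX", int(p)) for p in pos])
        a = assign_features_to_states(fs, fragments)
        assert a.n_assigned + sum(a.exclusions.values()) == 200


class TestFold:
    def test_reference_ratio(self):
        assert fold_enrichment(78.3, 12.7) == pytest.approx(6.2, abs=0.05)

    def test_uniform_is_unity_and_empty_is_zero(self):
        assert fold_enrichment(50, 50) == 1.0
        assert fold_enrichment(0, 48.0) == 0.0

    def test_zero_genome_fraction_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(10.0, 0.0)


class TestGenePairs:
    def _genes(self, rows):
        return GeneModels(pd.DataFrame(
            [{"gene_id": f"g{i}", "chrom": "chrX", "start": s, "end": e, "strand": st}
             for i, (s, e, st) in enumerate(rows)]))

    def test_divergent_pair_is_head_to_head(self):
        pairs = classify_gene_pairs(self._genes([(0, 1000, "-"), (1500, 2500, "+")]))
        assert pairs.loc[0, "orientation"] == HEAD_TO_HEAD
        assert pairs.loc[0, "gap"] == 500 and pairs.loc[0, "in_window"]

    def test_wide_gap_flagged_out_of_window(self):
        pairs = classify_gene_pairs(self._genes([(0, 1000, "-"), (3500, 4500, "+")]))
        assert pairs.loc[0, "orientation"] == HEAD_TO_HEAD
        assert not pairs.loc[0, "in_window"]

    def test_same_strand_is_head_to_tail(self):
        pairs = classify_gene_pairs(self._genes([(0, 1000, "+"), (1500, 2500, "+")]))
        assert pairs.loc[0, "orientation"] == HEAD_TO_TAIL

    def test_convergent_is_tail_to_tail(self):
        pairs = classify_gene_pairs(self._genes([(0, 1000, "+"), (1500, 2500, "-")]))
        assert pairs.loc[0, "orientation"] == TAIL_TO_TAIL

    def test_overlapping_bodies_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="overlapping"):
            pairs = classify_gene_pairs(self._genes([(0, 1000, "-"), (500, 2000, "+")]))
        assert pairs.empty

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 20),
                              st.booleans()), min_size=2, max_size=6))
    def test_strand_flip_mirror_symmetry(self, raw):
        # build non-overlapping genes, then mirror coordinates and strands
        rows, pos = [], 0
        for gap, length, plus in raw:
            start = pos + gap
            rows.append((start * 100, (start + length) * 100, "+" if plus else "-"))
            pos = start + length
        total = pos * 100 + 1000
        fwd = classify_gene_pairs(self._genes(rows))
        mirrored = [(total - e, total - s, "+" if st_ == "-" else "-")
                    for s, e, st_ in reversed(rows)]
        rev = classify_gene_pairs(self._genes(mirrored))
        assert sorted(fwd["orientation"]) == sorted(rev["orientation"])
        assert sorted(fwd["gap"]) == sorted(rev["gap"])


class TestEnrichmentReport:
    def test_chi_square_matches_hand_expansion(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(1, 500, size=4)
            fracs = rng.dirichlet(np.ones(4)) * 100
            labels = pd.Series(
                ["cyan"] * counts[0] + ["blue"] * counts[1]
                + ["green"] * counts[2] + ["magenta"] * counts[3])
            from chromband.feature_enrichment import StateAssignment
            report = enrichment_report(
                StateAssignment(labels),
                dict(zip(["blue", "cyan", "green", "magenta"], fracs)))
            total = counts.sum()
            order = sorted(zip(["cyan", "blue", "green", "magenta"], counts))
            obs = [c for _, c in order]
            exp = [total * report.table.set_index("state").loc[s, "genome_pct"] /
                   report.table["genome_pct"].sum() for s, _ in order]
            # independent check against scipy and the literal formula
            exp_raw = total * np.array(sorted(zip(
                ["blue", "cyan", "green", "magenta"], fracs)))[:, 1].astype(float)
            exp_raw /= exp_raw.sum() / total
            assert report.statistic == pytest.approx(chi_square_by_hand(obs, exp_raw))
            scipy_stat, _ = stats.chisquare(obs, exp_raw)
            assert report.statistic == pytest.approx(scipy_stat)

    def test_concentrated_counts_maximize_chi_square(self):
        from chromband.feature_enrichment import StateAssignment
        fracs = {s: 25.0 for s in ("cyan", "blue", "green", "magenta")}
        conc = enrichment_report(StateAssignment(pd.Series(["cyan"] * 100)), fracs)
        spread = enrichment_report(
            StateAssignment(pd.Series(["cyan"] * 40 + ["blue"] * 30
                                      + ["green"] * 20 + ["magenta"] * 10)), fracs)
        assert conc.statistic > spread.statistic


class TestOrientationSummary:
    def test_counts_and_percentages(self, fragments):
        genes = GeneModels(pd.DataFrame([
            # divergent pair with facing 5' ends in cyan
            {"gene_id": "a", "chrom": "chrX", "start": 100, "end": 400, "strand": "-"},
            {"gene_id": "b", "chrom": "chrX", "start": 600, "end": 900, "strand": "+"},
            # divergent pair in magenta
            {"gene_id": "c", "chrom": "chrX", "start": 2500, "end": 2900, "strand": "-"},
            {"gene_id": "d", "chrom": "chrX", "start": 3000, "end": 3400, "strand": "+"},
        ]))
        pairs = classify_gene_pairs(genes)
        report = orientation_state_summary(
            pairs, genes, fragments,
            {"cyan": 25.0, "blue": 25.0, "green": 25.0, "magenta": 25.0})
        row = report.table.set_index("state")
        assert row.loc["cyan", "count"] == 2 and row.loc["magenta", "count"] == 2
        assert row.loc["cyan", "feature_pct"] == 50.0


class TestPromoters:
    def _promoters(self):
        return FeatureSet(pd.DataFrame([
            {"chrom": "chrX", "start": 100, "end": 250, "strand": ".",
             "name": "p1", "attr": "broad"},
            {"chrom": "chrX", "start": 400, "end": 550, "strand": ".",
             "name": "p2", "attr": "broad"},
            {"chrom": "chrX", "start": 1200, "end": 1201, "strand": ".",
             "name": "p3", "attr": "peaked"},
        ]))

    def test_class_state_table(self, fragments):
        dist = promoter_class_distribution(self._promoters(), fragments)
        t = dist.table.set_index(["class", "state"])
        assert t.loc[("broad", "cyan"), "count"] == 2
        assert t.loc[("broad", "cyan"), "pct"] == 100.0
        assert t.loc[("broad", "blue"), "pct"] == 0.0
        assert t.loc[("peaked", "blue"), "count"] == 1

    def test_unknown_class_label_rejected(self, fragments):
        bad = FeatureSet(pd.DataFrame([{
            "chrom": "chrX", "start": 0, "end": 10, "strand": ".",
            "name": "p", "attr": "sharp"}]))
        with pytest.raises(ValueError, match="sharp"):
            promoter_class_distribution(bad, fragments)

    def test_interband_broad_coverage_percentages(self, fragments):
        interbands = FeatureSet.from_records([
            ("chrX", 0, 300), ("chrX", 350, 600), ("chrX", 2400, 3000)])
        dist = promoter_class_distribution(self._promoters(), fragments, interbands)
        s = dist.interband_summary
        assert (s["n_with_broad"], s["n_without_broad"]) == (2, 1)
        assert s["pct_without_broad"] == 33.3


class TestOverlapPercentages:
    def test_all_in_one_state(self, fragments):
        fs = FeatureSet.points([("chrX", 100), ("chrX", 200), ("chrX", 900)])
        pct, excl = overlap_percentages(fs, fragments)
        assert pct["cyan"] == 100.0 and excl[NO_DATA] == 0

    def test_features_only_in_gaps_all_excluded(self, fragments):
        fs = FeatureSet.points([("chrX", 2100), ("chrX", 2300)])
        pct, excl = overlap_percentages(fs, fragments)
        assert excl[NO_DATA] == 2
        assert (pct == 0).all()
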