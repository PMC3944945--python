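"""Corpus ingestion, frequency tables, TTR, Pareto curves, depth-of-use."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from readzipf.coding_model import EmptyInputError, Section
from readzipf.corpus_stats import (
    ColumnMap,
    ConfigurationError,
    EncounterCorpus,
    build_frequency_table,
    filter_section,
    pareto_curve,
    read_events,
    stratify_by_practice,
    summarize,
    type_token_ratio,
    usage_depth_profile,
    write_events,
)

from conftest import make_corpus


def _write_csv(tmp_path, rows, header="patient_id,practice_id,date,code"):
    path = tmp_path / "events.csv"
    path.write_text("\n".join([header] + rows) + "\n", encoding="utf-8")
    return path


class TestReadEvents:
    def test_basic_ingest(self, tmp_path):
        path = _write_csv(tmp_path, [
            "S1,P1,2005-01-01,G3011",
            "S2,P1,2005-01-02,G30",
            "S3,P2,2005-01-03,a111",
        ])
        corpus = read_events(path)
        assert corpus.n_tokens == 3
        assert corpus.n_types == 3
        assert corpus.rejects.empty

    def test_malformed_rows_collected(self, tmp_path):
        path = _write_csv(tmp_path, [
            "S1,P1,2005-01-01,G3011",
            "S2,P1,2005-01-02,G30111",  # 6 characters
            "S3,P2,2005-01-03,a111",
            "S4,P2,2005-01-04,68",
        ])
        corpus = read_events(path)
        assert corpus.n_tokens == 3
        assert len(corpus.rejects) == 1
        line, raw, reason = corpus.rejects.iloc[0]
        assert line == 2 and raw == "G30111" and "G30111" in reason

    def test_missing_column_is_config_error(self, tmp_path):
        path = _write_csv(tmp_path, ["S1,P1,2005-01-01,G3011"])
        with pytest.raises(ConfigurationError, match="read_code"):
            read_events(path, ColumnMap(code="read_code"))

    def test_mostly_rejected_is_hard_failure(self, tmp_path):
        path = _write_csv(tmp_path, [
            "S1,P1,2005-01-01,??????",
            "S2,P1,2005-01-02,!!!",
            "S3,P2,2005-01-03,G30",
        ])
        with pytest.raises(ConfigurationError, match="rejected"):
            read_events(path)

    def test_custom_columns_and_tsv(self, tmp_path):
        path = tmp_path / "events.tsv"
        path.write_text("pt\tprac\twhen\trc\nS1\tP1\t2005-01-01\tG30\n", encoding="utf-8")
        corpus = read_events(path, {"patient": "pt", "practice": "prac",
                                    "date": "when", "code": "rc"}, sep="\t")
        assert corpus.n_tokens == 1

    def test_write_read_roundtrip(self, tmp_path):
        corpus = make_corpus(["G30", "a1", "68", "G30"])
        path = tmp_path / "out.csv"
        write_events(corpus, path)
        back = read_events(path)
        assert back.df["code"].tolist() == ["G30", "a1", "68", "G30"]


class TestSectionAndPractice:
    def test_filter_section_by_case(self):
        corpus = make_corpus(["G3011", "a111", "68"])
        assert filter_section(corpus, Section.DIAGNOSIS).df["code"].tolist() == ["G3011"]
        assert filter_section(corpus, Section.MEDICATION).df["code"].tolist() == ["a111"]
        assert filter_section(corpus, Section.PROCESS_OF_CARE).df["code"].tolist() == ["68"]

    def test_filter_idempotent(self):
        corpus = make_corpus(["G3011", "a111", "68", "G2"])
        once = filter_section(corpus, Section.DIAGNOSIS)
        twice = filter_section(once, Section.DIAGNOSIS)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_section_partition_conserves_tokens(self, rng):
        codes = list(rng.choice(["G1", "G22", "a9", "b88", "7", "812"], size=200))
        corpus = make_corpus(codes)
        total = sum(
            filter_section(corpus, s).n_tokens for s in Section
        )
        assert total == corpus.n_tokens

    def test_stratify_by_practice(self):
        corpus = make_corpus(["G1", "G2", "G3"], practices=["P1", "P1", "P2"])
        strata = stratify_by_practice(corpus)
        assert {k: v.n_tokens for k, v in strata.items()} == {"P1": 2, "P2": 1}
        # union of strata recovers the corpus
        assert sum(v.n_tokens for v in strata.values()) == corpus.n_tokens

    def test_single_practice_stratum_is_identity(self):
        corpus = make_corpus(["G1", "G2"])
        (stratum,) = stratify_by_practice(corpus).values()
        pd.testing.assert_frame_equal(stratum.df, corpus.df)


class TestFrequencyTable:
    def test_counts_and_views(self):
        corpus = make_corpus(["A1", "A1", "B2"])
        table = build_frequency_table(corpus)
        assert table.counts.to_dict() == {"A1": 2, "B2": 1}
        assert table.rank_frequency.tolist() == [[1, 2], [2, 1]]
        assert sorted(table.freq_sample.tolist()) == [1, 2]

    def test_degenerate_single_type(self):
        table = build_frequency_table(make_corpus(["G1"] * 7))
        assert table.rank_frequency.tolist() == [[1, 7]]
        assert table.freq_sample.tolist() == [7]

    def test_empty_corpus_rejected(self):
        with pytest.raises(EmptyInputError):
            build_frequency_table(make_corpus([]))

    def test_rank_frequency_matches_sort_and_count_oracle(self, rng):
        codes = list(rng.choice(["A", "B", "C", "D", "E1", "F2"], size=300))
        table = build_frequency_table(make_corpus(codes))
        # independent oracle: plain counting and sorting
        from collections import Counter
        oracle = sorted(Counter(codes).values(), reverse=True)
        assert table.rank_frequency[:, 1].tolist() == oracle
        assert table.n_tokens == 300
        assert int(table.counts.sum()) == 300

    def test_zipf_alpha1_top_ratio(self, diagnosis_terminology):
        # f(r) = r^-1 implies f(1)/f(2) = 2, up to sampling error
        from readzipf import SyntheticConfig, sample_zipf_corpus
        cfg = SyntheticConfig(n_types=50, n_tokens=50_000, alpha=1.0, seed=3,
                              depth_rank_correlation=0.0)
        corpus, _ = sample_zipf_corpus(diagnosis_terminology, cfg)
        f = build_frequency_table(corpus).rank_frequency[:, 1]
        assert f[0] / f[1] == pytest.approx(2.0, rel=0.1)


class TestTTR:
    def test_arithmetic(self):
        table = build_frequency_table(make_corpus(["A", "B", "C", "D", "E"] * 40))
        assert type_token_ratio(table) == pytest.approx(2.5)

    def test_all_distinct_bound(self):
        codes = [f"A{i:03d}"[:4] for i in range(50)]
        table = build_frequency_table(make_corpus(codes))
        assert type_token_ratio(table) == pytest.approx(100.0)

    def test_self_concatenation_halves_ttr(self, rng):
        codes = list(rng.choice(["A", "B", "C", "D"], size=40))
        t1 = build_frequency_table(make_corpus(codes))
        t2 = build_frequency_table(make_corpus(codes + codes))
        assert type_token_ratio(t2) == pytest.approx(type_token_ratio(t1) / 2)

    def test_more_repetition_lower_ttr(self, diagnosis_terminology):
        from readzipf import SyntheticConfig, sample_zipf_corpus
        low_rep = SyntheticConfig(n_types=1000, n_tokens=5_000, alpha=1.0, seed=9)
        high_rep = SyntheticConfig(n_types=1000, n_tokens=100_000, alpha=1.0, seed=9)
        ttrs = []
        for cfg in (high_rep, low_rep):
            corpus, _ = sample_zipf_corpus(diagnosis_terminology, cfg)
            ttrs.append(type_token_ratio(build_frequency_table(corpus)))
        assert ttrs[0] < ttrs[1]


class TestDepthProfileAndPareto:
    def test_by_type_vs_by_token(self):
        corpus = make_corpus(["G"] * 9 + ["G3"])
        table = build_frequency_table(corpus)
        by_type = usage_depth_profile(table, "by_type").percent_at_depth
        by_token = usage_depth_profile(table, "by_token").percent_at_depth
        assert by_type[1] == pytest.approx(50.0) and by_type[2] == pytest.approx(50.0)
        assert by_token[1] == pytest.approx(90.0) and by_token[2] == pytest.approx(10.0)

    def test_pareto_hand_counts(self):
        table = build_frequency_table(make_corpus(["A", "B", "C", "C"]))
        curve = pareto_curve(table)  # freq_sample {1,1,2}
        assert curve.x.tolist() == [1, 2]
        assert curve.tail_prob.tolist() == [1.0, pytest.approx(1 / 3)]

    def test_pareto_singleton(self):
        table = build_frequency_table(make_corpus(["A"] * 5))
        curve = pareto_curve(table)
        assert curve.x.tolist() == [5] and curve.tail_prob.tolist() == [1.0]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=30), min_size=1, max_size=40))
    def test_pareto_invariants_vs_recount(self, sample):
        codes = [c for i, k in enumerate(sample) for c in [f"C{i:03d}"[:5]] * k]
        table = build_frequency_table(make_corpus(codes))
        curve = pareto_curve(table)
        assert curve.tail_prob[0] == 1.0
        assert np.all(np.diff(curve.tail_prob) < 0) or len(curve.x) == 1
        assert np.all(curve.tail_prob > 0)
        # brute-force recount oracle
        for x, p in zip(curve.x, curve.tail_prob):
            assert p == pytest.approx(sum(1 for v in sample if v >= x) / len(sample))

    def test_summary(self):
        corpus = make_corpus(["G", "G3", "G3", "G30"])
        s = summarize(corpus)
        assert s.n_tokens == 4 and s.n_types == 3
        assert s.ttr_percent == pytest.approx(75.0)
        assert s.mean_code_depth == pytest.approx(2.0)
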