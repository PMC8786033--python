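"""Record I/O, the topic filtering cascade, and per-record binnings."""

import json
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vaxlens.records import (
    DemographicTable,
    KeywordPattern,
    TweetRecord,
    bin_account_age,
    bin_followers,
    bin_sentiment,
    cascade_from_counts,
    chi_square_compare,
    filter_cascade,
    map_occupation,
    read_records,
    round_percent,
    summarize_demographics,
    write_csv,
    write_jsonl,
)

UTC = timezone.utc


def make_record(i=0, **kw):
    defaults = dict(
        tweet_id=f"t{i}",
        created_at=datetime(2021, 1, 1, 12, tzinfo=UTC),
        lang="en",
        user_type="individual",
        is_covid=True,
        is_vaccine=False,
    )
    defaults.update(kw)
    return TweetRecord(**defaults)


class TestIO:
    def test_jsonl_round_trip(self, tmp_path):
        records = [
            make_record(0, sentiment_polarity=0.3, emotion="joy"),
            make_record(1, user_type="organization", is_vaccine=True),
            make_record(2, gender="female", age_band="19-29", follower_count=42),
        ]
        path = tmp_path / "records.jsonl"
        write_jsonl(records, path)
        loaded, issues = read_records(path)
        assert issues == []
        assert loaded == records

    def test_csv_round_trip_parses_iso_timestamp(self, tmp_path):
        path = tmp_path / "records.csv"
        write_csv([make_record(0)], path)
        loaded, issues = read_records(path, format="csv")
        assert issues == []
        assert loaded[0].created_at.date().isoformat() == "2021-01-01"
        assert loaded[0].created_at.tzinfo is not None

    def test_out_of_range_sentiment_rejected_with_diagnostic(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        rows = [
            {"tweet_id": "a", "created_at": "2021-01-01T00:00:00Z"},
            {"tweet_id": "b", "created_at": "2021-01-01T00:00:00Z", "sentiment_polarity": 1.5},
        ]
        path.write_text("\n".join(json.dumps(r) for r in rows) + "\n")
        loaded, issues = read_records(path)
        assert len(loaded) == 1
        assert len(issues) == 1
        assert issues[0].line == 2
        assert "sentiment_polarity" in issues[0].message

    def test_missing_mandatory_field_rejected(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(json.dumps({"created_at": "2021-01-01T00:00:00Z"}) + "\n")
        loaded, issues = read_records(path)
        assert loaded == [] and "tweet_id" in issues[0].message

    def test_malformed_timestamp_is_record_level_not_fatal(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        rows = [
            {"tweet_id": "a", "created_at": "not-a-date"},
            {"tweet_id": "b", "created_at": "2021-01-01T00:00:00Z"},
        ]
        path.write_text("\n".join(json.dumps(r) for r in rows) + "\n")
        loaded, issues = read_records(path)
        assert [r.tweet_id for r in loaded] == ["b"]
        assert issues[0].line == 1


class TestFilterCascade:
    covid = KeywordPattern.from_terms(["covid", "coronavirus", "#covid19"])
    vaccine = KeywordPattern.from_terms(["vaccine", "vaccination", "pfizer"])

    def test_empty_input(self):
        result = filter_cascade([], self.covid, self.vaccine)
        assert result.stage_counts == (0, 0, 0, 0) and result.retained == []

    def test_hand_enumerated_counts(self):
        records = (
            [make_record(i, lang="es", is_covid=None, is_vaccine=None, text="hola") for i in range(3)]
            + [make_record(i + 3, is_covid=False, is_vaccine=False) for i in range(3)]
            + [make_record(i + 6, is_covid=True, is_vaccine=False) for i in range(3)]
            + [make_record(9, is_covid=True, is_vaccine=True)]
        )
        result = filter_cascade(records, self.covid, self.vaccine)
        assert result.stage_counts == (10, 7, 4, 1)
        assert [r.tweet_id for r in result.retained] == ["t9"]

    def test_text_matching_when_flags_absent(self):
        records = [
            make_record(0, is_covid=None, is_vaccine=None, text="the COVID vaccine works"),
            make_record(1, is_covid=None, is_vaccine=None, text="covid cases are rising"),
            make_record(2, is_covid=None, is_vaccine=None, text="nothing to see"),
        ]
        result = filter_cascade(records, self.covid, self.vaccine)
        assert result.n_covid == 2 and result.n_vaccine == 1

    def test_record_without_text_or_flags_collects_diagnostic(self):
        rec = make_record(0, is_covid=None, is_vaccine=None, text=None)
        result = filter_cascade([rec], self.covid, self.vaccine)
        assert result.retained == [] and len(result.issues) == 1

    def test_stage_counts_monotone_on_random_streams(self, rng):
        records = [
            make_record(
                i,
                lang=rng.choice(["en", "es"]),
                is_covid=bool(rng.random() < 0.5),
                is_vaccine=False,
            )
            for i in range(200)
        ]
        for rec in records:
            if rec.is_covid and rng.random() < 0.3:
                rec.is_vaccine = True
        result = filter_cascade(records, self.covid, self.vaccine)
        n, e, c, v = result.stage_counts
        assert n >= e >= c >= v

    def test_published_cascade_arithmetic(self):
        counts = cascade_from_counts(524_293_459, 512_781_119, 10_314_577)
        assert counts["vaccine"] == 1_197_763

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            cascade_from_counts(100, 150, 10)


class TestMappings:
    @pytest.mark.parametrize(
        "soc,expected",
        [("C2", "OC1"), ("C1", "OC2"), ("C3", "OC2")]
        + [(f"C{i}", "OC3") for i in range(4, 10)],
    )
    def test_occupation_collapse(self, soc, expected):
        assert map_occupation(soc) == expected

    def test_occupation_total_surjective_with_preimage_sizes(self):
        image = {}
        for i in range(1, 10):
            image.setdefault(map_occupation(f"C{i}"), []).append(i)
        assert sorted(len(v) for v in image.values()) == [1, 2, 6]
        assert set(image) == {"OC1", "OC2", "OC3"}

    def test_unknown_code_named_in_error(self):
        with pytest.raises(ValueError, match="C10"):
            map_occupation("C10")

    @pytest.mark.parametrize(
        "polarity,expected",
        [(0.0, "neutral"), (-0.5, "negative"), (0.05, "positive"),
         (-0.05, "negative"), (0.0499, "neutral"), (1.0, "positive"), (-1.0, "negative")],
    )
    def test_sentiment_trichotomy(self, polarity, expected):
        assert bin_sentiment(polarity) == expected

    def test_sentiment_out_of_range(self):
        with pytest.raises(ValueError):
            bin_sentiment(1.2)

    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_sentiment_agrees_with_interval_oracle(self, p):
        oracle = "negative" if p <= -0.05 else ("positive" if p >= 0.05 else "neutral")
        assert bin_sentiment(p) == oracle

    def test_account_age_bands(self):
        tweet = datetime(2021, 1, 1, tzinfo=UTC)
        assert bin_account_age(datetime(2010, 1, 1, tzinfo=UTC), tweet) == ">=10"
        exactly_5 = tweet - timedelta(days=5 * 365.25)
        assert bin_account_age(exactly_5, tweet) == "5-10"
        almost_5 = tweet - timedelta(days=4.99 * 365.25)
        assert bin_account_age(almost_5, tweet) == "<5"

    def test_negative_account_age_rejected(self):
        tweet = datetime(2021, 1, 1, tzinfo=UTC)
        with pytest.raises(ValueError):
            bin_account_age(tweet + timedelta(days=1), tweet)

    @pytest.mark.parametrize("n,expected", [(0, "<500"), (499, "<500"), (500, "500-5000"),
                                            (4999, "500-5000"), (5000, ">=5000")])
    def test_follower_bands(self, n, expected):
        assert bin_followers(n) == expected

    @given(st.integers(min_value=0, max_value=10**9))
    def test_followers_agree_with_interval_oracle(self, n):
        oracle = "<500" if n < 500 else ("500-5000" if n < 5000 else ">=5000")
        assert bin_followers(n) == oracle

    def test_bins_pure_on_random_inputs(self, rng):
        values = rng.integers(0, 10_000, size=10_000)
        first = [bin_followers(int(v)) for v in values]
        second = [bin_followers(int(v)) for v in reversed(values)]
        assert first == list(reversed(second))


class TestDemographics:
    def test_from_counts_reproduces_published_gender_share(self):
        table = DemographicTable.from_counts("gender", {"male": 661_511, "female": 417_594})
        assert table.percents == {"male": 61.30, "female": 38.70}

    def test_single_record_is_100_percent(self):
        table = summarize_demographics([make_record(0, gender="male")], "gender")
        assert table.rows == [("male", 1, 100.00)]

    def test_denominator_excludes_missing_attribute(self):
        records = [
            make_record(0, gender="male"),
            make_record(1, gender="female"),
            make_record(2, user_type="organization"),  # no gender
        ]
        table = summarize_demographics(records, "gender")
        assert table.column_total == 2

    def test_percents_sum_to_100_within_rounding(self):
        counts = {"a": 333, "b": 333, "c": 334}
        table = DemographicTable.from_counts("x", counts)
        assert abs(sum(table.percents.values()) - 100.0) <= 0.05

    def test_round_percent_half_up(self):
        assert round_percent(1, 800) == 0.13  # 0.125 rounds up
        with pytest.raises(ValueError):
            round_percent(1, 0)

    def test_empty_denominator_errors(self):
        with pytest.raises(ValueError):
            summarize_demographics([make_record(0)], "gender")


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        a = DemographicTable.from_counts("g", {"x": 50, "y": 50})
        b = DemographicTable.from_counts("g", {"x": 200, "y": 200})
        stat, df, p = chi_square_compare(a, b)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # counts (10,20 / 20,10): all expected cells are 15, so the
        # statistic is 4 * (10-15)^2 / 15 = 20/3
        a = DemographicTable.from_counts("g", {"x": 10, "y": 20})
        b = DemographicTable.from_counts("g", {"x": 20, "y": 10})
        stat, df, p = chi_square_compare(a, b)
        assert stat == pytest.approx(4 * 25 / 15)
        assert df == 1

    def test_published_gender_composition_differs(self):
        a = DemographicTable.from_counts("gender", {"male": 661_511, "female": 417_594})
        b = DemographicTable.from_counts("gender", {"male": 50_156, "female": 44_404})
        stat, df, p = chi_square_compare(a, b)
        assert p < 0.001

    def test_mismatched_labels_error(self):
        a = DemographicTable.from_counts("g", {"x": 10})
        b = DemographicTable.from_counts("g", {"y": 10})
        with pytest.raises(ValueError, match="labels"):
            chi_square_compare(a, b)


class TestKeywordYaml:
    def test_patterns_load_from_yaml(self, tmp_path):
        path = tmp_path / "keywords.yaml"
        path.write_text(
            "covid:\n  - covid\n  - coronavirus\n"
            "vaccine:\n  terms: [vaccine, pfizer]\n  match_mode: substring\n"
        )
        covid = KeywordPattern.from_yaml(path, "covid")
        vaccine = KeywordPattern.from_yaml(path, "vaccine")
        assert covid.matches("new CoViD wave")
        assert vaccine.match_mode == "substring"
        assert vaccine.matches("getpfizernow")
        with pytest.raises(KeyError):
            KeywordPattern.from_yaml(path, "missing")

    def test_default_lists_are_valid_patterns(self):
        from vaxlens.records import DEFAULT_COVID_TERMS, DEFAULT_VACCINE_TERMS
        covid = KeywordPattern.from_terms(DEFAULT_COVID_TERMS)
        vaccine = KeywordPattern.from_terms(DEFAULT_VACCINE_TERMS)
        assert covid.matches("COVID-19 cases rising")  # hashtag/token match
        assert vaccine.matches("got my #CovidVaccine today")
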