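"""Published aggregate tables from a year-long COVID-19 vaccine tweet study.

These are the aggregate inputs of the observational study the pipeline
re-implements (June 2020 - July 2021, English-language tweets): the topic
filtering cascade stage counts and the demographic composition of the
vaccine-related corpus next to a 100,000-tweet general-content benchmark
drawn at five major vaccine-related events.  Raw tweets are not
redistributable; these summary counts are the only real-data inputs the
package ships and are used to exercise the counting arithmetic.

Note the demographic denominators: gender, age, occupation, account age,
follower number, sentiment class and emotion are tabulated over the
1,079,105 individual-classified, scored tweets, while location uses the
684,275 located tweets and user type the full 1,197,763.
"""

from __future__ import annotations

from .records import DemographicTable

__all__ = [
    "CASCADE_COUNTS",
    "VACCINE_CORPUS_COUNTS",
    "BENCHMARK_CORPUS_COUNTS",
    "vaccine_demographic_table",
    "benchmark_demographic_table",
]

#: aggregate stage counts of the filtering cascade
CASCADE_COUNTS = {
    "collected": 1_449_301_580,  # english + excluded non-English
    "non_english_excluded": 925_008_121,
    "english": 524_293_459,
    "non_covid_excluded": 512_781_119,
    "non_vaccine_excluded": 10_314_577,
    "vaccine_related": 1_197_763,
}

#: per-characteristic group counts of the vaccine-related corpus
VACCINE_CORPUS_COUNTS: dict[str, dict[str, int]] = {
    "user_type": {"individual": 1_079_105, "organization": 118_658},
    "gender": {"male": 661_511, "female": 417_594},
    "age_band": {"<=18": 157_395, "19-29": 254_920, "30-39": 202_451, ">=40": 464_339},
    "occupation_cat": {"OC1": 385_276, "OC2": 347_257, "OC3": 346_572},
    "continent": {
        "North America": 274_565,
        "Europe": 179_683,
        "Asia": 106_713,
        "Africa": 67_805,
        "Oceania": 39_414,
        "South America": 15_794,
        "Antarctica": 301,
    },
    "account_age_band": {"<5": 478_914, "5-10": 349_595, ">=10": 250_596},
    "follower_band": {"<500": 619_808, "500-5000": 368_780, ">=5000": 90_517},
    "sentiment": {"negative": 411_990, "neutral": 292_273, "positive": 374_842},
    "emotion": {
        "fear": 528_667,
        "joy": 313_423,
        "surprise": 153_807,
        "sadness": 42_124,
        "anger": 23_814,
        "disgust": 17_270,
    },
}

#: the same characteristics over the general-content benchmark sample
BENCHMARK_CORPUS_COUNTS: dict[str, dict[str, int]] = {
    "user_type": {"individual": 94_560, "organization": 5_440},
    "gender": {"male": 50_156, "female": 44_404},
    "age_band": {"<=18": 35_036, "19-29": 32_142, "30-39": 11_112, ">=40": 16_270},
    "occupation_cat": {"OC1": 20_102, "OC2": 31_176, "OC3": 43_282},
    "continent": {
        "North America": 21_202,
        "Europe": 13_132,
        "Asia": 12_388,
        "Africa": 7_320,
        "Oceania": 1_250,
        "South America": 1_292,
        "Antarctica": 26,
    },
    "account_age_band": {"<5": 58_341, "5-10": 26_333, ">=10": 9_886},
    "follower_band": {"<500": 55_745, "500-5000": 32_742, ">=5000": 6_073},
    "sentiment": {"negative": 41_555, "neutral": 29_987, "positive": 23_018},
    "emotion": {
        "fear": 21_703,
        "joy": 31_819,
        "surprise": 28_690,
        "sadness": 8_940,
        "anger": 2_570,
        "disgust": 838,
    },
}


def vaccine_demographic_table(characteristic: str) -> DemographicTable:
    """Demographic table of the vaccine-related corpus for one characteristic."""
    return DemographicTable.from_counts(
        characteristic, VACCINE_CORPUS_COUNTS[characteristic]
    )


def benchmark_demographic_table(characteristic: str) -> DemographicTable:
    """Demographic table of the general-content benchmark sample."""
    return DemographicTable.from_counts(
        characteristic, BENCHMARK_CORPUS_COUNTS[characteristic]
    )
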