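"""Bundled case/nest count tables from a published multi-population
shorebird incubation-monitoring study.

The tables transcribe body-text tallies (not per-row table digits, which
are typographically unreliable in the source): 70 uniparental-incubation
cases from 68 nests (14 with a female as the remaining incubator), 55
nests with known outcome (15 hatched, 4 depredated, 36 deserted), 398
monitored nests in total, and 69 cases with a known phase start of which
7 started after the species-typical incubation period had elapsed.
Start-fraction and duration values are synthetic but constrained to the
published medians and ranges (start: median 71%, range 11-155%, filtered
median 70%, range 11-95%; duration: median 3 d, range 1-19 d).  The
per-species outcome split beyond the published totals (e.g. which failed
nests were depredated) is an arbitrary deterministic allocation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: total number of monitored nests of biparental species across all populations
TOTAL_MONITORED_NESTS = 398

# species, population, total monitored nests (best effort), uniparental
# nests, male-only uniparental nests, known-outcome nests, successful nests
_SPECIES_ROWS = [
    ("western_sandpiper", "barrow", 21, 10, 8, 7, 3),
    ("bairds_sandpiper", "barrow", 18, 8, 4, 6, 5),
    ("long_billed_dowitcher", "barrow", 13, 4, 4, 3, 0),
    ("american_golden_plover", "barrow", 23, 6, 4, 4, 0),
    ("semipalmated_sandpiper", "barrow", 183, 36, 31, 31, 4),
    ("black_tailed_godwit", "iceland", 5, 1, 1, 1, 1),
    ("redshank", "netherlands", 4, 2, 2, 2, 2),
    ("dunlin", "barrow", 23, 1, 1, 1, 0),
    ("black_tailed_godwit", "netherlands", 4, 0, 0, 0, 0),
    ("redshank", "iceland", 2, 0, 0, 0, 0),
    ("dunlin", "iceland", 12, 0, 0, 0, 0),
    ("dunlin", "greenland", 2, 0, 0, 0, 0),
    ("little_ringed_plover", "czech_republic", 17, 0, 0, 0, 0),
    ("semipalmated_plover", "barrow", 8, 0, 0, 0, 0),
    ("common_ringed_plover", "iceland", 7, 0, 0, 0, 0),
    ("eurasian_oystercatcher", "iceland", 7, 0, 0, 0, 0),
    ("whimbrel", "iceland", 6, 0, 0, 0, 0),
    ("eurasian_golden_plover", "iceland", 4, 0, 0, 0, 0),
    ("ruddy_turnstone", "barrow", 1, 0, 0, 0, 0),
]

# number of depredated nests among the known-outcome failures, per species
_DEPREDATED = {"semipalmated_sandpiper": 3, "western_sandpiper": 1}

# synthetic start-fraction values (percent of the typical incubation period
# elapsed at phase start) for the 62 cases at or below 100%:
# min 11, max 95, median 70; combined with the 7 late cases the full median
# of all 69 known starts is 71.
_START_LE_100 = sorted(
    [11]
    + list(range(12, 69, 2))  # 29 values 12..68
    + [69]
    + [71, 71, 71, 71]
    + list(range(72, 95))  # 23 values 72..94
    + [88, 90, 92]
    + [95]
)
# the 7 cases that started after the typical incubation period had passed
_START_GT_100 = [103, 110, 118, 125, 133, 144, 155]

# durations in days for the 69 cases with a known duration: median 3, range 1-19
_DURATIONS = (
    [1] * 10 + [2] * 18 + [3] * 12 + [4] * 8 + [5] * 6 + [6] * 4
    + [7] * 3 + [8] * 2 + [10] * 2 + [12, 14, 16, 19]
)


def reference_populations() -> pd.DataFrame:
    """Per-population monitored-nest roster with uniparental tallies."""
    return pd.DataFrame(
        _SPECIES_ROWS,
        columns=[
            "species",
            "population",
            "total_nests",
            "uniparental_nests",
            "male_only_nests",
            "known_outcome_nests",
            "successful_nests",
        ],
    )


def reference_nests() -> pd.DataFrame:
    """One row per uniparentally incubated nest: species, sex, outcome."""
    rows = []
    for species, population, _total, uni, male, known, success in _SPECIES_ROWS:
        if uni == 0:
            continue
        depredated = _DEPREDATED.get(species, 0)
        for i in range(uni):
            sex = "M" if i < male else "F"
            if i < success:
                outcome = "hatched"
            elif i < known:
                outcome = "depredated" if i - success < depredated else "deserted"
            else:
                outcome = "unknown"
            rows.append(
                {
                    "nest_id": f"{species[:4]}_{population[:4]}_{i:02d}",
                    "species": species,
                    "population": population,
                    "sex": sex,
                    "outcome": outcome,
                }
            )
    df = pd.DataFrame(rows)
    assert len(df) == 68
    return df


def reference_cases() -> pd.DataFrame:
    """One row per uniparental-incubation case (70 cases from 68 nests).

    Two nests contribute two cases each (a temporal desertion followed by a
    permanent one); one further nest has a single temporal case.  One case
    has an unknown phase start and duration.
    """
    nests = reference_nests()
    rows = []
    for _, nest in nests.iterrows():
        rows.append(
            {
                "nest_id": nest["nest_id"],
                "case": 1,
                "species": nest["species"],
                "population": nest["population"],
                "sex": nest["sex"],
                "outcome": nest["outcome"],
                "cause": "natural/unknown",
                "temporal": False,
            }
        )
    df = pd.DataFrame(rows).sort_values("nest_id").reset_index(drop=True)

    # two nests with a second (permanent) case; the first case of each is
    # temporal; a third nest has a single temporal case.  One double nest is
    # female so that cases split 14 F / 56 M.
    female_ids = df.loc[df["sex"] == "F", "nest_id"].tolist()
    male_ids = df.loc[df["sex"] == "M", "nest_id"].tolist()
    double_ids = [female_ids[0], male_ids[0]]
    extra = []
    for nid in double_ids:
        base = df[df["nest_id"] == nid].iloc[0].to_dict()
        df.loc[df["nest_id"] == nid, "temporal"] = True
        df.loc[df["nest_id"] == nid, "cause"] = "temporal"
        base.update({"case": 2, "temporal": False, "cause": "natural/unknown"})
        extra.append(base)
    df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    single_temporal = male_ids[1]
    df.loc[(df["nest_id"] == single_temporal) & (df["case"] == 1), ["temporal", "cause"]] = [
        True,
        "temporal",
    ]

    # published cause tallies: 13 post-capture, 3 experimental removals (all
    # from one species), remainder natural (the 3 temporal cases stay as is)
    df = df.sort_values(["species", "nest_id", "case"]).reset_index(drop=True)
    natural = df.index[df["cause"] == "natural/unknown"].tolist()
    removal_idx = [
        i for i in natural if df.loc[i, "species"] == "semipalmated_sandpiper"
    ][:3]
    df.loc[removal_idx, "cause"] = "experimental-removal"
    natural = df.index[df["cause"] == "natural/unknown"].tolist()
    df.loc[natural[:13], "cause"] = "post-capture"

    # start fractions and durations: deterministic assignment; the 7 late
    # (>100%) starts go to deserted-outcome cases, one case lacks both values
    df["start_fraction_pct"] = np.nan
    df["duration_d"] = np.nan
    deserted_idx = df.index[(df["outcome"] == "deserted") & (df["case"] == 1)].tolist()
    late_idx = deserted_idx[:7]
    df.loc[late_idx, "start_fraction_pct"] = _START_GT_100
    unknown_start = df.index[df["outcome"] == "unknown"][0]
    remaining = [i for i in df.index if i not in late_idx and i != unknown_start]
    df.loc[remaining, "start_fraction_pct"] = _START_LE_100
    df.loc[[i for i in df.index if i != unknown_start], "duration_d"] = _DURATIONS

    assert len(df) == 70
    assert (df["sex"] == "F").sum() == 14
    assert df["start_fraction_pct"].notna().sum() == 69
    return df
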