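"""Summary tables, case-level descriptive statistics and actograms.

Percent columns are stored at full precision; :func:`render_percent`
rounds to whole percent for display.  Every emitted table passes a
self-consistency audit (each percentage equals 100 * numerator /
denominator recomputed from the same row).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from unicub.data_model import Dataset, UniparentalPhase, phases_to_frame
from unicub.extraction import IncubationStateSeries
from unicub.synthetic import TruthLedger

SUMMARY_COLUMNS = (
    "species",
    "population",
    "total_nests",
    "uniparental_nests",
    "uniparental_pct",
    "male_only",
    "male_only_pct",
    "known_outcome",
    "successful",
    "successful_pct",
)


def render_percent(value: float) -> int:
    """Round a stored full-precision percentage to whole percent."""
    return int(round(value))


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den else float("nan")


def audit_percentages(df: pd.DataFrame) -> None:
    """Check that each percent column matches its counts; raises on mismatch."""
    checks = [
        ("uniparental_pct", "uniparental_nests", "total_nests"),
        ("male_only_pct", "male_only", "uniparental_nests"),
        ("successful_pct", "successful", "known_outcome"),
    ]
    for pct_col, num_col, den_col in checks:
        if pct_col not in df.columns:
            continue
        for _, row in df.iterrows():
            if row[den_col] == 0:
                if not math.isnan(row[pct_col]):
                    raise AssertionError(f"{pct_col} defined with zero denominator")
                continue
            expect = 100.0 * row[num_col] / row[den_col]
            if not math.isclose(row[pct_col], expect, rel_tol=0, abs_tol=1e-9):
                raise AssertionError(
                    f"{pct_col}={row[pct_col]} inconsistent with "
                    f"100*{row[num_col]}/{row[den_col]}"
                )


def species_summary_table(
    nests: pd.DataFrame,
    cases: Optional[pd.DataFrame] = None,
    total_monitored: Optional[int] = None,
) -> pd.DataFrame:
    """Per species x population uniparental-incubation overview plus an ALL row.

    ``nests`` needs one row per monitored nest with columns ``species``,
    ``population``, ``outcome`` and either a per-nest case flag
    (``uniparental`` bool and ``sex``) or an accompanying ``cases`` table
    (one row per case with ``nest_id``, ``sex``).  Rows are ordered by
    percent of nests with uniparental cases (descending), then by total
    nests; the pooled ALL row uses ``total_monitored`` as its denominator
    when given (the roster can exceed the per-row tallies).
    """
    nests = nests.copy()
    if cases is not None and "uniparental" not in nests.columns:
        case_nests = set(cases["nest_id"])
        nests["uniparental"] = nests["nest_id"].isin(case_nests)
    if "uniparental" not in nests.columns:
        nests["uniparental"] = True  # a table of only uniparental nests

    rows = []
    for (species, population), sub in nests.groupby(["species", "population"], sort=True):
        uni = sub[sub["uniparental"]]
        known = uni[uni["outcome"].isin(["hatched", "depredated", "deserted"])]
        male = int((uni["sex"] == "M").sum()) if "sex" in uni.columns else 0
        rows.append(
            {
                "species": species,
                "population": population,
                "total_nests": len(sub),
                "uniparental_nests": len(uni),
                "uniparental_pct": _pct(len(uni), len(sub)),
                "male_only": male,
                "male_only_pct": _pct(male, len(uni)),
                "known_outcome": len(known),
                "successful": int((known["outcome"] == "hatched").sum()),
                "successful_pct": _pct((known["outcome"] == "hatched").sum(), len(known)),
            }
        )
    table = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    if len(table):
        table = table.sort_values(
            ["uniparental_pct", "total_nests"], ascending=[False, False], na_position="last"
        ).reset_index(drop=True)

    if len(nests):
        uni = nests[nests["uniparental"]]
        known = uni[uni["outcome"].isin(["hatched", "depredated", "deserted"])]
        male = int((uni["sex"] == "M").sum()) if "sex" in nests.columns else 0
        total = int(total_monitored) if total_monitored is not None else len(nests)
        all_row = pd.DataFrame(
            [
                {
                    "species": "ALL",
                    "population": "ALL",
                    "total_nests": total,
                    "uniparental_nests": len(uni),
                    "uniparental_pct": _pct(len(uni), total),
                    "male_only": male,
                    "male_only_pct": _pct(male, len(uni)),
                    "known_outcome": len(known),
                    "successful": int((known["outcome"] == "hatched").sum()),
                    "successful_pct": _pct(
                        (known["outcome"] == "hatched").sum(), len(known)
                    ),
                }
            ]
        )
        body = table.copy()
        audit_percentages(body)
        table = pd.concat([body, all_row], ignore_index=True)
    return table


def outcome_shares(nests: pd.DataFrame) -> dict[str, float]:
    """Outcome percentages among known-outcome uniparental nests."""
    if "uniparental" in nests.columns:
        nests = nests[nests["uniparental"]]
    known = nests[nests["outcome"].isin(["hatched", "depredated", "deserted"])]
    n = len(known)
    return {
        "n_known_outcome": n,
        "hatched_pct": _pct((known["outcome"] == "hatched").sum(), n),
        "deserted_pct": _pct((known["outcome"] == "deserted").sum(), n),
        "depredated_pct": _pct((known["outcome"] == "depredated").sum(), n),
    }


def case_sex_share(cases: pd.DataFrame) -> dict[str, float]:
    """Percent of cases by sex of the remaining (incubating) parent."""
    n = len(cases)
    return {
        "n_cases": n,
        "male_pct": _pct((cases["sex"] == "M").sum(), n),
        "female_pct": _pct((cases["sex"] == "F").sum(), n),
    }


def case_summary_stats(cases: pd.DataFrame) -> dict:
    """Descriptive statistics of phase duration and start fraction.

    Reports medians, ranges and Ns, plus a filtered variant excluding cases
    whose phase started after the typical incubation period (> 100%) and the
    share of cases removed by that filter.
    """
    if len(cases) == 0:
        return {"n_cases": 0, "empty": True}
    dur = cases["duration_d"].dropna()
    start = cases["start_fraction_pct"].dropna()
    late = start[start > 100.0]
    kept = start[start <= 100.0]
    out = {
        "n_cases": len(cases),
        "empty": False,
        "duration": {
            "n": int(dur.size),
            "median_d": float(dur.median()) if dur.size else float("nan"),
            "min_d": float(dur.min()) if dur.size else float("nan"),
            "max_d": float(dur.max()) if dur.size else float("nan"),
        },
        "start_fraction": {
            "n": int(start.size),
            "median_pct": float(start.median()) if start.size else float("nan"),
            "min_pct": float(start.min()) if start.size else float("nan"),
            "max_pct": float(start.max()) if start.size else float("nan"),
        },
        "start_fraction_filtered": {
            "n": int(kept.size),
            "median_pct": float(kept.median()) if kept.size else float("nan"),
            "min_pct": float(kept.min()) if kept.size else float("nan"),
            "max_pct": float(kept.max()) if kept.size else float("nan"),
        },
        "late_start_share_pct": _pct(late.size, start.size),
        "n_late_start": int(late.size),
    }
    return out


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted sample median (averages across an exact half-weight split)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0 or w.sum() <= 0:
        raise ValueError("weighted_median needs non-empty values and positive weights")
    order = np.argsort(v)
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    half = 0.5 * w.sum()
    idx = int(np.searchsorted(cum, half))
    if math.isclose(cum[idx], half, rel_tol=0, abs_tol=1e-12) and idx + 1 < v.size:
        return 0.5 * (v[idx] + v[idx + 1])
    return float(v[idx])


def headline_statistics(
    nests: pd.DataFrame, cases: pd.DataFrame, total_monitored: int
) -> dict[str, float]:
    """The pooled cross-species percentages (full precision).

    Keys: hatched/deserted/depredated shares of known-outcome uniparental
    nests, male share of cases, share of monitored nests with at least one
    case, and share of known-start cases starting after the typical
    incubation period.
    """
    outcomes = outcome_shares(nests)
    sexes = case_sex_share(cases)
    stats = case_summary_stats(cases)
    n_case_nests = cases["nest_id"].nunique()
    return {
        "pct_known_outcome_hatched": outcomes["hatched_pct"],
        "pct_known_outcome_deserted": outcomes["deserted_pct"],
        "pct_known_outcome_depredated": outcomes["depredated_pct"],
        "pct_cases_male": sexes["male_pct"],
        "pct_nests_with_case": _pct(n_case_nests, total_monitored),
        "pct_cases_start_after_period": stats["late_start_share_pct"],
        "n_known_outcome": outcomes["n_known_outcome"],
        "n_cases": sexes["n_cases"],
        "n_case_nests": int(n_case_nests),
        "n_known_start": stats["start_fraction"]["n"],
        "n_monitored": int(total_monitored),
    }


def ledger_summary_inputs(ds: Dataset, ledger: TruthLedger) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build summary-table inputs (nests, cases) from generator truth."""
    nests = []
    for nest_id in ds.nest_ids:
        meta = ds.metadata[nest_id]
        row = ledger.nests[ledger.nests["nest_id"] == nest_id].iloc[0]
        nests.append(
            {
                "nest_id": nest_id,
                "species": meta.species,
                "population": meta.population,
                "outcome": meta.outcome,
                "uniparental": bool(row["deserted"]),
                "sex": row["solo_sex"] if row["deserted"] else None,
            }
        )
    nests_df = pd.DataFrame(nests)
    cases = nests_df[nests_df["uniparental"]][["nest_id", "species", "population", "sex"]]
    return nests_df, cases.reset_index(drop=True)


def render_actogram(
    trace,
    states: IncubationStateSeries,
    phases: Sequence[UniparentalPhase],
    out: Union[str, Path],
    title: Optional[str] = None,
) -> Path:
    """Render a one-row-per-day actogram of one nest's record to ``out``.

    Nest temperature is coloured by attending parent (no incubation /
    female / male), surface temperature is overlaid, and each day row is
    marked as biparental or uniparental depending on phase overlap.
    Deterministic: rendering the same input twice produces identical files.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(states.df) == 0:
        raise ValueError("cannot render an actogram from an empty trace")

    df = states.df.copy()
    df["nest_temp_c"] = trace.rows["nest_temp_c"].to_numpy()
    df["surface_temp_c"] = trace.rows["surface_temp_c"].to_numpy()
    local = pd.DatetimeIndex(df["timestamp_local"])
    df["day"] = local.normalize()
    df["hour"] = local.hour + local.minute / 60.0 + local.second / 3600.0

    phase_frame = phases_to_frame(list(phases)) if phases else None
    days = df["day"].drop_duplicates().tolist()
    colors = {"none": "#e8638f", "F": "#e6b800", "M": "#274370", "unknown": "#888888"}

    fig, axes = plt.subplots(
        len(days), 1, figsize=(10, max(1.2, 0.85 * len(days))), sharex=True, squeeze=False
    )
    for ax, day in zip(axes[:, 0], days):
        sub = df[df["day"] == day]
        ax.plot(sub["hour"], sub["surface_temp_c"], color="#9fd7e8", lw=0.8, zorder=1)
        for key, color in colors.items():
            sel = sub["attending"] == key
            if sel.any():
                ax.scatter(
                    sub.loc[sel, "hour"],
                    sub.loc[sel, "nest_temp_c"],
                    s=1.2,
                    color=color,
                    zorder=2,
                    rasterized=False,
                )
        uniparental_day = False
        if phase_frame is not None:
            day_start, day_end = day, day + pd.Timedelta(days=1)
            for _, p in phase_frame.iterrows():
                if p["start_utc"] < day_end and p["end_utc"] > day_start:
                    uniparental_day = True
        ax.set_facecolor("#f2f2f2" if uniparental_day else "#eef7ee")
        ax.set_ylabel(day.strftime("%m-%d"), rotation=0, ha="right", va="center", fontsize=7)
        ax.set_yticks([])
        ax.set_xlim(0, 24)
    axes[-1, 0].set_xlabel("local solar hour")
    if title:
        axes[0, 0].set_title(title, fontsize=9)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=110, metadata={"Software": "unicub"})
    plt.close(fig)
    return out
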